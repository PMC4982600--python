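"""Synthetic example PWMs for the AP-1 and NF-Y (CCAAT) binding motifs.

These matrices are constructed from the published consensus motifs — AP-1:
TGA(C/G)TCA; NF-Y: the CCAAT box — with moderately degenerate flanks, and are
bundled so the scanning and benchmarking machinery runs out of the box.  They
are synthetic: built here from the consensus, not taken from any curated
matrix library, and their exact frequencies match no database entry.

Counts are per-position base tallies out of 100 over the columns A, C, G, T.
"""

from __future__ import annotations

import numpy as np

from .pwm import PWM

__all__ = ["ap1_pwm", "nfy_pwm", "default_library", "NFY_CORE_OFFSET"]

#: Offset of the first C of the CCAAT core within the NF-Y matrix.
NFY_CORE_OFFSET = 3

# 11 positions: two moderately informative flanks on each side of the
# 7 bp TGA(C/G)TCA core.
_AP1_COUNTS = [
    [65, 8, 19, 8],     # flank, A-leaning
    [8, 12, 12, 68],    # flank, T-leaning
    [2, 2, 2, 94],      # T
    [2, 2, 94, 2],      # G
    [94, 2, 2, 2],      # A
    [1, 49, 49, 1],     # C/G
    [2, 2, 2, 94],      # T
    [2, 94, 2, 2],      # C
    [94, 2, 2, 2],      # A
    [12, 68, 12, 8],    # flank, C-leaning
    [65, 8, 19, 8],     # flank, A-leaning
]

# 11 positions: three informative flanks each side of the CCAAT core, with
# the weak 3' (c/g)a preference of the consensus environment.  The flanks are
# what make the matrix discriminative — the bare pentamer occurs by chance
# roughly once per 250 bp of random sequence.
_NFY_COUNTS = [
    [55, 15, 15, 15],   # flank, A-leaning
    [15, 45, 15, 25],   # flank, C-leaning
    [12, 56, 22, 10],   # flank, C-leaning
    [2, 94, 2, 2],      # C
    [2, 94, 2, 2],      # C
    [94, 2, 2, 2],      # A
    [94, 2, 2, 2],      # A
    [2, 2, 2, 94],      # T
    [10, 42, 38, 10],   # flank, C/G
    [58, 16, 16, 10],   # flank, A-leaning
    [22, 26, 36, 16],   # flank, G-leaning
]


def ap1_pwm(pseudocount: float = 0.0) -> PWM:
    """Synthetic AP-1 matrix (consensus core TGA(C/G)TCA)."""
    return PWM("AP1_SYN", np.array(_AP1_COUNTS, dtype=float), pseudocount, "AP-1 (synthetic)")


def nfy_pwm(pseudocount: float = 0.0) -> PWM:
    """Synthetic NF-Y matrix (consensus core CCAAT)."""
    return PWM("NFY_SYN", np.array(_NFY_COUNTS, dtype=float), pseudocount, "NF-Y (synthetic)")


def default_library(pseudocount: float = 0.0) -> list[PWM]:
    return [ap1_pwm(pseudocount), nfy_pwm(pseudocount)]
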