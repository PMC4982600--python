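"""PWM parsing and MATCH-style scoring against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from motifarch.pwm import (
    PWM,
    MatchConfig,
    best_score,
    core_positions,
    information_vector,
    parse_transfac,
    reverse_complement,
    scan_sequence,
    score_window,
    write_transfac,
)

from conftest import random_dna

TOY_TRANSFAC = """\
ID M_CCAAT
XX
P0      A      C      G      T
01      0     10      0      0
02      0     10      0      0
03     10      0      0      0
04     10      0      0      0
05      0      0      0     10
XX
//
ID M_TAIL
01      1      2      3      4
02      4      3      2      1
"""


class TestParseTransfac:
    def test_pure_ccaat_record(self):
        pwms = parse_transfac(TOY_TRANSFAC)
        assert [p.id for p in pwms] == ["M_CCAAT", "M_TAIL"]
        ccaat = pwms[0]
        assert len(ccaat) == 5
        assert ccaat.consensus == "CCAAT"
        # single-base columns give frequency exactly 1
        assert ccaat.freqs[0, 1] == 1.0

    def test_lenient_tail_record_without_terminator(self):
        tail = parse_transfac(TOY_TRANSFAC)[1]
        assert len(tail) == 2
        np.testing.assert_allclose(tail.freqs.sum(axis=1), 1.0)

    @pytest.mark.parametrize(
        "bad",
        [
            "ID X\n01  1  2  3\n//\n",  # wrong column count
            "ID X\n01  1  a  3  4\n//\n",  # non-numeric
            "ID X\n01  0  0  0  0\n//\n",  # zero row sum
        ],
    )
    def test_malformed_records_rejected(self, bad):
        with pytest.raises(ValueError, match="X"):
            parse_transfac(bad)

    def test_pseudocount_changes_frequencies(self):
        p0 = parse_transfac(TOY_TRANSFAC)[0]
        p1 = parse_transfac(TOY_TRANSFAC, pseudocount=1.0)[0]
        assert p0.freqs[0, 0] == 0.0
        assert p1.freqs[0, 0] == pytest.approx(1 / 14)

    def test_round_trip_through_writer(self, tmp_path, ap1):
        path = tmp_path / "lib.transfac"
        write_transfac([ap1], path)
        back = parse_transfac(path.read_text())
        assert back[0].id == ap1.id
        np.testing.assert_allclose(back[0].counts, ap1.counts, atol=0.01)


class TestInformationVector:
    @pytest.mark.parametrize(
        "freqs, expected",
        [
            ([[0.25, 0.25, 0.25, 0.25]], 0.0),
            ([[1.0, 0.0, 0.0, 0.0]], math.log(4)),
            ([[0.5, 0.5, 0.0, 0.0]], math.log(2)),
        ],
    )
    def test_closed_forms(self, freqs, expected):
        assert information_vector(np.array(freqs))[0] == pytest.approx(expected)


class TestScoreWindow:
    def test_consensus_scores_one(self, nfy):
        assert score_window(nfy, nfy.consensus) == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self, nfy):
        anti = "".join("ACGT"[b] for b in nfy.freqs.argmin(axis=1))
        assert score_window(nfy, anti) == pytest.approx(0.0, abs=1e-12)

    def test_toy_matrix_all_dinucleotides_match_hand_oracle(self):
        # independent literal transcription of the Current/Min/Max formulas
        counts = np.array([[8, 2, 0, 0], [0, 0, 5, 5]], dtype=float)
        pwm = PWM("toy", counts)
        f = counts / counts.sum(axis=1, keepdims=True)
        info = []
        for row in f:
            info.append(sum(x * math.log(4 * x) for x in row if x > 0))
        mx = sum(i * row.max() for i, row in zip(info, f))
        mn = sum(i * row.min() for i, row in zip(info, f))
        for b1 in range(4):
            for b2 in range(4):
                window = "ACGT"[b1] + "ACGT"[b2]
                expected = (info[0] * f[0, b1] + info[1] * f[1, b2] - mn) / (mx - mn)
                assert score_window(pwm, window) == pytest.approx(expected, abs=1e-9)

    def test_random_matrices_match_literal_formula(self, rng):
        """1000 random (matrix, window) pairs against the literal formula."""
        for _ in range(1000):
            L = int(rng.integers(1, 13))
            counts = rng.integers(0, 50, size=(L, 4)).astype(float)
            counts[counts.sum(axis=1) == 0, 0] = 1
            pwm = PWM("r", counts)
            window = "".join("ACGT"[i] for i in rng.integers(0, 4, size=L))
            f = pwm.freqs
            info = [
                sum(x * math.log(4 * x) for x in row if x > 0) for row in f
            ]
            cur = sum(i * f[k, "ACGT".index(b)] for k, (i, b) in enumerate(zip(info, window)))
            mx = sum(i * row.max() for i, row in zip(info, f))
            mn = sum(i * row.min() for i, row in zip(info, f))
            expected = 1.0 if math.isclose(mx, mn) else (cur - mn) / (mx - mn)
            assert score_window(pwm, window) == pytest.approx(expected, abs=1e-9)

    def test_uniform_matrix_scores_one_by_convention(self):
        pwm = PWM("uni", np.full((3, 4), 5.0))
        assert score_window(pwm, "ACG") == 1.0

    def test_length_mismatch_raises(self, nfy):
        with pytest.raises(ValueError):
            score_window(nfy, "ACGT")


class TestScanSequence:
    def test_planted_consensus_found_on_plus_strand(self, ap1, rng):
        seq = random_dna(rng, 7) + ap1.consensus + random_dna(rng, 30)
        hits = [h for h in scan_sequence(ap1, seq, MatchConfig(0.99)) if h.mss > 0.999]
        assert any(h.position == 7 and h.strand == "+" for h in hits)

    def test_planted_reverse_complement_found_on_minus_strand(self, ap1, rng):
        seq = random_dna(rng, 3) + reverse_complement(ap1.consensus) + random_dna(rng, 30)
        hits = [h for h in scan_sequence(ap1, seq, MatchConfig(0.99)) if h.mss > 0.999]
        assert any(h.position == 3 and h.strand == "-" for h in hits)

    def test_matches_brute_force_rescan(self, nfy, rng):
        seq = random_dna(rng, 1000)
        hits = scan_sequence(nfy, seq, MatchConfig(0.8))
        # independent naive scan
        L = len(nfy)
        expected = set()
        for j in range(len(seq) - L + 1):
            w = seq[j : j + L]
            if score_window(nfy, w) >= 0.8:
                expected.add((j, "+"))
            if score_window(nfy, reverse_complement(w)) >= 0.8:
                expected.add((j, "-"))
        assert {(h.position, h.strand) for h in hits} == expected

    def test_short_sequence_yields_no_hits(self, nfy):
        assert scan_sequence(nfy, "ACGT") == []

    def test_threshold_monotonicity(self, nfy, rng):
        seq = random_dna(rng, 2000)
        previous = None
        for thr in (0.5, 0.7, 0.9, 0.99):
            hits = {(h.position, h.strand) for h in scan_sequence(nfy, seq, MatchConfig(thr))}
            if previous is not None:
                assert hits <= previous
            previous = hits

    def test_reverse_complement_mirrors_hits(self, ap1, rng):
        seq = random_dna(rng, 500)
        fwd = scan_sequence(ap1, seq, MatchConfig(0.75))
        rev = scan_sequence(ap1, reverse_complement(seq), MatchConfig(0.75))
        L = len(ap1)
        n = len(seq)
        mirrored = {(n - L - h.position, "-" if h.strand == "+" else "+") for h in rev}
        assert {(h.position, h.strand) for h in fwd} == mirrored


class TestBestScore:
    def test_all_n_sequence_is_unscorable(self, nfy):
        assert best_score(nfy, "N" * 50) is None

    def test_equals_max_over_full_scan(self, nfy, rng):
        seq = random_dna(rng, 400)
        hits = scan_sequence(nfy, seq, MatchConfig(0.0))
        assert best_score(nfy, seq) == pytest.approx(max(h.mss for h in hits))

    def test_planted_consensus_scores_one(self, ap1, rng):
        seq = random_dna(rng, 100) + ap1.consensus + random_dna(rng, 100)
        assert best_score(ap1, seq) == pytest.approx(1.0)


class TestCorePositions:
    def test_explicit_information_profile(self):
        # positions 2..6 fully conserved, rest uniform
        counts = np.full((8, 4), 5.0)
        for i in range(2, 7):
            counts[i] = [20, 0, 0, 0]
        assert core_positions(PWM("c", counts)) == (2, 7)

    def test_uniform_matrix_tie_breaks_to_zero(self):
        assert core_positions(PWM("u", np.full((7, 4), 3.0))) == (0, 5)

    def test_short_matrix_has_no_core(self):
        assert core_positions(PWM("s", np.full((4, 4), 3.0))) is None

    def test_matches_exhaustive_window_search(self, rng):
        for _ in range(25):
            L = int(rng.integers(5, 15))
            counts = rng.integers(1, 30, size=(L, 4)).astype(float)
            pwm = PWM("r", counts)
            sums = [pwm.info[s : s + 5].sum() for s in range(L - 4)]
            assert core_positions(pwm)[0] == int(np.argmax(sums))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.data())
def test_mss_bounded_for_random_matrices_and_windows(data):
    L = data.draw(st.integers(1, 10))
    counts = np.array(
        data.draw(
            st.lists(
                st.lists(st.integers(0, 40), min_size=4, max_size=4),
                min_size=L,
                max_size=L,
            )
        ),
        dtype=float,
    )
    counts[counts.sum(axis=1) == 0, 0] = 1
    window = "".join(
        data.draw(st.lists(st.sampled_from("ACGT"), min_size=L, max_size=L))
    )
    s = score_window(PWM("h", counts), window)
    assert -1e-12 <= s <= 1 + 1e-12
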