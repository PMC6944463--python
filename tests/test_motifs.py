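"""PWM scanning, nearest-motif assignment and information content."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from occuclass.motifs import (
    DEFAULT_TAM_CONSENSUS,
    MotifHit,
    PwmModel,
    build_consensus,
    default_tam_pwm,
    ic_half_contrast,
    nearest_tam,
    reverse_complement,
    scan_pwm,
)

# hand arithmetic: two positions at 0.97 on the consensus base, uniform
# background -> 2 * log2(0.97 / 0.25) bits
TOY_TWO_POS_SCORE = 3.912113304824806


def toy_pwm():
    probs = np.full((2, 4), 0.01).T  # placeholder, replaced below
    probs = np.full((4, 2), 0.01)
    probs[0, 0] = 0.97  # A at position 1
    probs[1, 1] = 0.97  # C at position 2
    return PwmModel(probs)


class TestPwmModel:
    def test_columns_must_sum_to_one(self):
        bad = np.full((4, 3), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            PwmModel(bad)

    def test_consensus_and_max_score(self):
        pwm = default_tam_pwm()
        assert pwm.consensus() == DEFAULT_TAM_CONSENSUS
        assert pwm.width == 22
        assert pwm.max_score == pytest.approx(22 * np.log2(0.91 / 0.25))

    def test_round_trip(self, tmp_path):
        pwm = default_tam_pwm()
        p = tmp_path / "tam.pwm"
        pwm.write(p)
        back = PwmModel.read(p)
        np.testing.assert_allclose(back.probs, pwm.probs, atol=1e-5)


class TestScan:
    def test_toy_score_hand_arithmetic(self):
        hits = scan_pwm("AC", toy_pwm(), min_score=1.0)
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].score == pytest.approx(TOY_TWO_POS_SCORE, abs=1e-9)

    def test_uniform_pwm_scores_zero(self):
        pwm = PwmModel(np.full((4, 3), 0.25))
        hits = scan_pwm("ACGTACG", pwm, min_score=0.0)
        assert len(hits) == 2 * 5  # both strands, every window
        assert all(h.score == 0.0 for h in hits)

    def test_short_sequence_empty(self):
        assert scan_pwm("ACG", default_tam_pwm(), min_score=0) == []

    def test_n_windows_skipped(self):
        pwm = toy_pwm()
        hits = scan_pwm("ANAC", pwm, min_score=-100)
        assert all(h.start != 0 and h.start != 1 for h in hits)

    def test_agrees_with_exhaustive_rescoring(self, rng):
        """Every reported hit and no other window clears the threshold when
        each window is rescored one by one."""
        seq = "".join(rng.choice(list("ACGT"), size=2_000))
        pwm = default_tam_pwm()
        threshold = 0.0
        hits = scan_pwm(seq, pwm, min_score=threshold)
        found = {(h.start, h.strand): h.score for h in hits}
        w = pwm.width
        for pos in range(len(seq) - w + 1):
            window = seq[pos : pos + w]
            for strand, oriented in (("+", window), ("-", reverse_complement(window))):
                score = pwm.score_sequence(oriented)
                if score >= threshold:
                    assert (pos, strand) in found
                    assert found[(pos, strand)] == pytest.approx(score, abs=1e-9)
                else:
                    assert (pos, strand) not in found

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement mirrors positions and keeps scores."""
        seq = "".join(rng.choice(list("ACGT"), size=3_000))
        pwm = default_tam_pwm()
        fwd = scan_pwm(seq, pwm, min_score=5.0)
        rev = scan_pwm(reverse_complement(seq), pwm, min_score=5.0)
        L, w = len(seq), pwm.width

        def key(hits):
            return sorted(
                (h.start, h.strand, round(h.score, 6), h.sequence) for h in hits
            )

        mirrored = [
            MotifHit(h.chrom, L - h.start - w, "+-"[h.strand == "+"], h.score, h.sequence)
            for h in rev
        ]
        assert key(fwd) == key(mirrored)


class TestNearestTam:
    def _hit(self, start, w=22):
        return MotifHit("c", start, "+", 12.0, "A" * w)

    def test_closest_wins(self):
        summit = 5000
        close = self._hit(summit + 150 - 11)
        far = self._hit(summit - 300 - 11)
        best, n = nearest_tam(summit, [far, close], flank=1000)
        assert best is close and n == 2

    def test_empty_window(self):
        best, n = nearest_tam(5000, [self._hit(50_000)], flank=1000)
        assert best is None and n == 0

    def test_tie_breaks_to_lower_coordinate(self):
        summit = 5000
        left = self._hit(summit - 200 - 11)
        right = self._hit(summit + 200 - 11)
        best, n = nearest_tam(summit, [right, left], flank=1000)
        assert best is left and n == 2

    def test_matches_exhaustive_minimization(self, rng):
        for _ in range(100):
            summit = int(rng.integers(2_000, 50_000))
            hits = [self._hit(int(s)) for s in rng.integers(0, 60_000, size=30)]
            best, n = nearest_tam(summit, hits, flank=1000)
            window = [h for h in hits if summit - 1000 <= h.midpoint <= summit + 1000]
            assert n == len(window)
            if window:
                exp = min(window, key=lambda h: (abs(h.midpoint - summit), h.start))
                assert best.start == exp.start
            else:
                assert best is None


class TestConsensus:
    def test_identical_stack_is_two_bits(self):
        pwm, ic = build_consensus(["ACGT"] * 5, pseudocount=0.0)
        np.testing.assert_allclose(ic, 2.0)

    def test_uniform_position_zero_bits(self):
        pwm, ic = build_consensus(["A", "C", "G", "T"], pseudocount=0.0)
        assert ic[0] == pytest.approx(0.0, abs=1e-12)

    def test_three_sequence_toy_stack_hand_computed(self):
        # columns: (A,A,A) -> IC 2; (C,C,T) -> 2 - H(2/3,1/3) = 1.0817042
        pwm, ic = build_consensus(["AC", "AC", "AT"], pseudocount=0.0)
        assert ic[0] == pytest.approx(2.0, abs=1e-12)
        assert ic[1] == pytest.approx(1.0817041659455104, abs=1e-9)

    def test_zero_sequences_error(self):
        with pytest.raises(ValueError, match="zero sequences"):
            build_consensus([])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.text(alphabet="ACGT", min_size=6, max_size=6), min_size=1, max_size=20))
    def test_ic_bounds_property(self, seqs):
        _, ic = build_consensus(seqs)
        assert np.all(ic >= 0.0) and np.all(ic <= 2.0)


class TestIcHalfContrast:
    def test_identity(self):
        pwm = default_tam_pwm()
        out = ic_half_contrast(pwm, pwm)
        assert out["delta_5p"] == 0.0 and out["delta_3p"] == 0.0

    def test_two_bit_vs_uniform(self):
        sharp, _ = build_consensus(["ACGTACGTACGTACGTACGTAC"] * 3, pseudocount=0.0)
        flat = PwmModel(np.full((4, 22), 0.25))
        out = ic_half_contrast(sharp, flat)
        assert out["delta_3p"] == pytest.approx(2.0)
        assert out["delta_5p"] == pytest.approx(2.0)

    def test_width_mismatch(self):
        with pytest.raises(ValueError, match="width"):
            ic_half_contrast(default_tam_pwm(), PwmModel(np.full((4, 10), 0.25)))
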