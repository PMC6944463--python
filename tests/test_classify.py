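"""Peak scores, TSS association and cross-condition categories."""

import numpy as np
import pytest

from occuclass.classify import (
    associate_tss,
    categorize,
    category_counts,
    peak_score,
    score_distribution_export,
    ClassifiedPeak,
)
from occuclass.intervals import GenomicInterval, TssRecord
from occuclass.peaks import Peak


def mk_peak(start, end, pid="p", summit=None, ip=10, inp=5):
    return Peak(pid, GenomicInterval("c", start, end), summit or (start + end) // 2, ip, inp)


class TestPeakScore:
    def test_symmetric_input_is_zero(self):
        assert peak_score(50, 50, 1e6, 1e6, 500) == pytest.approx(0.0)

    def test_direct_arithmetic(self):
        # log2(101/51) with equal totals, any width
        assert peak_score(100, 50, 1e6, 1e6, 500) == pytest.approx(0.9857861407802992)

    def test_width_cancels(self):
        assert peak_score(100, 50, 1e6, 1e6, 500) == pytest.approx(
            peak_score(100, 50, 1e6, 1e6, 2000)
        )

    def test_doubling_input_total_adds_one(self):
        base = peak_score(100, 50, 1e6, 1e6, 500)
        assert peak_score(100, 50, 1e6, 2e6, 500) == pytest.approx(base + 1.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            peak_score(1, 1, 1e6, 1e6, 0)
        with pytest.raises(ValueError):
            peak_score(1, 1, 0, 1e6, 100)

    def test_vectorized(self):
        out = peak_score(np.array([100, 50]), np.array([50, 50]), 1e6, 1e6, 500)
        assert out.shape == (2,)


class TestAssociateTss:
    def _tss(self, pos, gid="g1"):
        return TssRecord(gid, "c", pos)

    def test_window_arithmetic(self):
        # peak [1000,1500), TSS 1700: window [1450,1951) overlaps
        links = associate_tss([mk_peak(1000, 1500)], [self._tss(1700)])
        assert links["p"] == ["g1"]

    def test_boundary_half_open(self):
        # TSS 1750: window [1500, 2001) does not reach into [1000,1500)
        links = associate_tss([mk_peak(1000, 1500)], [self._tss(1750)])
        assert links["p"] == []

    def test_inclusive_upstream_edge(self):
        # TSS 250 downstream of the last peak base (1499): included
        links = associate_tss([mk_peak(1000, 1500)], [self._tss(1749)])
        assert links["p"] == ["g1"]

    def test_multiple_genes_linked_sorted(self):
        links = associate_tss(
            [mk_peak(1000, 1500)],
            [self._tss(1200, "gB"), self._tss(900, "gA"), self._tss(9000, "gC")],
        )
        assert links["p"] == ["gA", "gB"]

    def test_agrees_with_per_base_oracle(self, rng):
        """Association must equal a literal per-base membership check over
        random peak/TSS pairs."""
        flank = 250
        for _ in range(500):
            ps = int(rng.integers(0, 9_000))
            peak = mk_peak(ps, ps + int(rng.integers(1, 600)))
            tss_pos = int(rng.integers(0, 10_000))
            links = associate_tss([peak], [self._tss(tss_pos)], flank=flank)
            brute = any(
                abs(base - tss_pos) <= flank
                for base in range(peak.interval.start, peak.interval.end)
            )
            assert bool(links["p"]) == brute


class TestCategorize:
    def test_mixed_overlap_example(self):
        wt = [mk_peak(100, 200, "w1"), mk_peak(300, 400, "w2")]
        mut = [mk_peak(150, 250, "m1"), mk_peak(500, 600, "m2")]
        out = categorize(wt, mut)
        by_cat = {p.id: p.category for p in out}
        assert by_cat == {"w1": "common", "w2": "F80L_absent", "m2": "F80L_only"}

    def test_identical_sets_all_common(self):
        wt = [mk_peak(100, 200, "w1"), mk_peak(300, 400, "w2")]
        mut = [mk_peak(100, 200, "m1"), mk_peak(300, 400, "m2")]
        out = categorize(wt, mut)
        counts = category_counts(out)
        assert counts == {"common": 2, "F80L_absent": 0, "F80L_only": 0}

    def test_wt_partition_identity_on_random_inputs(self, rng):
        """|common| + |F80L_absent| = |WT| holds on every input."""
        for _ in range(20):
            wt = [
                mk_peak(int(s) * 4, int(s) * 4 + int(rng.integers(50, 200)), f"w{i}")
                for i, s in enumerate(np.sort(rng.choice(50_000, size=15, replace=False)))
            ]
            mut = [
                mk_peak(int(s) * 4, int(s) * 4 + int(rng.integers(50, 200)), f"m{i}")
                for i, s in enumerate(np.sort(rng.choice(50_000, size=10, replace=False)))
            ]
            c = category_counts(categorize(wt, mut))
            assert c["common"] + c["F80L_absent"] == len(wt)

    def test_mut_partition_identity_when_one_to_one(self):
        """|common| + |F80L_only| = |MUT| when every overlap is one-to-one."""
        wt = [mk_peak(100, 200, "w1"), mk_peak(1000, 1100, "w2")]
        mut = [mk_peak(150, 260, "m1"), mk_peak(5000, 5100, "m2"), mk_peak(7000, 7050, "m3")]
        c = category_counts(categorize(wt, mut))
        assert c["common"] + c["F80L_only"] == len(mut)

    def test_many_to_one_collapses_to_wt_record(self):
        wt = [mk_peak(100, 500, "w1")]
        mut = [mk_peak(120, 180, "m1"), mk_peak(300, 350, "m2")]
        out = categorize(wt, mut)
        assert len(out) == 1
        assert out[0].category == "common"
        assert out[0].matched_peak_ids == ["m1", "m2"]


class TestScoreDistribution:
    def test_single_peak_rows(self):
        p = ClassifiedPeak(
            "p1", GenomicInterval("c", 0, 100), 50, "common", score_wt=1.0, score_mut=0.5
        )
        df = score_distribution_export([p])
        assert len(df) == 2
        assert set(df.condition) == {"WT", "MUT"}

    def test_empty_input_ok(self):
        df = score_distribution_export([])
        assert len(df) == 0

    def test_common_scores_exceed_absent_scores_on_synthetic_data(self, pipeline_result):
        """The WT score distribution of retained (common) peaks sits above the
        F80L-absent one, mirroring weaker binding at lost sites."""
        df = score_distribution_export(pipeline_result.classified)
        wt = df[df.condition == "WT"]
        med_common = wt[wt.category == "common"].score.median()
        med_absent = wt[wt.category == "F80L_absent"].score.median()
        assert med_common > med_absent

    def test_absent_class_enriched_for_weak_3prime_sites(self, pipeline_result):
        """One-sided rank test on truth s3: F80L-absent peaks cover sites with
        lower 3'-half scores than common peaks."""
        from scipy.stats import mannwhitneyu

        sites = pipeline_result.dataset.truth.sites.dropna(subset=["s3"])
        by_cat = {"common": [], "F80L_absent": []}
        for p in pipeline_result.classified:
            if p.category not in by_cat:
                continue
            cover = sites[(sites.pos < p.interval.end) & (sites.end > p.interval.start)]
            by_cat[p.category].extend(cover.s3.tolist())
        stat = mannwhitneyu(by_cat["F80L_absent"], by_cat["common"], alternative="less")
        assert stat.pvalue < 1e-6
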