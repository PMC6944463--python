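"""Ground-truth generator: determinism, occupancy model, count moments."""

import numpy as np
import pytest

from occuclass.motifs import HALF_SPLIT, default_tam_pwm
from occuclass.simulate import (
    SyntheticConfig,
    generate_genome,
    read_genome_fasta,
    simulate_chip_counts,
    simulate_rna_counts,
    write_genome_fasta,
)


def small_config(**kw):
    base = dict(
        genome_length=300_000,
        n_genes=60,
        n_bound_promoters=30,
        n_direct_down=10,
        n_indirect=8,
        n_silent=5,
        depth_ip=200_000,
        depth_input=200_000,
        seed=3,
    )
    base.update(kw)
    return SyntheticConfig(**base)


class TestGenerateGenome:
    def test_deterministic_under_fixed_seed(self):
        d1 = generate_genome(small_config())
        d2 = generate_genome(small_config())
        assert d1.genome == d2.genome
        assert d1.truth.sites.equals(d2.truth.sites)
        assert d1.truth.genes.equals(d2.truth.genes)
        assert d1.tss == d2.tss

    def test_seed_changes_output(self):
        d1 = generate_genome(small_config(seed=3))
        d2 = generate_genome(small_config(seed=4))
        assert d1.genome != d2.genome

    def test_null_planting(self):
        ds = generate_genome(small_config(n_bound_promoters=0))
        assert len(ds.truth.sites) == 0

    def test_tss_spacing_respected(self):
        ds = generate_genome(small_config())
        pos = sorted(t.tss for t in ds.tss)
        assert min(b - a for a, b in zip(pos, pos[1:])) >= 2000

    def test_planted_motifs_present_in_genome(self):
        ds = generate_genome(small_config())
        seq = ds.genome[ds.truth.config.chrom_name]
        for row in ds.truth.sites.itertuples():
            if row.strength != "none":
                assert seq[row.pos : row.end] == row.sequence

    def test_weak_sites_have_lower_3prime_scores(self):
        """Rescoring the planted sequences against the generator PWM must put
        weak 3'-half scores below strong ones; 5' halves stay comparable."""
        ds = generate_genome(small_config(n_bound_promoters=30, seed=9))
        sites = ds.truth.sites
        pwm = default_tam_pwm()
        lo = pwm.log_odds
        best = lo.max(axis=0)

        def rescored_s3(seq):  # independent rescoring oracle
            idx = ["ACGT".index(b) for b in seq]
            return sum(lo[c, j] - best[j] for j, c in enumerate(idx) if j >= HALF_SPLIT)

        weak = sites[sites.strength == "weak"]
        strong = sites[sites.strength == "strong"]
        s3_weak = [rescored_s3(s) for s in weak.sequence]
        s3_strong = [rescored_s3(s) for s in strong.sequence]
        assert np.mean(s3_weak) < np.mean(s3_strong)
        np.testing.assert_allclose(s3_weak, weak.s3.to_numpy(), atol=1e-9)

    def test_occupancy_ordering_invariant(self):
        """With delta <= 1 and a3_mut >= a3_wt, mutant occupancy never exceeds
        wild-type occupancy at any site."""
        for seed in (1, 2):
            ds = generate_genome(small_config(seed=seed))
            s = ds.truth.sites
            assert (s.occupancy_mut <= s.occupancy_wt + 1e-12).all()

    def test_parameter_identity(self):
        """delta=1 with equal 3'-half sensitivities makes the two conditions'
        occupancies identical at every motif site."""
        cfg = small_config(delta=1.0, a3_mut=0.25, a3_wt=0.25, frac_motifless=0.0)
        s = generate_genome(cfg).truth.sites
        np.testing.assert_allclose(s.occupancy_wt, s.occupancy_mut, atol=1e-12)

    def test_gene_labels_partition(self):
        genes = generate_genome(small_config()).truth.genes
        assert set(genes.label) <= {"direct", "indirect", "null"}
        assert genes.gene_id.is_unique

    def test_fasta_round_trip(self, tmp_path):
        ds = generate_genome(small_config())
        p = tmp_path / "genome.fa"
        write_genome_fasta(p, ds.genome)
        assert read_genome_fasta(p) == ds.genome

    def test_genome_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            SyntheticConfig(genome_length=10_000, n_genes=300).validate()


class TestChipCounts:
    def test_deterministic(self):
        ds = generate_genome(small_config())
        b1 = simulate_chip_counts(ds.truth, "WT")
        b2 = simulate_chip_counts(ds.truth, "WT")
        assert b1.equals(b2)

    def test_unknown_condition(self):
        ds = generate_genome(small_config())
        with pytest.raises(ValueError, match="condition"):
            simulate_chip_counts(ds.truth, "HET")

    def test_no_enrichment_limit(self):
        """With no planted occupancy, IP and input bin means agree within
        Monte-Carlo error."""
        ratios = []
        for seed in range(10):
            ds = generate_genome(small_config(n_bound_promoters=0, seed=seed))
            bins = simulate_chip_counts(ds.truth, "WT")
            ratios.append(bins.ip_count.mean() / bins.input_count.mean())
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.01)

    def test_site_bins_enriched_in_wt(self):
        ds = generate_genome(small_config())
        bins = simulate_chip_counts(ds.truth, "WT")
        strong = ds.truth.sites[ds.truth.sites.occupancy_wt > 0.7]
        bw = ds.truth.config.bin_width
        site_bins = bins.iloc[[int(p // bw) for p in strong.pos]]
        assert site_bins.ip_count.mean() > 3 * bins.input_count.mean()

    def test_weak_3prime_sites_lose_mutant_occupancy(self):
        """Directly from the stated logistic model: mean mutant occupancy over
        weak-3' sites sits below that of strong-3' sites."""
        s = generate_genome(small_config()).truth.sites
        weak = s[s.strength == "weak"].occupancy_mut.mean()
        strong = s[s.strength == "strong"].occupancy_mut.mean()
        assert weak < strong


class TestRnaCounts:
    def test_null_effect_centers_at_zero(self):
        cfg = small_config(effect_log2fc=0.0, n_indirect=0)
        ds = generate_genome(cfg)
        counts = simulate_rna_counts(ds.truth)
        expressed = counts[counts.sum(axis=1) > 50]
        lfc = np.log2(expressed[["MUT_1", "MUT_2"]].mean(axis=1) + 0.5) - np.log2(
            expressed[["WT_1", "WT_2"]].mean(axis=1) + 0.5
        )
        assert abs(lfc.mean()) < 0.05

    def test_poisson_limit_variance_over_mean(self):
        """As NB dispersion -> 0 the per-gene variance/mean ratio -> 1
        (moment check over 200 genes x 40 replicates)."""
        cfg = small_config(
            genome_length=1_000_000,
            n_genes=200,
            n_bound_promoters=0,
            n_silent=0,
            n_indirect=0,
            nb_dispersion=1e-9,
            n_replicates=40,
        )
        ds = generate_genome(cfg)
        counts = simulate_rna_counts(ds.truth)
        wt = counts[[c for c in counts.columns if c.startswith("WT")]]
        ratio = (wt.var(axis=1, ddof=1) / wt.mean(axis=1)).replace([np.inf], np.nan).dropna()
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_full_loss_effect_recovers_minus_one(self):
        """Direct-down genes with complete occupancy loss and a 1-unit effect
        show an empirical mean log2FC of ~ -1 (Monte-Carlo band)."""
        cfg = small_config(
            effect_log2fc=1.0,
            frac_motifless=1.0,  # motifless sites lose everything in the mutant
            n_direct_down=30,
            n_replicates=10,
            n_indirect=0,
        )
        ds = generate_genome(cfg)
        counts = simulate_rna_counts(ds.truth)
        direct = ds.truth.genes[ds.truth.genes.label == "direct"].gene_id
        sub = counts.loc[direct]
        wt_cols = [c for c in counts.columns if c.startswith("WT")]
        mut_cols = [c for c in counts.columns if c.startswith("MUT")]
        lfc = np.log2(sub[mut_cols].mean(axis=1)) - np.log2(sub[wt_cols].mean(axis=1))
        assert lfc.mean() == pytest.approx(-1.0, abs=0.08)

    def test_deterministic(self):
        ds = generate_genome(small_config())
        assert simulate_rna_counts(ds.truth).equals(simulate_rna_counts(ds.truth))
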