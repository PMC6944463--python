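"""End-to-end orchestration: simulate -> call peaks -> classify -> motif ->
express -> direct targets, plus the master-table/summary exports and the
deterministic supplementary-table counting used for headline numbers.

A *direct target* is a gene whose expression changes in the mutant and whose
promoter (TSS +/- 250 bp) carries a wild-type peak lost in the mutant
(category ``F80L_absent``).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classify as _classify
from . import expression as _expression
from . import motifs as _motifs
from . import peaks as _peaks
from . import simulate as _simulate
from .classify import CATEGORIES, ClassifiedPeak
from .intervals import COORDINATE_HEADER, TssRecord

# Genome-wide TAM scan threshold used by the pipeline (log2-odds bits).
# Degraded 3'-half instances of the shipped 22-bp PWM still clear 10 bits,
# while a random 22-mer needs >= 16/22 consensus matches to reach it
# (binomial tail ~ 3e-6 per window, i.e. ~a dozen chance hits in 2 Mb).
TAM_SCAN_MIN_BITS = 10.0


@dataclass
class PipelineResult:
    """Everything one pipeline run computes, kept in memory."""

    config: _simulate.SyntheticConfig
    dataset: _simulate.SyntheticDataset
    wt_bins: pd.DataFrame
    mut_bins: pd.DataFrame
    wt_bin_tests: pd.DataFrame
    mut_bin_tests: pd.DataFrame
    wt_peaks: list
    mut_peaks: list
    classified: list[ClassifiedPeak]
    motif_hits: list
    nearest_by_peak: dict[str, tuple]
    consensus: dict[str, tuple]
    ic_contrast: dict[str, float] | None
    expression: pd.DataFrame
    direct_targets: pd.DataFrame
    master_table: pd.DataFrame = field(default=None)
    summary: dict = field(default_factory=dict)


def run_pipeline(
    config: _simulate.SyntheticConfig | None = None,
    fdr: float = 0.05,
    max_gap: int = 0,
    tss_flank: int = 250,
    motif_flank: int = 1000,
    consensus_flank: int = 250,
    min_score: float = TAM_SCAN_MIN_BITS,
) -> PipelineResult:
    """Run the full synthetic analysis at the configured study conditions."""
    config = config or _simulate.SyntheticConfig()
    dataset = _simulate.generate_genome(config)
    truth = dataset.truth

    wt_bins = _simulate.simulate_chip_counts(truth, "WT", config)
    mut_bins = _simulate.simulate_chip_counts(truth, "MUT", config)

    wt_tests = _peaks.bin_enrichment(wt_bins, fdr=fdr)
    mut_tests = _peaks.bin_enrichment(mut_bins, fdr=fdr)
    wt_tests.attrs.update(wt_bins.attrs)
    mut_tests.attrs.update(mut_bins.attrs)
    wt_peaks = _peaks.assemble_peaks(wt_tests, max_gap=max_gap, id_prefix="wt")
    mut_peaks = _peaks.assemble_peaks(mut_tests, max_gap=max_gap, id_prefix="mut")

    classified = _classify.categorize(wt_peaks, mut_peaks)
    _classify.fill_condition_counts(classified, wt_bins, mut_bins)
    _classify.apply_tss_links(classified, dataset.tss, flank=tss_flank)

    # genome-wide TAM scan with the shipped analysis PWM
    pwm = _motifs.default_tam_pwm(config.motif_match_prob)
    chrom = config.chrom_name
    hits = _motifs.scan_pwm(dataset.genome[chrom], pwm, min_score=min_score, chrom=chrom)
    nearest: dict[str, tuple] = {
        p.id: _motifs.nearest_tam(p.summit, hits, flank=motif_flank) for p in classified
    }

    consensus: dict[str, tuple] = {}
    for cat in ("common", "F80L_absent"):
        seqs = []
        for p in classified:
            if p.category != cat or not p.tss_associated:
                continue
            hit, _ = _motifs.nearest_tam(p.summit, hits, flank=consensus_flank)
            if hit is not None:
                seqs.append(hit.sequence)
        if seqs:
            consensus[cat] = _motifs.build_consensus(seqs)
    ic_contrast = None
    if "common" in consensus and "F80L_absent" in consensus:
        ic_contrast = _motifs.ic_half_contrast(
            consensus["common"][0], consensus["F80L_absent"][0]
        )

    counts = _simulate.simulate_rna_counts(truth, config)
    lengths = pd.Series(
        {t.gene_id: t.exonic_length for t in dataset.tss}, name="exonic_length"
    )
    gene_types = pd.Series({t.gene_id: t.gene_type for t in dataset.tss})
    expression = _expression.expression_pipeline(counts, lengths, gene_types=gene_types)

    direct = call_direct_targets(classified, expression)

    result = PipelineResult(
        config=config,
        dataset=dataset,
        wt_bins=wt_bins,
        mut_bins=mut_bins,
        wt_bin_tests=wt_tests,
        mut_bin_tests=mut_tests,
        wt_peaks=wt_peaks,
        mut_peaks=mut_peaks,
        classified=classified,
        motif_hits=hits,
        nearest_by_peak=nearest,
        consensus=consensus,
        ic_contrast=ic_contrast,
        expression=expression,
        direct_targets=direct,
    )
    result.master_table = build_master_table(result)
    result.summary = summarize(result)
    return result


def call_direct_targets(
    classified: list[ClassifiedPeak],
    expression: pd.DataFrame,
    require_all_lost: bool = False,
) -> pd.DataFrame:
    """Changing genes linked (TSS +/- 250 bp) to a TSS-associated
    ``F80L_absent`` peak, ranked within direction by |log2fc| (descending,
    gene id breaking ties).

    ``require_all_lost`` additionally demands that *every* promoter peak
    linked to the gene is F80L_absent (a gene with both a retained and a lost
    promoter peak is then excluded).
    """
    lost_link: dict[str, list[str]] = {}
    kept_link: set[str] = set()
    for p in classified:
        if not p.tss_associated:
            continue
        for g in p.linked_genes:
            if p.category == "F80L_absent":
                lost_link.setdefault(g, []).append(p.id)
            else:
                kept_link.add(g)

    changing = expression[expression["status"].isin(["up", "down"])]
    rows = []
    for gene_id, row in changing.iterrows():
        if gene_id not in lost_link:
            continue
        if require_all_lost and gene_id in kept_link:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "direction": row["status"],
                "log2fc": row["log2fc"],
                "adj_p": row["adj_p"],
                "peak_id": sorted(lost_link[gene_id])[0],
                "n_lost_peaks": len(lost_link[gene_id]),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene_id", "direction", "log2fc", "adj_p", "peak_id", "n_lost_peaks"]
    )
    if len(df):
        df["abs_lfc"] = df["log2fc"].abs()
        df = (
            df.sort_values(
                ["direction", "abs_lfc", "gene_id"], ascending=[True, False, True]
            )
            .drop(columns="abs_lfc")
            .reset_index(drop=True)
        )
    return df


MASTER_COLUMNS = [
    "peak_id", "category", "chrom", "start", "end", "summit",
    "score_wt", "score_mut", "ip_wt", "input_wt", "ip_mut", "input_mut",
    "tss_associated", "n_tss_genes", "linked_genes", "n_tams",
    "tam_start", "tam_end", "tam_strand", "tam_score", "tam_sequence",
    "tam_offset", "gene_log2fc", "gene_adj_p", "gene_status",
]


def build_master_table(result: PipelineResult) -> pd.DataFrame:
    """One row per classified peak: coordinates, category, per-condition
    counts/scores, motif assignment, and the linked genes' expression calls."""
    expr = result.expression
    rows = []
    for p in result.classified:
        hit, n_tams = result.nearest_by_peak.get(p.id, (None, 0))
        genes = ",".join(p.linked_genes) if p.linked_genes else ""
        g0 = p.linked_genes[0] if p.linked_genes else None
        erow = expr.loc[g0] if g0 is not None and g0 in expr.index else None
        rows.append(
            {
                "peak_id": p.id,
                "category": p.category,
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "summit": p.summit,
                "score_wt": p.score_wt,
                "score_mut": p.score_mut,
                "ip_wt": p.ip_wt,
                "input_wt": p.input_wt,
                "ip_mut": p.ip_mut,
                "input_mut": p.input_mut,
                "tss_associated": p.tss_associated,
                "n_tss_genes": len(p.linked_genes),
                "linked_genes": genes,
                "n_tams": n_tams,
                "tam_start": hit.start if hit else pd.NA,
                "tam_end": hit.end if hit else pd.NA,
                "tam_strand": hit.strand if hit else "",
                "tam_score": hit.score if hit else np.nan,
                "tam_sequence": hit.sequence if hit else "",
                "tam_offset": (hit.midpoint - p.summit) if hit else np.nan,
                "gene_log2fc": erow["log2fc"] if erow is not None else np.nan,
                "gene_adj_p": erow["adj_p"] if erow is not None else np.nan,
                "gene_status": erow["status"] if erow is not None else "",
            }
        )
    return pd.DataFrame(rows, columns=MASTER_COLUMNS)


def summarize(result: PipelineResult) -> dict:
    """Headline numbers of a run; every figure the acceptance suite inspects."""
    cls = result.classified
    all_counts = _classify.category_counts(cls, tss_only=False)
    tss_counts = _classify.category_counts(cls, tss_only=True)
    status = result.expression["status"]

    absent_tss = [p for p in cls if p.category == "F80L_absent" and p.tss_associated]
    common_tss = [p for p in cls if p.category == "common" and p.tss_associated]

    def _tam_absent_frac(peaks):
        if not peaks:
            return float("nan")
        n0 = sum(1 for p in peaks if result.nearest_by_peak[p.id][1] == 0)
        return n0 / len(peaks)

    direct = result.direct_targets
    summary = {
        "wt_peak_count": all_counts["common"] + all_counts["F80L_absent"],
        "mut_peak_count": all_counts["common"] + all_counts["F80L_only"],
        "category_counts": all_counts,
        "tss_category_counts": tss_counts,
        "tss_associated_wt": tss_counts["common"] + tss_counts["F80L_absent"],
        "tam_absent_fraction_f80l_absent": _tam_absent_frac(absent_tss),
        "tam_absent_fraction_common": _tam_absent_frac(common_tss),
        "expressed_genes": int((status != "not_expressed").sum()),
        "down_genes": int((status == "down").sum()),
        "up_genes": int((status == "up").sum()),
        "direct_targets_down": int((direct["direction"] == "down").sum()) if len(direct) else 0,
        "direct_targets_up": int((direct["direction"] == "up").sum()) if len(direct) else 0,
    }
    if result.ic_contrast:
        summary["ic_delta_5p"] = result.ic_contrast["delta_5p"]
        summary["ic_delta_3p"] = result.ic_contrast["delta_3p"]
    return summary


def recovery_metrics(result: PipelineResult) -> dict:
    """Truth-aware recovery figures for the synthetic run.

    - lost-site recovery: fraction of sites solidly bound in WT whose mutant
      occupancy is clearly below the calling threshold (truth ``below_call``)
      that are overlapped by a peak classified F80L_absent;
    - high-occupancy WT coverage: fraction of sites with WT occupancy >= 0.5
      covered by any WT peak;
    - direct-target precision/recall for the down direction against genes
      labeled direct whose site is truth-lost (>= 90% occupancy loss).
    """
    truth = result.dataset.truth
    sites = truth.sites

    def _covered(site, peaks_list) -> bool:
        return any(
            p.interval.start < site.end and site.pos < p.interval.end
            for p in peaks_list
        )

    below = truth.below_call_sites()
    lost = truth.lost_sites()
    absent_peaks = [p for p in result.classified if p.category == "F80L_absent"]
    n_rec = sum(1 for s in below.itertuples() if _covered(s, absent_peaks))

    high = sites[sites["occupancy_wt"] >= _simulate.OCC_HIGH_MIN]
    n_cov = sum(1 for s in high.itertuples() if _covered(s, result.wt_peaks))

    truth_direct = set(
        truth.genes.loc[truth.genes["label"] == "direct", "gene_id"]
    ) & set(lost["gene_id"])
    called = result.direct_targets
    called_down = (
        set(called.loc[called["direction"] == "down", "gene_id"]) if len(called) else set()
    )
    tp = len(called_down & truth_direct)
    precision = tp / len(called_down) if called_down else float("nan")
    recall = tp / len(truth_direct) if truth_direct else float("nan")

    return {
        "n_below_call_sites": int(len(below)),
        "lost_site_recovery": n_rec / len(below) if len(below) else float("nan"),
        "n_lost_sites": int(len(lost)),
        "n_high_occupancy_sites": int(len(high)),
        "high_occupancy_coverage": n_cov / len(high) if len(high) else float("nan"),
        "n_truth_direct_down": len(truth_direct),
        "n_called_direct_down": len(called_down),
        "direct_target_precision": precision,
        "direct_target_recall": recall,
    }


def export_all(result: PipelineResult, outdir) -> None:
    """Write the master table, expression table, score table, truth tables,
    peak calls and summary JSON; byte-identical across reruns of one config."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "master_peaks.tsv"), "w") as fh:
        fh.write(COORDINATE_HEADER + "\n")
        result.master_table.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    result.expression.to_csv(
        os.path.join(outdir, "expression.tsv"), sep="\t", float_format="%.6g"
    )
    score_tab = _classify.score_distribution_export(result.classified)
    score_tab.to_csv(
        os.path.join(outdir, "peak_scores.tsv"), sep="\t", index=False, float_format="%.6g"
    )
    result.direct_targets.to_csv(
        os.path.join(outdir, "direct_targets.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )
    _peaks.write_narrowpeak(os.path.join(outdir, "wt_peaks.narrowPeak"), result.wt_peaks)
    _peaks.write_narrowpeak(os.path.join(outdir, "mut_peaks.narrowPeak"), result.mut_peaks)
    _simulate.write_truth_tables(outdir, result.dataset.truth)
    summary = dict(result.summary)
    summary.update(recovery_metrics(result))
    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Supplementary-table counting
# ---------------------------------------------------------------------------

PEAK_TABLE_REQUIRED = ["peak_id", "category", "n_tss_genes", "n_tams"]
GENE_TABLE_REQUIRED = ["gene_id", "log2fc", "adj_p"]


def acceptance_from_supplementary(
    peak_table: pd.DataFrame,
    gene_table: pd.DataFrame,
    fc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> dict:
    """Recompute headline counts from exported per-peak and per-gene tables.

    ``peak_table`` needs columns peak_id, category (common / F80L_absent /
    F80L_only; spaces and hyphens in labels are normalized), n_tss_genes,
    n_tams, and optionally gene_status for direct-target counting.
    ``gene_table`` needs gene_id, log2fc, adj_p.
    """
    miss1 = [c for c in PEAK_TABLE_REQUIRED if c not in peak_table.columns]
    miss5 = [c for c in GENE_TABLE_REQUIRED if c not in gene_table.columns]
    if miss1 or miss5:
        raise ValueError(
            "supplementary schema error; missing peak-table columns "
            f"{miss1}, gene-table columns {miss5}"
        )
    cat = (
        peak_table["category"]
        .astype(str)
        .str.strip()
        .str.replace(" ", "_")
        .str.replace("-", "_")
    )
    unknown = set(cat.unique()) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown peak categories: {sorted(unknown)}")

    cat_counts = {c: int((cat == c).sum()) for c in CATEGORIES}
    tss = peak_table["n_tss_genes"].fillna(0).astype(int) > 0
    tss_counts = {c: int(((cat == c) & tss).sum()) for c in CATEGORIES}

    absent_tss = (cat == "F80L_absent") & tss
    n_absent = int(absent_tss.sum())
    tam_absent = int((peak_table.loc[absent_tss, "n_tams"].fillna(0).astype(int) == 0).sum())

    lfc = pd.to_numeric(gene_table["log2fc"], errors="coerce")
    ap = pd.to_numeric(gene_table["adj_p"], errors="coerce")
    down = int(((lfc <= -fc_threshold) & (ap <= alpha)).sum())
    up = int(((lfc >= fc_threshold) & (ap <= alpha)).sum())

    out = {
        "peaks_total_wt": cat_counts["common"] + cat_counts["F80L_absent"],
        "peaks_total_mut": cat_counts["common"] + cat_counts["F80L_only"],
        "category_counts": cat_counts,
        "tss_category_counts": tss_counts,
        "tam_absent_fraction_f80l_absent": (tam_absent / n_absent) if n_absent else float("nan"),
        "down_genes": down,
        "up_genes": up,
    }
    if "gene_status" in peak_table.columns:
        direct = peak_table.loc[absent_tss & peak_table["gene_status"].isin(["up", "down"])]
        out["direct_targets_down"] = int((direct["gene_status"] == "down").sum())
        out["direct_targets_up"] = int((direct["gene_status"] == "up").sum())
    return out
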