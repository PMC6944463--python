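"""Peak scoring, TSS association and cross-condition peak categories.

Peaks called in the two conditions are matched by any-overlap and assigned to
three categories: ``common`` (present in both), ``F80L_absent`` (present in
wild type only) and ``F80L_only`` (present in the mutant only).  Each
classified record keeps the wild-type coordinates (mutant coordinates for
mutant-exclusive peaks) together with both conditions' fragment counts and
normalized peak scores, so score distributions can be contrasted by category.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .intervals import GenomicInterval, TssRecord
from .peaks import Peak

CATEGORIES = ("common", "F80L_absent", "F80L_only")


@dataclass
class ClassifiedPeak:
    """A peak carrying category, per-condition counts/scores and TSS links."""

    id: str
    interval: GenomicInterval
    summit: int
    category: str
    ip_wt: int = 0
    input_wt: int = 0
    ip_mut: int = 0
    input_mut: int = 0
    score_wt: float = np.nan
    score_mut: float = np.nan
    tss_associated: bool = False
    linked_genes: list[str] = field(default_factory=list)
    matched_peak_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}, got {self.category!r}")


def peak_score(
    ip_count, input_count, total_ip: float, total_input: float, width: float
) -> float | np.ndarray:
    """Library- and width-normalized log2 IP/input contrast.

    score = log2[(ip+1) / (total_ip * width)] - log2[(input+1) / (total_input * width)]

    The width term cancels algebraically but is kept so the two addends are
    interpretable per-sample normalized densities.  A +1 pseudocount keeps
    zero-count peaks finite.  Accepts scalars or aligned arrays.
    """
    if np.any(np.asarray(width) <= 0):
        raise ValueError("peak width must be positive")
    if total_ip <= 0 or total_input <= 0:
        raise ValueError("library totals must be positive")
    ip = np.asarray(ip_count, dtype=float)
    inp = np.asarray(input_count, dtype=float)
    if np.any(ip < 0) or np.any(inp < 0):
        raise ValueError("counts must be non-negative")
    score = np.log2((ip + 1) / (total_ip * width)) - np.log2((inp + 1) / (total_input * width))
    return float(score) if np.isscalar(ip_count) else score


def associate_tss(
    peaks: list, tss: list[TssRecord], flank: int = 250
) -> dict[str, list[str]]:
    """Map each peak id to the genes whose TSS lies within ``flank`` bp.

    A peak qualifies when at least one of its bases falls in the inclusive
    window [tss - flank, tss + flank], rendered half-open as
    [tss - flank, tss + flank + 1).  Strand is ignored.
    """
    tree_by_chrom: dict[str, IntervalTree] = {}
    for t in tss:
        lo = max(t.tss - flank, 0)
        hi = t.tss + flank + 1
        tree_by_chrom.setdefault(t.chrom, IntervalTree()).addi(lo, hi, t.gene_id)
    out: dict[str, list[str]] = {}
    for p in peaks:
        iv = p.interval
        tree = tree_by_chrom.get(iv.chrom)
        hits = sorted(h.data for h in tree.overlap(iv.start, iv.end)) if tree else []
        out[p.id] = hits
    return out


def categorize(wt_peaks: list[Peak], mut_peaks: list[Peak]) -> list[ClassifiedPeak]:
    """Assign cross-condition categories by any-overlap matching.

    Every WT peak becomes one record: ``common`` if it overlaps >= 1 mutant
    peak (the record keeps the WT coordinates; all overlapping mutant peak ids
    are noted), else ``F80L_absent``.  Mutant peaks overlapping no WT peak
    become ``F80L_only`` records.  Mutant peaks consumed by a WT overlap
    produce no record of their own, so
    |common| + |F80L_absent| = |WT| always, and
    |common| + |F80L_only| = |MUT| when matching is one-to-one.
    """
    mut_trees: dict[str, IntervalTree] = {}
    for m in mut_peaks:
        mut_trees.setdefault(m.interval.chrom, IntervalTree()).addi(
            m.interval.start, m.interval.end, m
        )
    wt_trees: dict[str, IntervalTree] = {}
    for w in wt_peaks:
        wt_trees.setdefault(w.interval.chrom, IntervalTree()).addi(
            w.interval.start, w.interval.end, w
        )

    out: list[ClassifiedPeak] = []
    for w in wt_peaks:
        tree = mut_trees.get(w.interval.chrom)
        matches = (
            sorted((iv.data for iv in tree.overlap(w.interval.start, w.interval.end)),
                   key=lambda m: (m.interval.start, m.id))
            if tree
            else []
        )
        out.append(
            ClassifiedPeak(
                id=w.id,
                interval=w.interval,
                summit=w.summit,
                category="common" if matches else "F80L_absent",
                ip_wt=w.ip_count,
                input_wt=w.input_count,
                matched_peak_ids=[m.id for m in matches],
            )
        )
    for m in mut_peaks:
        tree = wt_trees.get(m.interval.chrom)
        if tree and tree.overlap(m.interval.start, m.interval.end):
            continue
        out.append(
            ClassifiedPeak(
                id=m.id,
                interval=m.interval,
                summit=m.summit,
                category="F80L_only",
                ip_mut=m.ip_count,
                input_mut=m.input_count,
            )
        )
    return out


def fill_condition_counts(
    classified: list[ClassifiedPeak],
    wt_bins: pd.DataFrame,
    mut_bins: pd.DataFrame,
) -> None:
    """Sum both conditions' bin counts over each classified span and compute
    per-condition peak scores in place.

    Using the bin grids (rather than the condition-specific peak calls) gives
    every record counts in *both* conditions, including the condition where
    the peak was not called.
    """
    totals = {
        "wt": (wt_bins.attrs.get("total_ip", int(wt_bins["ip_count"].sum())),
               wt_bins.attrs.get("total_input", int(wt_bins["input_count"].sum()))),
        "mut": (mut_bins.attrs.get("total_ip", int(mut_bins["ip_count"].sum())),
                mut_bins.attrs.get("total_input", int(mut_bins["input_count"].sum()))),
    }
    for cond, bins in (("wt", wt_bins), ("mut", mut_bins)):
        by_chrom = {c: sub.sort_values("start") for c, sub in bins.groupby("chrom")}
        total_ip, total_input = totals[cond]
        for p in classified:
            sub = by_chrom.get(p.interval.chrom)
            if sub is None:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            mask = (starts < p.interval.end) & (ends > p.interval.start)
            ip = int(sub["ip_count"].to_numpy()[mask].sum())
            inp = int(sub["input_count"].to_numpy()[mask].sum())
            score = peak_score(ip, inp, total_ip, total_input, p.interval.width)
            if cond == "wt":
                p.ip_wt, p.input_wt, p.score_wt = ip, inp, score
            else:
                p.ip_mut, p.input_mut, p.score_mut = ip, inp, score


def apply_tss_links(
    classified: list[ClassifiedPeak], tss: list[TssRecord], flank: int = 250
) -> None:
    links = associate_tss(classified, tss, flank=flank)
    for p in classified:
        p.linked_genes = links.get(p.id, [])
        p.tss_associated = bool(p.linked_genes)


def score_distribution_export(classified: list[ClassifiedPeak]) -> pd.DataFrame:
    """Long-format (peak, category, condition, score) table for ECDF/density
    plotting, with per-group quantiles in ``DataFrame.attrs['quantiles']``."""
    rows = []
    for p in classified:
        for cond, score in (("WT", p.score_wt), ("MUT", p.score_mut)):
            if np.isfinite(score):
                rows.append(
                    {"peak_id": p.id, "category": p.category, "condition": cond, "score": score}
                )
    df = pd.DataFrame(rows, columns=["peak_id", "category", "condition", "score"])
    if len(df):
        q = (
            df.groupby(["category", "condition"])["score"]
            .quantile([0.25, 0.5, 0.75])
            .unstack()
        )
        df.attrs["quantiles"] = q
    return df


def category_counts(classified: list[ClassifiedPeak], tss_only: bool = False) -> dict[str, int]:
    counts = {c: 0 for c in CATEGORIES}
    for p in classified:
        if tss_only and not p.tss_associated:
            continue
        counts[p.category] += 1
    return counts
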