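"""Enrichment-based peak detection from binned IP/input fragment counts.

The detector is deliberately simple and fully specified: each genomic bin is
tested for IP enrichment over the matched input library with a one-sided
binomial test, p-values are BH-adjusted across all bins, and maximal runs of
enriched bins are merged into summit-bearing peaks.  Externally called peaks
(ENCODE narrowPeak) can instead be ingested and filtered by the same
enriched-bin intersection rule, mirroring a two-tool peak-retention workflow.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .intervals import COORDINATE_HEADER, GenomicInterval, ParseError

BIN_COLUMNS = ["chrom", "start", "end", "ip_count", "input_count"]


@dataclass(frozen=True)
class Peak:
    """A called peak: a merged run of enriched bins with a summit.

    ``ip_count``/``input_count`` are fragment counts summed over the span in
    the condition the peak was called in.  ``retained`` records whether the
    peak survived the enriched-bin intersection filter (always True for peaks
    assembled from our own bins).
    """

    id: str
    interval: GenomicInterval
    summit: int
    ip_count: int
    input_count: int
    retained: bool = True

    def __post_init__(self) -> None:
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError(
                f"summit {self.summit} outside peak span "
                f"[{self.interval.start}, {self.interval.end})"
            )
        if self.ip_count < 0 or self.input_count < 0:
            raise ValueError("peak counts must be non-negative")


def bin_enrichment(
    bins: pd.DataFrame,
    total_ip: int | None = None,
    total_input: int | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-bin one-sided binomial enrichment test with BH control.

    Parameters
    ----------
    bins : DataFrame
        Aligned bin grid with columns ``chrom, start, end, ip_count,
        input_count`` (one row per bin; IP and input share the grid).
    total_ip, total_input : int, optional
        Library sizes.  Default to the column sums.
    fdr : float
        BH threshold defining the ``enriched`` flag.

    Returns
    -------
    DataFrame
        Input columns plus ``p_value``, ``q_value``, ``enriched``.  Under the
        null each bin's IP count is Binomial(n = ip+input,
        p = total_ip / (total_ip + total_input)); the reported p-value is the
        upper tail P(X >= ip).
    """
    missing = [c for c in BIN_COLUMNS if c not in bins.columns]
    if missing:
        raise ValueError(f"bin table missing columns: {missing}")
    if (bins["end"] - bins["start"] <= 0).any():
        raise ValueError("bin grid contains empty or inverted bins")
    ip = bins["ip_count"].to_numpy(dtype=np.int64)
    inp = bins["input_count"].to_numpy(dtype=np.int64)
    if (ip < 0).any() or (inp < 0).any():
        raise ValueError("negative bin counts")
    total_ip = int(ip.sum()) if total_ip is None else int(total_ip)
    total_input = int(inp.sum()) if total_input is None else int(total_input)
    if total_ip < ip.sum() or total_input < inp.sum():
        raise ValueError("library totals smaller than the per-bin sums")
    p0 = total_ip / (total_ip + total_input)
    n = ip + inp
    # upper tail including the observed count: P(X >= ip | n, p0)
    p = binom.sf(ip - 1, n, p0)
    p[n == 0] = 1.0
    _, q, _, _ = multipletests(p, method="fdr_bh")
    out = bins.copy()
    out["p_value"] = p
    out["q_value"] = q
    out["enriched"] = q <= fdr
    return out


def assemble_peaks(
    bin_tests: pd.DataFrame, max_gap: int = 0, id_prefix: str = "peak"
) -> list[Peak]:
    """Merge runs of enriched bins (inter-bin gap <= ``max_gap``) into peaks.

    The summit is the midpoint of the enriched bin with the highest IP count
    (leftmost on ties); counts are summed over every bin inside the merged
    span, gap bins included.
    """
    required = {"chrom", "start", "end", "ip_count", "input_count", "enriched"}
    missing = required - set(bin_tests.columns)
    if missing:
        raise ValueError(f"bin test table missing columns: {sorted(missing)}")
    df = bin_tests.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    peaks: list[Peak] = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.reset_index(drop=True)
        enriched_idx = np.flatnonzero(sub["enriched"].to_numpy())
        if enriched_idx.size == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        runs: list[list[int]] = [[enriched_idx[0]]]
        for i in enriched_idx[1:]:
            prev = runs[-1][-1]
            if starts[i] - ends[prev] <= max_gap:
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            span_start = int(starts[run[0]])
            span_end = int(ends[run[-1]])
            in_span = sub[(sub["start"] >= span_start) & (sub["end"] <= span_end)]
            run_bins = sub.iloc[run]
            top = run_bins.loc[run_bins["ip_count"].idxmax()]  # idxmax -> leftmost tie
            summit = int((top["start"] + top["end"]) // 2)
            peaks.append(
                Peak(
                    id=f"{id_prefix}_{len(peaks) + 1}",
                    interval=GenomicInterval(chrom, span_start, span_end),
                    summit=summit,
                    ip_count=int(in_span["ip_count"].sum()),
                    input_count=int(in_span["input_count"].sum()),
                )
            )
    return peaks


def retain_external_peaks(peaks: list[Peak], bin_tests: pd.DataFrame) -> list[Peak]:
    """Flag externally called peaks that overlap >= 1 enriched bin.

    Non-overlapping peaks are kept with ``retained=False`` so the filter is
    auditable.
    """
    trees: dict[str, IntervalTree] = {}
    for row in bin_tests[bin_tests["enriched"]].itertuples():
        trees.setdefault(row.chrom, IntervalTree()).addi(row.start, row.end)
    out = []
    for p in peaks:
        tree = trees.get(p.interval.chrom)
        hit = bool(tree and tree.overlap(p.interval.start, p.interval.end))
        out.append(replace(p, retained=hit))
    return out


# ---------------------------------------------------------------------------
# narrowPeak I/O
# ---------------------------------------------------------------------------


def read_narrowpeak(path) -> list[Peak]:
    """Read ENCODE narrowPeak (10 columns; summit offset in column 10)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) != 10:
                raise ParseError(f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(f)}")
            try:
                start, end, offset = int(f[1]), int(f[2]), int(f[9])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer field") from exc
            summit = start + offset if offset >= 0 else (start + end) // 2
            try:
                out.append(
                    Peak(
                        id=f[3] if f[3] != "." else f"np_{lineno}",
                        interval=GenomicInterval(f[0], start, end),
                        summit=summit,
                        ip_count=max(int(float(f[6])), 0),
                        input_count=0,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_narrowpeak(path, peaks: list[Peak]) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t0\t.\t{p.ip_count}\t-1\t-1"
                f"\t{p.summit - iv.start}\n"
            )


def write_bin_audit(path, bin_tests: pd.DataFrame) -> None:
    """Audit TSV of the per-bin test (p, q and the enriched flag)."""
    with open(path, "w") as fh:
        fh.write(COORDINATE_HEADER + "\n")
        bin_tests.to_csv(fh, sep="\t", index=False)


def read_bin_counts(ip_path, input_path) -> pd.DataFrame:
    """Read per-sample binned-count TSVs (chrom, bin_start, bin_end, count)
    onto one grid, validating that the grids match."""
    ip = pd.read_csv(ip_path, sep="\t", comment="#")
    inp = pd.read_csv(input_path, sep="\t", comment="#")
    key = ["chrom", "bin_start", "bin_end"]
    if not ip[key].equals(inp[key]):
        raise ValueError("IP and input bin grids do not match")
    out = ip.rename(columns={"bin_start": "start", "bin_end": "end", "count": "ip_count"})
    out["input_count"] = inp["count"].to_numpy()
    return out[BIN_COLUMNS]


def write_bin_counts(path, bins: pd.DataFrame, which: str) -> None:
    """Write one sample's binned counts (``which`` is 'ip' or 'input')."""
    col = f"{which}_count"
    with open(path, "w") as fh:
        fh.write(COORDINATE_HEADER + "\n")
        out = bins[["chrom", "start", "end", col]].rename(
            columns={"start": "bin_start", "end": "bin_end", col: "count"}
        )
        out.to_csv(fh, sep="\t", index=False)
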