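"""Genomic coordinate primitives and interval arithmetic.

All coordinates in this package are 0-based, half-open (``[start, end)``),
the BED convention.  Readers for 1-based formats (GTF) convert on input.
Strand is carried on every interval but deliberately ignored by the overlap
machinery: the promoter-association rule applied downstream is
strand-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from intervaltree import IntervalTree

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span.

    Parameters
    ----------
    chrom : str
        Chromosome name.  Compared by exact string match (no "chr" aliasing).
    start : int
        0-based inclusive start (bp).
    end : int
        0-based exclusive end (bp); must exceed ``start``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlaps_any(self, other)


@dataclass(frozen=True)
class TssRecord:
    """A gene anchored by its transcription start site.

    ``exonic_length`` (total exonic bp) feeds RPKM normalization; ``gene_type``
    lets the expression stage restrict to protein-coding genes.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str = "."
    exonic_length: int = 1000
    gene_name: str | None = None
    gene_type: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.exonic_length <= 0:
            raise ValueError(f"exonic_length must be > 0 for {self.gene_id}")
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0 for {self.gene_id}")


def overlaps_any(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff two half-open intervals share at least one base.

    Adjacent intervals ([100,200) vs [200,300)) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def map_pairs(
    set_a: Iterable[GenomicInterval], set_b: Iterable[GenomicInterval]
) -> "dict[GenomicInterval, list[GenomicInterval]]":
    """Map every member of ``set_a`` to all overlapping members of ``set_b``.

    Output is deterministic: A-members are keyed in (chrom, start, end) order
    and each overlap list is sorted the same way.  Built on an interval tree
    per chromosome, so cost is ~O((|A|+|B|) log |B|).
    """
    a_sorted = sorted(set_a, key=_sort_key)
    trees: dict[str, IntervalTree] = {}
    for b in set_b:
        trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b)
    out: dict[GenomicInterval, list[GenomicInterval]] = {}
    for a in a_sorted:
        tree = trees.get(a.chrom)
        hits = [iv.data for iv in tree.overlap(a.start, a.end)] if tree else []
        out[a] = sorted(hits, key=_sort_key)
    return out


def _sort_key(iv: GenomicInterval):
    return (iv.chrom, iv.start, iv.end)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

COORDINATE_HEADER = "# coordinates: 0-based, half-open [start, end)"


class ParseError(ValueError):
    """Malformed record in an input file; message names the line number."""


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line


def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (name/strand kept when present)."""
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns, got {len(f)}")
        try:
            start, end = int(f[1]), int(f[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        name = f[3] if len(f) > 3 and f[3] != "." else None
        strand = f[5] if len(f) > 5 and f[5] in VALID_STRANDS else "."
        try:
            out.append(GenomicInterval(f[0], start, end, strand=strand, name=name))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path, intervals: Iterable[GenomicInterval], scores: Mapping | None = None) -> None:
    """Write BED6 (BED3 plus name/score/strand columns, '.'/0 when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = scores.get(iv.name, 0) if scores else 0
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
            )


_GTF_ATTR_KEYS = ("gene_id", "gene_name", "gene_type")


def _gtf_attributes(raw: str) -> dict[str, str]:
    attrs = {}
    for chunk in raw.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, value = chunk.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf_genes(path) -> list[TssRecord]:
    """Read gene features from a GTF into TSS records.

    GTF is 1-based, fully closed; the TSS is the feature start on '+' genes and
    the feature end on '-' genes, converted to the internal 0-based convention.
    ``exonic_length`` falls back to the gene span when no explicit attribute
    (``exonic_length``) is present.
    """
    out = []
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if len(f) < 9:
            raise ParseError(f"{path}:{lineno}: expected 9 GTF columns, got {len(f)}")
        if f[2] != "gene":
            continue
        try:
            start1, end1 = int(f[3]), int(f[4])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        if end1 < start1:
            raise ParseError(f"{path}:{lineno}: end < start")
        start0, end0 = start1 - 1, end1  # 1-based closed -> 0-based half-open
        strand = f[6] if f[6] in VALID_STRANDS else "."
        attrs = _gtf_attributes(f[8])
        if "gene_id" not in attrs:
            raise ParseError(f"{path}:{lineno}: missing gene_id attribute")
        tss = start0 if strand != "-" else end0 - 1
        out.append(
            TssRecord(
                gene_id=attrs["gene_id"],
                chrom=f[0],
                tss=tss,
                strand=strand,
                exonic_length=int(attrs.get("exonic_length", end0 - start0)),
                gene_name=attrs.get("gene_name"),
                gene_type=attrs.get("gene_type", "protein_coding"),
            )
        )
    return out


def read_tss_tsv(path) -> list[TssRecord]:
    """Read the package's flat TSS annotation table.

    Columns: gene_id, chrom, tss, strand, exonic_length[, gene_name, gene_type].
    """
    out = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        f = line.split("\t")
        if header is None:
            header = f
            continue
        row = dict(zip(header, f))
        try:
            out.append(
                TssRecord(
                    gene_id=row["gene_id"],
                    chrom=row["chrom"],
                    tss=int(row["tss"]),
                    strand=row.get("strand", "."),
                    exonic_length=int(row.get("exonic_length", 1000)),
                    gene_name=row.get("gene_name"),
                    gene_type=row.get("gene_type", "protein_coding"),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_tss_tsv(path, records: Iterable[TssRecord]) -> None:
    with open(path, "w") as fh:
        fh.write(COORDINATE_HEADER + "\n")
        fh.write("gene_id\tchrom\ttss\tstrand\texonic_length\tgene_name\tgene_type\n")
        for r in records:
            fh.write(
                f"{r.gene_id}\t{r.chrom}\t{r.tss}\t{r.strand}\t{r.exonic_length}"
                f"\t{r.gene_name or r.gene_id}\t{r.gene_type}\n"
            )
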