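"""PWM scanning, nearest-motif assignment, and consensus/information-content
analysis for the 22-bp THAP11-associated motif (TAM).

The TAM carries two blocks of consensus, a 5' CTGGGA and a 3' TGTAGT.  The
analyses here let the two halves be contrasted: peaks are assigned their
single closest TAM occurrence, matched 22-mers are stacked into per-category
consensus matrices, and per-position information content (IC, bits) is
compared half-by-half between categories.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# Default 22-bp TAM consensus used by the shipped analysis PWM: the 5' half
# carries the CTGGGA block, the 3' half the TGTAGT block.
DEFAULT_TAM_CONSENSUS = "ACTGGGAAGTGCTGTAGTCAAT"
HALF_SPLIT = 11  # 0-based index where the 3' half starts (equal 11/11 halves)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence.

    ``sequence`` is the matched window in motif orientation (reverse
    complemented for '-' hits); ``score`` is the log-odds sum in bits.
    """

    chrom: str
    start: int
    strand: str
    score: float
    sequence: str

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)

    @property
    def midpoint(self) -> float:
        return self.start + len(self.sequence) / 2


class PwmModel:
    """A position probability matrix with background, scored in log2-odds.

    ``probs`` is 4 x width (rows A, C, G, T); every column must sum to 1.
    """

    def __init__(self, probs, background=None, pseudocount: float = 0.0):
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 2 or probs.shape[0] != 4 or probs.shape[1] < 1:
            raise ValueError(f"probs must be 4 x width, got shape {probs.shape}")
        colsums = probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("every PWM column must sum to 1 (within 1e-9)")
        self.probs = probs
        self.background = (
            np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        )
        if self.background.shape != (4,) or not np.isclose(self.background.sum(), 1.0):
            raise ValueError("background must be 4 probabilities summing to 1")
        self.pseudocount = float(pseudocount)

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """4 x width matrix of log2(p / background), -inf-safe via tiny floor."""
        with np.errstate(divide="ignore"):
            return np.log2(np.maximum(self.probs, 1e-300) / self.background[:, None])

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def score_sequence(self, seq: str) -> float:
        """Log-odds score of one exact-width sequence (bits)."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != PWM width {self.width}")
        lo = self.log_odds
        return float(sum(lo[_CODE[b], j] for j, b in enumerate(seq.upper())))

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        """Per-position IC in bits for uniform background:
        IC_j = 2 + sum_b p_bj log2 p_bj.  Bounded in [0, 2]."""
        p = self.probs
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = np.where(p > 0, p * np.log2(p), 0.0).sum(axis=0)
        return np.clip(2.0 + ent, 0.0, 2.0)

    @classmethod
    def from_counts(cls, counts, pseudocount: float = 0.5, background=None) -> "PwmModel":
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(counts / counts.sum(axis=0), background=background, pseudocount=pseudocount)

    @classmethod
    def from_consensus(
        cls, consensus: str, match_prob: float = 0.91, background=None
    ) -> "PwmModel":
        """Build a PWM in which each column puts ``match_prob`` on the
        consensus base and spreads the rest evenly."""
        w = len(consensus)
        probs = np.full((4, w), (1.0 - match_prob) / 3.0)
        for j, b in enumerate(consensus.upper()):
            probs[_CODE[b], j] = match_prob
        return cls(probs, background=background)

    def reverse_complemented(self) -> "PwmModel":
        return PwmModel(self.probs[::-1, ::-1], background=self.background[::-1])

    # -- flat-file form: 4 rows (A/C/G/T) of tab-separated probabilities -----

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# PWM probabilities, rows A/C/G/T, one column per position\n")
            fh.write("base\t" + "\t".join(f"p{j + 1}" for j in range(self.width)) + "\n")
            for i, b in enumerate(BASES):
                fh.write(b + "\t" + "\t".join(f"{v:.6f}" for v in self.probs[i]) + "\n")

    @classmethod
    def read(cls, path) -> "PwmModel":
        rows = {}
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or line.startswith("base"):
                    continue
                f = line.rstrip("\n").split("\t")
                if f[0] in _CODE:
                    rows[f[0]] = [float(x) for x in f[1:]]
        if set(rows) != set(BASES):
            raise ValueError(f"PWM file {path} missing base rows: {set(BASES) - set(rows)}")
        probs = np.array([rows[b] for b in BASES])
        return cls(probs / probs.sum(axis=0))


def default_tam_pwm(match_prob: float = 0.91) -> PwmModel:
    """The shipped analysis PWM: the 22-bp TAM consensus with near-uniform
    off-consensus mass.  Intended for synthetic runs; real analyses should
    supply an experimentally derived matrix."""
    return PwmModel.from_consensus(DEFAULT_TAM_CONSENSUS, match_prob=match_prob)


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3, anything else (N) -> -1."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def _scan_one_strand(codes: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """Scores of every window of width lo.shape[1]; NaN where a window holds N."""
    w = lo.shape[1]
    n_win = codes.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    scores = np.zeros(n_win)
    bad = np.zeros(n_win, dtype=bool)
    for j in range(w):
        col = codes[j : j + n_win]
        bad |= col < 0
        scores += lo[np.clip(col, 0, 3), j]
    scores[bad] = np.nan
    return scores


def scan_pwm(
    sequence: str,
    pwm: PwmModel,
    min_score: float | None = None,
    chrom: str = ".",
) -> list[MotifHit]:
    """Scan both strands of a sequence for PWM matches scoring >= min_score.

    ``min_score`` defaults to 60% of the PWM's maximum achievable log-odds.
    Windows containing N are skipped.  Hits are sorted by start position
    (forward strand first on exact ties).  Reverse-strand hits are reported at
    their forward-strand coordinates with the matched sequence in motif
    orientation.
    """
    if min_score is None:
        min_score = 0.6 * pwm.max_score
    codes = encode_sequence(sequence)
    seq_upper = sequence.upper()
    hits: list[MotifHit] = []
    w = pwm.width
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complemented().log_odds)):
        scores = _scan_one_strand(codes, lo)
        for pos in np.flatnonzero(scores >= min_score):
            window = seq_upper[pos : pos + w]
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=int(pos),
                    strand=strand,
                    score=float(scores[pos]),
                    sequence=window if strand == "+" else reverse_complement(window),
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def nearest_tam(
    summit: int, hits: list[MotifHit], flank: int = 1000
) -> tuple[MotifHit | None, int]:
    """The single closest motif hit to a peak summit, plus the count of hits
    within the window [summit - flank, summit + flank].

    Distance is |hit midpoint - summit|; ties break to the lower-coordinate
    hit.  Returns (None, 0) when the window is empty.
    """
    in_window = [h for h in hits if summit - flank <= h.midpoint <= summit + flank]
    if not in_window:
        return None, 0
    best = min(in_window, key=lambda h: (abs(h.midpoint - summit), h.start, h.strand))
    return best, len(in_window)


def build_consensus(
    sequences: list[str], pseudocount: float = 0.5
) -> tuple[PwmModel, np.ndarray]:
    """Stack aligned motif-oriented k-mers into a consensus PWM and its IC.

    Sequences must share one width and be pre-oriented (reverse-strand hits
    already reverse complemented, as ``scan_pwm`` reports them).
    """
    if not sequences:
        raise ValueError("cannot build a consensus from zero sequences")
    w = len(sequences[0])
    if any(len(s) != w for s in sequences):
        raise ValueError("all stacked sequences must share one width")
    counts = np.zeros((4, w))
    for s in sequences:
        for j, b in enumerate(s.upper()):
            if b in _CODE:
                counts[_CODE[b], j] += 1
    pwm = PwmModel.from_counts(counts, pseudocount=pseudocount)
    return pwm, pwm.information_content()


def ic_half_contrast(
    pwm_a: PwmModel, pwm_b: PwmModel, split: int = HALF_SPLIT
) -> dict[str, float]:
    """Mean per-half IC of two equal-width PWMs and their differences.

    Returns mean IC over positions [0, split) (5' half) and [split, width)
    (3' half) for each matrix, plus delta_5p / delta_3p = mean_IC(a) -
    mean_IC(b) per half.
    """
    if pwm_a.width != pwm_b.width:
        raise ValueError(f"width mismatch: {pwm_a.width} vs {pwm_b.width}")
    ic_a, ic_b = pwm_a.information_content(), pwm_b.information_content()
    out = {
        "a_5p": float(ic_a[:split].mean()),
        "a_3p": float(ic_a[split:].mean()),
        "b_5p": float(ic_b[:split].mean()),
        "b_3p": float(ic_b[split:].mean()),
    }
    out["delta_5p"] = out["a_5p"] - out["b_5p"]
    out["delta_3p"] = out["a_3p"] - out["b_3p"]
    return out


def write_hits_bed(path, hits: list[MotifHit]) -> None:
    """Motif hits as BED6; column 5 holds the log-odds score in centibits
    (bits x 100, rounded), BED's usual integer-score convention."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.chrom}\t{h.start}\t{h.end}\ttam\t{round(h.score * 100)}\t{h.strand}\n"
            )
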