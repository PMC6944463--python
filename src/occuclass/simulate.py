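"""Ground-truthed simulator for paired-condition promoter ChIP and RNA-seq.

The simulator emulates the comparative design the package analyzes: a
wild-type (WT) transcription factor and a DNA-binding-domain point mutant
(MUT) profiled by ChIP over the same genome, plus a 2+2-replicate RNA-seq
experiment in which genes that lose promoter occupancy in the mutant are
preferentially downregulated.

Occupancy model
---------------
Each bound promoter carries one planted 22-bp motif whose 5'- and 3'-half
log-odds sub-scores (s5, s3, measured relative to the consensus sequence, so
0 = perfect half and negative = degraded) drive occupancy through a logistic
response:

    occupancy_wt  =          logistic(a5*s5 + a3_wt*s3  + c0)
    occupancy_mut = delta *  logistic(a5*s5 + a3_mut*s3 + c0)

with a3_mut > a3_wt making the mutant steeper in the 3'-half score (mutant
binding is hypersensitive to 3'-half degradation) and ``delta`` a global
mutant protein-abundance factor (default 0.46).  The intercept c0 is
calibrated so the median strong site reaches ~0.9 WT occupancy.  A configured
fraction of bound promoters carries occupancy without a recognizable motif
(non-sequence-specific recruitment), and loses it entirely in the mutant.

Counts
------
Input bins are Poisson at a uniform background rate; IP bins overlapping a
site's footprint gain ``enrichment_max * occupancy``-fold signal.  RNA counts
are negative binomial; direct-target genes' mutant means shrink by
``2^(-effect_log2fc * occupancy-loss-fraction)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .intervals import TssRecord
from .motifs import BASES, HALF_SPLIT, PwmModel, default_tam_pwm

# Truth-label thresholds.  Two notions of "losing" a site are kept apart:
# - lost (drives the direct-target gene truth): bound in WT (occupancy >=
#   OCC_PRESENT_MIN) with at least LOSS_FRAC_MIN of that occupancy gone in
#   the mutant;
# - below_call (drives peak-classification recovery): solidly bound in WT
#   (>= OCC_PRESENT_CALL_MIN) while the mutant occupancy sits clearly below
#   what a caller can detect at the default depths (<= OCC_LOST_MAX).
# "High-occupancy" sites (peak-coverage checks) clear OCC_HIGH_MIN in WT.
OCC_PRESENT_MIN = 0.05
LOSS_FRAC_MIN = 0.9
OCC_PRESENT_CALL_MIN = 0.10
OCC_LOST_MAX = 0.03
OCC_HIGH_MIN = 0.5

_STREAM_GENOME, _STREAM_CHIP_WT, _STREAM_CHIP_MUT, _STREAM_RNA = range(4)


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the simulator.

    Defaults are the package's reference conditions: a 2 Mb genome, 300
    genes, 150 bound promoters, 300-bp bins, two replicates per condition,
    and a mutant protein-abundance factor of 0.46.
    """

    genome_length: int = 2_000_000
    chrom_name: str = "chrS"
    n_genes: int = 300
    n_bound_promoters: int = 150
    min_tss_spacing: int = 2_000
    bin_width: int = 300
    # ChIP depths: expected background fragments per library
    depth_ip: int = 1_000_000
    depth_input: int = 1_000_000
    background_rate: float | None = None  # fragments/bp; derived from depth if None
    enrichment_max: float = 10.0
    site_halfwidth: int = 90  # fragment smear around the motif footprint
    tss_motif_jitter: int = 100  # motif planted within +/- this of the TSS
    # occupancy model
    a5: float = 0.25
    a3_wt: float = 0.25
    a3_mut: float = 0.6
    delta: float = 0.46
    target_wt_occupancy: float = 0.9  # calibration point for c0
    # motif planting
    motif_match_prob: float = 0.91
    weak_fraction: float = 0.5
    weak_degradation: float = 0.3  # mixture weight toward uniform in the 3' half
    frac_motifless: float = 0.15
    # RNA-seq
    n_replicates: int = 2
    n_direct_down: int = 60
    n_indirect: int = 40
    n_silent: int = 30
    effect_log2fc: float = 1.5
    indirect_log2fc: float = 1.2
    nb_dispersion: float = 0.02
    rna_log_mean: float = 6.2  # ln-scale mean of baseline expression (~500 counts)
    rna_log_sd: float = 1.2
    exonic_length_range: tuple[int, int] = (500, 3000)
    seed: int = 0

    def validate(self) -> None:
        if not (0 < self.delta <= 1):
            raise ValueError(f"delta must be in (0, 1], got {self.delta}")
        if not (self.a3_mut >= self.a3_wt >= 0) or self.a5 < 0:
            raise ValueError("require a3_mut >= a3_wt >= 0 and a5 >= 0")
        if self.n_bound_promoters > self.n_genes:
            raise ValueError("n_bound_promoters cannot exceed n_genes")
        for name in ("genome_length", "n_genes", "bin_width", "depth_ip", "depth_input"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.weak_fraction <= 1 and 0 <= self.frac_motifless <= 1):
            raise ValueError("weak_fraction and frac_motifless must be in [0, 1]")
        if not (0 <= self.weak_degradation <= 1):
            raise ValueError("weak_degradation must be in [0, 1]")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per condition")
        if self.n_genes * self.min_tss_spacing > self.genome_length:
            raise ValueError(
                "genome too short to place "
                f"{self.n_genes} genes {self.min_tss_spacing} bp apart"
            )

    @property
    def bg_rate_ip(self) -> float:
        return (
            self.background_rate
            if self.background_rate is not None
            else self.depth_ip / self.genome_length
        )

    @property
    def bg_rate_input(self) -> float:
        return (
            self.background_rate
            if self.background_rate is not None
            else self.depth_input / self.genome_length
        )

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), stream]))


@dataclass
class SyntheticTruth:
    """Everything the recovery analyses may compare against.

    ``sites``: one row per planted site (sub-scores, occupancies, labels).
    ``genes``: one row per gene (baseline mean, true log2 effect, label in
    {direct, indirect, null}).
    """

    sites: pd.DataFrame
    genes: pd.DataFrame
    config: SyntheticConfig
    c0: float

    def lost_sites(self) -> pd.DataFrame:
        s = self.sites
        return s[s["lost"]]

    def below_call_sites(self) -> pd.DataFrame:
        s = self.sites
        return s[s["below_call"]]


@dataclass
class SyntheticDataset:
    genome: dict[str, str]
    tss: list[TssRecord]
    truth: SyntheticTruth


def _sample_motif(
    rng: np.random.Generator, pwm: PwmModel, degradation_3p: float
) -> str:
    """Draw a 22-mer from the generator PWM; the 3' half's column
    probabilities are mixed toward uniform with weight ``degradation_3p``."""
    probs = pwm.probs.copy()
    g = degradation_3p
    probs[:, HALF_SPLIT:] = (1 - g) * probs[:, HALF_SPLIT:] + g * 0.25
    cum = probs.cumsum(axis=0)
    u = rng.random(pwm.width)
    idx = (u[None, :] > cum).sum(axis=0)
    return "".join(BASES[i] for i in idx)


def _half_scores(seq: str, pwm: PwmModel) -> tuple[float, float]:
    """(s5, s3): per-half log-odds relative to the consensus sequence (<= 0)."""
    lo = pwm.log_odds
    best = lo.max(axis=0)
    codes = [BASES.index(b) for b in seq]
    rel = np.array([lo[c, j] - best[j] for j, c in enumerate(codes)])
    return float(rel[:HALF_SPLIT].sum()), float(rel[HALF_SPLIT:].sum())


def generate_genome(config: SyntheticConfig) -> SyntheticDataset:
    """Build the genome, gene annotation and planted-site truth table.

    The background sequence is i.i.d. uniform; TSSs are laid out on an evenly
    spaced grid with jitter (guaranteeing >= ``min_tss_spacing``); each bound
    promoter receives one motif instance within +/- ``tss_motif_jitter`` bp of
    its TSS, or occupancy without a motif for the motifless fraction.
    Occupancies for both conditions are evaluated here and recorded in the
    truth table.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = config._rng(_STREAM_GENOME)
    L, chrom = config.genome_length, config.chrom_name

    seq = rng.integers(0, 4, size=L, dtype=np.int8)

    # TSS layout: even slots + jitter that preserves the minimum spacing
    slot = L // config.n_genes
    jitter_max = max((slot - config.min_tss_spacing) // 2, 0)
    centers = np.arange(config.n_genes) * slot + slot // 2
    jitter = rng.integers(-jitter_max, jitter_max + 1, size=config.n_genes)
    tss_pos = np.clip(centers + jitter, 200, L - 200)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    lo_len, hi_len = config.exonic_length_range
    exonic = rng.integers(lo_len, hi_len + 1, size=config.n_genes)

    tss_records = [
        TssRecord(
            gene_id=f"G{i + 1:04d}",
            chrom=chrom,
            tss=int(tss_pos[i]),
            strand=str(strands[i]),
            exonic_length=int(exonic[i]),
            gene_name=f"gene{i + 1}",
        )
        for i in range(config.n_genes)
    ]

    # choose bound promoters and site classes
    bound_idx = np.sort(rng.choice(config.n_genes, size=config.n_bound_promoters, replace=False))
    n_bound = bound_idx.size
    motifless = rng.random(n_bound) < config.frac_motifless
    weak = (~motifless) & (rng.random(n_bound) < config.weak_fraction)

    pwm = default_tam_pwm(config.motif_match_prob)
    rows = []
    for k, gi in enumerate(bound_idx):
        tss = int(tss_pos[gi])
        offset = int(rng.integers(-config.tss_motif_jitter, config.tss_motif_jitter + 1))
        pos = int(np.clip(tss + offset - pwm.width // 2, 0, L - pwm.width))
        if motifless[k]:
            motif_seq, s5, s3 = "", np.nan, np.nan
            strength = "none"
        else:
            g = config.weak_degradation if weak[k] else 0.0
            motif_seq = _sample_motif(rng, pwm, g)
            seq[pos : pos + pwm.width] = [BASES.index(b) for b in motif_seq]
            s5, s3 = _half_scores(motif_seq, pwm)
            strength = "weak" if weak[k] else "strong"
        rows.append(
            {
                "site_id": f"S{k + 1:04d}",
                "gene_id": f"G{gi + 1:04d}",
                "pos": pos,
                "end": pos + pwm.width,
                "sequence": motif_seq,
                "s5": s5,
                "s3": s3,
                "strength": strength,
            }
        )
    sites = pd.DataFrame(
        rows,
        columns=["site_id", "gene_id", "pos", "end", "sequence", "s5", "s3", "strength"],
    )

    # occupancy model; c0 calibrated on the strong-site median
    with_motif = sites["strength"] != "none"
    strong = sites["strength"] == "strong"
    ref = sites[strong] if strong.any() else sites[with_motif]
    if len(ref):
        med = config.a5 * ref["s5"].median() + config.a3_wt * ref["s3"].median()
    else:
        med = 0.0
    c0 = float(logit(config.target_wt_occupancy) - med)

    occ_wt = np.zeros(len(sites))
    occ_mut = np.zeros(len(sites))
    if with_motif.any():
        s5 = sites.loc[with_motif, "s5"].to_numpy()
        s3 = sites.loc[with_motif, "s3"].to_numpy()
        occ_wt[with_motif.to_numpy()] = expit(config.a5 * s5 + config.a3_wt * s3 + c0)
        occ_mut[with_motif.to_numpy()] = config.delta * expit(
            config.a5 * s5 + config.a3_mut * s3 + c0
        )
    if (~with_motif).any():
        n_ml = int((~with_motif).sum())
        occ_wt[(~with_motif).to_numpy()] = rng.uniform(0.3, 0.7, size=n_ml)
        occ_mut[(~with_motif).to_numpy()] = 0.0
    sites["occupancy_wt"] = occ_wt
    sites["occupancy_mut"] = occ_mut
    loss_frac = 1.0 - sites["occupancy_mut"] / sites["occupancy_wt"].clip(lower=1e-12)
    sites["lost"] = (sites["occupancy_wt"] >= OCC_PRESENT_MIN) & (loss_frac >= LOSS_FRAC_MIN)
    sites["below_call"] = (sites["occupancy_wt"] >= OCC_PRESENT_CALL_MIN) & (
        sites["occupancy_mut"] <= OCC_LOST_MAX
    )

    genes = _build_gene_truth(config, rng, tss_records, sites)
    genome = {chrom: "".join(BASES[i] for i in seq)}
    truth = SyntheticTruth(sites=sites, genes=genes, config=config, c0=c0)
    return SyntheticDataset(genome=genome, tss=tss_records, truth=truth)


def _build_gene_truth(
    config: SyntheticConfig,
    rng: np.random.Generator,
    tss_records: list[TssRecord],
    sites: pd.DataFrame,
) -> pd.DataFrame:
    gene_ids = [t.gene_id for t in tss_records]
    n = len(gene_ids)
    baseline = rng.lognormal(config.rna_log_mean, config.rna_log_sd, size=n)

    # silent genes: essentially unexpressed, exercising the RPKM filter
    silent_pool = [g for g in gene_ids if g not in set(sites["gene_id"])]
    rng.shuffle(silent_pool)
    silent = set(silent_pool[: config.n_silent])
    baseline = np.where(np.isin(gene_ids, list(silent)), 0.05, baseline)

    # direct targets: genes whose promoter site is prone to occupancy loss
    loss_pool = sites.loc[sites["strength"].isin(["weak", "none"]), "gene_id"].tolist()
    rng.shuffle(loss_pool)
    direct = set(loss_pool[: config.n_direct_down])

    # indirect effects at unbound, non-silent promoters (half up, half down)
    indirect_pool = [
        g for g in gene_ids if g not in set(sites["gene_id"]) and g not in silent
    ]
    rng.shuffle(indirect_pool)
    indirect = indirect_pool[: config.n_indirect]
    indirect_sign = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(indirect)}

    site_by_gene = sites.set_index("gene_id")
    labels, effects = [], []
    for g in gene_ids:
        if g in direct:
            occ_wt = site_by_gene.loc[g, "occupancy_wt"]
            occ_mut = site_by_gene.loc[g, "occupancy_mut"]
            loss_frac = 1.0 - occ_mut / max(occ_wt, 1e-12)
            labels.append("direct")
            effects.append(-config.effect_log2fc * float(loss_frac))
        elif g in indirect_sign:
            mag = abs(rng.normal(config.indirect_log2fc, 0.25))
            labels.append("indirect")
            effects.append(indirect_sign[g] * mag)
        else:
            labels.append("null")
            effects.append(0.0)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "baseline_mean": baseline,
            "true_log2fc": effects,
            "label": labels,
        }
    )


def simulate_chip_counts(
    truth: SyntheticTruth, condition: str, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Binned IP and input fragment counts for one condition.

    Returns a DataFrame on the bin grid (chrom, start, end, ip_count,
    input_count) with the per-sample totals in ``DataFrame.attrs``.  Input
    bins are Poisson at the uniform background rate; IP bins overlapping a
    site footprint (motif +/- ``site_halfwidth``) get
    ``background * (1 + enrichment_max * occupancy)``.
    """
    config = config or truth.config
    cond = condition.upper()
    if cond not in ("WT", "MUT"):
        raise ValueError(f"condition must be 'WT' or 'MUT', got {condition!r}")
    rng = config._rng(_STREAM_CHIP_WT if cond == "WT" else _STREAM_CHIP_MUT)

    L, bw = config.genome_length, config.bin_width
    n_bins = (L + bw - 1) // bw
    starts = np.arange(n_bins) * bw
    ends = np.minimum(starts + bw, L)
    widths = (ends - starts).astype(float)

    lam_input = config.bg_rate_input * widths
    lam_ip = config.bg_rate_ip * widths.copy()

    occ_col = "occupancy_wt" if cond == "WT" else "occupancy_mut"
    for row in truth.sites.itertuples():
        occ = getattr(row, occ_col)
        if occ <= 0:
            continue
        foot_start = max(row.pos - config.site_halfwidth, 0)
        foot_end = min(row.end + config.site_halfwidth, L)
        first = foot_start // bw
        last = (foot_end - 1) // bw
        for b in range(first, last + 1):
            lam_ip[b] = max(
                lam_ip[b],
                config.bg_rate_ip * widths[b] * (1.0 + config.enrichment_max * occ),
            )

    ip = rng.poisson(lam_ip)
    inp = rng.poisson(lam_input)
    out = pd.DataFrame(
        {
            "chrom": config.chrom_name,
            "start": starts,
            "end": ends,
            "ip_count": ip,
            "input_count": inp,
        }
    )
    out.attrs["total_ip"] = int(ip.sum())
    out.attrs["total_input"] = int(inp.sum())
    out.attrs["condition"] = cond
    return out


def simulate_rna_counts(
    truth: SyntheticTruth, config: SyntheticConfig | None = None
) -> pd.DataFrame:
    """Gene x sample NB count matrix (columns WT_1..WT_n, MUT_1..MUT_n).

    MUT means are ``baseline * 2^true_log2fc``; the NB size parameter is
    1 / nb_dispersion (Poisson in the nb_dispersion -> 0 limit).
    """
    config = config or truth.config
    rng = config._rng(_STREAM_RNA)
    genes = truth.genes
    base = genes["baseline_mean"].to_numpy()
    mu = {
        "WT": base,
        "MUT": base * np.power(2.0, genes["true_log2fc"].to_numpy()),
    }
    data = {}
    for cond in ("WT", "MUT"):
        for r in range(1, config.n_replicates + 1):
            data[f"{cond}_{r}"] = _nb_draw(rng, mu[cond], config.nb_dispersion)
    return pd.DataFrame(data, index=pd.Index(genes["gene_id"], name="gene_id"))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    if dispersion <= 1e-12:
        out[pos] = rng.poisson(mu[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mu[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def read_genome_fasta(path) -> dict[str, str]:
    """Load a genome FASTA as {chromosome: sequence} (indexed access via
    pyfaidx, so large references are not parsed by hand)."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_genome_fasta(path, genome: dict[str, str], line_width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def write_truth_tables(outdir, truth: SyntheticTruth) -> None:
    """Site- and gene-level ground truth as commented TSVs."""
    import os

    from .intervals import COORDINATE_HEADER

    with open(os.path.join(outdir, "truth_sites.tsv"), "w") as fh:
        fh.write(COORDINATE_HEADER + "\n")
        fh.write(f"# occupancy intercept c0 = {truth.c0:.6f}\n")
        truth.sites.to_csv(fh, sep="\t", index=False)
    truth.genes.to_csv(os.path.join(outdir, "truth_genes.tsv"), sep="\t", index=False)
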