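# Methods

This note documents the models behind `occuclass`, the defaults and why they
were chosen, what the simulator does and does not emulate, and the numerical
decisions that are not obvious from the code.

## Coordinates and interval semantics

All internal coordinates are 0-based, half-open `[start, end)` (the BED
convention); every emitted table says so in a header comment. GTF input
(1-based, closed) is converted on read. Adjacent intervals never count as
overlapping. Strand is carried on every record but ignored by all overlap
tests: the promoter rule ("any peak base within ±250 bp of a TSS") is
deliberately strand-agnostic, and the ±250 bp window is inclusive of both
endpoints before conversion to half-open (`[tss−250, tss+251)`).
Chromosome names are compared as exact strings — no "chr" aliasing.

## Bin-enrichment peak detection

The detector is a transparent stand-in for heavier model-based callers; its
statistic is fully specified so results are auditable. For each bin the IP
count is referred to Binomial(n = ip + input, p = N_ip/(N_ip + N_input))
and the one-sided upper tail is taken; BH adjustment runs across all bins of
a condition, and `enriched ⇔ q ≤ fdr` (default 0.05). Defaults: 300-bp bins,
`max_gap = 0` (only directly adjacent enriched bins merge). The summit is
the midpoint of the enriched bin with the highest IP count (leftmost on
ties); counts are summed over every bin inside the merged span.

The exact binomial test is conservative at shallow depths (a discrete test's
attained size is below nominal); at the default simulated depths
(~150 fragments per bin per library) the attained level is ≈ 0.044 at
nominal 0.05 and approaches 0.05 as depth grows. Externally called peaks
(narrowPeak) can be ingested instead and filtered by the same enriched-bin
intersection rule; non-surviving peaks are kept with `retained=False` for
audit.

Lowering `fdr` always yields a nested subset of enriched bins (BH
monotonicity), which the tests assert.

## Peak score

`score = log2[(ip+1)/(N_ip·w)] − log2[(input+1)/(N_input·w)]`. The width
term cancels algebraically; it is kept because the two addends are then
interpretable per-sample normalized densities, which are also exported. The
+1 pseudocount keeps zero-count spans finite. Scores are *not* invariant to
scaling both libraries by a common factor — each sample is normalized by its
own total, which is the intended reading of a per-sample tag normalization.

## Cross-condition categories

Matching uses any-overlap (≥ 1 bp), the weakest assumption; the minimum
overlap is configurable upstream by widening/narrowing peaks. Every
wild-type peak yields exactly one record (common or F80L_absent, keeping the
WT coordinates and both conditions' counts summed from the bin grids), so
`|common| + |F80L_absent| = |WT|` holds identically. Mutant peaks
overlapping ≥ 1 WT peak are consumed; the mutant identity
`|common| + |F80L_only| = |MUT|` therefore holds exactly only for one-to-one
overlaps, and many-to-one cases collapse onto the WT record (asserted in
tests, documented here). Both conditions' counts for every record come from
the bin tables rather than the peak calls, so lost peaks still carry real
mutant counts and a mutant score.

## Motif model

The shipped 22-bp PWM puts 0.91 on each consensus base of
`ACTGGGAAGTGCTGTAGTCAAT` (a 5′ CTGGGA block and a 3′ TGTAGT block) with the
remainder spread evenly; background is uniform. It is intended for synthetic
runs — real analyses should supply an experimentally derived matrix in the
same 4-row tab-delimited format.

Scanning computes log2-odds on both strands (reverse-strand windows scored
against the reverse-complemented matrix and reported in motif orientation).
The scanner's generic default threshold is 60% of the matrix's maximum
score. The pipeline instead scans at a fixed 10 bits: the study design
requires degraded-3′-half instances (≈ 3 expected mismatches in the 3′ half,
≈ 15–20 bits) to remain detectable, while at 10 bits a random 22-mer needs
≥ 16 consensus matches, a binomial tail of ~3·10⁻⁶ per window — about a
dozen chance hits across the 2 Mb genome, i.e. ≪ 1 expected false motif per
peak window. Nearest-motif assignment minimizes |motif midpoint − summit|
within ±1000 bp (ties to the lower coordinate); consensus building uses the
single closest motif within ±250 bp of each qualifying summit, stacks the
matched 22-mers with a +0.5 pseudocount, and reports
`IC_j = 2 + Σ_b p_bj log2 p_bj` (0–2 bits). The 5′/3′ split is at position
11 of 22 — equal halves, since only the two hexamer blocks, not numeric
halves, are defined by the consensus itself.

One selection effect is worth knowing: peaks retained in both conditions are
conditioned on high occupancy, which sharpens *all* consensus positions
slightly, so the 5′-half IC difference between categories is small but not
exactly zero (≈ 0.05–0.2 bits at the reference conditions) while the 3′-half
difference is ≈ 0.7–0.8 bits. Smaller stacks also lose a little IC to the
pseudocount. The acceptance check therefore requires the 3′ contrast to be
large and the 5′ contrast to be both small (< 0.3 bits) and under half the
3′ contrast.

## Expression

RPKM = counts / (exonic kb · millions mapped); totals default to column
sums. A gene is expressed if RPKM ≥ 1.2 in at least one sample ("below 1.2
in all samples" discards; equality keeps). Protein-coding filtering, when
annotation is available, happens first.

The differential test: median-of-ratios size factors (geometric-mean
reference over genes positive everywhere); per-gene method-of-moments
dispersion `α̂ = (s² − μ̂)/μ̂²` from the pooled within-condition variance
(k = n₁+n₂−2 df), clipped to [0, 10]; a trend equal to the per-decile median
of the pooled variance converted to a dispersion — the median is divided by
`median(χ²_k)/k` (≈ 0.69 at k = 2) because the k-df median underestimates
the variance, which would otherwise make the test anti-conservative; final
dispersion = 0.5·α̂ + 0.5·trend. The Wald statistic is
`log2FC / SE` with `SE² = Σ_c (μ_c + α μ_c²)/(n_c μ_c² ln²2)` and a 0.5
pseudo-mean added to both condition means when either is zero. The statistic
is referred to a t distribution with a Satterthwaite effective df in which
only the raw 50%-weight dispersion share carries χ²_k noise, sized from the
stable trend so the df is uncorrelated with the realized estimate
(ν ≈ 9–10 at 2+2); against a normal reference the same estimator is
anti-conservative (null level ≈ 0.11), with the t reference the level is
≈ 0.047 at nominal 0.05. BH adjustment runs over tested genes. Cutoffs for
change calls are non-strict (≤ / ≥), configurable. Deliberately omitted
relative to full NB frameworks: independent filtering, outlier refitting,
fold-change shrinkage — the test trades a modest power cost (its detection
rate at a 1-unit effect, mean 100, dispersion 0.05, 2+2 is ≈ 0.58 versus
≈ 0.81 for a known-dispersion oracle) for exact transparency. A
cross-check test confirms its fold-change estimates track an established NB
implementation (r > 0.95).

## Simulator: what it emulates

Reference conditions (the defaults): 2 Mb single-chromosome genome, 300
genes ≥ 2 kb apart, 150 bound promoters, 300-bp bins, 10⁶ background
fragments per ChIP library (≈ 150 per bin), maximal fold enrichment 10, two
RNA replicates per condition. Problem sizes were chosen so a full run takes
a few seconds while every count of interest stays in the dozens-to-hundreds.

Each bound promoter gets one motif instance within ±100 bp of its TSS, drawn
from the shipped PWM; with probability 0.5 the 3′-half columns are first
mixed 30% toward uniform ("weak" sites, ~3 expected 3′ mismatches), and 15%
of bound promoters instead carry occupancy with no motif at all
(non-sequence-specific recruitment — these lose binding entirely in the
mutant and are what makes a fraction of lost peaks motif-free). Half-scores
s5/s3 are log-odds *relative to the consensus sequence* (0 = perfect,
negative = degraded): with a shared intercept, mutant hypersensitivity
(a3_mut > a3_wt) only penalizes deficits if the scores are ≤ 0 — with
background-relative scores the ordering invariant occupancy_mut ≤
occupancy_wt would fail. Occupancy:

    occ_wt  =        logistic(a5·s5 + a3_wt·s3  + c0)      a5 = a3_wt = 0.25 /bit
    occ_mut = 0.46 · logistic(a5·s5 + a3_mut·s3 + c0)      a3_mut = 0.6 /bit

c0 is calibrated at generation time so the median strong site reaches 0.9 WT
occupancy. The 0.46 factor is the mutant protein's relative abundance; the
steeper 3′ coefficient makes a ~10-bit 3′ deficit negligible for the
wild type but fatal for the mutant — the mechanism the analysis is meant to
recover. The logistic form itself is a modeling choice (no quantitative
affinity model exists to copy); it is the simplest monotone map producing
the required bimodal sensitivity.

ChIP counts: input bins Poisson at the uniform background rate; IP bins
overlapping a site footprint (motif ± 90 bp, a fragment-size smear) at
`background · (1 + 10 · occupancy)`. Bins are generated directly — no
fragment-level reads, no duplicates, no GC or mappability structure.

RNA counts: NB with dispersion 0.02 (tight isogenic cultured-cell
replicates; typical genewise dispersions for cell-line experiments fall in
0.01–0.05), baseline means lognormal with median ≈ 500 counts, 30 "silent"
genes near zero to exercise the RPKM filter. 60 direct-target genes are
drawn from the weak/motifless bound promoters; their mutant mean shrinks by
`2^(−1.5 · loss_fraction)` where loss_fraction = 1 − occ_mut/occ_wt, so the
expression effect is proportional to how much occupancy was actually lost.
40 indirect genes at unbound promoters change ± ~1.2 log2 units (half up,
half down), and the rest are null. The 1.5 log2-unit full-loss effect is in
the range seen for direct activation targets of a lost factor.

Truth labels keep two distinct notions of "losing" a site, used by different
checks: *lost* (WT occupancy ≥ 0.05 and ≥ 90% of it gone) defines which
direct-target genes should be recoverable; *below_call* (WT occupancy
≥ 0.10, mutant ≤ 0.03) defines which sites a caller at the reference depths
must classify as F80L_absent — sites in the gray zone between detectability
bands belong to neither denominator and are not graded either way.

All randomness flows from one seed through fixed, labeled streams (genome,
WT ChIP, MUT ChIP, RNA), so identical configurations are byte-identical on
re-run, and changing one stage's draw does not perturb the others.

### What passing the synthetic suite does *not* show

The simulator has uniform background, perfectly aligned bin grids, no
copy-number or mappability artifacts, exactly one site per bound promoter,
independent bins, and a motif model identical to the scanning model. Success
here demonstrates the pipeline's logic and statistics are correct, not that
peak calling at these thresholds is well-calibrated on real chromatin, where
background structure, fragment-length effects and motif misspecification all
bite. The deterministic counting stage (`supp-counts`) is the only part
intended to run unchanged on real exported tables.

## Numerical details and degenerate inputs

- BH is `statsmodels` `fdr_bh` throughout; binomial tails are exact
  (`scipy.stats.binom.sf`). Empty bins (n = 0) get p = 1.
- Peaks with all-zero counts are scored finitely via the +1 pseudocount;
  genes with all-zero counts in both conditions get log2FC 0, p = 1.
- Nearest-motif ties break to the lower coordinate; summit ties to the
  leftmost bin; direct-target ranking ties break by gene id — all orderings
  deterministic.
- Consensus building refuses an empty category (error naming it) rather than
  emitting a degenerate matrix; an empty peak universe exports valid tables
  with zero data rows and all-zero summary counts.
- Size factors fall back to 1.0 when no gene is positive in every sample.

## Known limitations

- The bin-enrichment test ignores local background variation (no per-locus
  lambda); on real data broad enriched domains inflate the library total and
  slightly depress scores elsewhere.
- The NB test with two replicates leans heavily on the dispersion trend; a
  gene whose dispersion truly departs from its decile is mis-weighted.
- Peak categories are binary presence/absence at a threshold; quantitative
  differential-binding models would use the counts directly.
- The ±250 bp promoter rule links a peak to every TSS in range; bidirectional
  promoters yield multi-gene links, and the direct-target table counts a gene
  linked to both a lost and a retained peak as a target unless
  `require_all_lost` is set.
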