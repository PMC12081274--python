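# Methods

This note documents the models, estimators, and numerical choices behind
`cbskit`, and what its synthetic-data generator does and does not emulate.

## Binding activity

At each regulatory locus (rDHS), CTCF ChIP-seq strength is reported as a
Z-score per biosample, with a sentinel of −10 wherever the raw signal was
zero.  `mask_zero_signal` flags sentinel entries with an explicit boolean
mask; the mask, not the sentinel, is authoritative downstream.  The per-locus
**binding activity** is

    activity(r) = Σᵢ zᵢ / N

over the N unmasked biosamples — the arithmetic mean of the unmasked
Z-scores.  The conventional Stouffer combination Σᵢ zᵢ / √N is available as
`method="stouffer_sqrt"`; both are exposed because the mean is what the
defining formula states while Stouffer's method is what the technique is
usually called.  The default is the mean.  Summation uses `math.fsum`
(exactly rounded), so results are independent of accumulation order.

Activity scores are rank-binned into k equal-sized quantiles (default
k = 100; deciles are derived as ⌈q/10⌉).  Ties are broken by a stable sort on
(activity, locus id); bin sizes differ by at most one.  "Equal-sized bins"
is treated as a rank statement, not a value statement.

`call_bound` reproduces the thresholded binding call (bound iff any unmasked
Z strictly exceeds 1.64) together with the replication count, for sensitivity
analyses of threshold choice.

## CBS catalog

A position frequency matrix is converted to a log₂-odds PWM with a total
pseudocount of 0.8 distributed by the background composition (a common
JASPAR-ecosystem convention; the base and pseudocount largely cancel in
relative scores and score differences).  Scanning scores every motif-length
window on both strands; minus-strand windows are scored against the
column-reversed, base-complemented matrix and reported in plus-strand
coordinates.  The **relative score** (score − min)/(max − min) maps onto
[0, 1]; the catalog threshold defaults to 0.8 relative score.

Exclusion filtering removes hits on non-autosomal contigs and hits sharing
≥ 1 base with any exclusion interval (gaps, blacklist, coding exons),
matching default BED-intersection semantics; per-track removal tallies are
reported, and a hit may count against several tracks while being removed
once.  Motifs are annotated with the activity of their overlapping scored
rDHS (≥ 1 shared base, half-open coordinates); with multiple overlaps the
maximum activity wins, and motifs without a scored overlap are dropped from
the catalog.

## Allelic scoring (ΔPWM)

For each candidate SNV inside a catalog motif, a window of 14 bp of flanking
reference sequence on each side (29 bp total) is extracted.  Each allele's
score is the maximum log-odds over every motif-length subwindow that lies
entirely inside the window and covers the variant position, on both strands.
Note that with a 19-bp motif and 14-bp flanks, variants at motif offsets
outside [4, 14] cannot be covered by a full-length subwindow containing the
planted alignment; their scores come from partial-overlap alignments and are
correspondingly small.  The window size is kept at 14 bp flanks deliberately
— it is the extraction used by the analysis this package operationalizes —
and subwindows never extend past the extracted window.

    ΔPWM = ref_best − alt_best;   ΔPWM ≤ 0 → gain of binding,
                                  ΔPWM > 0 → loss of binding.

Alt scores are computed as `score + (alt_contribution − ref_contribution)`
per subwindow so that a hypothetical identity substitution yields exactly
0.0.  Windows truncated at contig edges are N-padded; subwindows containing
N are skipped, and a pair with no valid subwindow is dropped with a log
entry.  A REF allele disagreeing with the genome is a hard error.

### Significance

The null hypothesis is fully specified so it can be checked against an
exact oracle: the 29-bp window is drawn i.i.d. from a zeroth-order background
(uniform by default), the substituted allele uniformly from the three
non-reference bases, and ΔPWM is computed by exactly the same two-strand
subwindow rule as for observed variants.  The reported p-value is the
one-sided tail in the observed direction: P(Δ ≥ δ_obs) for losses,
P(Δ ≤ δ_obs) for gains, with atom ties included (tolerance 10⁻⁹ bits).

Two estimators are provided:

* `ExactScoreChangeNull` — full enumeration of all 4^W windows × 3
  substitutions; feasible for motif length ≤ 8 and window length ≤ 13.  Used
  as the oracle in tests.
* `ImportanceSamplingNull` — the production estimator, in the spirit of the
  importance-sampling approach popularized for allele-specific TF-binding
  tests.  The proposal draws each window from a 50/50 mixture of the
  background and the pseudocounted motif model embedded at a uniformly
  chosen offset; per-draw weights are background density / proposal density,
  and the tail estimate comes with a standard error.  The null distribution
  depends only on (PWM, background, flank) — not on the variant — so the
  pipeline builds it once (2 × 10⁵ draws) and evaluates every variant's
  p-value as a weighted tail lookup.

Truncated p-values (≈ 0) are floored at a dummy value of 10⁻⁷ before taking
−log₁₀; the floor is configurable.  Confidence is p < 0.05, strict.  When a
variant lies in several overlapping motifs, per-variant analyses keep the row
with the smallest p-value, then the largest |ΔPWM|, then the first motif
coordinate.

## MAPS

The mutability-adjusted proportion of singletons compares a class's observed
singleton proportion (singleton: allele count AC = 1) with the proportion
expected from its trinucleotide mutability.  Calibration groups a
presumed-neutral class (`synonymous_variant`) by (context, alt), and fits

    proportion_singleton ~ intercept + slope · μ

by weighted least squares with group variant counts as weights (statsmodels
WLS).  Expected singletons for any class are the per-variant predictions,
clipped to [0, 1], summed; because the model is linear this equals
n · (intercept + slope · mean μ) whenever no clipping occurs, and the code
asserts that identity when the clip is inactive.  Then

    MAPS = raw_proportion − expected_proportion,
    SEM  = sqrt(raw (1 − raw) / n).

By WLS orthogonality the calibration class scores exactly zero against its
own model (to numerical precision).  Contexts are literal plus-strand
3-mers (no pyrimidine-centering); the rate table must use the same
convention, and the synthetic generator emits it so.  Variants at contig
edges cannot be context-annotated and are excluded with a log entry.

QC before any MAPS or allelic analysis: bi-allelic SNVs only, AC > 0,
AF > 0, FILTER = PASS, and AN strictly greater than 76,000 (half-cohort
coverage).

## Enrichment statistics

"Conserved" and "pathogenic" proportions use ≥ thresholds (boundary counts).
Bootstrap confidence intervals follow a fixed-n resampling design: 10
independent iterations of B resamples of size n; the CI is the pooled
2.5/97.5 percentile and the point estimate the mean of per-iteration means.
Because the statistic is a proportion of a binary indicator, each resampled
proportion is distributed exactly as Binomial(n, p̂)/n, and the resamples are
drawn that way directly — identical in distribution to index resampling and
much faster.  Both Pearson and Spearman correlations are always available
(different parts of the upstream analysis report each).

## Synthetic data

The generator produces every input with known ground truth, as pure
functions of (config, seed):

* **Genome** — i.i.d. bases at configurable GC (default 0.41), 4 autosomal
  contigs of 400 kb.  Real genomes have repeat structure and regional
  composition this does not emulate.
* **PFM** — a constructed 19-bp CTCF-like matrix (`default_ctcf_pfm`):
  GC-rich consensus, high-information core, degenerate edges, and
  heterogeneous columns (varying consensus fractions 0.55–0.96; rotating
  uneven minor-base splits).  Column heterogeneity mirrors real count
  matrices and is what gives the score-change test resolution: with
  homogeneous columns all score changes collapse onto a few shared values
  and no substitution can be distinguished from the null.
* **rDHS matrix** — 3,000 loci × 214 biosamples (the breadth of the real
  CTCF ChIP compendium).  A planted fraction (default 0.4) is active:
  unmasked in 70% of biosamples with Z ~ N(4, 1.5); inactive loci are 90%
  masked with unmasked Z ~ N(0, 1).  No biosample covariance or
  tissue-specific structure is modeled.
* **Motifs** — 2,600 non-overlapping instances, 85% inside rDHS intervals,
  drawn per-position at fidelity 0.95 (consensus probability; otherwise one
  of the other three bases uniformly), +0.04 fidelity at active hosts,
  uniform random strand.
* **Variants** — 150,000 SNVs placed uniformly inside catalog motifs plus
  75,000 controls outside any motif (60% labeled `synonymous_variant` for
  calibration, the rest `intergenic_variant` as a held-out neutral class).
  Singleton probability: 0.40 + (−0.03)·(μ − μ̄) + planted excess for
  loss-of-binding variants by activity decile, clipped to [0, 1].  Loss/gain
  is determined with the package's own deterministic scorer, so the planted
  effect keys off the realized decile and class.  AC = 1 for singletons,
  2 + geometric otherwise; AN fixed at 152,000; 2% of records carry a
  spiked non-PASS filter.  No recurrent-mutation or coverage model.
* **Mutation rates** — all 64 × 3 (context, alt) combinations, lognormal
  around 1 with CpG transitions boosted 6-fold.
* **Conservation** — per-base N(0, 1) scores, +2 inside planted motifs of
  active rDHSs.

Because the generator's singleton mechanism is exactly the linear mutability
model MAPS calibrates, passing recovery tests demonstrates estimator
correctness, not robustness to model misspecification; real gnomAD spectra
(recurrence, coverage, population structure) are out of scope.

## Problem sizes and runtime

The default end-to-end run (1.6 Mb genome, 3,000 loci, ~2,500 catalog
motifs, ~90,000 scored variants, 2 × 10⁵ null draws) completes in well under
a minute on one CPU.  Test oracles use scaled-down instances: exact null
enumeration at window length 7, importance-sampling grids at 10⁵ draws per
point, MAPS recovery at 50,000 variants per class, bootstrap coverage over
500 simulations.

## Known limitations

* Activity is a cross-biosample aggregate; tissue-specific binding is not
  represented (in data or model).
* The 29-bp extraction makes motif-edge variants unreachable by a
  full-length alignment (see above); this mirrors the upstream choice rather
  than fixing it.
* The significance null is zeroth-order; first-order (dinucleotide)
  backgrounds are not implemented.
* bigWig reading is optional (pyBigWig); bedGraph is the tested baseline.
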