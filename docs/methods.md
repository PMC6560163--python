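# Methods

## Signature scoring

The MYC-activity score is cohort-relative.  Each of the 16 signature genes
(10 MYC-induced, 6 MYC-repressed) is rescaled so its sum across the cohort's
samples equals 100; per sample, all 60 up/down ratios are formed in
up-gene-major order and the score is their median (even ratio counts use the
conventional sample median, the mean of the two central order statistics).
A score above 1 is called MYC-high.

Choices made where the procedure leaves room:

- **Tie at exactly 1.**  Only ">1" and "<1" are defined by the rule; a
  sample at exactly 1 is assigned MYC-low — the conservative call for
  treatment selection — and a boundary warning is emitted.
- **Linear scale.**  Ratios and the >1 threshold are meaningful only on the
  linear normalized scale; log2 transformation is used for visualization and
  concordance, never for scoring.
- **Cohort size.**  The normalization sums over the analysed samples, so a
  single-sample "cohort" degenerates to all ratios = 1 (score 1, MYC-low).
  To score a new sample against an established cohort, pass that cohort's
  per-gene sums via `reference_sums`; this extension is clearly an addition
  to the published procedure.
- **Even-count caveat.**  With an even number of ratios the mean-of-two
  median breaks the exact score ↔ 1/score antisymmetry under exchanging the
  up and down gene sets; the property holds exactly for odd ratio counts and
  is tested there.

## Expression input and normalization

Count tables are delimited text (TSV default, CSV accepted), genes in rows,
first column headed `gene`; binary instrument files are out of scope.  Gene
symbols match case-sensitively; signature genes missing at read time warn,
and scoring errors out only when the genes are actually required.

Housekeeping normalization rescales each sample so the geometric mean of its
housekeeping genes equals the across-sample mean of those geometric means —
the standard content-normalization convention for hybridization counts.  The
procedure is idempotent and absorbs any per-sample scale factor completely;
because the anchor (the across-sample mean) itself depends on the data,
rescaling one input column changes the output only by a single global
factor, which is irrelevant downstream (the score removes per-gene scale,
ratios remove per-sample scale).  Five housekeeping genes (SDHA, CLTC, TBP,
GUSB, RPL19) ship as the default list; it is configurable.  Whether
housekeeping normalization precedes scoring matters only through per-sample
scale; both paths are exposed (`--normalize-housekeeping`), default on in
the pipeline.

Technical replicates are averaged arithmetically per `replicate_group`
before any normalization, groups ordered by first appearance.

## Synthetic cohorts

`simulate_cohort` draws counts from a negative binomial with
var = μ + α·μ² (α = `dispersion`; α = 0 degrades to Poisson).  MYC-high
samples have up-gene means multiplied by `effect_size` and down-gene means
divided by it (symmetric on the log scale); housekeeping genes ignore the
label.  Defaults mirror the targeted study design: 24 samples split 11/13,
baseline mean 500 counts (a typical mid-range nCounter signal), dispersion
0.1 (moderate overdispersion for technical + biological noise), effect size
2.  One seed drives a splittable generator so cohort and plate streams are
independent but jointly reproducible; in the pipeline each drug's plate gets
its own derived stream.

What the generator does *not* emulate: stromal/blood contamination, RNA
degradation, probe-specific efficiency differences, batch structure, or any
correlation structure among the 16 genes beyond the shared subgroup shift.
Passing tests therefore demonstrate that the pipeline recovers truth under
its own statistical assumptions, not that those assumptions hold for any
particular patient dataset.

## Chemograms

`simulate_plate` produces triplicate viability readings from
v(d) = floor + (100 − floor)/(1 + (d/IC50)^hill), vehicle wells (dose 0) at
mean 100, readings truncated at 0.  The default dose ladder is eight
log-spaced points spanning 0.003–100 µM plus vehicle.  Noise is Gaussian,
either additive (SD in percentage points, default 5) or proportional (CV in
percent) — fluorescence-based viability readouts scale their error with the
signal, so the proportional model is used for IC50-recovery simulations.

Fitting minimizes residuals of the four-parameter log-logistic model in
log10-dose space with `scipy.optimize.least_squares`; the default loss is
soft-L1 (an M-estimator in the spirit of GraphPad's robust regression,
`robust=False` gives plain least squares; the two coincide on noise-free
data).  Twelve starting points (four IC50 anchors across the observed dose
range × hill slopes 0.5/1/2) guard against local minima.  The optimizer
constrains hill > 0 but the model's (top↔bottom, hill→−hill) symmetry is
resolved after fitting, so rising curves are representable.  A fit whose
response span is below 1 percentage point or whose IC50 lands more than 1.5
decades outside the tested range is flagged unconstrained: `converged=False`
and IC50 = NaN.  With 5% CV noise on the default design the median relative
IC50 error is ≈ 5%; with additive 5-point noise the intrinsic error of the
maximum-likelihood fit itself is ≈ 13%, a property of the noise model, not
the optimizer.

**Total AUC** is the trapezoidal area of the per-dose mean viability against
log10 dose over the observed positive-dose range, mean values floored at 0;
vehicle wells are used only for normalization (log 0 is undefined).  The
fitted-curve integral is not the default: integrating observed means is the
common "total AUC" convention and is robust to non-converged fits.  AUC
magnitudes depend on the dose grid, so only comparisons within one design
are meaningful.

Subgroup comparison: two-sided Mann–Whitney U (exact for small tie-free
groups), with Welch's t reported alongside; AUC distributions at n ≈ 11–13
per group are small and not reliably normal, so the rank test is primary.
A one-way ANOVA path for per-dose viability is available through
`scipy.stats` on the normalized table.

## Concordance

Paired PDTX/organoid cohorts are compared on subgroup-averaged log2
profiles (pseudocount 1): per label and per model, each gene's log2 values
are averaged across patients, and the two 16-vectors are correlated
(Pearson, two-sided t-based p, n − 2 df).  PCA centers genes across samples
and decomposes by SVD; component signs are fixed by making each component's
largest-magnitude loading positive.  Heatmap orderings use agglomerative
clustering with average linkage on 1 − Pearson distance (the common
heatmap-tool default), with deterministic tie-breaking by original index.

## Numerical notes

- Normalization and scoring are exact elementwise operations; tests hold
  them to 1e-9..1e-12 tolerances against naive loop references.
- Scores at the threshold boundary compare with `>` (strict); the boundary
  itself warns.
- Writers emit ≥ 10 significant digits so round-trips preserve values to
  1e-12 and repeated runs are byte-identical.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit configuration; no stage reads the clock or filesystem order.

## Problem sizes

The test suite and the reproduction script use desk-scale simulations:
100 random cohorts for normalization conservation, 50 for the scoring
oracle, 200 seeds for label recovery and 500 for the null call rate, 100
noisy curves for IC50 recovery, 100 replicate cohorts for subgroup
directionality, and 20 subgroup profiles for concordance.  These sizes give
Monte-Carlo standard errors well below the margins being asserted.

## Known limitations

- The score is cohort-relative; single-sample scoring requires a stored
  reference cohort and inherits its composition biases.
- The published AUC magnitudes for patient screens are not reproducible
  without the original plates and dose grid; the package validates
  direction and separation of subgroups on synthetic screens instead.
- Negative-binomial counts are a stand-in: no distributional information
  about real nCounter measurements on these genes is available.
- The hierarchical-clustering and PCA conventions (distance, linkage, sign)
  are configurable defaults chosen to match common heatmap tooling, not a
  unique specification.
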