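# Methods

## Popularity measures

The unit of analysis is a breed's registration time series N_b(t),
yearly puppy-registration counts with a kennel club. Years with no
record are treated as *missing*, not zero: breeds were recognized at
different dates, and imputing zeros would manufacture spurious peaks at
recognition boundaries. Every measure therefore runs on the breed's
observed span; a `missing_as_zero` switch restores the alternative.

* **Total popularity** P_b = Σ N_b(t).
* **Volatility** V_b = mean |N_b(t+1) − N_b(t)| over consecutive
  observed pairs. The divisor is the per-breed pair count (`n_changes`),
  which generalizes the canonical 79 of a full 80-year span to partial
  spans; pairs straddling a gap are excluded rather than interpolated.
* **Peak detection.** The peak year is the argmax of N_b, ties broken to
  the earliest year (deterministic; ties are measure-zero under noise).
  The beginning (end) of the boom–bust episode is the year strictly
  before (after) the peak at which registrations are at or below
  θ·N_b(t_peak), θ = 0.10 inclusive. "First time before/after" is read
  as the qualifying year *nearest* the peak (backward/forward scan),
  i.e. the boundaries of the single episode; the chronologically
  outermost reading is available via `peak_scan=outermost` because the
  verbal definition admits both. Breeds lacking either bound have no
  peak, and only the single highest peak is analyzed — no secondary-peak
  machinery, no smoothing, no per-capita normalization.
* **Rates** r⁺ = (N(t_peak) − N(t_begin)) / (t_peak − t_begin) and
  symmetrically r⁻, both positive, in registrations/year. Net change
  over elapsed years is the plainest reading of "rate of increase
  before the peak"; a peak-height-normalized variant (fraction of peak
  per year) sits behind `rate_normalized` in case a different
  normalization is wanted.
* **Recent change** N(y_b) − N(y_a) over a configurable window
  (default 1996–2005); breeds missing an endpoint are excluded from
  change-based correlations rather than erroring.

## Trait tables

Per-dog questionnaire records carry the 14 C-BARQ scales (0–4 bounded
scores). Breed-typical scores are plain means over dogs with a
non-missing value per scale, after dropping unknown-breed dogs and
breeds with fewer than `min_dogs_per_breed` dogs (default 20).
Longevity (years; survey-based and veterinary-hospital-based, either
possibly absent) and inherited-disorder counts join per breed.
Breed-name harmonization across sources is an explicit user-supplied
synonym map — never fuzzy matching — so joins are reproducible. Joins
are inner on breed, but correlations use pairwise-complete observations,
so each variable pair reports its own n.

## Inference

Popularity and trait variables are heavily skewed, so Pearson
correlations are assessed nonparametrically:

* **Permutation p**: two-sided, p = (1 + #{b : |r(x, π_b(y))| ≥
  |r(x,y)|}) / (B + 1) over B independent uniform permutations. The
  add-one convention keeps the Monte-Carlo test valid (p ≥ 1/(B+1),
  never 0). Comparisons use a 1e−12 relative guard so exact ties count
  as extreme.
* **Bootstrap CI**: paired resampling of (x_i, y_i) with replacement;
  percentile interval at α/2 and 1−α/2. Degenerate zero-variance
  resamples are redrawn. The percentile flavor is the default (BCa-free)
  because it is the simplest interval whose coverage we can and do
  validate by simulation; at n = 80 it covers a true ρ ∈ {0, 0.5} in
  ~93–95% of replicates — the familiar slight narrowness of percentile
  intervals, within the ±3% acceptance band.
* Both default to B = 50,000. "Bootstrapped permutation tests" is
  operationalized as this split — permutation null for significance,
  bootstrap for intervals — matching the two stated uses.
* **Multiple testing**: Bonferroni (min(1, m·p)) and Benjamini–Yekutieli
  (step-up with harmonic correction c(m) = Σ 1/i, valid under arbitrary
  dependence), both delegated to `statsmodels.multipletests` and applied
  per 14-trait panel by default (`family="global"` pools all 56). BY
  dominates BH dominates raw p, elementwise — asserted on random
  vectors.
* **ANOVA**: classical fixed-effects decomposition; η² = SS_between /
  SS_total. Zero total variance is an error; zero within-group variance
  with unequal means reports the minimum representable p with a
  `degenerate` flag.
* **Wilcoxon signed-rank** (survey vs veterinary longevity): zero
  differences dropped, mid-ranks for tied |d|. For n ≤ 25 the null
  distribution of W⁺ is exact via dynamic programming over doubled
  ranks (equivalent to enumerating all 2ⁿ sign assignments, but
  tie-tolerant, unlike off-the-shelf exact routines); larger n uses the
  normal approximation with tie and continuity corrections, which
  agrees with the exact tail to within 10% at n = 20.
* All Monte-Carlo routines accept a shared `numpy.random.Generator`;
  the pipeline threads a single seeded generator through every stage,
  so a fixed seed and inputs give byte-identical CSV outputs. Result
  rows record B and the seed.

## Synthetic data: what it emulates, and what it does not

* **Boom–bust series**: piecewise-exponential rise and fall between a
  baseline (`baseline_frac`·peak, default 4% — below the 10% threshold
  by construction) and the peak, shaped on the ~2,500 → 60,000 → ~3,000
  template. The exponential form gives closed-form threshold crossings,
  so the planted (t_begin, t_peak, t_end), rates and totals are *exact*
  on the noiseless integer curve (truth is re-read off the rounded curve
  to absorb boundary rounding). Noise is multiplicative lognormal
  (mean 1, coefficient of variation `noise_cv`) — count series' variance
  grows with scale — applied before integer rounding. At 10% noise the
  detected peak year stays within ±1 year of truth in ≥ 90% of runs.
* **Matrix preset**: 50 breeds / 30 peaked by default (92/60 in the
  full-input preset, with 80 of the 92 questionnaire breeds joinable to
  the registry and 12 breeds under the 20-dog filter, mirroring the
  structure of the real deposits).
* **Neutral null**: a Wright–Fisher copying process — each year N owners
  copy a uniformly random previous-year registration with probability
  1−μ, else pick uniformly — conserving the yearly total at N exactly.
  One-year frequency changes match binomial drift (mean 0, variance
  f(1−f)/N). The richer social-influence fashion models this nulls
  against are deliberately not implemented.
* **Trait tables**: trait t = ρ_t·z + √(1−ρ_t²)·ε with z the
  standardized popularity vector, affinely mapped to plausible ranges
  (scales ~2.0 ± 0.5 on 0–4; survey longevity ~11.5 y with veterinary
  estimates 3.5–5.5 y lower; disorder counts ~32 ± 15, rounded,
  floored at 1). Clipping and rounding attenuate the realized
  correlation negligibly at these settings (|ρ| ≤ 0.99 enforced).
* **Per-dog records**: breed means ~ Normal(2, between_sd), dog scores
  add within-breed noise and are clipped to [0, 4].

What the generators do *not* emulate: demographic realism (litter
sizes, breeder dynamics), secondary popularity peaks, non-stationary
questionnaire sampling, measurement error structure of owner reports,
or breed relatedness. Passing tests therefore show the estimators and
the pipeline are correct and calibrated on data with the stated
structure — not that the substantive conclusions would survive, say,
phylogenetic dependence between breeds, which the method ignores by
design.

## Numerical and design notes

* Registration counts are validated as non-negative integers; years
  must be consecutive; every breed needs ≥ 2 observed years (volatility
  is otherwise undefined and the matrix is rejected).
* Correlation pairs with n < 3 or zero variance are skipped with a
  logged warning, not errors — real trait tables are ragged.
* The variance-explained scenario (planted ρ = −0.32, n = 43) reports a
  mean R² of ~0.12 over 1,000 replicates rather than 0.1024: R² = r² is
  biased upward by ≈ (1−ρ²)²/n ≈ 0.019 at this n. The scenario is
  asserted as "about 10%" with that inflation accounted for; no
  bias-corrected (adjusted) R² is substituted, since plain R² is the
  quantity the analysis reports.
* Monte-Carlo problem sizes in the test and acceptance suites — 2,000
  null datasets at B = 2,000 for type-I calibration, 1,000 replicates
  at B = 2,000 for coverage, 1,000 random series for the peak oracle —
  were chosen so each check's Monte-Carlo standard error is several
  times smaller than its acceptance band.
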