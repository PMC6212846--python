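# Methods

## The measurement model

Droplet digital PCR partitions a diluted DNA sample into `n` droplets of
volume `v` (default 1 nl; configurable, since instruments calibrate to
slightly different values). With template molecules Poisson-distributed over
droplets at mean occupancy λ (copies per droplet), a droplet is positive
with probability `p = 1 − exp(−λ)`. The estimator inverts the observed
positive fraction,

    λ̂ = −ln(1 − p̂),    ĉ = λ̂ / v   (copies per µl),

and its sampling error is binomial in the droplet calls. The delta method
gives `sd(λ̂) = sqrt(p̂ / (n (1 − p̂)))`, from which the per-well confidence
interval (normal quantiles, clipped at zero) and the analytic CV

    cv(λ) = sqrt(p / ((1 − p) n)) / λ,   p = 1 − e^(−λ)

follow. The CV is U-shaped in λ: subsampling error dominates dilute wells,
partitioning error dominates nearly saturated ones, with a minimum near
λ ≈ 1.6. At 20,000 droplets the CV stays below 2.5% across the ~50-fold
occupancy range 0.11–5.73 copies/droplet and is ≈1% at 1000–2000 copies/µl
(λ of 1–2 at 1 nl), which is why a single dilution serves both early- and
late-replicating loci: the biology only spans a 2-fold range. Saturated
wells (all droplets positive) raise an error rather than returning
infinity — the sample must be diluted.

Technical replicates are summarised with a Student-t interval on n−1
degrees of freedom (two replicates are allowed, giving t with 1 df);
whether the normal or t quantile matches any particular instrument's
plotted error bars is not knowable from outside, so both per-well (normal)
and replicate (t) intervals are exposed. Wells may also be pooled before
the Poisson inversion (`merge_technical_replicates`), which is exact for
equal occupancies and strictly reduces the estimator CV.

## Relative copy number

In a replicating population, per-locus DNA abundance lies between 1
(unreplicated in every cell) and 2 (replicated in every cell), so
concentration is a proxy for replication timing. The package implements
three normalizations:

* **Baseline** — divide by the copy-adjusted mean over all probes,
  `baseline = mean_i(c_i / k_i)` with `k_i` copies per haploid genome. The
  probe value is `c_i / baseline`, so non-unique probes read their integer
  copy number (2, 3, …) in non-replicating material. Invariant to
  concentration units.
* **Dual (time-course)** — early-S samples are divided by a late-replicating
  control (still at constant concentration); from the switch sample onward,
  samples are divided by an early-replicating control and multiplied by 2
  (the control is itself fully replicated). The switch defaults to the
  argmax of the early/late control ratio, which peaks in mid S phase when
  the early control has finished and the late one has not started; ties
  break to the earlier sample and a flat course is flagged degenerate, not
  rejected.
* **Replication index** — `RI = (c_early − c_probe) / (c_early − c_late)`,
  the unique affine map sending the early control to 0 and the late control
  to 1. The classical density-transfer definition is in Trep space; the copy-number-space
  linear form is adopted because it is the only affine map with the same
  endpoints. RI is exactly invariant under multiplicative rescaling of all
  three concentrations, which is what makes sorted samples with different
  dynamic ranges comparable; values slightly outside [0, 1] are legitimate
  for probes earlier/later than the controls.

Allele-specific designs are summarised as the mutant/wild-type
concentration ratio (< 1 = delayed replication of the mutant allele), with
significance from a Tukey comparison of the replicate groups.

## Replication kinetics

Normalized copy number through a synchronized S phase is fitted with the
Boltzmann sigmoid `y(x) = A2 + (A1 − A2)/(1 + exp((x − x0)/dx))`. The model
has two equivalent parameterizations (swap plateaus, negate width); fits
are stored canonically with `dx > 0`, so `A1` is always the low-x plateau
and the curve is non-decreasing exactly when `A1 < A2`. Trep is the fitted
midpoint `x0`. Initialization uses the data extremes for the plateaus, the
mid-range crossing for `x0` and a tenth of the x-range for `dx`; flat
responses (range below `1e−9·|mean|`) are rejected as degenerate, and
optimizer failure raises an error carrying the initial iterate.

Bulk genome replication from flow cytometry divides per-sample DNA-content
medians by the arrested (G1) sample and linearly contrast-stretches the
course onto [1, 2]; replicated fraction = stretched − 1. The stretch uses
the observed min/max, so a single outlier sample can set an endpoint — a
robust-quantile variant is deliberately not the default, because the
stretch is defined by the course's own dynamic range. Mean DNA-content
summaries are accepted where medians are unavailable (the column used is
recorded). A Boltzmann fit over (time, stretched) is attached when at
least five samples support it; sample selection at a target bulk-replication
fraction reads fractions off the fit (falling back to observed fractions),
with ties to the earlier time.

## Sort-seq profiles

Binned read counts from a replicating and a non-replicating sample are
combined as `r_i = (rep_i / nonRep_i) · (nonRepSum / repSum)`, computed over
bins with at least `min_nonrep` (default 1) non-replicating reads; excluded
bins are recorded with reasons, and sums are taken over included bins only.
The formula is invariant to the global depth of either sample.

Because depth normalization only fixes the genome-wide mean, the raw ratio
is rescaled onto [1, 2] by the factor `f` minimizing the summed linear
exceedance `Σ max(0, 1 − f·r_i) + Σ max(0, f·r_i − 2)`. The published
description of this adjustment names only the out-of-range mass, so the
single multiplicative factor with a linear penalty is a reimplementation
decision, not a verbatim port. The objective is convex piecewise-linear
with breakpoints at `1/r_i` and `2/r_i`, so the exact minimiser is found by
breakpoint enumeration; on a tied plateau the factor closest to 1 is taken,
making the operation idempotent. One known property: the minimiser is
slightly conservative (a few percent low) on noisy data whose true values
crowd the upper end of the range, because bins near 2 carry about twice the
ratio weight of bins near 1 in the objective's derivative. At the default
simulation conditions this contributes roughly 0.01 to the mean absolute
recovery error.

Profiles can be smoothed per chromosome (never across boundaries) by LOESS
(default span 0.1) or a cubic smoothing spline with GCV-selected penalty;
chromosomes with fewer than 10 bins pass through with a warning. Probe
extraction takes the overlapping bin's value, the unweighted mean of
exactly two spanned bins, or the mean with a warning for unusually long
probes; probes with no overlap yield a missing value rather than a
failure. Profile-vs-probe comparisons are ordinary least squares with
`adjusted R² = 1 − (1 − R²)(n − 1)/(n − 2)`.

## Resolution statistics

Probe panels measured in technical replicates are compared by one-way
ANOVA and Tukey HSD (Tukey–Kramer for unequal replicate counts; scipy's
studentized-range implementation). The fully degenerate ANOVA case
(identical constant groups) reports F = 0, p = 1. Distinguishable states
along a genomically ordered panel are counted by cutting the sequence at
every adjacent pair whose adjusted p ≤ α — one plus the number of cuts,
never exceeding the probe count. The published analysis does not state its
counting rule; the adjacent-pair cut rule is the documented choice here.
The theoretical ceiling is `floor(1/d)` states for a smallest detectable
difference `d` on the one-to-two scale (14 at d = 0.07).

`min_detectable_difference` inverts the power question by bisection over
the two-group difference Δ, with power estimated by Monte-Carlo simulation
of replicate tables under multiplicative noise of the stated CV. For two
groups, the Tukey HSD p equals the pooled two-sided t p (the k = 2
studentized range is √2·|t|), so the inner loop uses the vectorized t form;
an explicit equivalence test guards this identity. The same seed is reused
at every bisection step so the estimated power curve is monotone in Δ. At
1% CV and three replicates the detectable difference is ≈0.03–0.05
copy-number units, comfortably below the 0.07 empirical resolution figure
the statistic is meant to support.

## The synthetic-data generator

The generator replaces the wet lab with the minimal model consistent with
the early/late/passive vocabulary of replication timing:

* **Landscape** — origins (position, firing time, efficiency) and a
  constant fork speed (default 1.5 kb/min) define
  `trep(x) = min_i(t_i + |x − o_i|/v)` (nearest-origin kinematics). With
  sub-unit efficiencies, per-cell active origin sets are Bernoulli-sampled
  (cells with no active origin are redrawn) and the population median over
  1000 cells is used. There is no inter-origin interference, stochastic
  firing-time variance, or checkpoint dynamics — a documented
  simplification.
* **Populations** — synchronized cells replicate locus x by time t with
  probability Φ((t − trep(x))/σ); the S-entry jitter σ defaults to 3 min,
  a fixture choice (real synchrony dispersion is not sharply known) that
  reproduces the slightly-sub-2 mid-S control ratios real courses show.
  Sorted-S and asynchronous populations model S cells as uniform over
  normalized S progression — progression normalized to the trep range on a
  1 kb chromosome grid, so the earliest locus is replicated in every S cell
  and the latest in none. Sorted gates default to 5% G1 + 5% G2
  contamination, mirroring observed few-percent gate impurity; profiles are
  renormalized so the latest-replicating locus reads exactly 1, which
  compresses the upper end below 2 exactly as contamination does in real
  sorted samples. The asynchronous mode realizes the
  1 → 1 + (S-phase fraction) dynamic-range arithmetic exactly (1 → 1.2 at
  20% S cells).
* **Measurement noise** — ddPCR wells draw positives binomially at
  `p = 1 − exp(−cv)` per droplet (20,000 droplets/well, 1 nl default);
  sequencing counts are negative-binomial with `CV² = 1/mean + 1/size`,
  size 640 by default so that counts at 1000 reads/bin have ≈5% CV
  (overdispersion 0 reduces to Poisson, ≈3.2% at the same depth).
* **Screens** — mutants delay the firing time of the origin nearest the
  target locus; in the fixture landscapes locus trep is origin-dominated,
  so an injected delay maps ~1:1 onto trep. Strains receive independent
  lognormally-scaled overall concentrations, forcing downstream comparisons
  through a dynamic-range-invariant statistic.

Every generator is deterministic given (parameters, seed).

What passing tests do and do not show: the generator reproduces the
statistical structure the analysis assumes (Poisson partitioning,
calibrated count overdispersion, population mixing), not the full
complexity of real data — no PCR inhibition or rain, no mappability/GC
bias, no karyotype heterogeneity, no origin interference. Recovery results
on synthetic data therefore bound what the arithmetic can do under the
stated noise model, and say nothing about probe design or wet-lab artefact
handling.

## Problem sizes and numerical choices

Simulation-backed tests use 2,000 wells per occupancy for Monte-Carlo CVs,
500 bins at 1000 reads/bin for profile recovery (statistics averaged over
a few independent count draws, since they estimate expected recovery),
3 technical replicates of 20,000 droplets for ddPCR fixtures, 100,000
label permutations for the Tukey oracle, and 2,000 Monte-Carlo tables per
bisection step for the power analysis. Screen fixtures inject delays in
3-minute steps, which map to ≈0.07 copy-number units under the fixture
landscape — the smallest difference the package's own power analysis says
three-replicate ddPCR can resolve; smaller injected differences would be
unresolvable in principle, not just in simulation.

Tie-breaks are uniform: earliest sample for switch points and
target-fraction selection, factor nearest 1 for the range adjustment.
Degenerate inputs are first-class: zero-positive wells estimate zero
concentration with an undefined CV, flat control-ratio courses are flagged
rather than rejected, σ = 0 synchrony is a step function, and probes
without profile overlap yield missing values.

## Known limitations

* The range adjustment's small conservative bias (above) is inherent to
  the exceedance objective; profiles whose true values crowd one end of
  [1, 2] are rescaled a few percent toward the centre.
* Nearest-origin kinematics cannot represent replication-time plateaus
  created by origin clusters firing stochastically; trep landscapes are
  piecewise linear.
* The dual normalization assumes the early control finishes replicating
  before the late control starts; landscapes violating this produce a
  discontinuity at the switch that the package does not attempt to repair.
* CI propagation through normalizations is first-order; for very small
  replicate counts the seeded parametric bootstrap
  (`copynumber.bootstrap_ratio_ci`) is the safer summary for ratios.
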