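# Methods

This note documents the statistical models implemented in `slftrap`, the
assumptions behind them, the defaults and why they were chosen, and the known
limitations. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Dispersion statistics

A *group* is a set of n ≥ 2 sampling units (sticky-band traps, or 1,000 cm²
of trap surface) observed together — in practice one site × date × instar.
For counts x₁…xₙ with mean x̄ and sample variance s² (n − 1 denominator):

* **Lloyd's mean crowding** m\* = x̄ + (s²/x̄ − 1), the expected number of
  neighbors per individual per unit.
* **Index of dispersion** I = s²/x̄; I = 1 under a Poisson (random)
  arrangement.
* **Randomness test** χ² = I(n − 1), referred to the α/2 and 1 − α/2
  quantiles of χ² with n − 1 df. Below the lower limit → uniform; above the
  upper → aggregated; between → random.

Choices: the n − 1 variance denominator (required for the Poisson identity
E[m\*] = mean to hold); two-sided α defaulting to 0.05 (quantiles
0.025/0.975), configurable because the convention is not universal; groups
with zero mean are reported as *unclassifiable* rather than dropped, so
tallies always account for every group.

**Trap area.** A sticky band on a tree of diameter DBH with a foam spacer of
width f and exposed band width w has area π(DBH + f)·w. The foam is added
once to the diameter by default (`foam_added_twice=True` adds it on both
sides); with DBH 17.6 cm, f 2.0 cm, w 7.6 cm this gives 467.97 cm².
Per-area counts are count × 1000 / area.

## Iwao patchiness regression

Across groups, mean crowding is regressed on mean density by OLS. The slope
β measures aggregation: β = 1 random, β > 1 aggregated, β < 1 uniform; for
negative binomial counts with common size k, m\* = m(1 + 1/k) exactly, so
β → 1 + 1/k. Inference on aggregation is a two-sided t-test of β = 1 using
the slope SE and residual df.

The through-origin variant uses the no-intercept estimator Σxy/Σx², and its
R² is computed on the *uncentered* total sum of squares — the convention
under which forced-origin fits report slightly higher R² because only one
parameter is estimated. The two R² values are therefore not comparable
between variants, and no ordering between them is asserted anywhere.

Grouping keys are parameters (`group_keys=("site", "date")` by default)
because the appropriate granularity depends on the study layout; subset
comparisons (`fit_by_subset`) take named record filters so that
pre-treatment versus whole-season stability checks are explicit and fail
loudly on an empty filter.

## Enumerative sample size

The number of sampling units needed to estimate mean density x with
proportional precision d (SE of the mean over the mean) is

    q = (t²/d²) · [(α + 1)/x + (β − 1)]

with α, β the patchiness intercept and slope and t defaulting to 1.96 (the
normal-approximation Student's t at P = 0.05). For β > 1, q falls to a
plateau t²/d²·(β − 1) as x grows — for aggregated populations sampling
effort is nearly density-independent, and before rounding the deviation from
the plateau is bounded by t²/d²/x when α = 0.

Rounding is **nearest integer (half up)**, not ceiling: at β = 2.08,
x = 250, d = 0.30 the formula gives 46.27, and reference tables print 46;
ceiling would print 47. The minimum returned is one sample. Labor cost is
plain arithmetic — n·(minutes/60)·wage — rounded half-up to cents.

## Replication for treatment detection

Counts are analysed on the log scale, ln(count + 1); the +1 keeps zero
catches defined. A treatment reducing mean counts by proportion r shifts the
log-scale mean by j = ln(1 − r), so the standardized effect is |j|/σ with σ
the between-plot SD of log counts, estimated from untreated control plots on
the assessment date. The smallest per-group n giving the target power
(default 80%) for a one-sided two-sample pooled-variance t-test at α = 0.05
is solved from the noncentral-t power function (statsmodels
`TTestIndPower`) and **rounded up** — replication must meet the target, not
approximate it. For |j|/σ = 0.5 the solution is 51 per group (the normal
approximation gives 49.5; the test suite brackets the answer with a
Monte-Carlo t-test oracle).

Assumptions: equal group sizes, common variance, approximate log-normality
of counts. The `qq_normality` hook reports the correlation of ordered log
counts with normal plotting positions as a numeric stand-in for Q-Q plot
inspection. Dates whose control counts are all equal have σ = 0 and are
flagged with an infinite requirement rather than an error.

## Design simulation (CRD vs. RCBD)

Each simulated experiment with n replicates per arm:

1. **Pretreatment abundance**: 2n draws from a negative binomial fitted to
   pretreatment counts. The *linear* parameterization (var = μ(1 + φ)) is
   the default for this fit.
2. **Assignment.** CRD: a uniformly random half of the plots is treated.
   RCBD: plots are sorted from highest to lowest pretreatment count (stable
   order on ties), consecutive pairs form blocks, and one plot per pair is
   treated at random.
3. **Projection.** Each plot's assessment-date count is an NB draw with mean
   β·N_init (β the regression slope of assessment-date on prior-date counts)
   and variance μ(1 + μ/k) — the *quadratic* parameterization, with
   k = `projection_dispersion`. Treated means are multiplied by (1 − r).
   N_init = 0 gives a deterministic 0.
4. **Analysis.** NB2 regression of post counts on the treatment indicator;
   one-tailed test that the treated mean is lower.

Parameterizations are explicit per stage because the two stages genuinely
use different variance laws; both are exposed and named
(`linear`/`quadratic`) rather than overloading one symbol.

**Block term.** The RCBD analysis defaults to a per-block N(0, σ²) random
intercept, fitted by maximizing the Laplace-approximated marginal likelihood
(block modes by closed-form Newton; σ and the NB size k on box-bounded log
scales; Wald SE from the observed information restricted to parameters not
on a bound — a variance component estimated at zero has no curvature and
would otherwise make the information singular). Fixed block indicators are
available via `block_effects="fixed"` but are *not* the default: with two
plots per block they suffer incidental-parameter bias (measured null
rejection ~0.11–0.13 at nominal 0.05 in this implementation) and frequent
non-convergence when low-count blocks appear, which is why the
random-intercept model is the recommended analysis.

**Significance reference.** The Wald statistic is referred to a one-sided
*t* distribution with df = observations − fixed mean parameters (CRD:
2n − 2; random-intercept RCBD: 2n − 3). A normal reference measured
anti-conservative at small n (≈0.11 at n = 4 per arm); the t reference
calibrates to ≈0.05–0.07 across n = 4–12 in the test suite's 300-simulation
cells.

**Degenerate outcomes.** A treated arm with zero catch against a positive
control arm is complete separation and counts as significant (it is the
limit of the NB fit). A fully zero experiment, a zero control arm, or a
non-converged fit counts as non-significant and is tallied in the output
(`n_flagged`), never silently dropped.

**Reproducibility.** Each grid cell spawns an independent child seed from
the grid seed (`numpy` `SeedSequence.spawn`), and draws within a simulation
are consumed in a fixed order (pretreatment, CRD assignment, RCBD
assignment, CRD projection, RCBD projection), so a grid is bit-identical
across runs and insensitive to cell order. Power estimates carry the
binomial MC standard error √(p(1−p)/n_sims) ≈ 0.023 at p = 0.8 with the
default 300 simulations per cell.

The test suite's reference grid uses pretreatment NB(mean 50, var 250),
projection slope 0.8, projection k = 5, n ∈ {4, 8, 12},
r ∈ {0, 0.45, 0.6, 0.75, 0.9} at 300 simulations per cell — small enough to
run in minutes on one core, large enough that the null calibration,
monotonicity, and the blocked design's mean-power advantage are all outside
MC noise.

## Temporal structure

Spearman rank correlations (average ranks on ties; pairs matched by trap id,
missing traps dropped pairwise, dates with fewer than 3 common traps
flagged) are computed in two modes: each date against the first date
(baseline) and against the immediately preceding date. With persistent trap
quality, the baseline series decays with lag while the consecutive-date
series stays high — the pattern that makes blocking on pretreatment counts
worthwhile only if assessment follows treatment quickly.

The seasonal summary fits an NB2 regression of per-trap counts on date as
the only factor (one indicator per date, no intercept). The model is
saturated in date, so fitted marginal means equal per-date sample means;
Wald intervals on the log scale give asymmetric 95% CIs on the response
scale. Dates with one trap or zero total catch are dropped with a warning
(a log-scale mean is not estimable at zero).

## Synthetic data generator

`SyntheticConfig` describes a trapping campaign; `generate` produces a tidy
trap-count table. Per trap i and date t the count is negative binomial
(quadratic size k) with mean

    μ_it = baseline_mean · exp(−decline_rate · days_t) · M_it · (1 − r·treated_i)

where M_it = exp(σz_it − σ²/2) is a mean-one log-normal multiplier whose
latent z follows a stationary AR(1) with coefficient `trap_autocorr` and
unit marginal variance, σ = `trap_sd_log`. Totals are split into the four
instars by a static multinomial mixture; an explicit `combined` row is also
written. `nb_size_k = inf` gives Poisson counts.

Defaults and what they emulate: 6 sites × 15 traps every 3 days (a
mid-season rural campaign); baseline 100 nymphs/trap declining 5%/day (the
observed order-of-magnitude seasonal decline); k = 2 (patchiness slope 1.5
before heterogeneity, within the 1.4–2.6 range seen on sticky bands);
`trap_autocorr = 0.8` with σ = 0.5 (consecutive-date rank correlations
around 0.7–0.8, decaying toward the baseline date with lag); trap geometry
DBH ~ N(17.6, 4.7) cm clipped at 5 cm, 7.6 cm band, 2 cm foam.

The quadratic-NB generator was chosen because it yields the exact identity
m\* = m(1 + 1/k), giving closed-form targets for slope-recovery tests. With
σ > 0 the marginal counts are *more* aggregated than NB(k): mixing over the
mean-one log-normal multiplier gives var/mean = 1 + mean·((1 + 1/k)e^{σ²} −
1), which exceeds the pure-NB ratio 1 + mean/k, so identity-based tests set
σ = 0 explicitly.

What the generator does **not** emulate — and what passing tests therefore
do not establish about field data: instar phenology (the mixture is static,
real instar composition shifts through the season); spatial structure within
a site (traps are exchangeable given their multiplier); trap saturation and
removal effects; weather-driven shared shocks across traps; and the
open-plot immigration/emigration that blurs treatment effects in real
trials. Results on synthetic data validate the *statistical machinery*, not
the field protocol.

## Numerical choices and degenerate inputs

* NB maximum likelihood for iid samples: sample-mean plug-in plus 1-D
  profile on log k (quadratic) or joint Nelder-Mead on (log μ, log φ)
  (linear); samples with variance ≤ mean are pinned at the Poisson boundary
  with a warning rather than chasing an unbounded k.
* NB2 regressions are warm-started from a Poisson GLM; non-convergence is
  reported as a flag, not an exception, so simulation loops can tally it.
* Dispersion bounds in the paired random-intercept fit: log k ∈ [−4, 8],
  log σ ∈ [−4, 2]; estimates on a bound are treated as boundary cases for
  the SE computation.
* All-zero count vectors raise explicit degenerate-sample errors in mean
  crowding and the dispersion test (the statistics are undefined), and
  CSV validation reports 1-based row numbers including the header, matching
  what a spreadsheet shows.

## Known limitations

* The design simulator models exactly two arms and pair blocks; unequal
  allocation, more arms, or larger blocks are out of scope.
* The Laplace approximation for the block random intercept is accurate for
  the moderate counts typical here but degrades for very sparse blocks
  (mostly-zero counts) — such experiments mostly resolve through the
  separation/degenerate paths instead.
* Sample-size formulas take the patchiness parameters as known; uncertainty
  in α and β is not propagated into q.
* Labor costing covers servicing time only (no travel, no trap materials).
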