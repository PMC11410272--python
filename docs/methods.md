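# Methods

This note documents the statistical model behind each analysis, the
defaults and why, what the synthetic-cohort generator does and does not
emulate, and the numerical choices a maintainer should know about.

## Standardisation and effect scales

All per-SD metrics standardise the raw score by the affine map
`z = (s − mean)/sd` computed in a reference subgroup — by default the
ancestry group being analysed, so "per SD" is ancestry-specific and
cross-ancestry comparisons are per-SD within each group. The population
SD (denominator n) is used so that the two-point example {0, 2} maps to
{−1, +1}; descriptive distribution summaries report the usual n−1 SD.
Because the same affine map is applied to everyone, subgroups other than
the reference do not generally end up with unit SD — that is intentional.

Quantitative traits are standardised to zero mean and unit variance
before regression; for sex-stratified work (and the pooled "all" analysis
that accompanies it) the trait is standardised within each sex separately
and then combined, which removes pure location/scale differences between
the sexes and changes the effect scale relative to the unstratified
analyses — reports label the convention used.

## Estimators

**OR per SD.** Logistic regression of case status on the standardised
score, adjusting for age at assessment (linear) and sex (dropped
automatically for sex-restricted traits). Newton/IRLS with tolerance
1e−8, at most 100 iterations; non-convergence is an error, never a silent
estimate. Complete separation is detected from a diverging coefficient or
unbounded standard error and reported as such.

**HR per SD.** Cox proportional hazards fit by an in-package
Newton–Raphson on the Breslow partial likelihood (tolerance 1e−8, 100
iterations), with optional delayed entry. The solver is exercised against
statsmodels' `PHReg` (Breslow, with and without entry) and lifelines in
the test suite. Default timescale is age; in incident mode individuals
enter the risk set at their assessment age and prevalent cases are
excluded. On the age timescale the age covariate is dropped (it is the
time axis). Breslow was chosen over Efron because event ages in the
intended inputs are effectively continuous (ties are rare), and the
Breslow likelihood is the one for which the small-data enumeration oracle
in the tests is written.

**AUC.** Mann–Whitney concordance with midrank handling of ties, i.e.
ties count ½. The CI is the DeLong analytic one (structural components
per case and control); a bootstrap CI would also be defensible but the
analytic form is deterministic and fast. The AUC is computed from the PRS
alone, without covariates.

**β per SD / r².** Ordinary least squares; r² is reported as the
*increment* in model R² from adding the score to the covariate-only
model, which isolates the score's contribution from age and sex.

**Effective sample sizes.** Two standard formulas:
`4·Σ n_j c_j (1−c_j)` over constituent GWASs, and `4/(1/n₀ + 1/n₁)` for a
single case-control design. They agree exactly on a single component —
an algebraic identity asserted in the tests.

## Percentile bands and cumulative incidence

Band membership uses the "≤" empirical CDF: individuals are sorted by
(score, individual id) — the id is a deterministic tie-break — ranked
1..n, and rank r has percentile 100·r/n; a band (low, high] holds
low < percentile ≤ high. Membership therefore depends on ranks only and
is invariant to monotone transforms of the score and to row order.

Cumulative incidence is 1 minus the Kaplan–Meier survival estimate
(lifelines), with Greenwood variance and log(−log) ("exponential
Greenwood") 95% bounds, which keep the interval inside [0, 1]. Two modes:
*lifetime* (default) enters everyone at age 0 and counts retrospective
diagnoses, matching from-birth incidence curves; *incident* left-truncates
at the assessment age and drops prevalent cases. Death and loss to
follow-up are treated as independent censoring — a Kaplan–Meier, not
Aalen–Johansen, estimate; with a competing mortality risk correlated with
the score this overstates absolute risk slightly. Documented limitation.

Gating: a per-ancestry metric needs at least 100 cases ("at least", so
exactly 100 passes); a curve needs more than 40 cases (so exactly 40 is
suppressed). Gated results keep their counts and a reason string.

## Score-vs-score comparison and ancestry change

The paired bootstrap draws the same resample of individuals for both
scores and takes the difference of the two estimates per replicate — on
the log scale for ratio metrics, natural scale for AUC and β. The
two-tailed p is `2·min(frac ≤ 0, frac ≥ 0)` clipped to
[2/(B+1), 1]; identical score columns short-circuit to difference 0,
p = 1. B defaults to 5000. Replicate failures (e.g. a resample with no
cases) are tolerated up to 5%, then an error.

Relative performance change of a target ancestry vs the reference is
`(log effect_target − log effect_ref)/log effect_ref` (β scale for
quantitative traits), with a delta-method CI treating strata as
independent; it is undefined when the reference log-effect is not
positive. Cross-trait averaging is an inverse-variance fixed-effect mean —
a package choice, recorded in the report, since "averaging across
traits" does not pin down a weighting.

## Strata

Age-window analyses select by age at assessment, exclude prevalent
cases, censor at a 10-year horizon and fit the Cox model on the follow-up
timescale. Sex-stratified analyses adjust for age only (sex is constant
within a stratum). Differences between disjoint strata use
`SE = √(SE₁² + SE₂²)` and a two-tailed z-test, with the usual
0.05/0.01/0.001 star annotations.

## Carrier equivalence

Carrier cumulative risk at the anchor age (default 70) comes from the
Kaplan–Meier curve of the carrier subgroup. The matched top fraction q is
found by evaluating the top-q band's KM risk on a 0.5-percentile grid
over q ∈ [0.001, 0.5] and taking the smallest fraction whose risk is
closest to the target. The grid is scanned exhaustively rather than
bisected: the band risk is a noisy step function of q, and bisection can
settle several grid steps away from the nearest-risk fraction. Overlap
between carriers and the matched band is reported (with its expectation
under independence), not removed. Subgroup filters such as "statin-free"
are generic row predicates applied before the analysis and recorded in
the output.

## Multivariate block

Score-score Pearson correlations are pairwise complete-case; one triangle
is computed and mirrored so the stored matrix is exactly symmetric.
Display order comes from complete-linkage hierarchical clustering of the
correlation rows (Euclidean distance), with rows entered in name order so
the leaf order is deterministic and permutation-invariant.

The mortality model is forward-stepwise Cox over candidate scores —
enter the smallest Wald p below `entry_p`, remove any selected score
whose p rises above `removal_p`, iterate to a fixpoint; both thresholds
default to 0.001 and are recorded in the output. Own-survival models use
time from assessment with age-at-assessment and sex as fixed covariates;
parental models take one observation per parent (age at death or
censoring from birth) adjusted for the participant's age at assessment
and the parent's sex. Within-family correlation between the two parents
is ignored in the standard errors — a documented limitation.

Model quality: Harrell's C (prediction ties ½) with a paired-bootstrap CI
on the change between nested models (1000 resamples by default, seed
recorded), and Royston & Sauerbrei's R²_D — the prognostic index is
replaced by Blom normal scores scaled by κ = √(8/π), the Cox coefficient
of that regressor is the separation D, and
`R²_D = (D²/κ²)/(D²/κ² + π²/6)`. A constant index returns 0.

A score whose latent value a parent shares at correlation ρ = 0.5 should
show about half its own-mortality log-HR in the parental model; the
own:parental ratio with a delta-method CI quantifies this 2:1
expectation.

## Synthetic cohort generator

The generator is the package's stand-in for a biobank testing subgroup
and defines the conditions under which everything is tested.

- **Composition.** Default 16,000/1,600/1,600/480 individuals labelled
  EUR/SAS/AFR/EAS — the 82/8/8/2 make-up of a large ancestry-maximised
  testing subgroup at roughly one-fifth scale, chosen so the whole suite
  runs in minutes while leaving non-EUR groups near their realistic
  (sometimes gated) case counts.
- **Scores.** Latent standard-normal per trait with a configurable
  cross-trait correlation (mixed through a lower-triangular Cholesky with
  one named substream per trait, so appending a trait never perturbs
  existing draws). Reported raw scores are per-ancestry affine maps of
  the latent score (location shifts up to 0.3 SD, scale up to 1.1) —
  standardisation must undo them.
- **Disease onset.** Proportional hazards on the age axis with a
  piecewise-constant baseline; event ages by inverse transform, exact per
  segment, including an optional linear age interaction of the per-SD
  log-HR (`exp((β + γ·age)·z)`) so age-window analyses have a
  controllable truth. The default disease approximates a
  coronary-artery-disease-like trait: baseline cumulative hazard ≈ 0.087
  by age 70 (≈ 8% female / ≈ 12% male risk with the sex log-HR 0.4),
  per-SD log-HR 0.5; a second, more heritable and commoner trait (per-SD
  log-HR 0.8) exercises correlation and clustering code.
- **Cross-ancestry attenuation** multiplies the true per-SD effect by
  1.0/0.9/0.85/0.75 (EUR/SAS/EAS/AFR), mirroring the reduced
  transferability the evaluation is designed to expose.
- **Carriers** are Bernoulli, independent of the score (low linkage
  between rare and common variation), default frequency 0.35% and hazard
  ratio 3 for the CAD-like trait.
- **Follow-up and mortality.** Assessment age ~ N(57, 8²) clipped to
  40–70, administrative censoring 10–14 years later; each person's death
  age is drawn from a piecewise-constant all-cause hazard conditional on
  being alive at assessment, with configurable per-score log-HRs.
  Parents' lifespans use the same hazard from birth, with latent scores
  `ρ·offspring + √(1−ρ²)·noise`, ρ = 0.5 by default.
- **Treatment flag.** A "statin-like" indicator drawn from a logistic
  model on a noisy risk proxy (score + carrier status + noise), giving
  ~10% treated with realistic confounding for subgroup-filter tests.
- **Analytic oracle.** `expected_cumulative_risk` integrates
  `1 − E[exp(−HR(z)·Λ₀(age))]` over the (band-truncated) score
  distribution by midpoint quadrature on the percentile scale, and is the
  reference for incidence and carrier tests.

What the generator does **not** emulate: genotypes or LD, EHR phenotyping
error, healthy-volunteer selection, informative censoring beyond the
score-mortality link, family structure beyond the parent-offspring score
correlation, and secular trends in cause-specific mortality. Passing
tests therefore demonstrate correctness of the estimators under the
stated model, not robustness to those real-data features.

## Problem sizes used in the tests

Unit tests run on micro-datasets (exact oracles) and cohorts of 10–50k;
the parameter-recovery checks use 50 replicates of n = 20,000 per
estimator; the trio-mortality check uses n = 100,000 with ~45,000
participant deaths and two parents per participant. These sizes were
chosen as the smallest at which the Monte-Carlo error of each check is
comfortably inside its assertion tolerance.

## Known limitations

- Kaplan–Meier treats death as independent censoring (no competing
  risks).
- Bootstrap comparisons are nominal, with no cross-trait multiplicity
  correction in the core (a Bonferroni helper exists, off by default).
- Parental survival models ignore within-family SE correlation.
- The stepwise mortality model is for insight, not prediction; explained
  variation is expected to be small and is reported as such.
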