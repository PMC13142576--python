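# Methods

This note records the models implemented by `iivd`, the assumptions and
numerical choices behind them, what the synthetic cohort generator does
and does not emulate, and the known limitations.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## 1. Normative T-scoring

Per battery test, a linear model `raw ~ age + sex + education` is fit by
least squares on a reference sample (default: the healthy-control
analysis set; the provenance of real internal norms is typically a
larger mixed sample, so this default is an explicit, configurable
assumption).  The *selective correction* rule is operationalized as:
fit the full three-covariate model, keep covariates with Wald p < α
(default α = 0.05), refit once on the retained set.  Sex enters as a
single male indicator; no interactions or splines.  The residual scale
uses the unbiased denominator n − k − 1.  T scores are

    T = 50 + 10 · s · (x − x̂) / s_resid,   s = −1 for timed tests,

so higher is better for every test.  Consequences worth knowing:

- Applied to its own reference the fitted norms give per-test mean
  exactly 50 (intercept + in-sample residuals) and SD
  10·sqrt((n−k−1)/(n−1)) — within 10 ± 0.01 for n ≳ 2000 (asserted).
- T scores are invariant to affine rescaling of a test's raw units
  (selection p-values, residual quotients unchanged; asserted).
- With a small reference (n ≈ 100), the per-test residual-scale noise is
  shared by everyone scored against it; out-of-reference groups pick up
  a small upward CoV bias (≈ +0.007 at n = 102, vanishing as 1/n).

## 2. Dispersion

CoV = (population SD of the 11 T scores) / (their mean); the n-divisor SD
is definitional here, with a `ddof=1` flag only for sensitivity analysis.
The attention/executive CoV restricts to SDMT, TMT-A, LNS, lexical
fluency and TMT-B.  Panels missing any score are excluded (and counted);
a non-positive mean composite makes CoV meaningless, so such panels are
excluded and counted rather than emitted as NaN — they do not occur in
the calibrated T range.  No winsorizing or trimming.

## 3. Staging and conversion

Stage labels follow the NSD-ISS anchors: SAA-negative → HC candidate;
SAA-positive with functional impairment (slight or greater) → Stage 3+;
SAA-positive with subtle signs and no impairment → 2A/2B by DAT deficit;
SAA-positive without signs → Stage 1.  The staging system's "subtle
signs" thresholds are defined in its own criteria, not reproduced here;
for synthetic data they are operationalized as any of {hyposmia flag,
RBDSQ ≥ 5, MDS-UPDRS III > 0} — real-data users should pass their own
sign rule.  HC analysis-set eligibility: baseline MoCA ≥ 27, no
hyposmia, negative SAA, Year-1 MoCA ≥ 26 with at most a 2-point decline.
Baseline is the first visit with a complete battery; conversion follow-up
accepts the earliest complete-battery visit 0.75–1.25 years after
baseline (real studies use actual dates; a window is the reproducible
surrogate).  Stage assignment is a pure function of a single visit.

## 4. Group statistics

Pooled t by default; Welch's t (Satterthwaite df) when a two-sided
variance F-test (larger variance on top) has p < 0.05; zero variance on
either side forces Welch by the convention p = 0.  Cohen's d always uses
the pooled SD, also under Welch — this matches how the published effect
sizes close against their printed summaries.  Signs are group1 − group2.
The BH step-up procedure runs across one table's rows as the family
(the family boundary is a design choice; each emitted table is one
family) and the report carries raw p, BH-adjusted p, and the flag, since
published tables are often ambiguous about which is printed.  Pearson
correlations use the t-approximation for p.

## 5. Logistic conversion models

Maximum likelihood by IRLS (Newton) with intercept; convergence at
max |ΔB| < 1e-8 within 100 iterations; SEs from the inverse observed
information; CIs via exp(B ± 1.959964·SE); LR test and Nagelkerke R²
against the intercept-only null on the same subjects; Hosmer–Lemeshow on
g = 10 near-equal risk deciles (ties kept together; df = g_eff − 2,
clamped at ≥ 1 for degenerate groupings).  After every fit the score
equations Xᵀ(y − p̂) = 0 are verified to 1e-6; complete or
quasi-separation is detected from divergence of the linear predictor and
raised, never silently returned.

**CoV scaling.** CoV enters the models per 0.1 unit (option:
raw units or z-scored).  A log-odds coefficient of 0.362 *per raw CoV
unit* would be statistically invisible at the cohort's CoV spread
(SD ≈ 0.08–0.10): it could not produce the observed converter versus
non-converter CoV separation (|d| ≈ 0.3), an LR χ²(2) near 46 at
n = 440, or coefficient recovery to ±0.05 at n = 50,000 (the Wald SE per
raw unit is ≈ 0.11 even at that n).  Per-0.1-unit entry is the unique
scaling consistent with all of these at once, so both the generator and
the fitted models use it.

## 6. The synthetic cohort generator

Per subject i: latent ability θᵢ ~ N(0, τ²) and within-person dispersion
σᵢ from a truncated-at-zero normal, negatively coupled to ability
(Gaussian copula, r = −0.30) — worse ability tends to accompany more
dispersion.  Test j at visit t is θᵢ + σᵢ·ε_ijt on a latent T metric,
mapped to plausible raw scales (registry defaults) with injected age /
sex / education effects so that norming has genuine signal; the exact raw
scales are irrelevant by affine invariance.  Clinical scales are rounded
clipped normals at the published group means/SDs; MDS-UPDRS III is a
zero-censored normal (the published mean/SD ratios are too overdispersed
for any zero-truncated normal), coupled to ability (r = −0.25) so that
converters also show lower composites; Hoehn & Yahr is an ordered probit
on the UPDRS latent.  Dispersion propensity is coupled to age, education,
depression and anxiety scores with copula correlations equal to the
published within-Stage-2 CoV correlations divided by the measured
attenuation of 11-test CoV (≈ 0.78).

Year-1 visits redraw the within-person noise (same θᵢ, σᵢ — no
progression model).  A configured fraction of Stage-2 subjects has a
Year-1 battery; their functional-impairment outcome is Bernoulli with
logit b₀ + 0.362·(CoV/0.1) + 0.09·UPDRS-III evaluated at the *baseline*
latent CoV, and impairment at Year 1 is what moves them to Stage 3+.

**Calibration.** Group dispersion parameters are solved once by
simulated moment matching with common random numbers (400,000 subjects;
`iivd._calibration`), and frozen as defaults:

- Stage 2: CoV mean/SD (0.21, 0.10) and composite SD 6.27 are matched
  exactly; the latent composite mean is 50 − 3.43 = 46.57, preserving
  the published HC−Stage-2 contrast (the absolute level shifts because
  HC-referenced norming pins HC at exactly 50).
- HC (the norming reference): per-test T variance is 100 by
  construction, so τ² + E[σ²] = 100.  With 11 tests and CoV mean 0.18
  this budget makes the published HC CoV SD of 0.07 unattainable — the
  feasible maximum is ≈ 0.066 — and makes the published HC composite SD
  (5.60) jointly infeasible with the CoV mean.  Calibration matches the
  CoV mean exactly and stores the realized SD (0.0658) as the configured
  target.  This is a structural property of any one-factor battery model
  normed on its own reference, and a point where the published moments
  are mutually in tension.
- The conversion intercept (−2.759) is solved so the mean conversion
  probability among baseline-staging-retained Stage-2 subjects is
  100/440; the follow-up fraction folds in the 1.24% of Year-1 offsets
  (N(1.0, 0.1²)) falling outside the window and the ≈ 3.4% of the arm
  staged 1 at baseline, so the *followed* expectation is ≈ 440.

What the generator does **not** emulate: between-test correlation
structure beyond a single ability factor, practice effects, item-level
scores, missing data (batteries are complete by default), progression of
scales between visits, race/ethnicity strata, genetic arms.  A green
simulation test therefore establishes the pipeline's behavior under this
stated world, not under real cohort idiosyncrasies.

## 7. Reproducibility and tolerances

Everything random flows from one integer seed through
`numpy.random.default_rng`; identical config + seed yields byte-identical
cohorts and report bundles (asserted).  Simulation-based test tolerances
are 3–4 Monte-Carlo standard errors at the n actually run, with the
calibration solver's own Monte-Carlo error added where relevant;
cross-seed SDs at the published scale (e.g. ±0.011 on the Stage-2 CoV
mean, ±18 on the followed count) set the acceptance bands.  Analytic
recomputation of published statistics from printed summaries uses
tolerances reflecting the 2-decimal rounding of those summaries
(|t|: max(0.15, 2.5%); d: 0.02); a few printed entries are not
reproducible from their own summaries under either t formula and are
excluded from assertion rather than matched loosely.

## 8. Known limitations

- The HC dispersion SD and composite SD cannot both reach their
  published values under self-referenced norming (see §6); relative
  group contrasts, not absolute HC spreads, are the calibration
  priority.
- With the default n = 102 reference, norm-estimation noise inflates
  Stage-2 measured CoV by ≈ +0.007 and widens its spread; this is a real
  property of small-reference norming, left in deliberately.
- The conversion model is cross-sectional logistic over a fixed window;
  no time-to-event modeling.
- Stage labels above 3 ("3plus") are not severity-resolved; 2A/2B split
  defaults to 50% DAT-deficit, an assumption where no published split is
  available.
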