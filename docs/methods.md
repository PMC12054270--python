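# Methods

This note records the statistical model implemented by `nestmi`, the default
parameter choices and why they were made, the numerical decisions, and the
limits of what the synthetic-data experiments can show.

## Data model

A cohort of N subjects is observed at T = 5 exams spaced 5 years apart.
Six variables are measured — smoking status (binary) plus BMI, SBP, DBP,
total cholesterol and fasting glucose (continuous) — and reduced to P = 5
components of the composite score: blood pressure pools SBP and DBP with a
conjunctive rule.  The full data are a single multivariate normal draw over
the 30 variable-time pairs plus two baseline covariates (age, sex-latent);
binary variables are dichotomised at the empirical quantile matching their
target prevalence, which fixes the prevalence exactly up to rank ties.

The joint correlation is block-structured: an exchangeable within-variable
correlation ρ_w across exams, a constant between-variable correlation ρ_b at
every time-pair, and a constant variable–covariate correlation ρ_c.  The
assembly is checked for positive definiteness at validation time and the
offending blocks are named on failure.

### Default cohort parameters

The exam-level moments of the access-restricted cohort this design emulates
(exact means, SDs, correlations and MAR coefficients) are not public, so the
defaults are the package's own calibration, chosen once to reproduce the
intended structure:
non-decreasing means, moderate-to-high within-variable correlation,
low between-variable correlation, and realized missingness rates matching
the documented study conditions.  They describe an ageing cohort (baseline
age 55 ± 9 y) whose risk factors drift upward over 20 years:

| variable | means at exams 1..5 | SD |
|---|---|---|
| BMI (kg/m²) | 27.0, 27.4, 27.8, 28.1, 28.3 | 4.8 |
| SBP (mmHg) | 125, 128, 131, 134, 137 | 17 |
| DBP (mmHg) | 78, 79, 79.5, 80, 80 | 10 |
| TC (mg/dL) | 205, 208, 210, 212, 213 | 38 |
| BG (mg/dL) | 98, 100, 102, 105, 108 | 22 |
| smoking prevalence | 0.22 at every exam | — |

with ρ_w = 0.70 for every variable, ρ_b = 0.15, ρ_c = 0.10.  Against the
ideal-level thresholds (non-smoker; BMI < 25; SBP < 120 and DBP < 80;
TC < 200; BG < 100 — the Life's Simple 7 ideal conventions, all
configurable) this yields a composite mean falling from ≈ 2.35 at exam 1 to
≈ 1.85 at exam 5, i.e. worsening population health, which is the regime in
which lower-tail non-attendance and survival bias are scientifically
interesting.

## Missingness generation

The cohort is split into halves.  The **MAR half** receives item-level
missingness in two designated components (BMI and TC by default) and
whole-wave non-attendance at exams 2–5, drawn Bernoulli from logistic models
in the standardized baseline value (items) or baseline composite (waves)
plus age and sex.  Intercepts are calibrated so the realized cohort-wide
rates are 5/3/8/9% per item and 5/4/8/11% per wave at exams 2–5.

The **MNAR half** receives whole-wave non-attendance only, keyed to the
subject's *current* composite: at exam t, members whose score ranks in the
scheduled tail fraction (10/15/20/25% at exams 2–5; lower tail in scenario
1, upper in scenario 2, both tails — half the fraction each — in scenario 3)
lose all six variables with probability 0.8.  Because the composite is
integer-valued, tail selection uses exact-fraction ranking with uniform
tie-breaking jitter; naive quantile thresholds overshoot on ties.

Two calibration modes exist because the percentile rule and the documented
realized missingness cannot both hold exactly: `mode="rule"` applies the
percentile schedule literally (realized within-group wave rates
8/12/16/20%), while `mode="rates"` back-solves the tail fraction so the
realized rates match a target schedule, by default 10/12.5/15/17.5% *of the
whole cohort*.  The study presets use the rate-calibrated mode: the
simulation experiments are defined by their realized missingness burden, and
the cohort-wide reading is the one consistent with the MAR rates applying to
half the cohort.  Both modes are exposed on `MnarScenario`.

## Death times and the survival analysis

Death times follow a piecewise-exponential model over the five 5-year
intervals with baseline hazards 0.012–0.032 /y (increasing) multiplied by
exp(γ₁ C_it + γ₂ᵀX_i), using the *true pre-missingness* composite at the
exam opening each interval.  Defaults γ₁ = log 0.85 per composite unit,
γ₂ = (log 1.06 per year of age over 55, log 1.4 for men) give ≈ 40%
cumulative mortality by year 25.  Exams strictly after a death are labelled
a third mechanism (post-death) and excluded from Cox risk sets, but they
*are* imputed: the chained-equations pass needs complete predictors, and
Stage 2 requires every Stage-1 cell fixed.  The k-transform is not applied
to post-death cells by default (the adjustment models the non-attendance
group; a switch extends it).

The Cox analysis uses counting-process episodes [exam_t, exam_{t+1}) with
the composite constant within the episode (the carry-forward convention for
a covariate measured at exams).  The default fitter is an in-package Breslow
partial-likelihood Newton solver whose risk-set sums are computed by
vectorised suffix cumulative sums over episodes sorted by start and stop;
it agrees with lifelines' `CoxTimeVaryingFitter` to ~1e-6 on tie-free data
(asserted in the tests) and is two orders of magnitude faster, which the
replicate loop requires.  `backend="lifelines"` selects the library fitter.

## Imputation engine

Chained equations treat each variable at each exam as a distinct column.
Elementary draws: bootstrap linear regression (resample, least-squares fit,
draw residual noise) for continuous columns — the default for its speed —
with Bayesian linear regression (scaled-inverse-χ² variance, normal
coefficient draw) retained and shown distributionally equivalent at moderate
n; approximate-Bayesian logistic regression (ML fit, normal perturbation of
the coefficients using the asymptotic covariance, Bernoulli redraw) for the
binary column.  Implementation notes:

* visit order is column order (exams within variable); the procedure is not
  order-sensitive in our experiments and no ordering is claimed;
* 5 sweeps after a marginal random initial fill (`n_iterations = 0`
  documentedly returns the initial fill);
* singular bootstrap designs are redrawn up to 10 times, then ridge-repaired;
  logistic separation falls back to a weak (λ = 0.5) ridge penalty; a
  single-class column imputes the constant class with a logged warning;
* observed cells are never touched, binary imputations are exactly {0, 1}.

Stage 1 runs the chain over the *full* missingness pattern and keeps only
the MNAR (and post-death) draws — chained equations need complete
predictors, and per-pattern observed-predictor models are fragile when
patterns proliferate.  The binary odds-ratio transform fits its logistic
model on the completed column using the column's own FCS predictor row; the
regressor set for this fit is a documented package default, not implied by
the combining rules.  The default k grid pairs continuous multipliers with
binary odds ratios {0.8→0.5, 0.9→0.5, 1→1, 1.1→2, 1.2→2} and is
user-overridable.

Within the study loop the m Stage-1 chains are shared across k values (the
transform is applied per k to the same raw draws) and Stage-2 seeds are
shared too; this is both a large saving and the paired design that makes
dose-response in k exact for continuous cells.

## Pooling and degrees of freedom

The nested combining rules are implemented exactly as stated in the README.
When both variance-ratio terms vanish (B = W = 0) the ν* expression is
undefined and the implementation uses the normal reference; no small-sample
(Barnard–Rubin-type) adjustment is applied because none is part of the
method.  Per-time means use the simple s²/N within-dataset variance; the
mixed model is fitted by ML (not REML) for likelihood comparability.

## Truth computation

True per-exam means and the true slope come from one complete synthetic
population (10⁶ subjects at full scale, 10⁵ at desk scale).  The slope truth
is computed by pooled OLS: for balanced complete panels under a
random-intercept (compound-symmetry) covariance the GLS fixed-effect
estimates coincide with OLS, so this equals the mixed-model slope without an
iterative fit over millions of rows (the equivalence is asserted in the
tests).  The log-hazard-ratio truth is the generating γ₁, not re-estimated.

## Study scales

Two presets ship.  The full-scale preset mirrors the motivating study
(3700 subjects, 500 replicates, m = n = 5).  The desk-scale preset
(1000 subjects, 100 replicates, m = n = 3, 10⁵-subject truth population) is
the package's reproducibility surface: it finishes in minutes per scenario
on one CPU and every reported bias and coverage carries a Monte-Carlo
standard error so tolerance checks are principled.  Note that coverage
probabilities are *scale-sensitive*: a fixed bias that destroys coverage at
n = 3700 may leave substantial coverage at n = 1000 because the interval is
√3.7 wider, so desk-scale coverages under misspecified assumptions are
systematically higher than their full-scale counterparts.

## What the synthetic experiments do and do not show

The generator reproduces the design of the motivating cohort, not its data:
exchangeable (not decaying) within-variable correlation, a single constant
between-variable correlation (in particular SBP–DBP correlation is not
elevated), per-wave independent non-attendance (so dropout is less monotone
than in real cohorts, where depleted longitudinal histories weaken LFCS and
AFCS), a single binary component, regular visit spacing, and no competing
risks.  Passing tests therefore demonstrate the internal validity of the
procedure — correct combining rules, exact k-adjustment, unbiasedness when
assumptions hold, the expected ordering of assumptions and structures — on
cohorts of this structure; they do not certify performance on any real
cohort, where the appropriate k must come from substantive knowledge or
follow-up samples.

## Known limitations

* Percent bias is reported as an absolute value (signed bias is retained in
  the raw results table); zero-truth estimands need absolute bias instead.
* The composite must be fully determined or fully missing per cell; partial
  credit for partially observed waves exists only through item-level
  imputation.
* Mixed-model-based FCS for irregular intervals, three-stage MI with
  stochastic k, selection-model and pattern-mixture Stage-1 alternatives,
  and rates of missing information are out of scope.
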