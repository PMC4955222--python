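# Methods

## Data model and estimators

A cohort couples a subject-level survival table (time in months, censoring
indicator, event type 1/2, clinical covariates) with a subjects × features
matrix of normalized log2 expression values.  Subject order after id
alignment is the canonical key; subsample and outlier index sets always
refer to positions in that order.  Missing values are rejected rather than
imputed.  Times are continuous with ties allowed; all partial likelihoods
use the Breslow tie approximation, so Cox and Fine–Gray fits handle ties
identically.

One weighted partial-likelihood engine underlies every regression.  A
*risk structure* precomputes, per model type, the cause event times and an
(event times × subjects) at-risk weight matrix:

- **cause-specific** — 0/1 indicators; other-cause events leave the risk
  set at their event time;
- **subdistribution (Fine–Gray)** — competing-event subjects remain at risk
  after their event with weight G(t−)/G(T_i−), where G is the Kaplan–Meier
  estimate of the censoring distribution, evaluated left-continuously.
  G = 0 cannot occur before the last observed time; the division is guarded
  anyway (weight 0).

Newton–Raphson with step-halving maximizes the likelihood; convergence is a
relative log-likelihood change below 1e-9 within 50 iterations, with
divergence (|β| > 50) reported as possible separation.  Wald p-values are
used throughout (one fit per feature is the cheapest screen at p features).
Baseline cumulative hazards are Breslow-type, computed in log space so that
extreme linear predictors cannot overflow.  The univariate screen fits all
per-feature models {feature} ∪ {age, prior_cv} simultaneously by a batched
Newton iteration; features that fail to converge get p-value 1 and a log
entry rather than aborting the screen.

## Componentwise likelihood-based boosting

Candidate features are standardized internally (mean 0, sd 1; coefficients
are reported on that scale) because componentwise selection is
scale-sensitive.  Initialization fits the mandatory covariates (age, prior
cardiovascular event) unpenalized.  Each step computes, for every candidate
j, the score U_j and Fisher information I_j of the one-parameter model at
the current linear predictor, applies Δβ_j = U_j/(I_j + λ) for the j
maximizing U_j²/(I_j + λ) (ties: lowest index), then refreshes the
mandatory covariates by one safeguarded Newton step with the candidate
contribution as offset (a full refit is available via
`full_mandatory_refit`).  The default penalty is λ = 9 × (events of the
modeled cause), i.e. roughly one tenth of an unpenalized Newton step per
update.  The step count is 100 for stability analyses and cross-validated
for prediction; CV uses event-stratified folds and the Verweij–van
Houwelingen criterion pl_full(θ_s) − pl_train(θ_s) summed over folds,
which permits choosing 0 steps.

## Stability analysis

Selection is repeated over B half-size subsamples drawn without replacement
(B = 10,000 at study scale; desk-scale analyses use B = 150–200, for which
the frequency standard error √(f(1−f)/B) is ≈ 0.04 at f = 0.3 — test
tolerances are set accordingly).  Subsamples with fewer than two events of
the modeled cause are recorded as missing rows and excluded from the
frequency denominator.  The univariate-top-k method selects the k features
with smallest screen p-values; k is calibrated as the rounded mean boosting
signature size over the same subsamples (k is also directly settable).

Joint-selection odds ratios are computed from the 2×2 inclusion cross-table
of every feature pair with frequency ≥ 0.1, with a 0.5 continuity
correction added to all cells of a table containing a zero.  The motivating
analysis identified outliers by visual inspection of these ORs plus scatter
plots; here the rule is algorithmic and therefore a documented surrogate: a
feature is *implicated* when it has a mutually facilitating partner
(OR ≥ 3) while at least 25% of its remaining pairings show exclusive
selection (OR ≤ 1/3); subjects whose robust z-score (x − median)/(1.4826·MAD)
exceeds 4 on an implicated feature are flagged (zero-MAD features are
skipped).  Plots are still emitted for human review.

The per-feature binomial regression uses a logit link on (selected, total)
counts per configuration with main effects for the four binary choices
(Fine–Gray vs cause-specific; outliers excluded; original endpoint;
univariate selection) and the five two-way interactions sh×outlier,
sh×endpoint, sh×univariate, outlier×endpoint, endpoint×univariate.
Interaction columns that are constant in a reduced configuration grid are
dropped; features always or never selected are flagged non-estimable rather
than reported with fabricated coefficients.  Bonferroni correction is
applied across qualifying features (max frequency ≥ 0.1) separately per
term, and significant effects are tallied by sign; the intercept is
excluded from the tallies.

## Prediction error

Prediction accuracy for cause 1 is the IPCW Brier score between predicted
cumulative incidence and observed status: cause-1 events by t contribute
(1−F̂)²/G(T_i−), competing events by t count as status 0 with the same
event-time weight, event-free subjects contribute F̂²/G(t), and subjects
censored before t contribute 0.  IPCW uses the marginal censoring
Kaplan–Meier of the full cohort (not covariate-adjusted).  Fine–Gray
incidence predictions are F̂_1(t|x) = 1 − exp(−Λ̂_0(t) e^{x′β}); the
cause-specific route combines both causes' baselines through the
product-integral.  The no-information error pairs every subject's outcome
with every subject's prediction (the standard permutation construction; its
exact form in the competing-risks setting is not prescribed anywhere
authoritative, so this choice is documented here).

The bootstrap study draws B sets of round(0.632·n) subjects without
replacement, refits all three models in-bag — the boosting step count
re-chosen by CV each time — and evaluates out-of-bag.  The .632+ combination
caps the out-of-bag error at the no-information error, computes the relative
overfitting R = (oob − apparent)/(noinf − apparent) clipped to [0, 1], and
returns (1−w)·apparent + w·min(oob, noinf) with w = 0.632/(1 − 0.368 R).
Model comparisons integrate per-bootstrap out-of-bag error differences by
the trapezoid rule and apply a two-sided Wilcoxon signed-rank test; an
all-zero difference is reported as p = 1 with a degenerate flag.  The
default grid is 40 equally spaced points from 0 to the 95th percentile of
observed times.  The study function fits subdistribution models, matching
the cumulative-incidence prediction target.

## Synthetic cohorts

The generator emulates a hemodialysis-cohort expression study: n = 321
subjects (desk scale: 250), ~24 months of administrative censoring plus a
small dropout hazard (0.005/month), two competing causes with latent
exponential cause-specific hazards, age (66 ± 17 years, log-HR 0.03/year on
both causes) and prior cardiovascular event (prevalence 0.35; log-HR 0.7 on
cause 1, 0.2 on cause 2).  Expression is Gaussian in equicorrelated blocks
(size 10, ρ = 0.5) — a stand-in, since the motivating data's distribution
is unpublished.  Five informative features per cause sit at the starts of
distinct blocks so each competes with correlated null neighbours; the
default effect is 0.8 log-HR per feature SD (HR ≈ 2.2, a strong prognostic
marker — the regime in which stable recovery is expected and which the
recovery checks therefore probe; weaker effects at ~25 events are not
reliably selectable by any method).  Baseline rates (0.00118 and
0.00500/month) were calibrated by Monte Carlo so mean event counts at study
scale match 30 (cause 1) and 71 (cause 2).

Because event times come from *cause-specific* hazards, ground-truth
effects are on that scale; recovery tests against subdistribution fits
assert signs and rankings, not exact coefficient values.  Outlier injection
shifts 3 subjects by 6 feature-SDs on a null neighbour of the first
informative block (one or two of them on a second neighbour as well, which
imprints the mutually facilitating OR pair), choosing subjects among
cause-1 events so the shifted feature acquires a spurious prognostic
signal that competes with the block's true feature.  The endpoint update
reassigns small fractions of subjects between the three label categories
(no event → cause 1: 1.5%, no event → cause 2: 2%, cause 2 → cause 1: 3%,
cause 1 → cause 2: 5%).

What passing tests on these cohorts do **not** show: robustness to
microarray-specific artifacts (dye bias, print-tip effects, heavy-tailed
intensity noise), non-Gaussian expression distributions, informative
censoring, or clinical-covariate structure beyond age and prior events.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale: n = 250,
p = 120–500, B = 150–200 subsamples, 20–25 bootstrap sets, chosen so the
full pipeline completes in minutes on one CPU while preserving p ≫ events.
At these sizes the clinical covariates' true Brier-score advantage over the
null model is ~1% and sits within resampling noise, so the prediction-error
ordering checks treat clinical ≈ null as equivalent within a 5% band while
requiring the expression model's advantage (when signal exists) strictly.

## Known limitations

- Fine–Gray standard errors are model-based (no robust sandwich variance).
- No time-varying covariates, stratified baselines, or left truncation.
- The outlier-implication rule is a surrogate for expert inspection; its
  thresholds (OR ≥ 3, ≥ 25% exclusive pairings, z > 4) are exposed
  parameters, not validated constants.
- Stability-path false-discovery control is out of scope; inclusion
  frequencies are reported as-is.
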