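""".632+ bootstrap prediction-error curves for competing-risks models.

Prediction accuracy for the cause of interest is tracked over time with the
inverse-probability-of-censoring-weighted (IPCW) Brier score between the
predicted cumulative incidence and the observed cause-1 status.  Bootstrap
sets of 0.632n subjects are drawn without replacement; models developed on
each in-bag set are evaluated on the out-of-bag remainder, and the apparent,
out-of-bag and no-information errors are combined by the .632+ rule, which
weights the out-of-bag estimate by the relative overfitting.  Curves are
produced for a covariate-free Aalen-Johansen null model, a clinical-only
regression (age, prior cardiovascular event), and the clinical+expression
boosting model with cross-validated step count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .boosting import DEFAULT_MANDATORY, BoostingFit, boost, cv_select_steps
from .core_data import CAUSE_CV, CompetingRisksDataset
from .survival import (RegressionFit, StepFunction, aalen_johansen,
                       censoring_survival, design_matrix, fit_fine_gray)

logger = logging.getLogger(__name__)


def draw_632_bootstrap(n: int, B: int, seed: int = 0):
    """B pairs (in_bag, out_of_bag): round(0.632 n) subjects drawn without
    replacement, the rest out-of-bag."""
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    size = int(round(0.632 * n))
    pairs = []
    for _ in range(B):
        perm = rng.permutation(n)
        pairs.append((np.sort(perm[:size]), np.sort(perm[size:])))
    return pairs


# ---------------------------------------------------------------------------
# Predicted cumulative incidence
# ---------------------------------------------------------------------------

def _linear_predictor(fit, dataset: CompetingRisksDataset) -> np.ndarray:
    if isinstance(fit, BoostingFit):
        return fit.linear_predictor(dataset)
    return design_matrix(dataset, fit.covariate_names) @ fit.coef


def predict_cif(fit, dataset: CompetingRisksDataset, times,
                competing_fit=None) -> np.ndarray:
    """Per-subject predicted cumulative incidence of the modeled cause.

    For a subdistribution (Fine-Gray) fit,
    ``F_1(t|x) = 1 - exp(-Lambda_0(t) exp(x'beta))`` with the Breslow-type
    baseline from the censoring-weighted risk sets.  For a cause-specific fit,
    the competing cause's fit must be supplied and the incidence is the
    product-integral combination of both cause-specific hazards.  Times beyond
    the last baseline jump use the last baseline value.  Returns an (n, T)
    matrix, monotone in t and in [0, 1].
    """
    times = np.asarray(times, dtype=float)
    if fit.model_type == "subdistribution":
        lp = _linear_predictor(fit, dataset)
        cumhaz = fit.baseline_cumhaz(times)                    # (T,)
        if times.size and times.max() > (fit.baseline_cumhaz.times.max()
                                         if fit.baseline_cumhaz.times.size else 0):
            logger.debug("prediction times extend beyond the last baseline "
                         "jump; baseline clamped at its last value")
        return 1.0 - np.exp(-np.outer(np.exp(lp), cumhaz))
    if fit.model_type == "cause_specific":
        if competing_fit is None:
            raise ValueError("cause-specific CIF prediction needs the "
                             "competing cause's fit")
        lp1 = _linear_predictor(fit, dataset)
        lp2 = _linear_predictor(competing_fit, dataset)
        bh1, bh2 = fit.baseline_cumhaz, competing_fit.baseline_cumhaz
        jumps = bh1.times
        d1 = np.diff(np.concatenate([[0.0], bh1.values]))      # baseline increments
        r1, r2 = np.exp(lp1), np.exp(lp2)
        # event-free survival just before each cause-1 jump
        surv_before = np.exp(-(np.outer(r1, bh1.left_limit(jumps))
                               + np.outer(r2, bh2.left_limit(jumps))))
        increments = surv_before * (d1[None, :] * r1[:, None])  # (n, k)
        cum = np.cumsum(increments, axis=1)
        idx = np.searchsorted(jumps, times, side="right")
        padded = np.concatenate([np.zeros((dataset.n, 1)), cum], axis=1)
        return np.clip(padded[:, idx], 0.0, 1.0)
    raise ValueError(f"unknown model_type {fit.model_type!r}")


# ---------------------------------------------------------------------------
# IPCW Brier score
# ---------------------------------------------------------------------------

def brier_curve(predictions: np.ndarray, dataset: CompetingRisksDataset,
                times, cause: int = CAUSE_CV,
                censoring: StepFunction | None = None) -> np.ndarray:
    """IPCW Brier score of the cause-1 status at each time.

    Subjects with a cause-1 event by t contribute (1 - F)^2 weighted
    1/G(T_i-); subjects with a competing event by t count as status 0 with
    the same event-time weight; subjects still event-free at t contribute
    F^2 weighted 1/G(t); subjects censored before t contribute 0.
    """
    times = np.asarray(times, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    if predictions.shape != (dataset.n, times.size):
        raise ValueError("predictions must be (n_subjects, n_times)")
    G = censoring_survival(dataset) if censoring is None else censoring
    g_event = G.left_limit(dataset.time)                 # G(T_i-)
    g_times = G(times)                                   # G(t)
    time = dataset.time[:, None]
    cause1 = ((dataset.event == 1) & (dataset.event_type == cause))[:, None]
    anyevent = (dataset.event == 1)[:, None]
    t = times[None, :]

    had_cause1 = cause1 & (time <= t)
    had_compet = anyevent & ~cause1 & (time <= t)
    at_risk = time > t

    need_event_w = (had_cause1 | had_compet).any(axis=1)
    if np.any(need_event_w & (g_event <= 0)):
        raise ValueError("censoring survival is 0 at a required event time; "
                         "use a shorter time grid")
    if np.any(at_risk.any(axis=0) & (g_times <= 0)):
        raise ValueError("censoring survival is 0 on the time grid; "
                         "use a shorter time grid")
    w_event = np.where(g_event > 0, 1.0 / np.where(g_event > 0, g_event, 1.0), 0.0)
    w_grid = 1.0 / np.where(g_times > 0, g_times, 1.0)

    contrib = (had_cause1 * (1.0 - predictions) ** 2 * w_event[:, None]
               + had_compet * predictions ** 2 * w_event[:, None]
               + at_risk * predictions ** 2 * w_grid[None, :])
    return contrib.sum(axis=0) / dataset.n


def no_information_error(predictions: np.ndarray, dataset: CompetingRisksDataset,
                         times, cause: int = CAUSE_CV,
                         censoring: StepFunction | None = None) -> np.ndarray:
    """No-information Brier: every subject's outcome paired with every
    subject's prediction (the permutation no-information rate)."""
    times = np.asarray(times, dtype=float)
    predictions = np.asarray(predictions, dtype=float)
    pbar = predictions.mean(axis=0)                      # (T,)
    p2bar = (predictions ** 2).mean(axis=0)
    # reuse the IPCW status decomposition: (s - p)^2 averaged over p pairings
    # equals s(1 - 2 pbar) + p2bar for binary s
    G = censoring_survival(dataset) if censoring is None else censoring
    g_event = G.left_limit(dataset.time)
    g_times = G(times)
    time = dataset.time[:, None]
    cause1 = ((dataset.event == 1) & (dataset.event_type == cause))[:, None]
    anyevent = (dataset.event == 1)[:, None]
    t = times[None, :]
    had_cause1 = cause1 & (time <= t)
    had_compet = anyevent & ~cause1 & (time <= t)
    at_risk = time > t
    w_event = np.where(g_event > 0, 1.0 / np.where(g_event > 0, g_event, 1.0), 0.0)
    w_grid = 1.0 / np.where(g_times > 0, g_times, 1.0)
    contrib = (had_cause1 * (1.0 - 2.0 * pbar[None, :] + p2bar[None, :]) * w_event[:, None]
               + had_compet * p2bar[None, :] * w_event[:, None]
               + at_risk * p2bar[None, :] * w_grid[None, :])
    return contrib.sum(axis=0) / dataset.n


def dot632plus(apparent: np.ndarray, oob: np.ndarray,
               noinf: np.ndarray) -> np.ndarray:
    """.632+ combination of apparent, out-of-bag and no-information errors.

    The out-of-bag error is capped at the no-information error; the relative
    overfitting R = (oob - apparent) / (noinf - apparent) is clipped to
    [0, 1] (0 when the denominator is <= 0 or oob <= apparent); the weight is
    w = 0.632 / (1 - 0.368 R) and the estimate (1 - w) apparent + w oob.
    """
    apparent = np.asarray(apparent, dtype=float)
    oob = np.asarray(oob, dtype=float)
    noinf = np.asarray(noinf, dtype=float)
    oob_c = np.minimum(oob, noinf)
    denom = noinf - apparent
    with np.errstate(divide="ignore", invalid="ignore"):
        R = np.where((denom > 0) & (oob_c > apparent),
                     (oob_c - apparent) / denom, 0.0)
    R = np.clip(R, 0.0, 1.0)
    w = 0.632 / (1.0 - 0.368 * R)
    return (1.0 - w) * apparent + w * oob_c


# ---------------------------------------------------------------------------
# The bootstrap study
# ---------------------------------------------------------------------------

@dataclass
class PredictionErrorCurve:
    """Error curves for one model across the bootstrap study."""

    model: str
    times: np.ndarray
    apparent: np.ndarray
    oob_mean: np.ndarray
    noinf: np.ndarray
    dot632plus: np.ndarray
    oob_per_bootstrap: np.ndarray        # (B, T), NaN rows for failed sets
    B: int


@dataclass
class ModelComparison:
    """Integrated out-of-bag error difference between two models."""

    integrals: np.ndarray
    mean_difference: float
    pvalue: float
    degenerate: bool = False


def compare_models(curves_a: PredictionErrorCurve,
                   curves_b: PredictionErrorCurve) -> ModelComparison:
    """Per-bootstrap trapezoidal integral of (error_a - error_b) over the
    grid, with a two-sided Wilcoxon signed-rank test across bootstraps."""
    if curves_a.times.shape != curves_b.times.shape or not np.allclose(
            curves_a.times, curves_b.times):
        raise ValueError("curves must share the time grid")
    diff = curves_a.oob_per_bootstrap - curves_b.oob_per_bootstrap
    valid = ~np.isnan(diff).any(axis=1)
    integrals = np.trapezoid(diff[valid], curves_a.times, axis=1)
    if integrals.size == 0 or np.allclose(integrals, 0.0):
        return ModelComparison(integrals, 0.0, 1.0, degenerate=True)
    stat = stats.wilcoxon(integrals, alternative="two-sided")
    return ModelComparison(integrals, float(integrals.mean()),
                           float(stat.pvalue), degenerate=False)


def default_time_grid(dataset: CompetingRisksDataset,
                      n_points: int = 40) -> np.ndarray:
    """40 equally spaced points from 0 to the 95th percentile of the
    observed times."""
    horizon = float(np.quantile(dataset.time, 0.95))
    return np.linspace(0.0, horizon, n_points)


def _null_predictions(train: CompetingRisksDataset, n_eval: int,
                      times: np.ndarray, cause: int) -> np.ndarray:
    aj = aalen_johansen(train, cause)
    return np.tile(aj(times), (n_eval, 1))


def run_prediction_error_study(dataset: CompetingRisksDataset,
                               B: int = 500, seed: int = 0,
                               times: np.ndarray | None = None,
                               mandatory=DEFAULT_MANDATORY,
                               penalty: float | None = None,
                               max_steps: int = 100, n_folds: int = 10,
                               cause: int = CAUSE_CV) -> dict:
    """Full .632+ study: null, clinical-only and clinical+expression models.

    For each bootstrap set the three models are developed on the in-bag
    subjects — the boosting step count re-chosen by cross-validation each
    time — and their Brier curves evaluated on the out-of-bag subjects.
    Returns ``{"null": PredictionErrorCurve, "clinical": ...,
    "clinical_expression": ..., "n_failed": int}``.  Models are Fine-Gray
    (subdistribution) fits, matching the cumulative-incidence prediction
    target.  Censoring weights use the marginal Kaplan-Meier estimate from
    the full cohort.
    """
    mandatory = list(mandatory)
    if times is None:
        times = default_time_grid(dataset)
    times = np.asarray(times, dtype=float)
    G = censoring_survival(dataset)

    # apparent errors from full-data fits
    pred_null = _null_predictions(dataset, dataset.n, times, cause)
    fit_clin = fit_fine_gray(dataset, mandatory, cause=cause)
    pred_clin = predict_cif(fit_clin, dataset, times)
    steps = cv_select_steps(dataset, model_type="subdistribution",
                            penalty=penalty, mandatory=mandatory,
                            max_steps=max_steps, n_folds=n_folds,
                            seed=seed, cause=cause)
    fit_expr = boost(dataset, model_type="subdistribution", n_steps=steps,
                     penalty=penalty, mandatory=mandatory, cause=cause)
    pred_expr = predict_cif(fit_expr, dataset, times)

    preds_full = {"null": pred_null, "clinical": pred_clin,
                  "clinical_expression": pred_expr}
    apparent = {m: brier_curve(p, dataset, times, cause, censoring=G)
                for m, p in preds_full.items()}
    noinf = {m: no_information_error(p, dataset, times, cause, censoring=G)
             for m, p in preds_full.items()}

    oob_err = {m: np.full((B, times.size), np.nan) for m in preds_full}
    n_failed = 0
    pairs = draw_632_bootstrap(dataset.n, B, seed=seed + 1)
    for b, (inbag, oob) in enumerate(pairs):
        try:
            train = dataset.subset(inbag)
            test = dataset.subset(oob)
            p_null = _null_predictions(train, test.n, times, cause)
            f_clin = fit_fine_gray(train, mandatory, cause=cause)
            p_clin = predict_cif(f_clin, test, times)
            s_b = cv_select_steps(train, model_type="subdistribution",
                                  penalty=penalty, mandatory=mandatory,
                                  max_steps=max_steps, n_folds=n_folds,
                                  seed=seed + 1000 + b, cause=cause)
            f_expr = boost(train, model_type="subdistribution", n_steps=s_b,
                           penalty=penalty, mandatory=mandatory, cause=cause)
            p_expr = predict_cif(f_expr, test, times)
            for m, p in (("null", p_null), ("clinical", p_clin),
                         ("clinical_expression", p_expr)):
                oob_err[m][b] = brier_curve(p, test, times, cause, censoring=G)
        except Exception as exc:  # noqa: BLE001 - failed sets are excluded
            n_failed += 1
            logger.warning("bootstrap set %d failed (%s); excluded", b, exc)
    if n_failed == B:
        raise RuntimeError("all bootstrap iterations failed")
    if B == 1:
        logger.warning("B = 1: .632+ estimates from a single bootstrap set "
                       "are unstable")

    curves = {}
    for m in preds_full:
        oob_mean = np.nanmean(oob_err[m], axis=0)
        curves[m] = PredictionErrorCurve(
            model=m, times=times, apparent=apparent[m], oob_mean=oob_mean,
            noinf=noinf[m], dot632plus=dot632plus(apparent[m], oob_mean, noinf[m]),
            oob_per_bootstrap=oob_err[m], B=B)
    curves["n_failed"] = n_failed
    return curves
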