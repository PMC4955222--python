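"""Competing-risks estimators: product-limit curves, Aalen-Johansen
cumulative incidence, cause-specific Cox and Fine-Gray regression, the
univariate screen, and FDR control.

All regression fitting goes through one weighted Breslow partial-likelihood
engine.  A :class:`RiskStructure` precomputes, for a dataset and model type,
the cause-specific event times and an (event-times x subjects) at-risk weight
matrix: indicator weights for the cause-specific hazard model, and
inverse-probability-of-censoring weights ``G(t-)/G(T_i-)`` that keep
competing-event subjects in the risk set for the Fine-Gray subdistribution
hazard model.  The same structure drives the Newton fits here and the
componentwise boosting updates elsewhere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core_data import CAUSE_CV, CAUSE_OTHER, CompetingRisksDataset, ModelingConfig

logger = logging.getLogger(__name__)

NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 50


class ConvergenceError(RuntimeError):
    """Raised when a Newton fit fails to converge; carries the trace."""

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace or []


# ---------------------------------------------------------------------------
# Step functions
# ---------------------------------------------------------------------------

@dataclass
class StepFunction:
    """Right-continuous step function: ``initial`` before the first jump,
    ``values[i]`` on ``[times[i], times[i+1])``."""

    times: np.ndarray
    values: np.ndarray
    initial: float = 1.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.shape != self.times.shape:
            raise ValueError("times and values must be 1-d and equal length")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("jump times must be strictly ascending")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[self.initial], self.values])
        return padded[idx]

    def left_limit(self, t):
        """Value just before ``t`` (left-continuous version)."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="left")
        padded = np.concatenate([[self.initial], self.values])
        return padded[idx]


def _product_limit(time: np.ndarray, is_event: np.ndarray) -> StepFunction:
    """Kaplan-Meier product-limit estimator for the given event indicator."""
    order = np.argsort(time, kind="stable")
    t, e = time[order], is_event[order]
    uniq = np.unique(t[e.astype(bool)])
    surv = 1.0
    vals = []
    for u in uniq:
        at_risk = int((t >= u).sum())
        d = int(((t == u) & e.astype(bool)).sum())
        surv *= 1.0 - d / at_risk
        vals.append(surv)
    return StepFunction(times=uniq, values=np.array(vals), initial=1.0)


def censoring_survival(dataset: CompetingRisksDataset) -> StepFunction:
    """Kaplan-Meier estimator G(t) of the censoring distribution.

    Censoring (event indicator 0) is treated as the event; deaths of either
    cause are treated as censored.
    """
    return _product_limit(dataset.time, (dataset.event == 0).astype(int))


def overall_survival(dataset: CompetingRisksDataset) -> StepFunction:
    """All-cause Kaplan-Meier survival (both event types count as events)."""
    return _product_limit(dataset.time, (dataset.event == 1).astype(int))


def aalen_johansen(dataset: CompetingRisksDataset, cause: int) -> StepFunction:
    """Aalen-Johansen estimator of the cause-specific cumulative incidence.

    F_c(t) accumulates S(t-) d_c(t) / n(t) over the distinct event times,
    where S is the all-cause Kaplan-Meier survival and n(t) the number at
    risk.  Nondecreasing; the incidences of all causes sum to at most
    1 - KM(t).
    """
    if cause not in (CAUSE_CV, CAUSE_OTHER):
        raise ValueError(f"cause must be 1 or 2, got {cause}")
    time, event, etype = dataset.time, dataset.event, dataset.event_type
    uniq = np.unique(time[event == 1])
    surv_before = 1.0
    inc = 0.0
    times, vals = [], []
    for u in uniq:
        at_risk = int((time >= u).sum())
        d_all = int(((time == u) & (event == 1)).sum())
        d_c = int(((time == u) & (event == 1) & (etype == cause)).sum())
        if d_c > 0:
            inc += surv_before * d_c / at_risk
            times.append(u)
            vals.append(inc)
        surv_before *= 1.0 - d_all / at_risk
    return StepFunction(times=np.array(times), values=np.array(vals), initial=0.0)


# ---------------------------------------------------------------------------
# Risk structure: event times and at-risk weights
# ---------------------------------------------------------------------------

@dataclass
class RiskStructure:
    """Precomputed partial-likelihood ingredients for one model type.

    ``weights[k, i]`` is subject i's at-risk weight at the k-th cause event
    time: 0/1 for the cause-specific model; for the subdistribution model,
    competing-event subjects stay at risk after their event with censoring
    weight G(t_k-)/G(T_i-).
    """

    event_times: np.ndarray     # (k,) distinct cause event times, ascending
    d: np.ndarray               # (k,) tied event counts
    weights: np.ndarray         # (k, n) at-risk weights
    event_mask: np.ndarray      # (n,) bool, cause events
    model_type: str
    cause: int
    censoring: StepFunction | None = None

    @property
    def n(self) -> int:
        return self.weights.shape[1]


def build_risk_structure(dataset: CompetingRisksDataset, cause: int = CAUSE_CV,
                         model_type: str = "subdistribution") -> RiskStructure:
    time, event, etype = dataset.time, dataset.event, dataset.event_type
    is_cause = (event == 1) & (etype == cause)
    uniq = np.unique(time[is_cause])
    if uniq.size == 0:
        raise ValueError(f"no events of cause {cause} in dataset")
    d = np.array([int(((time == u) & is_cause).sum()) for u in uniq])
    n = dataset.n
    k = uniq.size
    at_risk = time[None, :] >= uniq[:, None]          # (k, n)
    G = None
    if model_type == "cause_specific":
        W = at_risk.astype(float)
    elif model_type == "subdistribution":
        G = censoring_survival(dataset)
        W = at_risk.astype(float)
        competing = (event == 1) & (etype != cause)
        if competing.any():
            idx = np.flatnonzero(competing)
            g_ti = G.left_limit(time[idx])            # G(T_i-)
            g_tk = G.left_limit(uniq)                 # G(t_k-), (k,)
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(g_ti[None, :] > 0, g_tk[:, None] / g_ti[None, :], 0.0)
            past = time[idx][None, :] < uniq[:, None]  # competing event before t_k
            W[:, idx] = np.where(past, w, W[:, idx])
    else:
        raise ValueError(f"unknown model_type {model_type!r}")
    return RiskStructure(event_times=uniq, d=d, weights=W,
                         event_mask=is_cause, model_type=model_type,
                         cause=cause, censoring=G)


# ---------------------------------------------------------------------------
# Weighted Breslow partial likelihood: value, score, information
# ---------------------------------------------------------------------------

def partial_loglik(rs: RiskStructure, eta: np.ndarray) -> float:
    """Breslow partial log-likelihood at linear predictor ``eta``."""
    shift = float(eta.max()) if eta.size else 0.0
    r = np.exp(eta - shift)
    S0 = rs.weights @ r
    return float(eta[rs.event_mask].sum() - (rs.d * (np.log(S0) + shift)).sum())


def _pl_score_info(rs: RiskStructure, X: np.ndarray, eta: np.ndarray):
    """Log-likelihood, score vector and Fisher information for design X."""
    shift = float(eta.max())
    r = np.exp(eta - shift)
    Wr = rs.weights * r[None, :]
    S0 = Wr.sum(axis=1)
    ll = float(eta[rs.event_mask].sum() - (rs.d * (np.log(S0) + shift)).sum())
    S1 = Wr @ X                                   # (k, m)
    xbar = S1 / S0[:, None]
    U = X[rs.event_mask].sum(axis=0) - (rs.d[:, None] * xbar).sum(axis=0)
    a = (rs.d / S0) @ Wr                          # (n,): sum_k d_k Wr_ki / S0_k
    info = X.T @ (a[:, None] * X) - (rs.d[:, None] * xbar).T @ xbar
    return ll, U, info


def newton_fit(rs: RiskStructure, X: np.ndarray, offset: np.ndarray | None = None,
               init: np.ndarray | None = None, max_iter: int = NEWTON_MAX_ITER,
               tol: float = NEWTON_TOL):
    """Maximize the weighted partial likelihood over the columns of X.

    Returns (beta, loglik, information, n_iter).  Step-halving safeguards
    each Newton step; relative log-likelihood change below ``tol`` stops.
    """
    n, m = X.shape
    beta = np.zeros(m) if init is None else np.asarray(init, dtype=float).copy()
    off = np.zeros(n) if offset is None else offset
    trace = []
    ll, U, info = _pl_score_info(rs, X, off + X @ beta)
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, U, rcond=None)[0]
        new_beta, new_ll = beta, ll
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cll = partial_loglik(rs, off + X @ cand)
            if np.isfinite(cll) and cll >= ll:
                new_beta, new_ll = cand, cll
                break
            scale *= 0.5
        trace.append((it, new_ll))
        if not np.isfinite(new_ll):
            raise ConvergenceError("non-finite partial likelihood", trace)
        rel = abs(new_ll - ll) / (abs(ll) + 1e-12)
        beta = new_beta
        ll, U, info = _pl_score_info(rs, X, off + X @ beta)
        if rel < tol:
            return beta, ll, info, it
        if np.abs(beta).max() > 50:
            raise ConvergenceError(
                "coefficients diverging; possible complete separation", trace)
    raise ConvergenceError(f"no convergence in {max_iter} Newton iterations", trace)


def breslow_baseline(rs: RiskStructure, eta: np.ndarray) -> StepFunction:
    """Breslow estimator of the baseline cumulative hazard at fitted eta."""
    shift = float(eta.max()) if eta.size else 0.0
    log_S0 = np.log(rs.weights @ np.exp(eta - shift)) + shift
    return StepFunction(times=rs.event_times,
                        values=np.cumsum(rs.d * np.exp(-log_S0)),
                        initial=0.0)


# ---------------------------------------------------------------------------
# Regression fits
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """A fitted cause-specific Cox or Fine-Gray model."""

    covariate_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    loglik: float
    model_type: str
    cause: int
    n_iter: int
    baseline_cumhaz: StepFunction
    censoring: StepFunction | None = None

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.coef


def design_matrix(dataset: CompetingRisksDataset, covariates) -> np.ndarray:
    """Assemble columns by name from clinical covariates and expression."""
    cols = []
    fidx = {f: j for j, f in enumerate(dataset.feature_names)}
    for name in covariates:
        if name in dataset.clinical.columns:
            cols.append(dataset.clinical[name].to_numpy(float))
        elif name in fidx:
            cols.append(dataset.expression[:, fidx[name]])
        else:
            raise KeyError(f"covariate {name!r} not found in clinical or expression")
    return np.column_stack(cols)


def _fit_regression(dataset: CompetingRisksDataset, X: np.ndarray,
                    names: list[str], cause: int, model_type: str) -> RegressionFit:
    rs = build_risk_structure(dataset, cause=cause, model_type=model_type)
    beta, ll, info, n_iter = newton_fit(rs, X)
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf))
    pvals = 2 * stats.norm.sf(np.abs(z))
    baseline = breslow_baseline(rs, X @ beta)
    return RegressionFit(covariate_names=list(names), coef=beta, se=se,
                         pvalues=pvals, loglik=ll, model_type=model_type,
                         cause=cause, n_iter=n_iter, baseline_cumhaz=baseline,
                         censoring=rs.censoring)


def fit_cox_cause_specific(dataset: CompetingRisksDataset, covariates,
                           cause: int = CAUSE_CV) -> RegressionFit:
    """Cox model for the cause-specific hazard (other-cause events censored)."""
    X = design_matrix(dataset, covariates)
    return _fit_regression(dataset, X, list(covariates), cause, "cause_specific")


def fit_fine_gray(dataset: CompetingRisksDataset, covariates,
                  cause: int = CAUSE_CV) -> RegressionFit:
    """Fine-Gray model for the subdistribution hazard of the given cause."""
    X = design_matrix(dataset, covariates)
    return _fit_regression(dataset, X, list(covariates), cause, "subdistribution")


# ---------------------------------------------------------------------------
# Univariate screen (batched Newton across features) and FDR
# ---------------------------------------------------------------------------

def _batched_feature_newton(rs: RiskStructure, A: np.ndarray, X: np.ndarray,
                            max_iter: int = 25, tol: float = 1e-8):
    """Per-feature Newton fits of the model {adjust columns} + {feature}.

    Fits all p (q+1)-dimensional models jointly via batched score/information
    computations.  Returns (beta (p, q+1), se_feature (p,), converged (p,)).
    The feature is the last coordinate.
    """
    n, p = X.shape
    q = A.shape[1]
    m = q + 1
    W, d, ev = rs.weights, rs.d, rs.event_mask
    # per-feature sufficient statistic of the events
    ev_sum_A = A[ev].sum(axis=0)                    # (q,)
    ev_sum_X = X[ev].sum(axis=0)                    # (p,)
    beta = np.zeros((p, m))
    converged = np.zeros(p, dtype=bool)
    ll_prev = np.full(p, -np.inf)
    se_feat = np.full(p, np.nan)
    cols = [A[:, c] for c in range(q)]              # adjust columns
    for it in range(max_iter):
        eta = A @ beta[:, :q].T + X * beta[:, q][None, :]   # (n, p)
        shift = eta.max(axis=0)
        R = np.exp(eta - shift[None, :])
        S0 = W @ R                                  # (k, p)
        ll = (eta * ev[:, None]).sum(axis=0) - (d[:, None] * (np.log(S0) + shift[None, :])).sum(axis=0)
        # score
        U = np.empty((p, m))
        S1 = np.empty((m, W.shape[0], p))
        for c in range(q):
            S1[c] = W @ (R * cols[c][:, None])
            U[:, c] = ev_sum_A[c] - (d[:, None] * S1[c] / S0).sum(axis=0)
        S1[q] = W @ (R * X)
        U[:, q] = ev_sum_X - (d[:, None] * S1[q] / S0).sum(axis=0)
        # information
        info = np.empty((p, m, m))
        for c1 in range(m):
            v1 = cols[c1] if c1 < q else None
            for c2 in range(c1, m):
                if c1 < q and c2 < q:
                    prod = (cols[c1] * cols[c2])[:, None] * R
                elif c1 < q:
                    prod = R * (cols[c1][:, None] * X)
                else:
                    prod = R * (X * X)
                S2 = W @ prod
                term = (d[:, None] * (S2 / S0 - (S1[c1] / S0) * (S1[c2] / S0))).sum(axis=0)
                info[:, c1, c2] = term
                info[:, c2, c1] = term
        try:
            step = np.linalg.solve(info, U[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack([np.linalg.lstsq(info[j], U[j], rcond=None)[0]
                             for j in range(p)])
        improved = ll >= ll_prev - 1e-10
        # dampen any feature whose step explodes
        norm = np.abs(step).max(axis=1)
        step[norm > 10] *= (10 / norm[norm > 10])[:, None]
        beta = beta + np.where(improved[:, None], step, 0.5 * step)
        done = np.abs(ll - ll_prev) < tol * (np.abs(ll_prev) + 1e-12)
        converged |= done & np.isfinite(ll)
        ll_prev = ll
        if converged.all():
            break
        if np.abs(beta).max() > 50:
            runaway = np.abs(beta).max(axis=1) > 50
            beta[runaway] = np.clip(beta[runaway], -50, 50)
    # standard error of the feature coefficient from the final information
    for j in range(p):
        try:
            se_feat[j] = np.sqrt(np.linalg.inv(info[j])[q, q])
        except np.linalg.LinAlgError:
            se_feat[j] = np.nan
    return beta, se_feat, converged


def univariate_screen(dataset: CompetingRisksDataset,
                      config: ModelingConfig | None = None,
                      adjust: tuple = ("age", "prior_cv"),
                      cause: int = CAUSE_CV) -> np.ndarray:
    """Per-feature Wald p-values from {feature} + mandatory-covariate models.

    For each expression feature, fits the configured hazard model with the
    feature plus the adjustment covariates and records the feature's Wald
    p-value.  Features whose fit fails get p-value 1 (logged, not fatal).
    """
    model_type = "subdistribution" if config is None else config.hazard_type
    rs = build_risk_structure(dataset, cause=cause, model_type=model_type)
    A = design_matrix(dataset, adjust) if adjust else np.empty((dataset.n, 0))
    X = dataset.expression
    beta, se_feat, converged = _batched_feature_newton(rs, A, X)
    q = A.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta[:, q] / se_feat
    pvals = 2 * stats.norm.sf(np.abs(z))
    bad = ~np.isfinite(pvals) | ~converged
    if bad.any():
        logger.warning("univariate screen: %d features failed to converge; "
                       "p-values set to 1", int(bad.sum()))
        pvals = np.where(bad, 1.0, pvals)
    return pvals


def bh_fdr(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up selection at FDR level ``q``.

    Returns the sorted indices of the rejected hypotheses.
    """
    from statsmodels.stats.multitest import multipletests
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.array([], dtype=int)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return np.flatnonzero(reject)


def interaction_check(dataset: CompetingRisksDataset, lp_clinical: np.ndarray,
                      lp_expression: np.ndarray, cause: int = CAUSE_CV) -> RegressionFit:
    """Fine-Gray fit of (clinical score, expression score, their product).

    Used to test whether the clinical and expression linear predictors
    interact; the third coefficient and p-value carry the answer.
    """
    lp_clinical = np.asarray(lp_clinical, dtype=float)
    lp_expression = np.asarray(lp_expression, dtype=float)
    if lp_clinical.shape != (dataset.n,) or lp_expression.shape != (dataset.n,):
        raise ValueError("linear predictors must align with subjects")
    X = np.column_stack([lp_clinical, lp_expression, lp_clinical * lp_expression])
    return _fit_regression(dataset, X,
                           ["lp_clinical", "lp_expression", "interaction"],
                           cause, "subdistribution")
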