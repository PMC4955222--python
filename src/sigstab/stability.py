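"""Selection-stability analysis via subsampling.

Signature selection is repeated over many half-size subsamples drawn without
replacement; a feature's inclusion frequency (fraction of subsamples where it
enters the signature) is the stability measure.  Pairwise odds ratios of
joint selection expose artificial correlation structure — a small cluster of
mutually facilitating features whose presence excludes the rest typically
points at a few extreme observations — and a per-feature binomial regression
over the grid of modeling choices (hazard model, selection method, endpoint
version, outlier handling) quantifies which choices move inclusion the most.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .boosting import DEFAULT_MANDATORY, boost, selected_features
from .core_data import CAUSE_CV, CompetingRisksDataset, ModelingConfig
from .survival import univariate_screen

logger = logging.getLogger(__name__)

#: Binomial-regression term structure over the four binary modeling choices:
#: main effects plus the five two-way interactions of interest.
REGRESSION_TERMS = (
    "intercept", "sh", "outlier_excluded", "original_endpoint", "univariate",
    "sh:outlier_excluded", "sh:original_endpoint", "sh:univariate",
    "outlier_excluded:original_endpoint", "original_endpoint:univariate",
)


def draw_subsamples(n: int, B: int, fraction: float = 0.5,
                    seed: int = 0) -> list[np.ndarray]:
    """B index sets of size floor(fraction * n), drawn without replacement."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    size = int(np.floor(fraction * n))
    return [np.sort(rng.choice(n, size=size, replace=False)) for _ in range(B)]


@dataclass
class SelectionMatrix:
    """Per-subsample boolean inclusion record for one modeling configuration."""

    config: ModelingConfig
    subsample_indices: list[np.ndarray]
    inclusion: np.ndarray          # (B, p) bool
    valid: np.ndarray              # (B,) bool; rows with too few events are missing
    feature_names: list[str]
    k_univariate: int | None = None

    @property
    def B(self) -> int:
        return self.inclusion.shape[0]


def build_selection_matrix(dataset: CompetingRisksDataset, config: ModelingConfig,
                           subsamples: list[np.ndarray], n_steps: int = 100,
                           penalty: float | None = None,
                           mandatory=DEFAULT_MANDATORY,
                           k_univariate: int | None = None,
                           cause: int = CAUSE_CV) -> SelectionMatrix:
    """Run signature selection on every subsample.

    For multivariable boosting a row records the features with nonzero
    coefficient after ``n_steps`` fixed boosting steps.  For the univariate
    top-k method a row marks the k features with the smallest per-feature
    Wald p-values; when ``k_univariate`` is None, k is calibrated as the
    rounded mean signature size of a companion boosting run over the same
    subsamples.  Subsamples with fewer than 2 events of the modeled cause are
    recorded as missing rows.
    """
    p = dataset.p
    B = len(subsamples)
    inclusion = np.zeros((B, p), dtype=bool)
    valid = np.ones(B, dtype=bool)
    univariate = config.selection_method == "univariate_topk"
    if univariate and k_univariate is None:
        sizes = _boosting_signature_sizes(dataset, config, subsamples, n_steps,
                                          penalty, mandatory, cause)
        k_univariate = max(1, int(round(np.mean(sizes)))) if sizes else 1
        logger.info("univariate top-k calibrated to k=%d from companion "
                    "boosting run", k_univariate)
    name_to_col = {f: j for j, f in enumerate(dataset.feature_names)}
    for b, idx in enumerate(subsamples):
        sub = dataset.subset(idx)
        if sub.n_events(cause) < 2:
            valid[b] = False
            logger.warning("subsample %d has <2 events of cause %d; row "
                           "recorded as missing", b, cause)
            continue
        try:
            if univariate:
                pvals = univariate_screen(sub, config, adjust=tuple(mandatory),
                                          cause=cause)
                top = np.argsort(pvals, kind="stable")[:k_univariate]
                inclusion[b, top] = True
            else:
                fit = boost(sub, model_type=config.hazard_type, n_steps=n_steps,
                            penalty=penalty, mandatory=mandatory, cause=cause)
                for f in selected_features(fit):
                    inclusion[b, name_to_col[f]] = True
        except Exception as exc:   # noqa: BLE001 - a failed row is missing, not fatal
            valid[b] = False
            logger.warning("subsample %d failed (%s); row recorded as missing",
                           b, exc)
    return SelectionMatrix(config=config, subsample_indices=list(subsamples),
                           inclusion=inclusion, valid=valid,
                           feature_names=list(dataset.feature_names),
                           k_univariate=k_univariate)


def _boosting_signature_sizes(dataset, config, subsamples, n_steps, penalty,
                              mandatory, cause) -> list[int]:
    sizes = []
    for idx in subsamples:
        sub = dataset.subset(idx)
        if sub.n_events(cause) < 2:
            continue
        fit = boost(sub, model_type=config.hazard_type, n_steps=n_steps,
                    penalty=penalty, mandatory=mandatory, cause=cause)
        sizes.append(len(selected_features(fit)))
    return sizes


def inclusion_frequencies(matrix: SelectionMatrix) -> np.ndarray:
    """Per-feature selection proportion over the valid subsample rows."""
    if not matrix.valid.any():
        raise ValueError("no valid subsample rows")
    return matrix.inclusion[matrix.valid].mean(axis=0)


def joint_selection_odds_ratios(matrix: SelectionMatrix,
                                min_frequency: float = 0.1) -> pd.DataFrame:
    """Pairwise odds ratios of joint selection for frequent features.

    For each pair (j, l) passing the frequency threshold, the 2x2 cross-table
    of inclusion over subsamples gives OR = (n11 n00) / (n10 n01); 0.5 is
    added to every cell when any cell is zero.  OR >> 1 means joint selection,
    OR << 1 mutually exclusive selection.
    """
    freqs = inclusion_frequencies(matrix)
    keep = np.flatnonzero(freqs >= min_frequency)
    if keep.size < 2:
        raise ValueError(
            f"need >= 2 features with frequency >= {min_frequency}, "
            f"got {keep.size}")
    M = matrix.inclusion[matrix.valid][:, keep].astype(int)
    B = M.shape[0]
    n11 = M.T @ M
    colsum = M.sum(axis=0)
    n10 = colsum[:, None] - n11
    n01 = colsum[None, :] - n11
    n00 = B - n11 - n10 - n01
    cells = np.stack([n11, n10, n01, n00]).astype(float)
    zero = (cells == 0).any(axis=0)
    cells = np.where(zero[None], cells + 0.5, cells)
    orr = (cells[0] * cells[3]) / (cells[1] * cells[2])
    names = [matrix.feature_names[j] for j in keep]
    table = pd.DataFrame(orr, index=names, columns=names)
    np.fill_diagonal(table.values, np.nan)
    return table


def implicated_from_odds_ratios(table: pd.DataFrame, facilitation: float = 3.0,
                                exclusion: float = 1.0 / 3.0,
                                min_excluded_fraction: float = 0.25) -> list[str]:
    """Features implicated by the joint-selection structure.

    Algorithmic surrogate for visual inspection of the OR heatmap: a feature
    is implicated when it belongs to a mutually facilitating pair
    (OR >= ``facilitation``) while a substantial fraction of its remaining
    pairings show exclusive selection (OR <= ``exclusion``) — the pattern a
    few extreme observations imprint on selection.
    """
    out = []
    for f in table.index:
        row = table.loc[f].drop(f).dropna()
        if row.empty:
            continue
        if (row >= facilitation).any() and \
                (row <= exclusion).mean() >= min_excluded_fraction:
            out.append(f)
    return out


def flag_outlier_observations(dataset: CompetingRisksDataset,
                              implicated_features, z_threshold: float = 4.0):
    """Subjects with extreme robust z-scores on the implicated features.

    The robust z-score is (x - median) / (1.4826 * MAD).  Returns the flagged
    subject positions and the per-subject score table (one column per
    implicated feature) for scatter-plot review.  Features with zero MAD are
    skipped with a warning.
    """
    implicated = list(implicated_features)
    if not implicated:
        raise ValueError("implicated_features must be nonempty")
    fidx = {f: j for j, f in enumerate(dataset.feature_names)}
    scores = {}
    for f in implicated:
        j = f if isinstance(f, (int, np.integer)) else fidx[f]
        x = dataset.expression[:, j]
        med = np.median(x)
        mad = np.median(np.abs(x - med))
        if mad == 0:
            logger.warning("feature %s has zero MAD; skipped for outlier "
                           "flagging", dataset.feature_names[j])
            continue
        scores[dataset.feature_names[j]] = (x - med) / (1.4826 * mad)
    score_tab = pd.DataFrame(scores)
    if score_tab.empty:
        return np.array([], dtype=int), score_tab
    flagged = np.flatnonzero((score_tab.abs() > z_threshold).any(axis=1))
    return flagged, score_tab


# ---------------------------------------------------------------------------
# Binomial regression of inclusion on the modeling choices
# ---------------------------------------------------------------------------

def _config_design_row(config: ModelingConfig) -> np.ndarray:
    sh = 1.0 if config.hazard_type == "subdistribution" else 0.0
    out = 1.0 if config.outlier_handling == "outliers_excluded" else 0.0
    orig = 1.0 if config.endpoint == "original" else 0.0
    uni = 1.0 if config.selection_method == "univariate_topk" else 0.0
    return np.array([1.0, sh, out, orig, uni,
                     sh * out, sh * orig, sh * uni, out * orig, orig * uni])


@dataclass
class FeatureStabilityRegression:
    """Binomial-regression result for one feature's inclusion counts."""

    terms: tuple
    estimates: np.ndarray
    pvalues: np.ndarray
    degenerate: bool
    note: str = ""


def stability_regression(inclusion_by_config: dict) -> FeatureStabilityRegression:
    """Logit-link binomial regression of one feature's inclusion on the
    modeling choices.

    ``inclusion_by_config`` maps :class:`ModelingConfig` to
    ``(selected_count, total_rows)``.  The design has main effects for the
    four binary choices and the five two-way interactions of
    :data:`REGRESSION_TERMS`.  Features that are always or never selected
    under some margin yield non-estimable coefficients and are flagged
    degenerate rather than reported with fabricated values.
    """
    configs = list(inclusion_by_config)
    if len(configs) < 2:
        raise ValueError("need at least two configs")
    X = np.stack([_config_design_row(c) for c in configs])
    # drop interaction columns that are constant in a reduced config grid
    varying = [0] + [j for j in range(1, X.shape[1])
                     if np.unique(X[:, j]).size > 1]
    X_used = X[:, varying]
    counts = np.array([inclusion_by_config[c] for c in configs], dtype=float)
    success, total = counts[:, 0], counts[:, 1]
    nan = np.full(len(REGRESSION_TERMS), np.nan)
    if success.sum() == 0 or (success == total).all():
        return FeatureStabilityRegression(REGRESSION_TERMS, nan.copy(), nan.copy(),
                                          True, "feature always or never selected")
    endog = np.column_stack([success, total - success])
    try:
        import warnings as _warnings
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")   # separation handled below
            model = sm.GLM(endog, X_used, family=sm.families.Binomial())
            res = model.fit(maxiter=200)
    except Exception as exc:  # noqa: BLE001
        return FeatureStabilityRegression(REGRESSION_TERMS, nan.copy(), nan.copy(),
                                          True, f"fit failed: {exc}")
    est = nan.copy()
    pv = nan.copy()
    est[varying] = res.params
    pv[varying] = res.pvalues
    degenerate = bool(np.any(np.abs(res.params) > 15)
                      or not np.all(np.isfinite(res.bse)))
    note = "possible separation" if degenerate else ""
    return FeatureStabilityRegression(REGRESSION_TERMS, est, pv, degenerate, note)


@dataclass
class StabilityReport:
    """Assembled stability results across the modeling-choice grid."""

    frequencies: pd.DataFrame          # features x configs, plus min/max columns
    regressions: dict                  # feature -> FeatureStabilityRegression
    term_sign_counts: pd.DataFrame     # per term: Bonferroni-significant +/- counts
    alpha: float
    frequency_threshold: float
    flagged_outliers: np.ndarray | None = None
    odds_ratios: pd.DataFrame | None = None


def multi_feature_stability(matrices: list[SelectionMatrix],
                            frequency_threshold: float = 0.1,
                            alpha: float = 0.05) -> StabilityReport:
    """Per-feature modeling-choice regressions over all qualifying features.

    A feature qualifies when its inclusion frequency reaches
    ``frequency_threshold`` under at least one configuration.  Bonferroni
    correction at level ``alpha`` is applied across qualifying features,
    separately per term, and significant effects are tallied by sign.
    """
    if not matrices:
        raise ValueError("no selection matrices given")
    feature_names = matrices[0].feature_names
    freq_tab = pd.DataFrame(
        {m.config.label(): inclusion_frequencies(m) for m in matrices},
        index=feature_names)
    config_cols = list(freq_tab.columns)
    freq_tab["min"] = freq_tab[config_cols].min(axis=1)
    freq_tab["max"] = freq_tab[config_cols].max(axis=1)

    qualifying = freq_tab.index[freq_tab["max"] >= frequency_threshold]
    regressions = {}
    for feat in qualifying:
        j = feature_names.index(feat)
        counts = {m.config: (int(m.inclusion[m.valid][:, j].sum()),
                             int(m.valid.sum())) for m in matrices}
        regressions[feat] = stability_regression(counts)

    n_tests = max(len(regressions), 1)
    rows = []
    # intercept excluded from the tallies: only modeling-choice effects count
    for t, term in enumerate(REGRESSION_TERMS):
        if term == "intercept":
            continue
        pos = neg = 0
        for reg in regressions.values():
            if reg.degenerate or not np.isfinite(reg.pvalues[t]):
                continue
            if reg.pvalues[t] <= alpha / n_tests:
                if reg.estimates[t] > 0:
                    pos += 1
                else:
                    neg += 1
        rows.append({"term": term, "sig_positive": pos, "sig_negative": neg})
    sign_counts = pd.DataFrame(rows).set_index("term")
    return StabilityReport(frequencies=freq_tab, regressions=regressions,
                           term_sign_counts=sign_counts, alpha=alpha,
                           frequency_threshold=frequency_threshold)
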