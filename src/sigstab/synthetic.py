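"""Synthetic competing-risks cohorts with known ground truth.

The generator emulates the statistical structure of a hemodialysis-cohort
microarray study: ~24 months of follow-up, two competing causes of death
(cause 1 "death with prior cardiovascular event" is the rarer, cause 2 the
more frequent), heavy administrative censoring, a high-dimensional block-
correlated expression matrix with a few truly prognostic features, optional
extreme-valued outlier subjects that induce spurious selection, and an
endpoint update that reclassifies a small number of subjects.

Event times come from latent cause-specific exponential proportional-hazards
models, so ground-truth effects live on the cause-specific scale; tests
against subdistribution fits assert signs and rankings rather than exact
coefficient values.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .core_data import (CAUSE_CV, CAUSE_OTHER, NO_EVENT, CompetingRisksDataset,
                        EndpointRelabeling)


def _default_relabel_fractions() -> dict:
    # mirrors the pattern of a late endpoint update: a few censored subjects
    # turn out to have had events, and a few events switch cause
    return {"none_to_c1": 0.015, "none_to_c2": 0.02,
            "c2_to_c1": 0.03, "c1_to_c2": 0.05}


@dataclass
class CohortSpec:
    """Parameters of one synthetic cohort draw (the seed fixes everything)."""

    n: int = 250
    p: int = 500
    n_informative_cause1: int = 5
    n_informative_cause2: int = 5
    effect_size: float = 0.8            # log hazard ratio per informative feature
    block_size: int = 10
    within_block_correlation: float = 0.5
    baseline_rate_cause1: float = 0.00118  # events per month at lp = 0
    baseline_rate_cause2: float = 0.00500
    admin_censor_time: float = 24.0        # months
    random_censor_rate: float = 0.005      # dropout hazard per month
    age_mean: float = 66.0
    age_sd: float = 17.0
    prior_cv_prevalence: float = 0.35
    age_effect_cause1: float = 0.03        # per year, both causes age-linked
    age_effect_cause2: float = 0.03
    prior_cv_effect_cause1: float = 0.7
    prior_cv_effect_cause2: float = 0.2
    n_outliers: int = 0
    outlier_magnitude: float = 6.0         # in feature standard deviations
    relabel_fractions: dict = field(default_factory=_default_relabel_fractions)
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative_cause1 + self.n_informative_cause2 > self.p:
            raise ValueError("more informative features than features")
        if not (0 <= self.within_block_correlation < 1):
            raise ValueError("within_block_correlation must be in [0, 1)")
        if self.baseline_rate_cause1 <= 0 or self.baseline_rate_cause2 <= 0:
            raise ValueError("baseline rates must be positive")
        if self.random_censor_rate < 0:
            raise ValueError("random_censor_rate must be nonnegative")
        if self.n_outliers >= self.n:
            raise ValueError("n_outliers must be < n")
        # crude feasibility: expected events at lp = 0 must be at least 1
        lam = (self.baseline_rate_cause1 + self.baseline_rate_cause2
               + self.random_censor_rate)
        p_any = 1.0 - np.exp(-lam * self.admin_censor_time)
        for name, rate in (("cause 1", self.baseline_rate_cause1),
                           ("cause 2", self.baseline_rate_cause2)):
            expected = self.n * (rate / lam) * p_any
            if expected < 1:
                raise ValueError(
                    f"infeasible spec: expected {name} events ~{expected:.2f} < 1 "
                    f"(n={self.n}, rate={rate}, follow-up={self.admin_censor_time})")


def study_scale_spec(seed: int = 0, p: int = 26323) -> CohortSpec:
    """Spec sized to the motivating cohort: 321 subjects, 24-month window,
    baseline rates tuned by Monte Carlo so mean event counts match ~30
    (cause 1) and ~71 (cause 2)."""
    return CohortSpec(n=321, p=p, seed=seed,
                      baseline_rate_cause1=0.00118, baseline_rate_cause2=0.00500)


@dataclass
class GroundTruth:
    """Bookkeeping of one generated cohort: what a recovery test may assume."""

    informative_cause1: list[int]
    informative_cause2: list[int]
    beta_cause1: np.ndarray            # (p,) true cause-1 log hazard ratios
    beta_cause2: np.ndarray
    outlier_indices: list[int]
    outlier_features: list[int]
    relabeling: EndpointRelabeling | None
    relabel_counts: dict               # transition -> number of subjects moved

    def to_dict(self) -> dict:
        d = {
            "informative_cause1": list(map(int, self.informative_cause1)),
            "informative_cause2": list(map(int, self.informative_cause2)),
            "beta_cause1": np.asarray(self.beta_cause1).tolist(),
            "beta_cause2": np.asarray(self.beta_cause2).tolist(),
            "outlier_indices": list(map(int, self.outlier_indices)),
            "outlier_features": list(map(int, self.outlier_features)),
            "relabel_counts": {k: int(v) for k, v in self.relabel_counts.items()},
            "relabeling": (None if self.relabeling is None else
                           {str(k): [int(v[0]), int(v[1])]
                            for k, v in self.relabeling.mapping.items()}),
        }
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _block_correlated_matrix(rng: np.random.Generator, n: int, p: int,
                             block_size: int, rho: float) -> np.ndarray:
    """Gaussian features with equicorrelation ``rho`` inside each block."""
    X = np.empty((n, p))
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        width = stop - start
        shared = rng.standard_normal((n, 1))
        noise = rng.standard_normal((n, width))
        X[:, start:stop] = np.sqrt(rho) * shared + np.sqrt(1 - rho) * noise
    return X


def generate_cohort(spec: CohortSpec) -> tuple[CompetingRisksDataset, GroundTruth]:
    """Draw one cohort; the spec's seed fully determines the output.

    Informative features are placed at the starts of distinct correlation
    blocks (cause-1 features first), so each prognostic feature has correlated
    null neighbours competing for selection.  Latent event times per cause are
    exponential with rate ``baseline_rate_c * exp(lp_c)``; the observed time
    is the minimum of the two latent times, random censoring and the
    administrative cutoff.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p

    X = _block_correlated_matrix(rng, n, p, spec.block_size,
                                 spec.within_block_correlation)
    age = rng.normal(spec.age_mean, spec.age_sd, size=n)
    prior_cv = rng.binomial(1, spec.prior_cv_prevalence, size=n).astype(float)

    # informative features at block starts: cause 1 in the first blocks,
    # cause 2 in the following ones
    k1, k2 = spec.n_informative_cause1, spec.n_informative_cause2
    starts = list(range(0, p, spec.block_size))
    if len(starts) < k1 + k2:   # fewer blocks than informative features
        idx_all = list(range(p))
        inf1 = idx_all[:k1]
        inf2 = idx_all[k1:k1 + k2]
    else:
        inf1 = starts[:k1]
        inf2 = starts[k1:k1 + k2]
    beta1 = np.zeros(p)
    beta2 = np.zeros(p)
    beta1[inf1] = spec.effect_size
    beta2[inf2] = spec.effect_size

    age_c = age - spec.age_mean
    lp1 = (spec.age_effect_cause1 * age_c + spec.prior_cv_effect_cause1 * prior_cv
           + X @ beta1)
    lp2 = (spec.age_effect_cause2 * age_c + spec.prior_cv_effect_cause2 * prior_cv
           + X @ beta2)

    t1 = rng.exponential(1.0 / (spec.baseline_rate_cause1 * np.exp(lp1)))
    t2 = rng.exponential(1.0 / (spec.baseline_rate_cause2 * np.exp(lp2)))
    if spec.random_censor_rate > 0:
        c = rng.exponential(1.0 / spec.random_censor_rate, size=n)
    else:
        c = np.full(n, np.inf)
    c = np.minimum(c, spec.admin_censor_time)

    time = np.minimum(np.minimum(t1, t2), c)
    event = ((t1 <= c) & (t1 <= t2)) | ((t2 <= c) & (t2 < t1))
    etype = np.where(~event, NO_EVENT, np.where(t1 <= t2, CAUSE_CV, CAUSE_OTHER))

    ids = np.array([f"S{i:04d}" for i in range(n)], dtype=object)
    dataset = CompetingRisksDataset(
        subject_ids=ids, time=time, event=event.astype(int), event_type=etype,
        clinical=pd.DataFrame({"age": age, "prior_cv": prior_cv}),
        expression=X, feature_names=[f"G{j:05d}" for j in range(p)],
        endpoint_version="original",
    )

    outlier_idx: list[int] = []
    outlier_feats: list[int] = []
    if spec.n_outliers > 0:
        # shift null neighbours of the first cause-1 informative block so the
        # outliers can fake a prognostic signal; prefer cause-1 event subjects.
        # A subset of the outliers is also extreme on a second feature, so the
        # pair shows up as mutually facilitating in the joint-selection ORs.
        target1 = inf1[0] + 1 if inf1 and inf1[0] + 1 < p else p - 1
        target2 = inf1[0] + 2 if inf1 and inf1[0] + 2 < p else p - 2
        cause1_subjects = np.flatnonzero((dataset.event == 1)
                                         & (dataset.event_type == CAUSE_CV))
        pool = cause1_subjects if cause1_subjects.size >= spec.n_outliers else np.arange(n)
        subjects = rng.choice(pool, size=spec.n_outliers, replace=False)
        dataset, outlier_idx = inject_outliers(
            dataset, spec.n_outliers, spec.outlier_magnitude, [target1],
            seed=int(rng.integers(2**31)), subjects=subjects)
        n_second = max(1, spec.n_outliers // 2)
        dataset, _ = inject_outliers(
            dataset, n_second, spec.outlier_magnitude, [target2],
            seed=int(rng.integers(2**31)), subjects=subjects[:n_second])
        outlier_feats = sorted({target1, target2})

    relabeling, counts = _draw_relabeling(dataset, spec.relabel_fractions, rng)
    truth = GroundTruth(informative_cause1=list(inf1), informative_cause2=list(inf2),
                        beta_cause1=beta1, beta_cause2=beta2,
                        outlier_indices=list(map(int, outlier_idx)),
                        outlier_features=outlier_feats,
                        relabeling=relabeling, relabel_counts=counts)
    return dataset, truth


def _draw_relabeling(dataset: CompetingRisksDataset, fractions: dict,
                     rng: np.random.Generator):
    """Randomly reassign stated fractions of subjects between endpoint
    categories, emulating a late endpoint update."""
    labels = np.where(dataset.event == 1, dataset.event_type, NO_EVENT)
    mapping = {sid: (int(l), int(l))
               for sid, l in zip(dataset.subject_ids, labels)}
    moves = {"none_to_c1": (NO_EVENT, CAUSE_CV), "none_to_c2": (NO_EVENT, CAUSE_OTHER),
             "c2_to_c1": (CAUSE_OTHER, CAUSE_CV), "c1_to_c2": (CAUSE_CV, CAUSE_OTHER)}
    counts = {}
    taken: set = set()
    for key, (src, dst) in moves.items():
        frac = float(fractions.get(key, 0.0))
        pool = [i for i in np.flatnonzero(labels == src) if i not in taken]
        k = int(round(frac * len(pool)))
        chosen = rng.choice(pool, size=min(k, len(pool)), replace=False) if k else []
        for i in chosen:
            mapping[dataset.subject_ids[i]] = (int(src), int(dst))
            taken.add(int(i))
        counts[key] = len(chosen)
    return EndpointRelabeling(mapping), counts


def inject_outliers(dataset: CompetingRisksDataset, n_outliers: int,
                    magnitude: float, target_features, seed: int = 0,
                    subjects=None) -> tuple[CompetingRisksDataset, np.ndarray]:
    """Shift chosen subjects' values on the target features by
    ``magnitude x feature standard deviation``; everything else unchanged.

    Returns the modified dataset and the outlier subject positions.
    """
    if n_outliers == 0:
        return dataset.copy(), np.array([], dtype=int)
    if magnitude <= 0:
        raise ValueError("outlier magnitude must be positive")
    if n_outliers >= dataset.n:
        raise ValueError("n_outliers must be < n")
    rng = np.random.default_rng(seed)
    if subjects is None:
        subjects = rng.choice(dataset.n, size=n_outliers, replace=False)
    subjects = np.asarray(subjects, dtype=int)
    if subjects.size != n_outliers:
        raise ValueError("subjects must match n_outliers")
    out = dataset.copy()
    fidx = []
    for f in target_features:
        fidx.append(f if isinstance(f, (int, np.integer))
                    else dataset.feature_names.index(f))
    for j in fidx:
        sd = out.expression[:, j].std()
        out.expression[subjects, j] += magnitude * (sd if sd > 0 else 1.0)
    return out, subjects
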