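"""Domain types and delimited-text I/O for competing-risks cohorts.

A cohort couples a subject-level survival table (observed time in months,
censoring indicator, event type, clinical covariates) with a subjects x
features matrix of normalized log2 expression values.  Two event types are
distinguished: cause 1, death with a prior cardiovascular event, and cause 2,
death without one.  Subject order after id alignment is the canonical key:
every downstream index set (subsamples, outlier flags) refers to positions in
this order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Event-type code for death with prior cardiovascular event.
CAUSE_CV = 1
#: Event-type code for death without prior cardiovascular event.
CAUSE_OTHER = 2
#: Label used in relabeling files for "no event observed".
NO_EVENT = 0

ENDPOINT_VERSIONS = ("original", "updated")

HAZARD_TYPES = ("subdistribution", "cause_specific")
SELECTION_METHODS = ("multivariable_boosting", "univariate_topk")
OUTLIER_HANDLING = ("all_observations", "outliers_excluded")


class DataValidationError(ValueError):
    """Raised when an input table violates a dataset invariant."""


class AlignmentError(ValueError):
    """Raised when survival and expression tables disagree on subject ids."""


@dataclass(frozen=True)
class ModelingConfig:
    """One cell of the 2x2x2x2 grid of modeling choices.

    The four binary factors whose impact on selection stability is
    quantified: hazard model (Fine-Gray subdistribution vs cause-specific
    Cox), selection method (multivariable boosting vs univariate top-k),
    endpoint version (original vs updated), and outlier handling.
    """

    hazard_type: str = "subdistribution"
    selection_method: str = "multivariable_boosting"
    endpoint: str = "original"
    outlier_handling: str = "all_observations"

    def __post_init__(self) -> None:
        if self.hazard_type not in HAZARD_TYPES:
            raise ValueError(f"unknown hazard_type {self.hazard_type!r}")
        if self.selection_method not in SELECTION_METHODS:
            raise ValueError(f"unknown selection_method {self.selection_method!r}")
        if self.endpoint not in ENDPOINT_VERSIONS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.outlier_handling not in OUTLIER_HANDLING:
            raise ValueError(f"unknown outlier_handling {self.outlier_handling!r}")

    def label(self) -> str:
        parts = [
            "sh" if self.hazard_type == "subdistribution" else "csh",
            "multi" if self.selection_method == "multivariable_boosting" else "uni",
            self.endpoint,
            "all" if self.outlier_handling == "all_observations" else "noout",
        ]
        return "_".join(parts)


def config_grid(
    hazard_types: Sequence[str] = HAZARD_TYPES,
    selection_methods: Sequence[str] = SELECTION_METHODS,
    endpoints: Sequence[str] = ENDPOINT_VERSIONS,
    outlier_handling: Sequence[str] = OUTLIER_HANDLING,
) -> list[ModelingConfig]:
    """All combinations of the four modeling choices (16 by default)."""
    return [
        ModelingConfig(h, s, e, o)
        for h in hazard_types
        for s in selection_methods
        for e in endpoints
        for o in outlier_handling
    ]


@dataclass
class CompetingRisksDataset:
    """Aligned survival outcomes, clinical covariates and expression matrix.

    Attributes
    ----------
    subject_ids : array of str, shape (n,)
    time : float array, shape (n,)
        Observed time in months (event or censoring, whichever first).
    event : int array, shape (n,)
        1 if an event was observed, 0 if censored.
    event_type : int array, shape (n,)
        1 or 2 where ``event == 1``; 0 where censored.
    clinical : DataFrame, shape (n, q)
        Must contain at least ``age`` and ``prior_cv``.
    expression : float array, shape (n, p)
    feature_names : list of str, length p
    endpoint_version : {"original", "updated"}
    """

    subject_ids: np.ndarray
    time: np.ndarray
    event: np.ndarray
    event_type: np.ndarray
    clinical: pd.DataFrame
    expression: np.ndarray
    feature_names: list[str]
    endpoint_version: str = "original"

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids, dtype=object)
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        self.event_type = np.asarray(self.event_type, dtype=int)
        self.expression = np.asarray(self.expression, dtype=float)
        self.feature_names = list(self.feature_names)
        self.validate()

    # -- basic shape helpers -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        return self.expression.shape[1]

    def n_events(self, cause: int | None = None) -> int:
        if cause is None:
            return int(self.event.sum())
        return int(((self.event == 1) & (self.event_type == cause)).sum())

    def validate(self) -> None:
        n = self.n
        if n == 0:
            raise DataValidationError("empty dataset refused")
        for name, arr in (("time", self.time), ("event", self.event),
                          ("event_type", self.event_type)):
            if len(arr) != n:
                raise DataValidationError(f"{name} has length {len(arr)}, expected {n}")
        if self.expression.shape[0] != n:
            raise DataValidationError(
                f"expression has {self.expression.shape[0]} rows, expected {n}")
        if len(self.feature_names) != self.expression.shape[1]:
            raise DataValidationError("feature_names length mismatch with expression")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise DataValidationError("feature_names not unique")
        if len(set(self.subject_ids.tolist())) != n:
            raise DataValidationError("subject ids not unique")
        bad = np.flatnonzero(self.time < 0)
        if bad.size:
            raise DataValidationError(f"negative observed_time at rows {bad.tolist()}")
        bad = np.flatnonzero(~np.isin(self.event, (0, 1)))
        if bad.size:
            raise DataValidationError(f"event indicator not in {{0,1}} at rows {bad.tolist()}")
        bad = np.flatnonzero((self.event == 1) & ~np.isin(self.event_type, (CAUSE_CV, CAUSE_OTHER)))
        if bad.size:
            raise DataValidationError(f"unknown event type at rows {bad.tolist()}")
        bad = np.flatnonzero((self.event == 0) & (self.event_type != NO_EVENT))
        if bad.size:
            raise DataValidationError(
                f"event_type set for censored subjects at rows {bad.tolist()}")
        if self.endpoint_version not in ENDPOINT_VERSIONS:
            raise DataValidationError(f"unknown endpoint_version {self.endpoint_version!r}")
        if self.clinical.shape[0] != n:
            raise DataValidationError("clinical table row count mismatch")
        if self.clinical.isna().any().any():
            cols = self.clinical.columns[self.clinical.isna().any()].tolist()
            raise DataValidationError(f"missing values in clinical columns {cols}")
        if not np.isfinite(self.expression).all():
            raise DataValidationError("non-finite values in expression matrix")
        if not np.isfinite(self.time).all():
            raise DataValidationError("non-finite observed times")

    # -- transformations -----------------------------------------------------
    def copy(self) -> "CompetingRisksDataset":
        return CompetingRisksDataset(
            subject_ids=self.subject_ids.copy(),
            time=self.time.copy(),
            event=self.event.copy(),
            event_type=self.event_type.copy(),
            clinical=self.clinical.copy().reset_index(drop=True),
            expression=self.expression.copy(),
            feature_names=list(self.feature_names),
            endpoint_version=self.endpoint_version,
        )

    def subset(self, indices: Sequence[int]) -> "CompetingRisksDataset":
        """Dataset restricted to the given subject positions (order kept)."""
        idx = np.asarray(indices, dtype=int)
        if idx.size == 0:
            raise DataValidationError("empty dataset refused")
        if idx.min() < 0 or idx.max() >= self.n:
            raise IndexError(f"subject index out of range [0, {self.n})")
        return CompetingRisksDataset(
            subject_ids=self.subject_ids[idx],
            time=self.time[idx],
            event=self.event[idx],
            event_type=self.event_type[idx],
            clinical=self.clinical.iloc[idx].reset_index(drop=True),
            expression=self.expression[idx],
            feature_names=list(self.feature_names),
            endpoint_version=self.endpoint_version,
        )


@dataclass
class EndpointRelabeling:
    """Total per-subject mapping from original to updated event labels.

    Labels are 0 (no event observed), 1 (death with prior cardiovascular
    event), 2 (death without prior cardiovascular event).  Subjects not
    affected by the update map to themselves.
    """

    mapping: dict  # subject id -> (original_label, updated_label)

    def updated_label(self, subject_id, original_label: int) -> int:
        orig, upd = self.mapping[subject_id]
        if orig != original_label:
            raise DataValidationError(
                f"relabeling for {subject_id!r} expects original label {orig}, "
                f"dataset has {original_label}")
        return upd

    @classmethod
    def identity(cls, dataset: CompetingRisksDataset) -> "EndpointRelabeling":
        labels = np.where(dataset.event == 1, dataset.event_type, NO_EVENT)
        return cls({sid: (int(l), int(l))
                    for sid, l in zip(dataset.subject_ids, labels)})


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def apply_relabeling(dataset: CompetingRisksDataset,
                     relabeling: EndpointRelabeling) -> CompetingRisksDataset:
    """Rewrite event labels per an endpoint update; times are unchanged.

    Returns a copy with ``endpoint_version`` set to ``"updated"``.
    """
    missing = [sid for sid in dataset.subject_ids if sid not in relabeling.mapping]
    if missing:
        raise DataValidationError(f"relabeling does not cover subjects {missing[:5]}")
    unknown = [sid for sid in relabeling.mapping
               if sid not in set(dataset.subject_ids.tolist())]
    if unknown:
        raise DataValidationError(f"relabeling references unknown subjects {unknown[:5]}")
    out = dataset.copy()
    labels = np.where(out.event == 1, out.event_type, NO_EVENT)
    new_labels = np.array([relabeling.updated_label(sid, int(l))
                           for sid, l in zip(out.subject_ids, labels)])
    out.event = (new_labels != NO_EVENT).astype(int)
    out.event_type = np.where(new_labels != NO_EVENT, new_labels, NO_EVENT)
    out.endpoint_version = "updated"
    out.validate()
    return out


def exclude_observations(dataset: CompetingRisksDataset,
                         indices: Iterable[int]) -> CompetingRisksDataset:
    """Drop the subjects at the given positions; remaining rows unchanged."""
    drop = sorted(set(int(i) for i in indices))
    if any(i < 0 or i >= dataset.n for i in drop):
        raise IndexError(f"subject index out of range [0, {dataset.n})")
    keep = [i for i in range(dataset.n) if i not in set(drop)]
    if not keep:
        raise DataValidationError("empty dataset refused: cannot exclude all subjects")
    if not drop:
        return dataset.copy()
    return dataset.subset(keep)


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------

SURVIVAL_COLUMNS = ("id", "time", "status", "cause")


def read_dataset(survival_path: str | Path, expression_path: str | Path,
                 endpoint: str = "original") -> CompetingRisksDataset:
    """Read a cohort from a survival CSV and an expression TSV.

    The survival table must have columns ``id, time, status, cause`` plus
    clinical covariates (at least ``age`` and ``prior_cv``).  The expression
    file is tab-separated with the subject id in the first column and one
    column per feature.  Subjects are aligned by id and returned in the
    survival-table order.
    """
    surv = pd.read_csv(survival_path)
    missing_cols = [c for c in SURVIVAL_COLUMNS if c not in surv.columns]
    if missing_cols:
        raise DataValidationError(f"survival table missing columns {missing_cols}")
    expr = pd.read_csv(expression_path, sep="\t")
    expr = expr.set_index(expr.columns[0])

    surv_ids = surv["id"].astype(str).tolist()
    expr_ids = set(expr.index.astype(str))
    absent = [sid for sid in surv_ids if sid not in expr_ids]
    if absent:
        raise AlignmentError(f"expression matrix missing subject ids {absent[:5]}")
    extra = [sid for sid in expr.index.astype(str) if sid not in set(surv_ids)]
    if extra:
        raise AlignmentError(f"expression matrix has unknown subject ids {extra[:5]}")
    expr = expr.loc[surv_ids]

    if surv[["time", "status", "cause"]].isna().any().any():
        raise DataValidationError("missing values in survival table")
    clinical_cols = [c for c in surv.columns if c not in SURVIVAL_COLUMNS]
    return CompetingRisksDataset(
        subject_ids=np.array(surv_ids, dtype=object),
        time=surv["time"].to_numpy(float),
        event=surv["status"].to_numpy(int),
        event_type=surv["cause"].to_numpy(int),
        clinical=surv[clinical_cols].reset_index(drop=True),
        expression=expr.to_numpy(float),
        feature_names=[str(c) for c in expr.columns],
        endpoint_version=endpoint,
    )


def write_dataset(dataset: CompetingRisksDataset, survival_path: str | Path,
                  expression_path: str | Path) -> None:
    """Write a cohort in the formats :func:`read_dataset` consumes."""
    surv = pd.DataFrame({
        "id": dataset.subject_ids,
        "time": dataset.time,
        "status": dataset.event,
        "cause": dataset.event_type,
    })
    surv = pd.concat([surv, dataset.clinical.reset_index(drop=True)], axis=1)
    surv.to_csv(survival_path, index=False)
    expr = pd.DataFrame(dataset.expression, columns=dataset.feature_names)
    expr.insert(0, "id", dataset.subject_ids)
    expr.to_csv(expression_path, sep="\t", index=False)


def read_relabeling(path: str | Path) -> EndpointRelabeling:
    """Read an endpoint-update file: CSV (id, original_label, updated_label)."""
    tab = pd.read_csv(path)
    need = {"id", "original_label", "updated_label"}
    if not need.issubset(tab.columns):
        raise DataValidationError(f"relabeling file needs columns {sorted(need)}")
    return EndpointRelabeling({
        str(r.id): (int(r.original_label), int(r.updated_label))
        for r in tab.itertuples()
    })


def write_relabeling(relabeling: EndpointRelabeling, path: str | Path) -> None:
    rows = [{"id": sid, "original_label": o, "updated_label": u}
            for sid, (o, u) in relabeling.mapping.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
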