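"""Examination-cohort data model: CSV I/O, label transformations, splitting.

A cohort is one row per examinee: 62 numeric physical-examination features
(4 basic, 26 blood routine, 12 urine routine, 20 liver function) and three
binary disease labels in fixed column order (hypertension H, diabetes D,
fatty liver FL).

The two multi-label transformations live here:

* binary relevance (BR) — one single-label binary view per disease;
* label powerset (LP) — each of the 8 label combinations becomes one class
  of a multi-class problem, with the fixed combination order
  ``{000, 100, 010, 001, 110, 101, 011, 111} -> {0..7}``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

N_FEATURES = 62
LABEL_NAMES = ("H", "D", "FL")
N_LABELS = len(LABEL_NAMES)

#: group name -> number of feature columns, in on-disk column order
GROUP_SIZES = {"basic": 4, "blood": 26, "urine": 12, "liver": 20}

#: LP class order: index in this tuple is the class code
LP_PATTERNS = (
    (0, 0, 0), (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, 0, 1), (0, 1, 1), (1, 1, 1),
)
N_LP_CLASSES = len(LP_PATTERNS)

# lookup from the binary value 4H+2D+FL to the LP class code
_BITS_TO_CODE = np.empty(8, dtype=np.int64)
for _code, (_h, _d, _fl) in enumerate(LP_PATTERNS):
    _BITS_TO_CODE[4 * _h + 2 * _d + _fl] = _code
_CODE_TO_PATTERN = np.array(LP_PATTERNS, dtype=np.int64)


def feature_names() -> list[str]:
    """Positional feature column names f001..f062."""
    return [f"f{i:03d}" for i in range(1, N_FEATURES + 1)]


def default_feature_groups() -> dict[int, str]:
    """Column index -> group name for the canonical 4/26/12/20 layout."""
    groups: dict[int, str] = {}
    col = 0
    for name, size in GROUP_SIZES.items():
        for _ in range(size):
            groups[col] = name
            col += 1
    return groups


@dataclass
class CohortTable:
    """In-memory cohort: feature matrix, binary label matrix, annotations."""

    features: np.ndarray          # (n, 62) float
    labels: np.ndarray            # (n, 3) int in {0,1}, columns (H, D, FL)
    feature_groups: dict[int, str] = field(default_factory=default_feature_groups)
    row_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2 or self.labels.ndim != 2:
            raise ValidationError("features and labels must be 2-D")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValidationError("features and labels disagree on row count")
        if self.labels.shape[1] != N_LABELS:
            raise ValidationError(
                f"expected {N_LABELS} label columns, got {self.labels.shape[1]}"
            )
        bad = ~np.isin(self.labels, (0, 1))
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValidationError(f"non-binary label value in row {row}")
        self.labels = self.labels.astype(np.int64)
        if np.isnan(self.features).any():
            raise ValidationError("feature matrix contains missing values")
        if self.row_ids is None:
            self.row_ids = np.arange(self.n)
        else:
            self.row_ids = np.asarray(self.row_ids)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    def validate_schema(self) -> None:
        """Check the 62-column 4/26/12/20 grouped layout."""
        if self.features.shape[1] != N_FEATURES:
            raise SchemaError(
                f"expected {N_FEATURES} feature columns, got {self.features.shape[1]}"
            )
        counts: dict[str, int] = {}
        for g in self.feature_groups.values():
            counts[g] = counts.get(g, 0) + 1
        if counts != GROUP_SIZES:
            raise SchemaError(f"feature group sizes {counts} != {GROUP_SIZES}")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=feature_names())
        for j, name in enumerate(LABEL_NAMES):
            df[name] = self.labels[:, j]
        return df


class SplitIndices(NamedTuple):
    """Disjoint train/test row indices covering the whole cohort."""

    train_rows: np.ndarray
    test_rows: np.ndarray


class BRView(NamedTuple):
    """One binary-relevance view: shared features, one disease's labels."""

    disease: str
    features: np.ndarray
    labels: np.ndarray


def lp_encode(labels: np.ndarray) -> np.ndarray:
    """Map (H, D, FL) binary triples to LP class codes in {0..7}.

    The class order is the fixed combination order
    000->0, 100->1, 010->2, 001->3, 110->4, 101->5, 011->6, 111->7.
    """
    labels = np.asarray(labels)
    if labels.ndim == 1:
        labels = labels[None, :]
    if labels.shape[1] != N_LABELS:
        raise ValidationError(f"expected {N_LABELS} label columns")
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary")
    bits = 4 * labels[:, 0] + 2 * labels[:, 1] + labels[:, 2]
    return _BITS_TO_CODE[bits.astype(np.int64)]


def lp_decode(classes: np.ndarray) -> np.ndarray:
    """Inverse of :func:`lp_encode`: class codes back to (H, D, FL) triples."""
    classes = np.asarray(classes)
    if classes.ndim == 0:
        classes = classes[None]
    if not np.issubdtype(classes.dtype, np.integer):
        if not np.array_equal(classes, classes.astype(np.int64)):
            raise ValidationError("LP classes must be integers")
        classes = classes.astype(np.int64)
    if classes.min(initial=0) < 0 or classes.max(initial=0) >= N_LP_CLASSES:
        raise ValidationError("LP class out of range {0..7}")
    return _CODE_TO_PATTERN[classes]


def br_views(cohort: CohortTable) -> list[BRView]:
    """Split a cohort into three single-disease binary views.

    The feature matrix is shared; each view's label vector is an independent
    copy so views can be shuffled independently.
    """
    return [
        BRView(name, cohort.features, cohort.labels[:, j].copy())
        for j, name in enumerate(LABEL_NAMES)
    ]


def pmcc_matrix(labels: np.ndarray) -> np.ndarray:
    """Pearson product-moment correlation between binary label columns.

    On 0/1 columns this equals the phi coefficient of each pairwise 2x2
    table. These values supply the alpha weights of the correlated loss.
    """
    labels = np.asarray(labels, dtype=float)
    if labels.ndim != 2:
        raise ValidationError("labels must be a 2-D matrix")
    if labels.shape[0] < 2:
        raise ValidationError("need at least 2 records for a correlation")
    sd = labels.std(axis=0)
    for j, s in enumerate(sd):
        if s == 0:
            name = LABEL_NAMES[j] if labels.shape[1] == N_LABELS else str(j)
            raise ValidationError(
                f"label column {name!r} is constant; correlation undefined"
            )
    return np.corrcoef(labels, rowvar=False)


def split_cohort(
    cohort: CohortTable, train_fraction: float = 0.7, seed: int = 0
) -> SplitIndices:
    """Stratified train/test split on the LP classes, deterministic per seed.

    Each of the 8 label-combination strata lands within one record of
    ``train_fraction * stratum size`` in the training part; strata with at
    least 2 records contribute to both parts. A singleton stratum goes to
    the training part with a warning.
    """
    if not 0 < train_fraction < 1:
        raise ValidationError("train_fraction must be in (0, 1)")
    codes = lp_encode(cohort.labels)
    rng = np.random.default_rng(seed)
    train_parts: list[np.ndarray] = []
    test_parts: list[np.ndarray] = []
    for c in range(N_LP_CLASSES):
        rows = np.flatnonzero(codes == c)
        if rows.size == 0:
            continue
        if rows.size == 1:
            warnings.warn(
                f"LP class {c} has a single record; assigned to train",
                stacklevel=2,
            )
            train_parts.append(rows)
            continue
        perm = rng.permutation(rows)
        n_train = int(round(train_fraction * rows.size))
        n_train = min(max(n_train, 1), rows.size - 1)
        train_parts.append(perm[:n_train])
        test_parts.append(perm[n_train:])
    train = np.sort(np.concatenate(train_parts)) if train_parts else np.array([], int)
    test = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], int)
    return SplitIndices(train_rows=train, test_rows=test)


@dataclass
class Scaler:
    """Per-column z-score parameters estimated on training rows."""

    mean: np.ndarray
    sd: np.ndarray

    def transform(self, features: np.ndarray) -> np.ndarray:
        return (np.asarray(features, dtype=float) - self.mean) / self.sd

    def to_json(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_json(cls, d: dict) -> "Scaler":
        return cls(mean=np.asarray(d["mean"]), sd=np.asarray(d["sd"]))


def standardize(cohort: CohortTable, stats_from: SplitIndices) -> tuple[CohortTable, Scaler]:
    """Z-score all features using statistics of the training rows only.

    Test rows are transformed with the training mean/SD, so the training
    columns come out with mean 0, SD 1 while the test columns inherit any
    covariate shift. A zero-SD training column is centred but not scaled
    (SD recorded as 1) with a warning.
    """
    train = stats_from.train_rows
    if train.size == 0:
        raise ValidationError("training rows are empty")
    mean = cohort.features[train].mean(axis=0)
    sd = cohort.features[train].std(axis=0)
    zero = sd == 0
    if zero.any():
        cols = np.flatnonzero(zero).tolist()
        warnings.warn(f"constant feature columns {cols}: centred only", stacklevel=2)
        sd = np.where(zero, 1.0, sd)
    scaler = Scaler(mean=mean, sd=sd)
    out = CohortTable(
        features=scaler.transform(cohort.features),
        labels=cohort.labels.copy(),
        feature_groups=dict(cohort.feature_groups),
        row_ids=cohort.row_ids.copy(),
    )
    return out, scaler


def read_cohort_csv(path, validate_schema: bool = True) -> CohortTable:
    """Load a cohort CSV: header f001..f062 then H, D, FL.

    Rows with any missing value are dropped and counted in the log.
    Non-binary label values raise a :class:`ValidationError` citing the
    (0-based) data row.
    """
    df = pd.read_csv(path)
    expected = feature_names() + list(LABEL_NAMES)
    if validate_schema:
        if list(df.columns) != expected:
            for got, want in zip(df.columns, expected):
                if got != want:
                    raise SchemaError(f"unexpected column {got!r}, expected {want!r}")
            raise SchemaError(
                f"expected {len(expected)} columns, got {len(df.columns)}"
            )
    label_cols = [c for c in df.columns if c in LABEL_NAMES]
    if len(label_cols) != N_LABELS:
        raise SchemaError(f"label columns {LABEL_NAMES} not all present")
    feat_cols = [c for c in df.columns if c not in LABEL_NAMES]

    bad_label = df[label_cols].notna() & ~df[label_cols].isin((0, 1))
    if bad_label.any().any():
        row = int(np.argwhere(bad_label.to_numpy())[0, 0])
        raise ValidationError(f"non-binary label value in row {row}")

    n_before = len(df)
    df = df.dropna()
    n_dropped = n_before - len(df)
    if n_dropped:
        logger.info("dropped %d rows with missing values", n_dropped)

    cohort = CohortTable(
        features=df[feat_cols].to_numpy(dtype=float),
        labels=df[label_cols].to_numpy(),
        row_ids=df.index.to_numpy(),
    )
    if validate_schema:
        cohort.validate_schema()
    return cohort


def write_cohort_csv(cohort: CohortTable, path) -> None:
    """Write a cohort in the canonical CSV layout (f001..f062, H, D, FL)."""
    cohort.to_dataframe().to_csv(path, index=False)
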