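"""Canonical in-memory representation of temporal datasets.

Four study designs are supported, distinguished by whether the outcome is
itself measured over time (*temporal*) or is a single per-subject label
(*static*), and by whether the same subjects are measured repeatedly
(*longitudinal*) or each subject contributes exactly one measurement
occasion (*distinct*, i.e. repeated cross-sectional / time-course data).

The exchange format is a long-format delimited table with one row per
measurement and reserved columns ``subject``, ``time`` and ``target``;
every other column is a feature.  Time is kept as the actual real-valued
stamp; the measurement-occasion index needed for autoregressive lags is
derived by ranking the distinct times within each subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataFormatError, DataIntegrityError

RESERVED_COLUMNS = ("subject", "time", "target")


class Scenario(str, Enum):
    """Study design of a temporal dataset."""

    TEMPORAL_LONGITUDINAL = "temporal_longitudinal"
    TEMPORAL_DISTINCT = "temporal_distinct"
    STATIC_LONGITUDINAL = "static_longitudinal"
    STATIC_DISTINCT = "static_distinct"

    @property
    def is_temporal(self) -> bool:
        """True when the target is a per-measurement continuous trajectory."""
        return self in (Scenario.TEMPORAL_LONGITUDINAL, Scenario.TEMPORAL_DISTINCT)

    @property
    def is_static(self) -> bool:
        """True when the target is one categorical label per subject."""
        return not self.is_temporal

    @property
    def is_distinct(self) -> bool:
        """True when every subject has exactly one measurement occasion."""
        return self in (Scenario.TEMPORAL_DISTINCT, Scenario.STATIC_DISTINCT)

    @property
    def is_longitudinal(self) -> bool:
        return not self.is_distinct


@dataclass
class TemporalDataset:
    """Subjects x time-points x features with a target, typed by scenario.

    Parameters
    ----------
    subject_ids : array of shape (N,)
        Subject identifier per measurement row (any sortable dtype).
    time : array of shape (N,)
        Real-valued time stamp per row.
    features : array of shape (N, p)
        Feature matrix.
    target : array
        Length-N continuous vector for temporal scenarios; length-K integer
        label vector (aligned with :attr:`subjects`, the sorted unique
        subject ids) for static scenarios.
    scenario : Scenario
    feature_names : list of str, optional
        Defaults to ``["V1", ..., "Vp"]``.

    Rows are sorted by (subject, time) on construction and all scenario
    invariants are checked.
    """

    subject_ids: np.ndarray
    time: np.ndarray
    features: np.ndarray
    target: np.ndarray
    scenario: Scenario
    feature_names: list[str] = field(default=None)  # type: ignore[assignment]
    #: relaxed validation for held-out prediction splits: a single time
    #: point, a single subject or a single class are then permitted.
    prediction_split: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.scenario = Scenario(self.scenario)
        self.subject_ids = np.asarray(self.subject_ids)
        self.time = np.asarray(self.time, dtype=float)
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.target = np.asarray(self.target)
        if self.feature_names is None:
            self.feature_names = [f"V{j + 1}" for j in range(self.features.shape[1])]
        self._sort_rows()
        self.validate()

    # ------------------------------------------------------------------ #
    def _sort_rows(self) -> None:
        order = np.lexsort((self.time, self.subject_ids))
        self.subject_ids = self.subject_ids[order]
        self.time = self.time[order]
        self.features = self.features[order]
        if self.scenario.is_temporal:
            self.target = np.asarray(self.target, dtype=float)[order]

    # -- derived quantities -------------------------------------------- #
    @property
    def N(self) -> int:
        """Total number of measurements (rows)."""
        return len(self.subject_ids)

    @property
    def p(self) -> int:
        """Number of candidate features."""
        return self.features.shape[1]

    @property
    def subjects(self) -> np.ndarray:
        """Sorted unique subject identifiers (length K)."""
        return np.unique(self.subject_ids)

    @property
    def K(self) -> int:
        """Number of distinct subjects."""
        return len(self.subjects)

    @property
    def n_i(self) -> np.ndarray:
        """Measurements per subject, aligned with :attr:`subjects`."""
        _, counts = np.unique(self.subject_ids, return_counts=True)
        return counts

    @property
    def n_classes(self) -> int:
        if self.scenario.is_temporal:
            raise AttributeError("n_classes is defined for static scenarios only")
        return len(np.unique(self.target))

    def subject_row_indices(self) -> list[np.ndarray]:
        """Row indices per subject, aligned with :attr:`subjects`."""
        return [np.flatnonzero(self.subject_ids == s) for s in self.subjects]

    def occasion_ranks(self) -> np.ndarray:
        """Within-subject rank (0-based) of each row's time stamp.

        AR(1) working correlations decay with the difference of these ranks,
        not with the raw time gap.
        """
        ranks = np.empty(self.N, dtype=int)
        for idx in self.subject_row_indices():
            ranks[idx] = np.argsort(np.argsort(self.time[idx]))
        return ranks

    def row_target(self) -> np.ndarray:
        """Target expanded to one value per row (identity for temporal data)."""
        if self.scenario.is_temporal:
            return self.target
        lookup = {s: t for s, t in zip(self.subjects, self.target)}
        return np.array([lookup[s] for s in self.subject_ids])

    # -- validation ---------------------------------------------------- #
    def validate(self) -> None:
        """Raise :class:`DataIntegrityError` on any scenario-invariant violation."""
        if self.features.ndim != 2 or self.p < 1:
            raise DataIntegrityError("feature matrix must be N x p with p >= 1")
        if self.features.shape[0] != self.N or len(self.time) != self.N:
            raise DataIntegrityError("subject_ids, time and features disagree on N")
        if len(self.feature_names) != self.p:
            raise DataIntegrityError("feature_names length must equal p")
        if self.K < 2 and not self.prediction_split:
            raise DataIntegrityError("at least 2 distinct subjects are required")
        pairs = set(zip(self.subject_ids.tolist(), self.time.tolist()))
        if len(pairs) != self.N:
            raise DataIntegrityError("duplicate (subject, time) measurement occasion")
        if not np.all(np.isfinite(self.time)):
            raise DataIntegrityError("non-finite time stamps")
        if self.scenario.is_distinct and np.any(self.n_i != 1):
            raise DataIntegrityError(
                "distinct-design scenarios require exactly one measurement per subject"
            )
        n_times = len(np.unique(self.time))
        min_times = 3 if self.scenario.is_temporal else 2
        if n_times < min_times and not self.prediction_split:
            raise DataIntegrityError(
                f"{self.scenario.value} requires >= {min_times} distinct time values, "
                f"got {n_times}"
            )
        if self.scenario.is_temporal:
            if len(self.target) != self.N:
                raise DataIntegrityError("temporal target must have one value per row")
            if not np.all(np.isfinite(self.target)):
                raise DataIntegrityError("non-finite target values")
        else:
            if len(self.target) != self.K:
                raise DataIntegrityError("static target must have one label per subject")
            labels = np.unique(self.target)
            if not np.issubdtype(self.target.dtype, np.integer):
                raise DataIntegrityError("static labels must be integers 0..C-1")
            if (len(labels) < 2 and not self.prediction_split) or labels[0] < 0:
                raise DataIntegrityError("static labels must be >= 2 classes coded 0..C-1")


# ---------------------------------------------------------------------- #
# long-format table I/O
# ---------------------------------------------------------------------- #
def _infer_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_long_table(
    path,
    scenario: Scenario,
    *,
    sep: str | None = None,
    on_missing_features: str = "error",
) -> TemporalDataset:
    """Read a long-format delimited table into a :class:`TemporalDataset`.

    The table must contain the reserved columns ``subject``, ``time`` and
    ``target`` plus at least one feature column.  For static scenarios the
    target column holds the per-subject label replicated on every row of
    that subject; a within-subject varying label is an integrity error.

    Rows with a missing target are dropped with a warning.  Missing feature
    cells are an error by default (``on_missing_features="drop"`` drops the
    affected rows instead).
    """
    path = Path(path)
    scenario = Scenario(scenario)
    if sep is None:
        sep = _infer_sep(path)
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in RESERVED_COLUMNS if c not in df.columns]
    if missing:
        raise DataFormatError(f"missing reserved column(s): {missing}")
    feat_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    if not feat_cols:
        raise DataFormatError("table has no feature columns")
    n_missing_target = int(df["target"].isna().sum())
    if n_missing_target:
        warnings.warn(f"dropping {n_missing_target} rows with missing target")
        df = df[df["target"].notna()]
    feat_na = df[feat_cols].isna().any(axis=1)
    if feat_na.any():
        if on_missing_features == "drop":
            warnings.warn(f"dropping {int(feat_na.sum())} rows with missing features")
            df = df[~feat_na]
        else:
            raise DataFormatError(
                f"{int(feat_na.sum())} rows contain missing feature values"
            )
    try:
        time = df["time"].astype(float).to_numpy()
        features = df[feat_cols].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise DataFormatError(f"non-numeric cell: {exc}") from exc
    subject_ids = df["subject"].to_numpy()

    if scenario.is_temporal:
        target = df["target"].astype(float).to_numpy()
    else:
        per_subject = df.groupby("subject")["target"].nunique()
        if (per_subject > 1).any():
            bad = per_subject[per_subject > 1].index.tolist()
            raise DataIntegrityError(
                f"static target varies within subject(s) {bad}"
            )
        labels = df.groupby("subject")["target"].first().sort_index()
        target = labels.to_numpy().astype(int)
    return TemporalDataset(
        subject_ids=subject_ids,
        time=time,
        features=features,
        target=target,
        scenario=scenario,
        feature_names=feat_cols,
    )


def write_long_table(ds: TemporalDataset, path, *, sep: str | None = None) -> None:
    """Write ``ds`` as a long-format delimited table (inverse of :func:`read_long_table`)."""
    ds.validate()
    path = Path(path)
    if sep is None:
        sep = _infer_sep(path)
    df = pd.DataFrame({"subject": ds.subject_ids, "time": ds.time, "target": ds.row_target()})
    for j, name in enumerate(ds.feature_names):
        df[name] = ds.features[:, j]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------- #
def fold_units(ds: TemporalDataset) -> list:
    """Cross-validation fold units for a dataset.

    Subjects for the static-longitudinal design (a held-out fold removes
    whole trajectories) and distinct sorted time values for the other three
    designs (a held-out fold removes whole time points).  Partitioning the
    returned units induces an exhaustive, disjoint row partition.
    """
    if ds.scenario is Scenario.STATIC_LONGITUDINAL:
        return list(ds.subjects)
    return sorted(np.unique(ds.time).tolist())


def rows_for_unit(ds: TemporalDataset, unit) -> np.ndarray:
    """Row indices belonging to a fold unit returned by :func:`fold_units`."""
    if ds.scenario is Scenario.STATIC_LONGITUDINAL:
        return np.flatnonzero(ds.subject_ids == unit)
    return np.flatnonzero(ds.time == unit)


def subset_rows(
    ds: TemporalDataset, rows: np.ndarray, *, prediction_split: bool = False
) -> TemporalDataset:
    """New dataset restricted to ``rows`` (static labels re-aligned to kept subjects).

    ``prediction_split=True`` relaxes validation for held-out folds that
    are only ever predicted, never fitted (e.g. a single held-out time
    point).
    """
    rows = np.asarray(rows)
    subject_ids = ds.subject_ids[rows]
    if ds.scenario.is_temporal:
        target = ds.target[rows]
    else:
        keep = np.unique(subject_ids)
        lookup = {s: t for s, t in zip(ds.subjects, ds.target)}
        target = np.array([lookup[s] for s in keep], dtype=int)
    return TemporalDataset(
        subject_ids=subject_ids,
        time=ds.time[rows],
        features=ds.features[rows],
        target=target,
        scenario=ds.scenario,
        feature_names=list(ds.feature_names),
        prediction_split=prediction_split,
    )
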