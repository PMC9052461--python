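"""Shared domain types and delimited-text I/O.

The canonical in-memory unit is :class:`OmicsMatrix`: a continuous
feature x sample table with string identifiers on both axes, as produced
by Xena-style profile dumps (features in rows).  Companion types carry
per-sample class labels, three-state discretized data, and the output of
a feature-selection run.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Method",
    "OmicsMatrix",
    "ClassLabels",
    "DiscretizedMatrix",
    "CriterionParams",
    "StepTrace",
    "SelectionResult",
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "align",
]


class Method(str, enum.Enum):
    """Feature-selection algorithms known to the package.

    The five compared methods are mRMR, INMIFS, DFS, SVM-RFE-CBR and
    VWMRmR; MIFS, MIFS-U and NMIFS are kept as reference baselines.
    """

    MIFS = "MIFS"
    MIFS_U = "MIFS-U"
    MRMR = "mRMR"
    NMIFS = "NMIFS"
    INMIFS = "INMIFS"
    VWMRMR = "VWMRmR"
    DFS = "DFS"
    SVM_RFE_CBR = "SVM-RFE-CBR"

    @classmethod
    def compared(cls) -> tuple["Method", ...]:
        """The five methods benchmarked head-to-head."""
        return (cls.MRMR, cls.INMIFS, cls.DFS, cls.SVM_RFE_CBR, cls.VWMRMR)

    @classmethod
    def from_string(cls, name: str) -> "Method":
        for m in cls:
            if m.value.lower() == name.lower() or m.name.lower() == name.lower():
                return m
        raise ValueError(f"unknown method {name!r}; choose from "
                         f"{[m.value for m in cls]}")


def _check_ids(ids: Sequence[str], what: str) -> tuple[str, ...]:
    ids = tuple(str(i) for i in ids)
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for i in ids:
            if i in seen:
                dups.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what} identifiers: {sorted(set(dups))[:5]}")
    return ids


@dataclass(frozen=True)
class OmicsMatrix:
    """Continuous feature x sample matrix with identifiers.

    ``values`` has shape ``(len(feature_ids), len(sample_ids))`` and must
    be finite everywhere: missing values are rejected at load time rather
    than imputed.
    """

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", _check_ids(self.feature_ids, "feature"))
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples")
        if not np.all(np.isfinite(vals)):
            r, c = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value for feature {self.feature_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}")
        object.__setattr__(self, "values", vals)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.feature_ids),
                            columns=list(self.sample_ids))

    def subset_features(self, ids: Iterable[str]) -> "OmicsMatrix":
        ids = list(ids)
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in ids if f not in pos]
        if missing:
            raise KeyError(f"features not present: {missing[:5]}")
        idx = [pos[f] for f in ids]
        return OmicsMatrix(tuple(ids), self.sample_ids, self.values[idx])

    def subset_samples(self, ids: Iterable[str]) -> "OmicsMatrix":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"samples not present: {missing[:5]}")
        idx = [pos[s] for s in ids]
        return OmicsMatrix(self.feature_ids, tuple(ids), self.values[:, idx])


@dataclass(frozen=True)
class ClassLabels:
    """Per-sample categorical class labels.

    ``class_names`` fixes the class order used for integer coding; every
    class must be represented by at least one sample.
    """

    sample_ids: tuple[str, ...]
    labels: tuple[str, ...]
    class_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        labels = tuple(str(l) for l in self.labels)
        if len(labels) != len(self.sample_ids):
            raise ValueError("one label required per sample")
        names = tuple(self.class_names) or tuple(sorted(set(labels)))
        if set(labels) - set(names):
            raise ValueError(f"labels outside class_names: {set(labels) - set(names)}")
        present = set(labels)
        empty = [c for c in names if c not in present]
        if empty:
            raise ValueError(f"classes with no samples: {empty}")
        if len(names) < 2:
            raise ValueError("need at least 2 classes")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def codes(self) -> np.ndarray:
        """Integer class codes in ``class_names`` order."""
        lut = {c: i for i, c in enumerate(self.class_names)}
        return np.array([lut[l] for l in self.labels], dtype=np.int64)

    def subset(self, ids: Iterable[str]) -> "ClassLabels":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        labels = tuple(self.labels[pos[s]] for s in ids)
        return ClassLabels(tuple(ids), labels, self.class_names)


@dataclass(frozen=True)
class DiscretizedMatrix:
    """Three-state (-1/0/+1) version of an :class:`OmicsMatrix`."""

    feature_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    states: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "feature_ids", _check_ids(self.feature_ids, "feature"))
        object.__setattr__(self, "sample_ids", _check_ids(self.sample_ids, "sample"))
        states = np.asarray(self.states, dtype=np.int8)
        if states.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("states shape does not match identifiers")
        if not np.isin(states, (-1, 0, 1)).all():
            raise ValueError("states must lie in {-1, 0, 1}")
        object.__setattr__(self, "states", states)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def subset_features(self, ids: Iterable[str]) -> "DiscretizedMatrix":
        ids = list(ids)
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in ids]
        return DiscretizedMatrix(tuple(ids), self.sample_ids, self.states[idx])


@dataclass(frozen=True)
class CriterionParams:
    """Tunable parameters shared across the selection algorithms.

    beta     MIFS / MIFS-U redundancy weight (literature mid-range 0.5).
    w        VWMRmR weight: the redundancy multiplier (1 + w|S|/k) grows
             linearly as the selected set fills toward k.
    k        target subset size (50 in the benchmark protocol).
    dfs_p    l2,p row-sparsity exponent, 0 < p <= 2.
    dfs_reg  DFS regularization weight.
    cbr_tau  |Pearson r| threshold above which a marked feature is
             protected during RFE elimination.
    rfe_step features eliminated per RFE round; None = ceil(10% of
             survivors).
    """

    beta: float = 0.5
    w: float = 1.0
    k: int = 50
    dfs_p: float = 1.0
    dfs_reg: float = 1.0
    cbr_tau: float = 0.85
    rfe_step: int | None = None

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be non-negative")
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not (0 < self.dfs_p <= 2):
            raise ValueError("dfs_p must satisfy 0 < p <= 2")
        if not (0 <= self.cbr_tau <= 1):
            raise ValueError("cbr_tau must lie in [0, 1]")
        if self.rfe_step is not None and self.rfe_step < 1:
            raise ValueError("rfe_step must be >= 1")


@dataclass(frozen=True)
class StepTrace:
    """Per-step criterion decomposition for one selected feature."""

    feature_id: str
    relevance: float
    redundancy: float
    score: float


@dataclass(frozen=True)
class SelectionResult:
    """Ordered selected-feature list with per-step criterion traces."""

    method: Method
    params: CriterionParams
    selected: tuple[str, ...]
    trace: tuple[StepTrace, ...]
    converged: bool = True

    def __post_init__(self) -> None:
        if len(set(self.selected)) != len(self.selected):
            raise ValueError("selected features must be unique")
        if len(self.trace) != len(self.selected):
            raise ValueError("trace length must equal number of selected features")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "rank": np.arange(1, len(self.selected) + 1),
            "feature_id": list(self.selected),
            "relevance": [t.relevance for t in self.trace],
            "redundancy": [t.redundancy for t in self.trace],
            "score": [t.score for t in self.trace],
        })

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# delimited-text I/O

def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(path: str | Path,
                orientation: str = "features_in_rows",
                delimiter: str | None = None) -> OmicsMatrix:
    """Read a delimited numeric table into an :class:`OmicsMatrix`.

    The file must have one header row and one identifier column; the
    delimiter is inferred from the extension (.csv = comma, else tab)
    unless given.  ``orientation`` normalizes the table to features x
    samples.  Duplicate identifiers, ragged rows and non-numeric cells
    (including NA) are hard errors reported with row/column context.
    """
    if orientation not in ("features_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    try:
        df = pd.read_csv(path, sep=sep, index_col=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.ParserError as exc:  # ragged rows, etc.
        raise ValueError(f"{path}: malformed table: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        r, c = bad[0]
        row_kind = "feature" if orientation == "features_in_rows" else "sample"
        col_kind = "sample" if orientation == "features_in_rows" else "feature"
        raise ValueError(
            f"{path}: non-numeric cell {df.iat[r, c]!r} at {row_kind} "
            f"{df.index[r]!r}, {col_kind} {df.columns[c]!r}")
    if orientation == "samples_in_rows":
        numeric = numeric.T
    return OmicsMatrix(tuple(numeric.index), tuple(numeric.columns),
                       numeric.to_numpy(dtype=float))


def write_matrix(matrix: OmicsMatrix, path: str | Path,
                 delimiter: str | None = None) -> None:
    """Write features-in-rows delimited text at 12 significant digits."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    matrix.to_frame().to_csv(path, sep=sep, float_format="%.12g")


def read_labels(path: str | Path, delimiter: str | None = None) -> ClassLabels:
    """Read a two-column (sample_id, class) table."""
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, na_values=[])
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample_id, class)")
    return ClassLabels(tuple(df.iloc[:, 0]), tuple(df.iloc[:, 1]))


def write_labels(labels: ClassLabels, path: str | Path,
                 delimiter: str | None = None) -> None:
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    pd.DataFrame({"sample_id": list(labels.sample_ids),
                  "class": list(labels.labels)}).to_csv(path, sep=sep, index=False)


def align(matrix: OmicsMatrix, labels: ClassLabels) -> tuple[OmicsMatrix, ClassLabels]:
    """Restrict both inputs to their shared samples, sorted lexicographically.

    Sorting fixes a deterministic sample order so downstream seeded
    cross-validation is reproducible regardless of input file order.
    Raises on an empty intersection.
    """
    shared = sorted(set(matrix.sample_ids) & set(labels.sample_ids))
    if not shared:
        raise ValueError("matrix and labels share no sample identifiers")
    return matrix.subset_samples(shared), labels.subset(shared)
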