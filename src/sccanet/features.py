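"""Feature engineering for connectome-symptom analysis.

Turns per-subject symmetric connectivity matrices and clinical item tables
into the analysis-ready matrices ``X`` (subjects x connectivity features) and
``Y`` (subjects x items): vectorization of the unique matrix entries,
variability-based feature selection with the median absolute deviation (MAD),
confound residualization against demographic/motion covariates, and column
standardization.

The vectorization convention enumerates the upper triangle *including* the
diagonal in row-major order, so an ``m``-node matrix yields ``m(m+1)/2``
features (264 nodes -> 34,980).  Diagonal entries of a correlation matrix are
constant and carry zero MAD, so they are always discarded by the MAD filter;
the convention only fixes the printed feature count and the column order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "ClinicalMatrix",
    "CovariateTable",
    "vectorize_connectivity",
    "mad",
    "filter_by_mad",
    "residualize",
    "standardize",
    "rebuild_matrix",
]


@dataclass
class FeatureMatrix:
    """Subjects x connectivity-features matrix with a column -> edge map.

    Attributes
    ----------
    values
        ``(n_subjects, n_features)`` array of edge weights.
    feature_index
        ``(n_features, 2)`` integer array of 0-based ``(i, j)`` node pairs,
        ``i <= j``, one row per column of ``values``.
    subjects
        Subject identifiers, aligned with the rows of ``values``.
    selection_meta
        Bookkeeping from the MAD filter: per-feature MAD of the retained
        columns, the requested fraction and the realized retained count.
    """

    values: np.ndarray
    feature_index: np.ndarray
    subjects: np.ndarray
    selection_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_index = np.asarray(self.feature_index, dtype=int)
        self.subjects = np.asarray(self.subjects)
        if self.feature_index.shape != (self.values.shape[1], 2):
            raise ValueError(
                "feature_index must have one (i, j) row per column: "
                f"got {self.feature_index.shape} for {self.values.shape[1]} columns"
            )
        if np.any(self.feature_index[:, 0] > self.feature_index[:, 1]):
            raise ValueError("feature_index pairs must satisfy i <= j")
        pairs = {tuple(p) for p in self.feature_index}
        if len(pairs) != len(self.feature_index):
            raise ValueError("feature_index contains duplicate (i, j) pairs")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class ClinicalMatrix:
    """Subjects x items matrix of (possibly residualized) symptom scores."""

    values: np.ndarray
    items: np.ndarray
    subjects: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.items = np.asarray(self.items)
        self.subjects = np.asarray(self.subjects)
        if len(self.items) != self.values.shape[1]:
            raise ValueError("one item label per column required")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


#: Covariates are carried as a plain DataFrame indexed by subject with the
#: columns ``age`` (years), ``sex`` (0/1), ``race`` (categorical) and
#: ``motion`` (mean framewise displacement, mm).
CovariateTable = pd.DataFrame


def _check_symmetric(mat: np.ndarray, tol: float, label: str) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"connectivity matrix for subject {label!r} is not square: {mat.shape}")
    asym = np.max(np.abs(mat - mat.T))
    if asym > tol:
        raise ValueError(
            f"connectivity matrix for subject {label!r} is asymmetric "
            f"(max |A - A^T| = {asym:.3g} > {tol:.3g})"
        )


def upper_triangle_index(n_nodes: int) -> np.ndarray:
    """Row-major upper-triangle (including diagonal) edge enumeration."""
    i, j = np.triu_indices(n_nodes)
    return np.column_stack([i, j])


def vectorize_connectivity(
    matrices: Sequence[np.ndarray] | np.ndarray,
    subjects: Iterable | None = None,
    tol: float = 1e-8,
    fisher_z: bool = False,
) -> FeatureMatrix:
    """Stack the unique entries of symmetric matrices into a feature matrix.

    Parameters
    ----------
    matrices
        Sequence (or 3-d array) of per-subject square symmetric matrices with
        identical node order.
    subjects
        Optional subject identifiers; defaults to ``0..n-1``.
    tol
        Maximum tolerated absolute asymmetry per matrix.
    fisher_z
        Apply ``arctanh`` to the edge values (off by default: raw correlation
        weights are the standard input here).  Values are clipped to
        +-(1 - 1e-12) first so unit diagonals map to a finite constant.
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    if not mats:
        raise ValueError("no connectivity matrices supplied")
    n_nodes = mats[0].shape[0]
    subj = np.asarray(list(subjects)) if subjects is not None else np.arange(len(mats))
    if len(subj) != len(mats):
        raise ValueError("number of subject ids does not match number of matrices")
    rows = []
    iu = np.triu_indices(n_nodes)
    for label, mat in zip(subj, mats):
        if mat.shape != (n_nodes, n_nodes):
            raise ValueError(
                f"connectivity matrix for subject {label!r} has shape {mat.shape}, "
                f"expected ({n_nodes}, {n_nodes})"
            )
        _check_symmetric(mat, tol, str(label))
        row = mat[iu]
        if fisher_z:
            row = np.arctanh(np.clip(row, -1 + 1e-12, 1 - 1e-12))
        rows.append(row)
    return FeatureMatrix(
        values=np.vstack(rows),
        feature_index=upper_triangle_index(n_nodes),
        subjects=subj,
    )


def rebuild_matrix(values: np.ndarray, feature_index: np.ndarray, n_nodes: int) -> np.ndarray:
    """Inverse of vectorization: place a feature vector back on the node grid."""
    values = np.asarray(values, dtype=float)
    feature_index = np.asarray(feature_index, dtype=int)
    if len(values) != len(feature_index):
        raise ValueError("one value per feature_index row required")
    out = np.zeros((n_nodes, n_nodes))
    i, j = feature_index[:, 0], feature_index[:, 1]
    out[i, j] = values
    out[j, i] = values
    return out


def mad(values: np.ndarray) -> float:
    """Median absolute deviation from the median.

    ``median(|x_i - median(x)|)``, with even-length medians taken as the
    midpoint of the two central order statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("mad of an empty vector is undefined")
    return float(np.median(np.abs(x - np.median(x))))


def filter_by_mad(fm: FeatureMatrix, fraction: float) -> FeatureMatrix:
    """Retain the most variable connectivity features by MAD.

    Keeps the ``floor(fraction * p)`` features with the largest MAD across
    subjects, where ``p`` counts all enumerated features.  Zero-MAD features
    (e.g. the constant unit diagonal of a correlation matrix) always rank
    last and are never retained.  Ties are broken by the original column
    order, so the result is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    mads = np.median(
        np.abs(fm.values - np.median(fm.values, axis=0, keepdims=True)), axis=0
    )
    p = fm.n_features
    n_keep = int(np.floor(fraction * p))
    # stable sort on -mad keeps the original order among ties
    order = np.argsort(-mads, kind="stable")
    keep = order[:n_keep]
    keep = keep[mads[keep] > 0]
    keep = np.sort(keep)
    return FeatureMatrix(
        values=fm.values[:, keep],
        feature_index=fm.feature_index[keep],
        subjects=fm.subjects,
        selection_meta={
            "mad": mads[keep],
            "mad_all": mads,
            "fraction": fraction,
            "n_enumerated": p,
            "n_retained": int(len(keep)),
        },
    )


def _design_matrix(covariates: pd.DataFrame, which: Sequence[str]) -> np.ndarray:
    """Intercept + reference-level indicator encoding of selected covariates."""
    cols = [np.ones(len(covariates))]
    names = ["intercept"]
    for name in which:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not present in table")
        col = covariates[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, drop_first=True, dtype=float)
            for dcol in dummies.columns:
                cols.append(dummies[dcol].to_numpy())
                names.append(f"{name}[{dcol}]")
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"rank-deficient residualization design (rank {rank} < {design.shape[1]}); "
            f"columns: {names}"
        )
    return design


def residualize(
    matrix: np.ndarray,
    covariates: pd.DataFrame,
    which: Sequence[str] = ("age", "sex", "race", "motion"),
) -> np.ndarray:
    """Per-column least-squares residuals against intercept + covariates.

    ``which`` may be empty, in which case columns are simply mean-centered.
    The output is orthogonal to every design column.
    """
    matrix = np.asarray(matrix, dtype=float)
    if len(covariates) != matrix.shape[0]:
        raise ValueError(
            f"covariate rows ({len(covariates)}) do not align with matrix rows "
            f"({matrix.shape[0]})"
        )
    design = _design_matrix(covariates, which)
    beta, *_ = np.linalg.lstsq(design, matrix, rcond=None)
    return matrix - design @ beta


def standardize(matrix: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Center each column to mean 0 and scale to standard deviation 1.

    Uses the population standard deviation (``ddof=0``) by default.  Raises on
    zero-variance columns rather than silently producing NaNs.
    """
    matrix = np.asarray(matrix, dtype=float)
    sd = matrix.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"zero-variance column(s) at index {bad.tolist()}")
    return (matrix - matrix.mean(axis=0)) / sd
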