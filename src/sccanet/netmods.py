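"""Community-level summaries of connectivity loading matrices.

A fitted variate's connectivity loadings live on edges of the brain graph.
To interpret them, they are summarized against an a priori community
partition (e.g. default mode, fronto-parietal...):

* within-module loading of community m:   sum_{i,j in m} 2 W_ij / (|M|(|M|-1))
* between-module loading of (m, n), m!=n: sum_{i in m, j in n} W_ij / (|M||N|)

Significance of each community-pair cell comes from permuting node labels
uniformly at random while preserving every community's size; cross-dimension
"common edge" analysis intersects the per-dimension significant-edge masks
and prunes any edge that ever shows up in intersections of random edge sets
with the same per-dimension edge counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import fdr_adjust

__all__ = [
    "CommunityAssignment",
    "ModuleLoadingMatrix",
    "OverlapResult",
    "build_loading_matrix",
    "within_module_loading",
    "between_module_loading",
    "module_loading_matrix",
    "module_label_permutation",
    "common_edge_overlap",
    "nodal_strength",
]


@dataclass
class CommunityAssignment:
    """Per-node community labels in canonical node order."""

    labels: np.ndarray
    names: list | None = None    # optional per-node names

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise ValueError("labels must be a non-empty 1-d array")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def communities(self) -> np.ndarray:
        return np.unique(self.labels)

    def members(self, label) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def sizes(self) -> dict:
        labs, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))


@dataclass
class ModuleLoadingMatrix:
    mean_loading: pd.DataFrame   # community x community
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None


@dataclass
class OverlapResult:
    common_edge_mask: np.ndarray      # node x node binary
    mean_abs_loading: np.ndarray      # node x node, nonzero on surviving edges
    nodal_strength: np.ndarray        # per-node sum of incident mean |loading|
    n_candidate: int                  # edges present in every dimension
    n_eliminated: int                 # candidates removed by the null model


def _check_loading_matrix(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"loading matrix must be square, got {W.shape}")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError("loading matrix must be symmetric")
    return W


def build_loading_matrix(
    loadings: np.ndarray,
    feature_index: np.ndarray,
    n_nodes: int,
    significant_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Place (significant) feature loadings back on the node x node grid.

    The inverse of vectorization restricted to a stability-surviving feature
    set: non-significant features and the diagonal are zeroed.
    """
    loadings = np.asarray(loadings, dtype=float)
    feature_index = np.asarray(feature_index, dtype=int)
    if len(loadings) != len(feature_index):
        raise ValueError("one loading per feature_index row required")
    if feature_index.min(initial=0) < 0 or feature_index.max(initial=-1) >= n_nodes:
        raise ValueError("feature_index refers to nodes outside 0..n_nodes-1")
    seen = set()
    for i, j in feature_index:
        key = (min(i, j), max(i, j))
        if key in seen:
            raise ValueError(f"duplicate edge {key} in feature_index")
        seen.add(key)
    if significant_mask is not None:
        loadings = np.where(np.asarray(significant_mask, dtype=bool), loadings, 0.0)
    W = np.zeros((n_nodes, n_nodes))
    i, j = feature_index[:, 0], feature_index[:, 1]
    W[i, j] = loadings
    W[j, i] = loadings
    np.fill_diagonal(W, 0.0)
    return W


def within_module_loading(W: np.ndarray, comm: CommunityAssignment, m) -> float:
    """Mean loading over the unordered node pairs inside community ``m``."""
    W = _check_loading_matrix(W)
    idx = comm.members(m)
    size = len(idx)
    if size < 2:
        raise ValueError(f"community {m!r} has {size} node(s); within-module mean undefined")
    sub = W[np.ix_(idx, idx)]
    return float(np.sum(np.triu(sub, k=1)) * 2 / (size * (size - 1)))


def between_module_loading(W: np.ndarray, comm: CommunityAssignment, m, n) -> float:
    """Mean loading over node pairs spanning communities ``m`` and ``n``."""
    if m == n:
        raise ValueError("between-module loading requires two distinct communities")
    W = _check_loading_matrix(W)
    mi, ni = comm.members(m), comm.members(n)
    if len(mi) == 0 or len(ni) == 0:
        raise ValueError("empty community")
    return float(np.sum(W[np.ix_(mi, ni)]) / (len(mi) * len(ni)))


def module_loading_matrix(W: np.ndarray, comm: CommunityAssignment) -> pd.DataFrame:
    """All within- (diagonal) and between-module (off-diagonal) mean loadings."""
    labs = comm.communities
    out = pd.DataFrame(np.nan, index=labs, columns=labs)
    for a, la in enumerate(labs):
        if len(comm.members(la)) >= 2:
            out.loc[la, la] = within_module_loading(W, comm, la)
        for lb in labs[a + 1:]:
            val = between_module_loading(W, comm, la, lb)
            out.loc[la, lb] = val
            out.loc[lb, la] = val
    return out


def module_label_permutation(
    W: np.ndarray,
    comm: CommunityAssignment,
    B: int = 1000,
    seed: int = 0,
) -> ModuleLoadingMatrix:
    """Community-size-preserving label permutation test for module loadings.

    Each permutation reassigns node labels uniformly at random (a shuffle of
    the label vector, so every community keeps its size) and recomputes the
    module-loading matrix.  Cells are tested two-sided: p is the fraction of
    permuted |mean loading| that reaches the observed |mean loading|, with
    Benjamini-Hochberg FDR across the unique cells.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    W = _check_loading_matrix(W)
    observed = module_loading_matrix(W, comm)
    labs = observed.index.to_numpy()
    rng = np.random.default_rng(seed)
    exceed = np.zeros(observed.shape)
    obs_abs = np.abs(observed.to_numpy())
    for _ in range(B):
        perm = CommunityAssignment(rng.permutation(comm.labels))
        null = np.abs(module_loading_matrix(W, perm).loc[labs, labs].to_numpy())
        exceed += (null >= obs_abs - 1e-12).astype(float)
    p_mat = exceed / B
    # FDR over the unique upper-triangle cells (incl. diagonal), mirrored back
    iu = np.triu_indices(len(labs))
    flat_p = p_mat[iu]
    valid = ~np.isnan(observed.to_numpy()[iu])
    q_flat = np.full(flat_p.shape, np.nan)
    if valid.any():
        q_flat[valid] = fdr_adjust(flat_p[valid])
    q_mat = np.full(p_mat.shape, np.nan)
    q_mat[iu] = q_flat
    q_mat.T[iu] = q_flat
    p_df = pd.DataFrame(p_mat, index=labs, columns=labs).where(~observed.isna())
    q_df = pd.DataFrame(q_mat, index=labs, columns=labs).where(~observed.isna())
    return ModuleLoadingMatrix(mean_loading=observed, p=p_df, q=q_df)


def _edge_count(mask: np.ndarray) -> int:
    return int(np.sum(np.triu(mask, k=1)))


def common_edge_overlap(
    masks: list[np.ndarray],
    loadings: list[np.ndarray],
    B: int = 1000,
    seed: int = 0,
) -> OverlapResult:
    """Cross-dimension common significant edges against a density-matched null.

    Candidate edges are those present in *every* supplied binary mask (the
    sum-and-threshold-at-K rule).  The null model repeats, B times, the
    intersection of independently drawn uniformly random edge sets with the
    same per-dimension edge counts; any edge that appears at least once in a
    null intersection is eliminated.  Surviving edges get the mean absolute
    loading across dimensions and per-node strengths.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if len(masks) != len(loadings) or not masks:
        raise ValueError("need matching, non-empty mask and loading lists")
    n = np.asarray(masks[0]).shape[0]
    masks = [np.asarray(m).astype(bool) for m in masks]
    loads = [np.asarray(w, dtype=float) for w in loadings]
    for m, w in zip(masks, loads):
        if m.shape != (n, n) or w.shape != (n, n):
            raise ValueError("all masks and loading matrices must share the node count")
    candidate = np.logical_and.reduce(masks)
    np.fill_diagonal(candidate, False)
    counts = [_edge_count(m) for m in masks]
    iu = np.triu_indices(n, k=1)
    n_edges = len(iu[0])
    rng = np.random.default_rng(seed)
    eliminated = np.zeros(n_edges, dtype=bool)
    for _ in range(B):
        inter = np.ones(n_edges, dtype=bool)
        for cnt in counts:
            pick = np.zeros(n_edges, dtype=bool)
            pick[rng.choice(n_edges, size=cnt, replace=False)] = True
            inter &= pick
            if not inter.any():
                break
        eliminated |= inter
    elim_mat = np.zeros((n, n), dtype=bool)
    elim_mat[iu] = eliminated
    elim_mat |= elim_mat.T
    n_candidate = _edge_count(candidate)
    surviving = candidate & ~elim_mat
    mean_abs = np.mean([np.abs(w) for w in loads], axis=0) * surviving
    return OverlapResult(
        common_edge_mask=surviving,
        mean_abs_loading=mean_abs,
        nodal_strength=nodal_strength(mean_abs),
        n_candidate=n_candidate,
        n_eliminated=n_candidate - _edge_count(surviving),
    )


def nodal_strength(W: np.ndarray) -> np.ndarray:
    """Per-node sum of absolute loadings over incident edges."""
    W = _check_loading_matrix(W)
    return np.sum(np.abs(W), axis=1)
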