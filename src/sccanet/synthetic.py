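"""Synthetic cohorts with planted sparse canonical structure.

Real connectome-symptom cohorts of the kind this package analyzes live under
restricted access, so every downstream stage is exercised on simulated
cohorts whose ground truth is known exactly.  The generative model plants
``K*`` latent dimensions linking the two views:

* per subject, latent scores ``t_k ~ N(0, 1)``;
* edge pre-values ``z_ij = mu_ij + sum_k sigma_k t_k u*_k,(ij) + (confounds)
  + noise``, squashed into (-1, 1) by ``tanh``, symmetrized, unit diagonal;
  the baseline ``mu`` is elevated within communities so block structure is
  visible;
* clinical latents ``y_q = sum_k sigma_k t_k v*_k,q + (confounds) + noise``,
  discretized to ordinal item levels at fixed equal-mass quantile cuts.

``u*_k`` / ``v*_k`` are unit-norm sparse loading vectors over off-diagonal
edge features and items.  Covariates (age, sex, race, motion) act on both
views through per-feature random coefficients so that confound
residualization has something real to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .features import upper_triangle_index

__all__ = ["CohortConfig", "GroundTruth", "SyntheticCohort", "generate_cohort", "score_recovery"]


@dataclass
class CohortConfig:
    """Design of a simulated cohort.

    effect_scales (``sigma_k``) set the strength of each planted dimension in
    both views; confound_effects maps covariate name -> (effect on the
    connectivity view, effect on the clinical view) in pre-squash units.
    """

    n_subjects: int = 500
    n_nodes: int = 25
    community_sizes: Sequence[int] | None = None
    n_items: int = 40
    n_latent: int = 2
    conn_support_sizes: Sequence[int] | None = None
    clin_support_sizes: Sequence[int] | None = None
    effect_scales: Sequence[float] = (3.0, 2.0)
    confound_effects: dict | None = None
    noise_sd: float = 1.0
    item_levels: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if self.n_latent < 0:
            raise ValueError("n_latent must be >= 0")
        if self.item_levels < 2:
            raise ValueError("item_levels must be >= 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.community_sizes is None:
            # near-equal split into 4 communities by default
            k = min(4, self.n_nodes)
            base, extra = divmod(self.n_nodes, k)
            self.community_sizes = tuple(base + (1 if i < extra else 0) for i in range(k))
        if sum(self.community_sizes) != self.n_nodes:
            raise ValueError(
                f"community_sizes sums to {sum(self.community_sizes)}, expected n_nodes={self.n_nodes}"
            )
        n_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.conn_support_sizes is None:
            self.conn_support_sizes = tuple(
                max(1, n_edges // 10) for _ in range(self.n_latent)
            )
        if self.clin_support_sizes is None:
            self.clin_support_sizes = tuple(
                max(1, self.n_items // 4) for _ in range(self.n_latent)
            )
        for name, sizes, cap in (
            ("conn_support_sizes", self.conn_support_sizes, n_edges),
            ("clin_support_sizes", self.clin_support_sizes, self.n_items),
        ):
            if len(sizes) != self.n_latent:
                raise ValueError(f"{name} must have one entry per latent dimension")
            if any(s < 1 or s > cap for s in sizes):
                raise ValueError(f"{name} entries must lie in [1, {cap}]")
        self.effect_scales = tuple(self.effect_scales)[: self.n_latent]
        if len(self.effect_scales) != self.n_latent:
            raise ValueError("effect_scales must have one entry per latent dimension")
        if any(s < 0 for s in self.effect_scales):
            raise ValueError("effect_scales must be non-negative")
        if self.confound_effects is None:
            self.confound_effects = {
                "age": (0.02, 0.02),
                "sex": (0.1, 0.1),
                "race": (0.05, 0.05),
                "motion": (0.3, 0.0),
            }


@dataclass
class GroundTruth:
    """Planted loadings and latent scores of a simulated cohort."""

    u_true: np.ndarray          # (n_edge_features, K*) unit-norm sparse columns
    v_true: np.ndarray          # (n_items, K*)
    latent_scores: np.ndarray   # (n_subjects, K*)
    edge_index: np.ndarray      # (n_edge_features, 2) off-diagonal (i, j), i < j
    confound_coefs: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    connectivity: np.ndarray    # (n_subjects, n_nodes, n_nodes), symmetric, unit diagonal
    clinical: pd.DataFrame      # subjects x items, ordinal {0..levels-1}
    covariates: pd.DataFrame    # age / sex / race / motion
    communities: np.ndarray     # per-node community labels
    truth: GroundTruth
    config: CohortConfig

    @property
    def subjects(self) -> np.ndarray:
        return np.asarray(self.clinical.index)


def _sparse_unit_vectors(rng, dim: int, sizes: Sequence[int]) -> np.ndarray:
    """Columns with the requested support sizes, disjoint supports when possible."""
    K = len(sizes)
    out = np.zeros((dim, K))
    pool = rng.permutation(dim)
    cursor = 0
    for k, s in enumerate(sizes):
        if cursor + s <= dim:
            idx = pool[cursor:cursor + s]
            cursor += s
        else:
            idx = rng.choice(dim, size=s, replace=False)
        vals = rng.normal(size=s)
        vals += np.sign(vals.sum() or 1.0) * 0.5  # avoid near-cancelling supports
        out[idx, k] = vals / np.linalg.norm(vals)
    return out


def _ordinalize(latent: np.ndarray, levels: int) -> np.ndarray:
    """Equal-mass quantile discretization, columnwise."""
    qs = np.quantile(latent, np.linspace(0, 1, levels + 1)[1:-1], axis=0)
    out = np.zeros_like(latent, dtype=int)
    for cut in qs:
        out += (latent > cut).astype(int)
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw one cohort from the planted-structure generative model.

    Deterministic for a fixed ``config.seed``; a single seeded generator
    drives every draw.
    """
    rng = np.random.default_rng(config.seed)
    n, m, K = config.n_subjects, config.n_nodes, config.n_latent
    edge_index = upper_triangle_index(m)
    offdiag = edge_index[:, 0] < edge_index[:, 1]
    edge_index = edge_index[offdiag]
    n_edges = len(edge_index)

    # covariates: ranges emulate a developmental community sample
    covariates = pd.DataFrame(
        {
            "age": rng.uniform(8, 22, size=n),
            "sex": rng.integers(0, 2, size=n),
            "race": rng.choice(["A", "B", "C"], size=n, p=[0.5, 0.35, 0.15]),
            "motion": rng.lognormal(mean=-2.3, sigma=0.5, size=n),
        },
        index=pd.Index([f"sub-{i:04d}" for i in range(n)], name="subject_id"),
    )

    u_true = _sparse_unit_vectors(rng, n_edges, config.conn_support_sizes)
    v_true = _sparse_unit_vectors(rng, config.n_items, config.clin_support_sizes)
    t = rng.normal(size=(n, K))
    sigma = np.asarray(config.effect_scales)

    # confound design: standardized numeric covariates + indicator for race
    conf_cols = {
        "age": (covariates["age"] - covariates["age"].mean()) / covariates["age"].std(),
        "sex": covariates["sex"] - covariates["sex"].mean(),
        "race": (covariates["race"] != "A").astype(float) - (covariates["race"] != "A").mean(),
        "motion": (covariates["motion"] - covariates["motion"].mean())
        / covariates["motion"].std(),
    }
    conn_conf = np.zeros((n, n_edges))
    clin_conf = np.zeros((n, config.n_items))
    confound_coefs: dict = {}
    for name, col in conf_cols.items():
        eff_conn, eff_clin = config.confound_effects.get(name, (0.0, 0.0))
        beta_conn = rng.normal(scale=1.0, size=n_edges) * eff_conn
        beta_clin = rng.normal(scale=1.0, size=config.n_items) * eff_clin
        conn_conf += np.outer(col.to_numpy(), beta_conn)
        clin_conf += np.outer(col.to_numpy(), beta_clin)
        confound_coefs[name] = {"connectivity": beta_conn, "clinical": beta_clin}

    # baseline mu: within-community elevation on the pre-squash scale
    labels = np.repeat(np.arange(len(config.community_sizes)), config.community_sizes)
    same = labels[edge_index[:, 0]] == labels[edge_index[:, 1]]
    mu = np.where(same, 0.45, 0.10)

    signal = (t * sigma) @ u_true.T if K else 0.0
    z = mu + signal + conn_conf + rng.normal(scale=config.noise_sd, size=(n, n_edges))
    edge_vals = np.tanh(z)

    connectivity = np.empty((n, m, m))
    i, j = edge_index[:, 0], edge_index[:, 1]
    for s in range(n):
        mat = np.eye(m)
        mat[i, j] = edge_vals[s]
        mat[j, i] = edge_vals[s]
        connectivity[s] = mat

    clin_latent = (
        ((t * sigma) @ v_true.T if K else 0.0)
        + clin_conf
        + rng.normal(scale=config.noise_sd, size=(n, config.n_items))
    )
    clinical = pd.DataFrame(
        _ordinalize(clin_latent, config.item_levels),
        index=covariates.index,
        columns=[f"item_{q:03d}" for q in range(config.n_items)],
    )

    truth = GroundTruth(
        u_true=u_true,
        v_true=v_true,
        latent_scores=t,
        edge_index=edge_index,
        confound_coefs=confound_coefs,
    )
    return SyntheticCohort(
        connectivity=connectivity,
        clinical=clinical,
        covariates=covariates,
        communities=labels,
        truth=truth,
        config=config,
    )


def _aligned_loading_corr(a: np.ndarray, b: np.ndarray) -> float:
    """|Pearson correlation| between two loading vectors (0 if degenerate)."""
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(abs(np.corrcoef(a, b)[0, 1]))


def score_recovery(
    truth: GroundTruth,
    model,
    feature_index: np.ndarray | None = None,
) -> pd.DataFrame:
    """How well a fitted model recovers the planted loadings.

    Greedily matches estimated variates to true dimensions one-to-one by the
    combined |correlation| of their connectivity and clinical loadings
    (order- and sign-invariant).  When the model was fitted on a feature
    subset, pass its ``feature_index`` so true edge loadings can be restricted
    to the retained columns.

    Returns a table with one row per true dimension: the matched estimated
    component and the u/v recovery correlations, all in [0, 1].
    """
    U_est = model.U
    V_est = model.V
    K_true = truth.u_true.shape[1]
    if V_est.shape[0] != truth.v_true.shape[0]:
        raise ValueError(
            f"item dimension mismatch: model has {V_est.shape[0]}, truth has {truth.v_true.shape[0]}"
        )
    if feature_index is not None:
        lut = {tuple(p): k for k, p in enumerate(truth.edge_index)}
        try:
            rows = [lut[tuple(p)] for p in np.asarray(feature_index)]
        except KeyError as exc:
            raise ValueError(f"feature {exc.args[0]} not present in the truth edge index") from exc
        U_true = truth.u_true[rows]
    else:
        if U_est.shape[0] != truth.u_true.shape[0]:
            raise ValueError(
                f"edge-feature dimension mismatch: model has {U_est.shape[0]}, "
                f"truth has {truth.u_true.shape[0]}"
            )
        U_true = truth.u_true

    K_est = U_est.shape[1]
    score = np.zeros((K_true, K_est))
    u_corr = np.zeros((K_true, K_est))
    v_corr = np.zeros((K_true, K_est))
    for a in range(K_true):
        for b in range(K_est):
            u_corr[a, b] = _aligned_loading_corr(U_true[:, a], U_est[:, b])
            v_corr[a, b] = _aligned_loading_corr(truth.v_true[:, a], V_est[:, b])
            score[a, b] = 0.5 * (u_corr[a, b] + v_corr[a, b])

    rows = []
    avail = set(range(K_est))
    order = np.argsort(-np.max(score, axis=1, initial=0.0), kind="stable")
    for a in order:
        if not avail:
            rows.append((a, -1, 0.0, 0.0))
            continue
        b = max(avail, key=lambda c: (score[a, c], -c))
        avail.discard(b)
        rows.append((a, b, u_corr[a, b], v_corr[a, b]))
    out = pd.DataFrame(
        rows, columns=["true_dim", "matched_component", "u_recovery", "v_recovery"]
    ).sort_values("true_dim").reset_index(drop=True)
    out["recovery"] = 0.5 * (out["u_recovery"] + out["v_recovery"])
    return out
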