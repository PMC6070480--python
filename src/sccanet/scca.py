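"""Sparse canonical correlation analysis by penalized matrix decomposition.

Solves, for two column-standardized views ``X`` (n x p) and ``Y`` (n x q),

    maximize  u' X'Y v   subject to  ||u||2^2 <= 1, ||v||2^2 <= 1,
                                     ||u||1 <= c1,  ||v||1 <= c2,

the elastic-net-constrained rank-1 decomposition of the cross-product matrix
``Z = X'Y``.  Each component is obtained by alternating soft-thresholded
power iterations; later components are extracted after rank-1 deflation of
``Z``.  Sparsity is parameterized on a 0-1 scale per view: the L1 bound is
``c = max(1, frac * sqrt(dim))``, so ``frac = 1`` never activates the L1
constraint (Cauchy-Schwarz) and ``frac = 0`` maps to the minimal feasible
bound of 1 (a single active feature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SccaParams",
    "CanonicalVariate",
    "CanonicalModel",
    "soft_threshold",
    "l1_constrain",
    "fit_component",
    "fit_scca",
    "covariance_explained",
]


@dataclass
class SccaParams:
    """Solver settings.

    c1_frac, c2_frac
        Sparsity of the connectivity (u) and clinical (v) loadings on the
        0-1 scale described in the module docstring.
    n_components
        Number of canonical variates to extract by deflation.
    tol, max_iter
        Convergence tolerance (max absolute change in u and v between
        iterations) and iteration cap per component.
    """

    c1_frac: float = 1.0
    c2_frac: float = 1.0
    n_components: int = 1
    tol: float = 1e-6
    max_iter: int = 100

    def __post_init__(self) -> None:
        for name in ("c1_frac", "c2_frac"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class CanonicalVariate:
    u: np.ndarray            # connectivity loadings, ||u||2 <= 1
    v: np.ndarray            # clinical loadings, ||v||2 <= 1
    d: float                 # singular value u' Z v (non-negative)
    r: float                 # Pearson correlation of Xu and Yv
    cov_frac: float          # share of total extracted covariance
    x_scores: np.ndarray     # brain scores Xu
    y_scores: np.ndarray     # clinical scores Yv


@dataclass
class CanonicalModel:
    variates: list[CanonicalVariate]
    params: SccaParams
    convergence: list[dict] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.variates)

    @property
    def U(self) -> np.ndarray:
        """Connectivity loadings stacked as columns (p x K)."""
        return np.column_stack([cv.u for cv in self.variates])

    @property
    def V(self) -> np.ndarray:
        """Clinical loadings stacked as columns (q x K)."""
        return np.column_stack([cv.v for cv in self.variates])

    @property
    def correlations(self) -> np.ndarray:
        return np.array([cv.r for cv in self.variates])

    @property
    def singular_values(self) -> np.ndarray:
        return np.array([cv.d for cv in self.variates])


def soft_threshold(a: np.ndarray, delta: float) -> np.ndarray:
    """Componentwise ``sign(a) * max(|a| - delta, 0)``."""
    if delta < 0:
        raise ValueError("delta must be non-negative")
    a = np.asarray(a, dtype=float)
    return np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)


def _unit(a: np.ndarray) -> np.ndarray:
    return a / np.linalg.norm(a)


def l1_constrain(a: np.ndarray, c: float) -> np.ndarray:
    """Project a direction onto the unit L2 sphere subject to an L1 cap.

    Returns ``w = S(a, delta) / ||S(a, delta)||_2`` for the smallest
    ``delta >= 0`` such that ``||w||_1 <= c``.  ``||w(delta)||_1`` is
    continuous and non-increasing in ``delta``, and between consecutive
    sorted ``|a|`` values the constraint ``||w||_1 = c`` reduces to a
    quadratic in ``delta``, so the threshold is solved exactly from the
    sorted magnitudes.  ``c >= 1`` is required: 1 is the smallest L1 norm any
    unit-L2 vector can have, attained by a single active coordinate (ties go
    to the lowest index).
    """
    a = np.asarray(a, dtype=float)
    norm = np.linalg.norm(a)
    if norm == 0:
        raise ValueError("cannot normalize an all-zero direction")
    if c < 1:
        raise ValueError(f"L1 bound must be >= 1, got {c}")
    w = a / norm
    if np.sum(np.abs(w)) <= c:
        return w
    abs_a = np.abs(a)

    def _single() -> np.ndarray:
        idx = int(np.argmax(abs_a))
        out = np.zeros_like(a)
        out[idx] = np.sign(a[idx])
        return out

    if c <= 1.0 + 1e-12:
        return _single()
    # sorted magnitudes b[0] >= b[1] >= ...; with m coordinates active and
    # delta in [b[m], b[m-1]) the L1 norm of w(delta) is
    #   f(delta) = (S1_m - m*delta) / sqrt(S2_m - 2*delta*S1_m + m*delta^2)
    d = abs_a.size
    b = np.sort(abs_a)[::-1]
    S1 = np.cumsum(b)
    S2 = np.cumsum(b * b)
    m_arr = np.arange(1, d + 1)
    delta_lo = np.append(b[1:], 0.0)  # lower endpoint of each interval
    numer = S1 - m_arr * delta_lo
    denom_sq = np.maximum(S2 - 2 * delta_lo * S1 + m_arr * delta_lo**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_lo = np.where(denom_sq > 0, numer / np.sqrt(denom_sq), 0.0)
    hit = np.flatnonzero(f_lo >= c)
    if hit.size == 0:  # cannot happen after the feasibility check; be safe
        return _single()
    m = int(m_arr[hit[0]])
    s1, s2 = S1[m - 1], S2[m - 1]
    # (s1 - m*delta)^2 = c^2 (s2 - 2*delta*s1 + m*delta^2)
    A = m * (m - c * c)
    Bq = 2 * s1 * (c * c - m)
    Cq = s1 * s1 - c * c * s2
    if abs(A) < 1e-30:
        delta = -Cq / Bq
    else:
        disc = max(Bq * Bq - 4 * A * Cq, 0.0)
        roots = np.array([(-Bq - np.sqrt(disc)) / (2 * A), (-Bq + np.sqrt(disc)) / (2 * A)])
        lo, hi = delta_lo[m - 1], b[m - 1]
        inside = roots[(roots >= lo - 1e-12) & (roots <= hi + 1e-12)]
        delta = float(inside.max()) if inside.size else float(np.clip(roots.max(), lo, hi))
    s = soft_threshold(a, max(delta, 0.0))
    if not np.any(s):
        return _single()
    w = _unit(s)
    if np.sum(np.abs(w)) > c + 1e-6:
        # tied maxima can make the smallest attainable L1 norm exceed c
        return _single()
    return w


def _l1_bound(frac: float, dim: int) -> float:
    return max(1.0, frac * np.sqrt(dim))


def _leading_right_singular_vector(Z: np.ndarray) -> np.ndarray:
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = vt[0]
    # deterministic orientation: largest-magnitude entry positive
    pivot = int(np.argmax(np.abs(v)))
    return v if v[pivot] >= 0 else -v


def fit_component(
    Z: np.ndarray,
    c1: float,
    c2: float,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, float, dict]:
    """Rank-1 penalized decomposition of a cross-product matrix.

    Alternates ``u <- l1_constrain(Z v, c1)`` and ``v <- l1_constrain(Z' u,
    c2)`` from the leading right singular vector of ``Z`` until the maximum
    absolute change in both loadings drops below ``tol``.  Returns
    ``(u, v, d, log)`` with ``d = u' Z v >= 0``.
    """
    Z = np.asarray(Z, dtype=float)
    if not np.any(Z):
        raise ValueError("cross-product matrix is identically zero")
    v = _leading_right_singular_vector(Z)
    u = np.zeros(Z.shape[0])
    log = {"n_iter": 0, "converged": False, "objective": []}
    for it in range(max_iter):
        u_new = l1_constrain(Z @ v, c1)
        v_new = l1_constrain(Z.T @ u_new, c2)
        obj = float(u_new @ Z @ v_new)
        log["objective"].append(obj)
        delta = max(np.max(np.abs(u_new - u)), np.max(np.abs(v_new - v)))
        u, v = u_new, v_new
        log["n_iter"] = it + 1
        if delta < tol:
            log["converged"] = True
            break
        # near the L1 boundary the support can oscillate while the objective
        # is stationary; treat a stagnant objective as converged
        if it >= 2 and abs(obj - log["objective"][-3]) < tol * max(1.0, abs(obj)):
            log["converged"] = True
            break
    if not log["converged"]:
        warnings.warn(
            f"sparse CCA component did not converge in {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    d = float(u @ Z @ v)
    if d < 0:
        u = -u
        d = -d
    return u, v, d, log


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def _apply_sign_convention(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orient a variate so its largest-|v| clinical loading is positive.

    Joint flips of (u, v) leave the singular value, the score correlation and
    the covariance-explained share unchanged; this just makes output
    canonical. Ties go to the lowest item index (numpy argmax).
    """
    if not np.any(v):
        return u, v
    pivot = int(np.argmax(np.abs(v)))
    if v[pivot] < 0:
        return -u, -v
    return u, v


def fit_scca(X, Y, params: SccaParams) -> CanonicalModel:
    """Fit a multi-component sparse CCA model.

    ``X`` and ``Y`` may be raw arrays or the FeatureMatrix / ClinicalMatrix
    containers; rows (subjects) must align.  Component ``k`` is extracted from
    the deflated cross-product ``Z_k = Z_{k-1} - d u u v'`` starting from
    ``Z_1 = X'Y``.  Deterministic for fixed inputs.
    """
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    Yv = np.asarray(getattr(Y, "values", Y), dtype=float)
    if Xv.shape[0] != Yv.shape[0]:
        raise ValueError(
            f"X and Y disagree on the number of subjects: {Xv.shape[0]} vs {Yv.shape[0]}"
        )
    p, q = Xv.shape[1], Yv.shape[1]
    K = min(params.n_components, p, q)
    c1 = _l1_bound(params.c1_frac, p)
    c2 = _l1_bound(params.c2_frac, q)
    Z = Xv.T @ Yv
    variates: list[CanonicalVariate] = []
    logs: list[dict] = []
    for _ in range(K):
        if not np.any(Z):
            break
        u, v, d, log = fit_component(Z, c1, c2, tol=params.tol, max_iter=params.max_iter)
        Z = Z - d * np.outer(u, v)
        u, v = _apply_sign_convention(u, v)
        xs, ys = Xv @ u, Yv @ v
        variates.append(
            CanonicalVariate(
                u=u, v=v, d=d, r=_pearson(xs, ys), cov_frac=np.nan,
                x_scores=xs, y_scores=ys,
            )
        )
        logs.append(log)
    if not variates:
        raise ValueError("no canonical variates could be extracted (zero cross-product)")
    model = CanonicalModel(variates=variates, params=params, convergence=logs)
    fracs = covariance_explained(model)
    for cv, frac in zip(model.variates, fracs):
        cv.cov_frac = float(frac)
    return model


def covariance_explained(model: CanonicalModel, squared: bool = False) -> np.ndarray:
    """Per-component share of the total extracted covariance.

    The default definition is ``d_k / sum_j d_j``; with ``squared=True`` the
    shares are ``d_k^2 / sum_j d_j^2``.  Shares sum to 1 over the extracted
    components.
    """
    d = model.singular_values
    if squared:
        d = d ** 2
    total = d.sum()
    if total == 0:
        raise ValueError("all singular values are zero; covariance shares undefined")
    return d / total
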