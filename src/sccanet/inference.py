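"""Permutation significance and resampling stability for canonical variates.

Permutation test: the clinical matrix rows are shuffled to break the
subject-level linkage between views, the sparse CCA is refitted with the
original penalties, and each refitted variate is matched back to its
reference variate by correlating clinical loading vectors (permutation can
rotate the variate order and reflect signs).  The empirical p-value for a
variate is the fraction of its B matched null correlations that reach its
observed correlation; Benjamini-Hochberg FDR is applied across the selected
variates.

Stability selection: each of R resamples draws two-thirds of the subjects
without replacement and restores the sample size by redrawing the remaining
third with replacement from those two-thirds.  Refitted variates are matched
and sign-aligned to the reference, and a feature is flagged stable when its
percentile confidence interval over resamples excludes zero (95% for
clinical items, 99% for connectivity features).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from statsmodels.stats.multitest import multipletests

from .scca import CanonicalModel, SccaParams, fit_scca

__all__ = [
    "VariateMatch",
    "PermutationResult",
    "StabilityResult",
    "match_variates",
    "empirical_p",
    "permutation_test",
    "fdr_adjust",
    "stability_resample",
]


@dataclass
class VariateMatch:
    assignment: np.ndarray     # candidate index matched to each reference variate
    signs: np.ndarray          # +-1 per reference variate
    match_scores: np.ndarray   # |corr| of the matched clinical loading vectors


@dataclass
class PermutationResult:
    B: int
    observed_r: np.ndarray     # per selected variate
    null_r: np.ndarray         # (B, n_selected) matched null correlations
    p: np.ndarray
    q: np.ndarray
    selected: list[int]
    seed: int

    def summary(self) -> dict:
        out = {}
        for i, k in enumerate(self.selected):
            label = f"< {1.0 / self.B:g}" if self.p[i] == 0 else f"{self.p[i]:g}"
            out[k] = {"r": float(self.observed_r[i]), "p": label, "q": float(self.q[i])}
        return out


@dataclass
class StabilityResult:
    R: int
    ci_level_u: float
    ci_level_v: float
    u_lo: np.ndarray           # (p, n_selected) lower CI bounds, connectivity
    u_hi: np.ndarray
    v_lo: np.ndarray           # (q, n_selected), clinical
    v_hi: np.ndarray
    u_significant: np.ndarray  # CI excludes zero
    v_significant: np.ndarray
    u_mean: np.ndarray         # mean aligned loading over resamples
    v_mean: np.ndarray
    selected: list[int]
    seed: int
    draw_seeds: list[int] = field(default_factory=list)


def _abs_corr_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """|corr| and sign matrices between columns of A (reference) and B (candidate)."""
    out = np.zeros((A.shape[1], B.shape[1]))
    sign = np.zeros_like(out)
    for a in range(A.shape[1]):
        for b in range(B.shape[1]):
            x, y = A[:, a], B[:, b]
            if x.std() == 0 or y.std() == 0:
                c = 0.0
            else:
                c = float(np.corrcoef(x, y)[0, 1])
            out[a, b] = abs(c)
            sign[a, b] = 1.0 if c >= 0 else -1.0
    return out, sign


def match_variates(
    reference_v: np.ndarray,
    candidate_v: np.ndarray,
    method: str = "greedy",
) -> VariateMatch:
    """One-to-one matching of candidate variates to reference variates.

    Matches on the |Pearson correlation| between clinical loading vectors.
    ``greedy`` repeatedly takes the globally best remaining pair (the
    field-standard practice for small K); ``optimal`` solves the assignment
    problem maximizing the total |correlation|.  The matched sign is the sign
    of the matched correlation.  Deterministic.
    """
    R = np.asarray(reference_v, dtype=float)
    C = np.asarray(candidate_v, dtype=float)
    if R.ndim == 1:
        R = R[:, None]
    if C.ndim == 1:
        C = C[:, None]
    if R.shape[0] != C.shape[0]:
        raise ValueError(
            f"item dimension mismatch: reference {R.shape[0]} vs candidate {C.shape[0]}"
        )
    if C.shape[1] < R.shape[1]:
        raise ValueError("fewer candidate variates than reference variates")
    corr, sign = _abs_corr_matrix(R, C)
    n_ref = R.shape[1]
    assignment = np.full(n_ref, -1, dtype=int)
    if method == "optimal":
        rows, cols = optimize.linear_sum_assignment(-corr)
        assignment[rows] = cols
    elif method == "greedy":
        work = corr.copy()
        for _ in range(n_ref):
            a, b = np.unravel_index(np.argmax(work), work.shape)
            assignment[a] = b
            work[a, :] = -1.0
            work[:, b] = -1.0
    else:
        raise ValueError(f"unknown matching method {method!r}")
    scores = corr[np.arange(n_ref), assignment]
    signs = sign[np.arange(n_ref), assignment]
    return VariateMatch(assignment=assignment, signs=signs, match_scores=scores)


def fdr_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, monotone, capped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def empirical_p(null_r: np.ndarray, observed: float, add_one: bool = False) -> float:
    """Fraction of null correlations reaching the observed correlation.

    The default is the plain count ``#{r_i >= r} / B``; ``add_one`` applies
    the (count+1)/(B+1) correction recommended for small B.
    """
    null_r = np.asarray(null_r, dtype=float)
    B = len(null_r)
    if B < 1:
        raise ValueError("need at least one permutation")
    count = int(np.sum(null_r >= observed))
    if add_one:
        return (count + 1) / (B + 1)
    return count / B


def permutation_test(
    X,
    Y,
    params: SccaParams,
    selected: list[int] | None = None,
    B: int = 1000,
    seed: int = 0,
    reference: CanonicalModel | None = None,
    add_one: bool = False,
    aggregate_observed: bool = False,
) -> PermutationResult:
    """Permutation significance of selected canonical variates.

    Each permutation shuffles the rows of ``Y``, refits the model with
    identical penalties and ``K = max(selected) + 1`` components, matches the
    refitted variates to the reference by clinical loadings, and records the
    matched score correlations.  By default each variate's null is compared
    against that variate's own observed correlation; with
    ``aggregate_observed`` every variate's null is compared to the mean
    observed correlation over the selected variates.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    Yv = np.asarray(getattr(Y, "values", Y), dtype=float)
    model = reference if reference is not None else fit_scca(Xv, Yv, params)
    if selected is None:
        selected = list(range(model.n_components))
    if max(selected) >= model.n_components:
        raise ValueError("selected component index exceeds fitted components")
    K_fit = max(selected) + 1
    fit_params = SccaParams(
        c1_frac=params.c1_frac, c2_frac=params.c2_frac, n_components=K_fit,
        tol=params.tol, max_iter=params.max_iter,
    )
    ref_V = model.V[:, selected]
    observed = model.correlations[selected]
    rng = np.random.default_rng(seed)
    null_r = np.empty((B, len(selected)))
    n = Yv.shape[0]
    for b in range(B):
        perm = rng.permutation(n)
        null_model = fit_scca(Xv, Yv[perm], fit_params)
        match = match_variates(ref_V, null_model.V)
        null_r[b] = null_model.correlations[match.assignment]
    target = np.full(len(selected), observed.mean()) if aggregate_observed else observed
    p = np.array([empirical_p(null_r[:, i], target[i], add_one) for i in range(len(selected))])
    q = fdr_adjust(p)
    return PermutationResult(
        B=B, observed_r=observed, null_r=null_r, p=p, q=q,
        selected=list(selected), seed=seed,
    )


def _resample_indices(rng: np.random.Generator, n: int) -> np.ndarray:
    """Two-thirds without replacement, final third redrawn from those."""
    n_core = int(round(2 * n / 3))
    core = rng.choice(n, size=n_core, replace=False)
    extra = rng.choice(core, size=n - n_core, replace=True)
    return np.concatenate([core, extra])


def stability_resample(
    X,
    Y,
    params: SccaParams,
    reference: CanonicalModel,
    selected: list[int] | None = None,
    R: int = 1000,
    seed: int = 0,
    ci_level_u: float = 0.99,
    ci_level_v: float = 0.95,
) -> StabilityResult:
    """Resampling confidence intervals for individual loadings.

    Connectivity loadings (u) use the wider ``ci_level_u`` (99% by default),
    clinical loadings (v) the ``ci_level_v`` (95%); a feature is flagged
    significant for a variate when its interval excludes zero.
    """
    if R < 2:
        raise ValueError("R must be >= 2")
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    Yv = np.asarray(getattr(Y, "values", Y), dtype=float)
    n = Xv.shape[0]
    if n < 6:
        raise ValueError("need at least 6 subjects to resample thirds")
    if selected is None:
        selected = list(range(reference.n_components))
    K_fit = max(selected) + 1
    fit_params = SccaParams(
        c1_frac=params.c1_frac, c2_frac=params.c2_frac, n_components=K_fit,
        tol=params.tol, max_iter=params.max_iter,
    )
    ref_V = reference.V[:, selected]
    rng = np.random.default_rng(seed)
    draw_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=R)]
    p_dim, q_dim, K_sel = Xv.shape[1], Yv.shape[1], len(selected)
    u_draws = np.empty((R, p_dim, K_sel))
    v_draws = np.empty((R, q_dim, K_sel))
    for r, s in enumerate(draw_seeds):
        idx = _resample_indices(np.random.default_rng(s), n)
        refit = fit_scca(Xv[idx], Yv[idx], fit_params)
        match = match_variates(ref_V, refit.V)
        u_draws[r] = refit.U[:, match.assignment] * match.signs
        v_draws[r] = refit.V[:, match.assignment] * match.signs

    def _ci(draws: np.ndarray, level: float):
        alpha = (1 - level) / 2
        lo = np.quantile(draws, alpha, axis=0)
        hi = np.quantile(draws, 1 - alpha, axis=0)
        return lo, hi

    u_lo, u_hi = _ci(u_draws, ci_level_u)
    v_lo, v_hi = _ci(v_draws, ci_level_v)
    return StabilityResult(
        R=R, ci_level_u=ci_level_u, ci_level_v=ci_level_v,
        u_lo=u_lo, u_hi=u_hi, v_lo=v_lo, v_hi=v_hi,
        u_significant=(u_lo > 0) | (u_hi < 0),
        v_significant=(v_lo > 0) | (v_hi < 0),
        u_mean=u_draws.mean(axis=0), v_mean=v_draws.mean(axis=0),
        selected=list(selected), seed=seed, draw_seeds=draw_seeds,
    )
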