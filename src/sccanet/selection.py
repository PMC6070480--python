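"""Sparsity tuning and variate selection.

The two L1 sparsity fractions are tuned by grid search: each candidate cell
is scored by the mean first-variate canonical correlation over random
subsamples (by default 10 draws of two-thirds of the discovery sample,
without replacement), and the cell with the highest mean wins.  Ties prefer
the sparser cell.  Tuning belongs to the discovery role only; a replication
run reuses the frozen fractions.

The number of variates carried to inference is read off the
covariance-explained scree: components whose share lies strictly above the
mean share are selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scca import CanonicalModel, SccaParams, fit_scca

__all__ = ["TuningResult", "grid_search", "default_grid", "select_components"]


@dataclass
class TuningResult:
    surface: pd.DataFrame          # columns c1_frac, c2_frac, mean_first_r
    chosen: tuple[float, float]
    n_draws: int
    subsample_frac: float
    seed: int
    draw_seeds: list[int] = field(default_factory=list)


def default_grid(step: float = 0.1, include_zero: bool = False) -> list[tuple[float, float]]:
    """Cartesian sparsity grid in the given increments over (0, 1]."""
    if not 0 < step <= 1:
        raise ValueError("grid step must lie in (0, 1]")
    n = int(round(1.0 / step))
    if abs(n * step - 1.0) > 1e-9:
        raise ValueError(f"grid step {step} does not divide (0, 1]")
    vals = [round(k * step, 10) for k in range(0 if include_zero else 1, n + 1)]
    return [(a, b) for a in vals for b in vals]


def grid_search(
    X,
    Y,
    grid_step: float = 0.1,
    n_draws: int = 10,
    subsample_frac: float = 2 / 3,
    seed: int = 0,
    grid: list[tuple[float, float]] | None = None,
    scca_kwargs: dict | None = None,
) -> TuningResult:
    """Tune (c1_frac, c2_frac) on resampled first-variate correlations.

    For every grid cell the first canonical variate is fitted on each of
    ``n_draws`` subsamples (fraction ``subsample_frac`` of subjects, drawn
    without replacement) and the correlations averaged.  The same subsamples
    are used for every cell, so cells differ only in the penalty.
    Deterministic for a fixed seed.
    """
    Xv = np.asarray(getattr(X, "values", X), dtype=float)
    Yv = np.asarray(getattr(Y, "values", Y), dtype=float)
    n = Xv.shape[0]
    n_sub = int(round(subsample_frac * n))
    if n_sub < 10:
        raise ValueError(f"subsample of {n_sub} subjects is too small (need >= 10)")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    cells = grid if grid is not None else default_grid(grid_step)
    rng = np.random.default_rng(seed)
    draw_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_draws)]
    subsamples = [
        np.random.default_rng(s).choice(n, size=n_sub, replace=False) for s in draw_seeds
    ]
    kwargs = scca_kwargs or {}
    records = []
    for c1, c2 in cells:
        params = SccaParams(c1_frac=c1, c2_frac=c2, n_components=1, **kwargs)
        rs = [
            fit_scca(Xv[idx], Yv[idx], params).variates[0].r for idx in subsamples
        ]
        records.append((c1, c2, float(np.mean(rs))))
    surface = pd.DataFrame(records, columns=["c1_frac", "c2_frac", "mean_first_r"])
    # argmax with parsimony tie-break: smaller c1_frac, then smaller c2_frac
    best = surface.sort_values(
        ["mean_first_r", "c1_frac", "c2_frac"], ascending=[False, True, True]
    ).iloc[0]
    return TuningResult(
        surface=surface,
        chosen=(float(best["c1_frac"]), float(best["c2_frac"])),
        n_draws=n_draws,
        subsample_frac=subsample_frac,
        seed=seed,
        draw_seeds=draw_seeds,
    )


def select_components(model: CanonicalModel) -> list[int]:
    """Components whose covariance-explained share exceeds the mean share.

    Implements the scree dashed-line rule: with shares summing to 1 over K
    components, the mean share is 1/K and components strictly above it are
    kept.  If no share exceeds the mean (all equal), the first component is
    returned.  Indices are 0-based and ordered by extraction.
    """
    fracs = np.array([cv.cov_frac for cv in model.variates])
    if fracs.size == 0:
        raise ValueError("model has no components")
    selected = [k for k, f in enumerate(fracs) if f > fracs.mean()]
    return selected if selected else [0]
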