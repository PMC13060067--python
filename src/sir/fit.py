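"""Shape-constrained surface fits: the monotone cone M and its additive subclass A.

``fit_isotonic_2d`` computes the weighted least-squares projection of the
transformed grid onto the set M of surfaces non-increasing in each drug's
dose.  ``fit_monotone_additive`` projects onto the nested class
A = {alpha + u_i + v_j : u, v non-increasing, u_1 = v_1 = 0}, the
"no interaction" null.  Because A is a subset of M, the additive objective
is always at least the isotonic objective.

Missing wells enter both problems as zero-weight free variables; their
fitted values are resolved deterministically to the midpoint of the
tightest monotone envelope implied by the observed fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._solvers import (
    SolverError,
    additive_monotone_lsq,
    grid_constraint_pairs,
    isotonic_project,
)
from .grid import DoseGrid, TransformSpec, TransformedGrid, transform_responses

__all__ = [
    "MonotoneFit",
    "AdditiveFit",
    "fit_isotonic_2d",
    "fit_monotone_additive",
    "effective_df",
    "predict_missing",
    "SolverError",
]

DEFAULT_TOL = 1e-8
DEFAULT_LEVEL_TOL = 1e-6


@dataclass
class MonotoneFit:
    """2D isotonic fit: surface non-increasing along rows and columns."""

    theta_iso: np.ndarray
    objective: float
    solver_status: str
    tol: float = DEFAULT_TOL


@dataclass
class AdditiveFit:
    """Monotone-additive fit ``theta[i,j] = alpha + u[i] + v[j]``.

    ``u`` and ``v`` are non-increasing with ``u[0] = v[0] = 0`` so the
    intercept is identified.  ``df_null`` is the effective number of
    parameters, counted as distinct fitted levels (see
    :func:`effective_df`).
    """

    alpha: float
    u: np.ndarray
    v: np.ndarray
    theta_add: np.ndarray
    objective: float
    df_null: int
    solver_status: str = "optimal"
    tol: float = DEFAULT_TOL


def _fill_free_cells(theta: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, bool]:
    """Resolve unconstrained (missing) cells to the midpoint of their
    monotone envelope via two sweeps.

    The upper envelope sweeps from the low-dose corner (each cell bounded
    above by its dose-predecessors), the lower envelope from the high-dose
    corner.  Returns the filled surface and a flag indicating any
    one-sided (unbounded) envelope.
    """
    I, J = theta.shape
    ub = np.full((I, J), np.inf)
    lb = np.full((I, J), -np.inf)
    out = theta.copy()
    one_sided = False
    for i in range(I):
        for j in range(J):
            cands = []
            if i > 0:
                cands.append(out[i - 1, j] if fixed[i - 1, j] else ub[i - 1, j])
            if j > 0:
                cands.append(out[i, j - 1] if fixed[i, j - 1] else ub[i, j - 1])
            if cands:
                ub[i, j] = min(cands)
    for i in range(I - 1, -1, -1):
        for j in range(J - 1, -1, -1):
            cands = []
            if i + 1 < I:
                cands.append(out[i + 1, j] if fixed[i + 1, j] else lb[i + 1, j])
            if j + 1 < J:
                cands.append(out[i, j + 1] if fixed[i, j + 1] else lb[i, j + 1])
            if cands:
                lb[i, j] = max(cands)
    for i in range(I):
        for j in range(J):
            if fixed[i, j]:
                continue
            lo, hi = lb[i, j], ub[i, j]
            if np.isfinite(lo) and np.isfinite(hi):
                out[i, j] = 0.5 * (lo + hi)
            elif np.isfinite(hi):
                out[i, j] = hi
                one_sided = True
            elif np.isfinite(lo):
                out[i, j] = lo
                one_sided = True
            else:  # isolated cell with no observed neighbour in either cone
                out[i, j] = np.nanmean(theta[fixed]) if fixed.any() else 0.0
                one_sided = True
    return out, one_sided


def fit_isotonic_2d(tg: TransformedGrid, tol: float = DEFAULT_TOL) -> MonotoneFit:
    """Weighted least-squares projection onto the monotone cone M.

    Minimises ``sum_ij w_ij (Z_ij - theta_ij)^2`` subject to
    ``theta[i+1, j] <= theta[i, j]`` and ``theta[i, j+1] <= theta[i, j]``.
    Solved exactly through the dual nonnegative least-squares problem.
    """
    Z, W = tg.Z, tg.W
    obs = W > 0
    if not obs.any():
        raise ValueError("no positively weighted cells")
    theta = np.full(Z.shape, np.nan)
    if obs.all():
        pairs = grid_constraint_pairs(Z.shape)
        flat, status = isotonic_project(Z.ravel(), W.ravel(), pairs, tol=tol)
        theta = flat.reshape(Z.shape)
    else:
        pairs = grid_constraint_pairs(Z.shape, obs_mask=obs)
        # solve over observed cells only; the covering pairs encode the
        # induced order, then free cells are filled by the envelope pass
        full = np.where(obs, Z, 0.0)
        wfull = np.where(obs, W, 0.0)
        flat_idx = np.flatnonzero(obs.ravel())
        remap = -np.ones(Z.size, dtype=int)
        remap[flat_idx] = np.arange(flat_idx.size)
        sub_pairs = [(remap[a], remap[b]) for a, b in pairs]
        sub, status = isotonic_project(
            full.ravel()[flat_idx], wfull.ravel()[flat_idx], sub_pairs, tol=tol
        )
        theta.ravel()[flat_idx] = sub
        theta, _ = _fill_free_cells(theta, obs)
    objective = float(np.sum(W[obs] * (Z[obs] - theta[obs]) ** 2))
    return MonotoneFit(theta_iso=theta, objective=objective, solver_status=status, tol=tol)


def fit_monotone_additive(
    tg: TransformedGrid,
    tol: float = DEFAULT_TOL,
    level_tol: float = DEFAULT_LEVEL_TOL,
) -> AdditiveFit:
    """Weighted least-squares projection onto the monotone-additive class A."""
    Z, W = tg.Z, tg.W
    I, J = Z.shape
    obs = W > 0
    if not obs.any():
        raise ValueError("no positively weighted cells")
    if tg.n_eff < I + J - 1:
        warnings.warn(
            f"only {tg.n_eff} observed cells for {I + J - 1} additive parameters; "
            "fit may be weakly identified",
            stacklevel=2,
        )
    Zm = np.where(obs, Z, 0.0)
    alpha, u, v, status = additive_monotone_lsq(Zm, W, tol=tol)
    theta_add = alpha + u[:, None] + v[None, :]
    objective = float(np.sum(W[obs] * (Z[obs] - theta_add[obs]) ** 2))
    fit = AdditiveFit(
        alpha=alpha, u=u, v=v, theta_add=theta_add,
        objective=objective, df_null=1, solver_status=status, tol=tol,
    )
    fit.df_null = effective_df(fit, level_tol=level_tol)
    return fit


def effective_df(fit: AdditiveFit, level_tol: float = DEFAULT_LEVEL_TOL) -> int:
    """Effective degrees of freedom of the monotone-additive fit.

    Monotone regression pools dose levels that violate monotonicity into
    tied groups, so the parameter count is data dependent.  We count the
    distinct fitted levels in each marginal effect (values within
    ``level_tol`` are merged) and return
    ``(#levels in u) + (#levels in v) - 1``: the shared intercept is the
    one level the two marginals have in common.  Always at least 1.
    """

    def n_levels(x: np.ndarray) -> int:
        x = np.sort(np.asarray(x, dtype=float))
        if x.size == 0:
            return 0
        return 1 + int(np.count_nonzero(np.diff(x) > level_tol))

    return max(1, n_levels(fit.u) + n_levels(fit.v) - 1)


def predict_missing(
    grid: DoseGrid,
    spec: TransformSpec | None = None,
    tol: float = DEFAULT_TOL,
    **transform_kwargs,
) -> np.ndarray:
    """Predict viability at unobserved wells from the monotone surface.

    Fits the 2D isotonic surface on the observed wells, resolves each
    missing well to the midpoint of its monotone envelope (the interval
    pinned by fitted values at lower and higher doses), and back-transforms.
    Returns the full I x J predicted-viability surface; index it with
    ``grid.missing`` for held-out wells.  Warns when a missing well is
    bounded on one side only (fully missing leading row/column).
    """
    spec = spec or TransformSpec()
    tg = transform_responses(grid, spec=spec, **transform_kwargs)
    obs = tg.W > 0
    Zobs = np.where(obs, tg.Z, 0.0)
    if obs.all():
        fitted = fit_isotonic_2d(tg, tol=tol).theta_iso
        return spec.inverse(fitted)
    pairs = grid_constraint_pairs(tg.shape, obs_mask=obs)
    flat_idx = np.flatnonzero(obs.ravel())
    remap = -np.ones(tg.Z.size, dtype=int)
    remap[flat_idx] = np.arange(flat_idx.size)
    sub_pairs = [(remap[a], remap[b]) for a, b in pairs]
    sub, _ = isotonic_project(
        Zobs.ravel()[flat_idx], tg.W.ravel()[flat_idx], sub_pairs, tol=tol
    )
    theta = np.full(tg.shape, np.nan)
    theta.ravel()[flat_idx] = sub
    theta, one_sided = _fill_free_cells(theta, obs)
    if one_sided:
        warnings.warn(
            "some missing wells had a one-sided monotone envelope; "
            "predictions there use the single available bound",
            stacklevel=2,
        )
    return spec.inverse(theta)
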