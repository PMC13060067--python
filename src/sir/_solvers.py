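"""Exact quadratic-program solvers for the monotone cone projections.

The weighted least-squares projection onto a polyhedral cone
``{theta : A theta <= 0}`` has a dual that is a nonnegative least-squares
problem: with ``theta = z - W^{-1} A' lam`` the dual is

    min_{lam >= 0} || W^{-1/2} A' lam - W^{1/2} z ||^2,

solved exactly by the active-set NNLS algorithm.  The monotone-additive
fit is reparametrised with nonnegative dose-step increments and solved by
bounded-variable least squares (BVLS).  Both are finite, exact algorithms;
no iterative tolerance tuning is involved.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import lsq_linear, nnls

__all__ = [
    "SolverError",
    "grid_constraint_pairs",
    "isotonic_project",
    "additive_monotone_lsq",
]


class SolverError(RuntimeError):
    """A QP solve failed to reach its stated tolerance."""


def grid_constraint_pairs(shape: tuple, obs_mask: np.ndarray | None = None):
    """Monotone-order constraints for an I x J grid, as index pairs.

    Each pair ``(a, b)`` encodes ``theta_flat[b] <= theta_flat[a]``
    (viability is non-increasing in each drug's dose).  For a fully
    observed grid these are the adjacent row/column pairs.  When
    ``obs_mask`` excludes cells, the pairs are the covering relations of
    the componentwise partial order restricted to observed cells: cell
    ``b`` dominates ``a`` in both coordinates and no observed cell lies
    strictly between.  That restriction is exact because unobserved cells
    are unconstrained free variables that can always interpolate along a
    monotone staircase path.
    """
    I, J = shape
    idx = np.arange(I * J).reshape(I, J)
    if obs_mask is None or np.all(obs_mask):
        pairs = []
        for i in range(I):
            for j in range(J):
                if i + 1 < I:
                    pairs.append((idx[i, j], idx[i + 1, j]))
                if j + 1 < J:
                    pairs.append((idx[i, j], idx[i, j + 1]))
        return pairs
    coords = np.argwhere(obs_mask)
    pairs = []
    for ai, aj in coords:
        for bi, bj in coords:
            if (bi, bj) == (ai, aj) or bi < ai or bj < aj:
                continue
            # covering pair iff no observed cell strictly between in the order
            between = (
                (coords[:, 0] >= ai)
                & (coords[:, 0] <= bi)
                & (coords[:, 1] >= aj)
                & (coords[:, 1] <= bj)
            )
            if between.sum() > 2:
                continue
            pairs.append((idx[ai, aj], idx[bi, bj]))
    return pairs


def _constraint_matrix(pairs, n: int) -> np.ndarray:
    A = np.zeros((len(pairs), n))
    for k, (a, b) in enumerate(pairs):
        A[k, b] = 1.0
        A[k, a] = -1.0
    return A


def isotonic_project(
    z: np.ndarray,
    w: np.ndarray,
    pairs,
    tol: float = 1e-8,
) -> tuple[np.ndarray, str]:
    """Weighted projection of flat vector ``z`` onto ``{theta : theta[b] <= theta[a]}``.

    All entries of ``w`` must be positive (zero-weight cells are excluded
    upstream and reattached by an envelope pass).  Returns the projected
    vector and a solver status string.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("isotonic_project requires strictly positive weights")
    if not pairs:
        return z.copy(), "optimal"
    A = _constraint_matrix(pairs, z.size)
    sw = np.sqrt(w)
    B = (A / sw).T  # n x m
    b = sw * z
    try:
        lam, _ = nnls(B, b, maxiter=max(30 * A.shape[0], 3000))
    except RuntimeError as exc:  # pragma: no cover - nnls rarely fails
        raise SolverError(f"NNLS dual did not converge: {exc}") from exc
    theta = z - (A.T @ lam) / w
    viol = float(np.max(A @ theta, initial=0.0))
    scale = max(1.0, float(np.max(np.abs(z))))
    if viol > max(tol, 1e-7) * scale:
        raise SolverError(f"isotonic projection infeasible: max violation {viol:.3e}")
    # snap tiny constraint violations introduced by round-off
    status = "optimal"
    return theta, status


def additive_monotone_lsq(
    Z: np.ndarray,
    W: np.ndarray,
    tol: float = 1e-8,
) -> tuple[float, np.ndarray, np.ndarray, str]:
    """Weighted LS fit of ``theta[i,j] = alpha + u[i] + v[j]`` with
    ``u, v`` non-increasing and ``u[0] = v[0] = 0``.

    Reparametrised as ``u[i] = -sum(a[:i])`` with increments ``a >= 0``
    (likewise ``v``), which turns the monotonicity constraints into simple
    bounds solved exactly by BVLS.  Returns ``(alpha, u, v, status)``.
    """
    Z = np.asarray(Z, dtype=float)
    W = np.asarray(W, dtype=float)
    I, J = Z.shape
    obs = W > 0
    rows, cols = np.nonzero(obs)
    z = Z[obs]
    sw = np.sqrt(W[obs])
    p = 1 + (I - 1) + (J - 1)
    X = np.zeros((z.size, p))
    X[:, 0] = 1.0
    for k in range(I - 1):
        X[:, 1 + k] = -(rows > k).astype(float)
    for k in range(J - 1):
        X[:, I + k] = -(cols > k).astype(float)
    res = lsq_linear(
        X * sw[:, None],
        z * sw,
        bounds=(np.r_[-np.inf, np.zeros(p - 1)], np.full(p, np.inf)),
        method="bvls",
        tol=tol,
    )
    if res.status < 0 or not np.all(res.x[1:] >= -1e-12):
        raise SolverError(f"BVLS additive fit failed: status {res.status}")
    alpha = float(res.x[0])
    a = np.maximum(res.x[1:I], 0.0)
    b = np.maximum(res.x[I:], 0.0)
    u = -np.concatenate([[0.0], np.cumsum(a)])
    v = -np.concatenate([[0.0], np.cumsum(b)])
    return alpha, u, v, "optimal"
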