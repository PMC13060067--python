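"""Shared fixtures and independent oracles for the test suite."""

from itertools import combinations

import numpy as np
import pytest

from sir import DoseGrid, TransformSpec
from sir._solvers import grid_constraint_pairs


def isotonic_bruteforce(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Exhaustive oracle for the weighted 2D isotonic projection.

    Enumerates every subset of the adjacency constraints as a candidate
    active set, solves the equality-constrained weighted least-squares
    problem for that subset, keeps candidates that are feasible for the
    full constraint set, and returns the feasible candidate with the
    smallest objective.  The projection's true active set is among the
    subsets and its equality-constrained solution is the projection
    itself, so the minimum over feasible candidates is exact.  Only
    usable for tiny grids (cost 2^m).
    """
    z = Z.ravel().astype(float)
    w = W.ravel().astype(float)
    pairs = grid_constraint_pairs(Z.shape)
    m, n = len(pairs), z.size
    A = np.zeros((m, n))
    for k, (a, b) in enumerate(pairs):
        A[k, b] = 1.0
        A[k, a] = -1.0
    best, best_obj = None, np.inf
    Wd = np.diag(w)
    for r in range(m + 1):
        for subset in combinations(range(m), r):
            As = A[list(subset)]
            # KKT system for min ||z-theta||_W^2 s.t. As theta = 0
            K = np.block([[Wd, As.T], [As, np.zeros((r, r))]])
            rhs = np.concatenate([w * z, np.zeros(r)])
            sol, *_ = np.linalg.lstsq(K, rhs, rcond=None)
            theta = sol[:n]
            if np.max(As @ theta, initial=0) > 1e-9:  # lstsq failed the equalities
                continue
            if np.max(A @ theta) > 1e-9:  # infeasible for the full cone
                continue
            obj = float(np.sum(w * (z - theta) ** 2))
            if obj < best_obj - 1e-15:
                best_obj, best = obj, theta
    return best.reshape(Z.shape)


@pytest.fixture
def rng():
    return np.random.default_rng(20260918)


@pytest.fixture
def spec():
    return TransformSpec()


def make_grid(Y, conc_row=None, conc_col=None, **kw) -> DoseGrid:
    Y = np.asarray(Y, dtype=float)
    I, J = Y.shape
    return DoseGrid(
        drug_row_name=kw.pop("drug_row_name", "drugA"),
        drug_col_name=kw.pop("drug_col_name", "drugB"),
        conc_row=conc_row if conc_row is not None else np.arange(1.0, I + 1),
        conc_col=conc_col if conc_col is not None else np.arange(1.0, J + 1),
        Y=Y,
        **kw,
    )


@pytest.fixture
def additive_grid():
    """Noiseless 4x4 grid whose logit surface is exactly additive monotone."""
    from scipy.special import expit

    alpha = 1.5
    u = np.array([0.0, -0.4, -0.8, -1.2])
    v = np.array([0.0, -0.3, -0.6, -0.9])
    Y = expit(alpha + u[:, None] + v[None, :])
    return make_grid(Y)
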