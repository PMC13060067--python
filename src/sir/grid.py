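"""Dose-response grids, response transforms, and replicate-based weighting.

A drug-combination experiment is an I x J grid of mean cell viabilities
``Y[i, j]`` in [0, 1], measured at strictly increasing concentrations of a
row drug and a column drug.  All downstream model fitting happens on an
unconstrained scale (by default the logit), with per-cell inverse-variance
weights computed from within-cell replicates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "DoseGrid",
    "TransformSpec",
    "TransformedGrid",
    "DegenerateGridError",
    "transform_responses",
    "compute_weights",
    "inverse_transform",
]

DEFAULT_EPS = 1e-6
DEFAULT_TAU = 1e-6
DEFAULT_WINSOR_PCT = 99.0


class DegenerateGridError(ValueError):
    """Raised when a grid has no usable observations."""


@dataclass
class DoseGrid:
    """Observed viability matrix for one drug pair.

    Parameters
    ----------
    drug_row_name, drug_col_name
        Labels for the two agents.
    conc_row, conc_col
        Strictly increasing concentration vectors (arbitrary units) of
        length I >= 2 and J >= 2.
    Y
        I x J matrix of mean viability in [0, 1]; ``nan`` marks a missing
        well.
    m
        I x J integer matrix of replicate counts; 0 exactly where Y is
        missing.
    s2
        I x J matrix of within-cell sample variances (unbiased, ddof=1);
        ``nan`` where fewer than two replicates are available.
    """

    drug_row_name: str
    drug_col_name: str
    conc_row: np.ndarray
    conc_col: np.ndarray
    Y: np.ndarray
    m: np.ndarray = None
    s2: np.ndarray = None
    block_id: str = ""

    def __post_init__(self) -> None:
        self.conc_row = np.asarray(self.conc_row, dtype=float)
        self.conc_col = np.asarray(self.conc_col, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        I, J = self.Y.shape
        if self.m is None:
            self.m = np.where(np.isfinite(self.Y), 1, 0)
        if self.s2 is None:
            self.s2 = np.full((I, J), np.nan)
        self.m = np.asarray(self.m, dtype=int)
        self.s2 = np.asarray(self.s2, dtype=float)
        if I < 2 or J < 2:
            raise ValueError(f"grid must be at least 2x2, got {I}x{J}")
        if self.conc_row.shape != (I,) or self.conc_col.shape != (J,):
            raise ValueError("concentration vectors do not match Y shape")
        for name, c in (("conc_row", self.conc_row), ("conc_col", self.conc_col)):
            if not np.all(np.diff(c) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        obs = np.isfinite(self.Y)
        if np.any((self.Y[obs] < 0) | (self.Y[obs] > 1)):
            raise ValueError("viability values must lie in [0, 1]")
        if np.any((self.m == 0) != ~obs):
            raise ValueError("m must be 0 exactly where Y is missing")

    @property
    def shape(self) -> tuple:
        return self.Y.shape

    @property
    def missing(self) -> np.ndarray:
        """Boolean mask, True at missing wells."""
        return ~np.isfinite(self.Y)


_FORWARD = {
    "logit": lambda y: logit(y),
    "identity": lambda y: y,
    "asinh": np.arcsinh,
    "log": np.log,
}
_INVERSE = {
    "logit": lambda z: expit(z),
    "identity": lambda z: z,
    "asinh": np.sinh,
    "log": np.exp,
}


@dataclass(frozen=True)
class TransformSpec:
    """Response transform: name in {logit, identity, asinh, log} plus the
    clamp bound ``eps`` applied to viability before the forward map.

    The logit is the default: it maps bounded viability to the real line,
    stabilises variance near 0 and 1, and defines additivity in log-odds
    of cell survival.
    """

    name: str = "logit"
    eps: float = DEFAULT_EPS

    def __post_init__(self) -> None:
        if self.name not in _FORWARD:
            raise ValueError(
                f"unknown transform {self.name!r}; expected one of {sorted(_FORWARD)}"
            )

    def forward(self, y):
        y = np.clip(np.asarray(y, dtype=float), self.eps, 1.0 - self.eps)
        return _FORWARD[self.name](y)

    def inverse(self, z):
        return _INVERSE[self.name](np.asarray(z, dtype=float))


@dataclass
class TransformedGrid:
    """Transformed responses Z with per-cell weights W.

    ``Z`` is finite wherever ``W > 0``; missing wells carry W = 0 and a
    nan Z.  ``n_eff`` counts the positively weighted cells and is the `n`
    of the degrees-of-freedom correction used in the bootstrap.
    """

    Z: np.ndarray
    W: np.ndarray
    eps: float = DEFAULT_EPS
    tau: float = DEFAULT_TAU
    spec: TransformSpec = field(default_factory=TransformSpec)
    n_eff: int = dataclasses.field(default=0)

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.Z.shape != self.W.shape:
            raise ValueError("Z and W shapes differ")
        if np.any(self.W < 0):
            raise ValueError("weights must be nonnegative")
        if np.any(~np.isfinite(self.Z) & (self.W > 0)):
            raise ValueError("Z must be finite wherever W > 0")
        self.n_eff = int(np.count_nonzero(self.W > 0))

    @classmethod
    def from_arrays(cls, Z, W=None, spec: TransformSpec | None = None) -> "TransformedGrid":
        """Build directly from a response matrix (unit weights by default)."""
        Z = np.asarray(Z, dtype=float)
        if W is None:
            W = np.where(np.isfinite(Z), 1.0, 0.0)
        return cls(Z=Z, W=W, spec=spec or TransformSpec())

    @property
    def shape(self) -> tuple:
        return self.Z.shape


def compute_weights(
    grid: DoseGrid,
    tau: float = DEFAULT_TAU,
    winsor_pct: float = DEFAULT_WINSOR_PCT,
) -> np.ndarray:
    """Inverse-variance weights ``w = m / max(s2, tau)`` from replicates.

    When no cell in the matrix carries replicate variance information the
    weights default to the uniform value ``1/tau``.  Cells with a single
    replicate in a matrix that has replicates elsewhere also get ``1/tau``
    (they carry no variance information of their own).  Positive weights
    are Winsorized (capped) at the ``winsor_pct`` percentile to limit the
    influence of near-zero-variance cells.  Missing wells get weight 0.
    """
    if not tau > 0:
        raise ValueError("tau must be positive")
    if not (50.0 < winsor_pct <= 100.0):
        raise ValueError("winsor_pct must be in (50, 100]")
    obs = ~grid.missing
    W = np.zeros(grid.shape)
    has_var = obs & (grid.m >= 2) & np.isfinite(grid.s2)
    if np.any(has_var):
        W[has_var] = grid.m[has_var] / np.maximum(grid.s2[has_var], tau)
        W[obs & ~has_var] = 1.0 / tau
    else:
        W[obs] = 1.0 / tau
    pos = W > 0
    if np.any(pos) and winsor_pct < 100.0:
        cap = np.percentile(W[pos], winsor_pct)
        W[pos] = np.minimum(W[pos], cap)
    return W


def transform_responses(
    grid: DoseGrid,
    spec: TransformSpec | None = None,
    tau: float = DEFAULT_TAU,
    winsor_pct: float = DEFAULT_WINSOR_PCT,
) -> TransformedGrid:
    """Clamp viabilities to [eps, 1-eps], apply the forward transform, and
    attach replicate-based weights.

    Raises
    ------
    DegenerateGridError
        If every well in the grid is missing.
    """
    spec = spec or TransformSpec()
    if np.all(grid.missing):
        raise DegenerateGridError("all wells missing; nothing to transform")
    Z = np.full(grid.shape, np.nan)
    obs = ~grid.missing
    Z[obs] = spec.forward(grid.Y[obs])
    W = compute_weights(grid, tau=tau, winsor_pct=winsor_pct)
    return TransformedGrid(Z=Z, W=W, eps=spec.eps, tau=tau, spec=spec)


def inverse_transform(values: np.ndarray, spec: TransformSpec | None = None) -> np.ndarray:
    """Map transformed-scale values back to the viability scale."""
    spec = spec or TransformSpec()
    return spec.inverse(values)
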