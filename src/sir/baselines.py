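"""Pointwise Bliss and HSA baseline surfaces plus concordance/benchmark statistics.

Both baselines predict the combination well from the monotherapy rows and
columns of the same grid and score the excess kill relative to that
prediction.  Excess is reported on the viability scale with positive =
synergy, matching the orientation of the SIR effect size S_SIR (note
this is the opposite sign of the inhibition-scale convention used by
some screening software).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fit import fit_isotonic_2d, fit_monotone_additive, predict_missing
from .grid import DoseGrid, TransformSpec, transform_responses
from .inference import effect_size_viability

__all__ = [
    "BaselineSurfaces",
    "bliss_surface",
    "hsa_surface",
    "baseline_surfaces",
    "replicate_concordance",
    "score_disagreement",
    "holdout_benchmark",
    "HoldoutResult",
]


@dataclass
class BaselineSurfaces:
    """Pointwise excess-over-reference surfaces and their matrix means."""

    bliss_excess: np.ndarray
    hsa_excess: np.ndarray
    summary_bliss: float
    summary_hsa: float


def _monotherapy(grid: DoseGrid) -> tuple[np.ndarray, np.ndarray]:
    """Monotherapy responses: first column for the row drug, first row for
    the column drug.  When the design has explicit zero-dose anchors these
    are them; otherwise the lowest dose approximates monotherapy (common
    screening convention)."""
    yA = grid.Y[:, 0]
    yB = grid.Y[0, :]
    if np.any(~np.isfinite(yA)) or np.any(~np.isfinite(yB)):
        raise ValueError("missing monotherapy anchor wells in first row/column")
    return yA, yB


def bliss_surface(grid: DoseGrid) -> np.ndarray:
    """Bliss independence excess: ``E_ij - Y_ij`` with ``E_ij = yA_i * yB_j``.

    Bliss assumes the two drugs act on survival probabilities
    independently, so expected combination viability is the product of the
    monotherapy viabilities.  Positive excess = more kill than expected =
    synergy.
    """
    yA, yB = _monotherapy(grid)
    return np.outer(yA, yB) - grid.Y


def hsa_surface(grid: DoseGrid) -> np.ndarray:
    """Highest-single-agent excess: ``min(yA_i, yB_j) - Y_ij``.

    The combination is compared against the more active of the two single
    agents at each dose pair.
    """
    yA, yB = _monotherapy(grid)
    return np.minimum.outer(yA, yB) - grid.Y


def baseline_surfaces(grid: DoseGrid) -> BaselineSurfaces:
    bliss = bliss_surface(grid)
    hsa = hsa_surface(grid)
    return BaselineSurfaces(
        bliss_excess=bliss,
        hsa_excess=hsa,
        summary_bliss=float(np.nanmean(bliss)),
        summary_hsa=float(np.nanmean(hsa)),
    )


def replicate_concordance(surfA: np.ndarray, surfB: np.ndarray) -> float:
    """Pearson correlation between two interaction/synergy surfaces over
    their jointly non-missing cells; nan (with a warning) when undefined."""
    a = np.asarray(surfA, dtype=float).ravel()
    b = np.asarray(surfB, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("surfaces have different shapes")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need at least 3 jointly finite cells")
    if np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        warnings.warn("constant surface: correlation undefined", stacklevel=2)
        return np.nan
    return float(stats.pearsonr(a[ok], b[ok]).statistic)


def score_disagreement(
    scoresA, scoresB, top_frac: float = 0.05
) -> tuple[float, float, float]:
    """Concordance of two matrix-level score vectors across a screen.

    Returns ``(pearson_r, sign_disagreement, top_k_jaccard)``: the
    correlation, the fraction of matrices where exactly one score is
    positive, and the Jaccard overlap of the top ``ceil(top_frac * n)``
    entries of each ranking (larger score = more synergistic).
    """
    a = np.asarray(scoresA, dtype=float)
    b = np.asarray(scoresB, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("score vectors must be 1D with equal length")
    r = float(stats.pearsonr(a, b).statistic) if np.ptp(a) and np.ptp(b) else np.nan
    sign_dis = float(np.mean((a > 0) != (b > 0)))
    k = int(np.ceil(top_frac * a.size))
    top_a = set(np.argsort(-a, kind="stable")[:k])
    top_b = set(np.argsort(-b, kind="stable")[:k])
    jac = len(top_a & top_b) / len(top_a | top_b) if (top_a | top_b) else np.nan
    return r, sign_dis, jac


@dataclass
class HoldoutResult:
    rmse_viability: float
    rmse_s_sir: float
    n_held_out: int
    seed: object


def _s_sir_surface(grid: DoseGrid, spec: TransformSpec) -> np.ndarray:
    tg = transform_responses(grid, spec=spec)
    iso = fit_isotonic_2d(tg)
    add = fit_monotone_additive(tg)
    return effect_size_viability(iso, add, spec)


def holdout_benchmark(
    grid: DoseGrid,
    frac: float = 0.2,
    seed=0,
    spec: TransformSpec | None = None,
) -> HoldoutResult:
    """Mask a fraction of interior wells, predict them back, and report RMSE.

    Interior wells exclude the first/last row and column so every held-out
    well retains a two-sided monotone envelope.  Reports RMSE of predicted
    vs observed viability at the held-out wells, and RMSE between the
    cellwise S_SIR surfaces computed on the full and on the masked data.
    ``frac = 0`` returns an empty result (nan RMSEs).
    """
    spec = spec or TransformSpec()
    I, J = grid.shape
    interior = np.zeros((I, J), dtype=bool)
    interior[1 : I - 1, 1 : J - 1] = True
    interior &= ~grid.missing
    n_int = int(interior.sum())
    if n_int < 1:
        raise ValueError("grid has no observed interior wells")
    n_hold = int(round(frac * n_int))
    if n_hold == 0:
        return HoldoutResult(np.nan, np.nan, 0, seed)
    rng = np.random.default_rng(seed)
    cells = np.argwhere(interior)
    pick = cells[rng.choice(n_int, size=n_hold, replace=False)]
    Y_masked = grid.Y.copy()
    m_masked = grid.m.copy()
    s2_masked = grid.s2.copy()
    Y_masked[pick[:, 0], pick[:, 1]] = np.nan
    m_masked[pick[:, 0], pick[:, 1]] = 0
    s2_masked[pick[:, 0], pick[:, 1]] = np.nan
    masked = DoseGrid(
        drug_row_name=grid.drug_row_name,
        drug_col_name=grid.drug_col_name,
        conc_row=grid.conc_row,
        conc_col=grid.conc_col,
        Y=Y_masked,
        m=m_masked,
        s2=s2_masked,
        block_id=grid.block_id,
    )
    pred = predict_missing(masked, spec=spec)
    err = pred[pick[:, 0], pick[:, 1]] - grid.Y[pick[:, 0], pick[:, 1]]
    rmse_v = float(np.sqrt(np.mean(err**2)))
    s_full = _s_sir_surface(grid, spec)
    s_mask = _s_sir_surface(masked, spec)
    ok = np.isfinite(s_full) & np.isfinite(s_mask)
    rmse_s = float(np.sqrt(np.mean((s_full[ok] - s_mask[ok]) ** 2)))
    return HoldoutResult(
        rmse_viability=rmse_v, rmse_s_sir=rmse_s, n_held_out=n_hold, seed=seed
    )
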