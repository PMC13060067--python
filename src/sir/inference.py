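"""Interaction surface, interaction energy, and the df-corrected wild bootstrap test.

The interaction surface ``delta = theta_iso - theta_add`` measures, on the
transformed (logit) scale, how far the best monotone fit departs from the
best monotone-additive fit.  Synergy is ``delta < 0`` (lower viability
than the additive expectation).  The global statistic is the normalized
interaction energy ``T = sum(w * delta^2) / sum(w)``; its null
distribution is approximated by a Rademacher wild bootstrap whose
residuals are inflated by ``sqrt(n_eff / (n_eff - df_null))`` to undo the
variance shrinkage caused by fitting the null to the same data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests

from .fit import (
    AdditiveFit,
    MonotoneFit,
    SolverError,
    fit_isotonic_2d,
    fit_monotone_additive,
)
from .grid import TransformSpec, TransformedGrid, inverse_transform

__all__ = [
    "InteractionResult",
    "BootstrapTest",
    "interaction_surface",
    "effect_size_viability",
    "interaction_energy",
    "directional_energy",
    "inflate_residuals",
    "wild_bootstrap_test",
    "bh_fdr",
]

# absolute tie tolerance when comparing bootstrap statistics to T_obs;
# guards the exactly-additive case where both are zero up to round-off
_T_TIE_TOL = 1e-10


@dataclass
class InteractionResult:
    """Per-matrix interaction summaries."""

    delta: np.ndarray
    s_sir: np.ndarray
    S2: float
    T: float
    df_null: int
    n_eff: int
    S2_syn: float = 0.0
    S2_ant: float = 0.0


@dataclass
class BootstrapTest:
    """Wild-bootstrap test outcome for one dose-response matrix."""

    T_obs: float
    T_star: np.ndarray
    p_value: float
    B: int
    seed: object
    inflation: float
    n_failed: int = 0
    result: InteractionResult | None = field(default=None, repr=False)
    iso: MonotoneFit | None = field(default=None, repr=False)
    add: AdditiveFit | None = field(default=None, repr=False)


def interaction_surface(iso: MonotoneFit, add: AdditiveFit) -> np.ndarray:
    """``delta = theta_iso - theta_add`` on the transformed scale."""
    if iso.theta_iso.shape != add.theta_add.shape:
        raise ValueError("fitted surfaces have different shapes")
    return iso.theta_iso - add.theta_add


def effect_size_viability(
    iso: MonotoneFit, add: AdditiveFit, spec: TransformSpec | None = None
) -> np.ndarray:
    """Effect size on the viability scale.

    ``S_SIR = inverse(theta_add) - inverse(theta_iso)``: positive values
    mean the combination kills more cells than the additive prediction
    (synergy), mirroring the sign convention ``delta < 0``.
    """
    spec = spec or TransformSpec()
    return inverse_transform(add.theta_add, spec) - inverse_transform(iso.theta_iso, spec)


def interaction_energy(delta: np.ndarray, W: np.ndarray) -> tuple[float, float]:
    """Interaction energy ``S2 = sum(w * delta^2)`` and its grid-size
    normalized variant ``T = S2 / sum(w)``."""
    delta = np.asarray(delta, dtype=float)
    W = np.asarray(W, dtype=float)
    if delta.shape != W.shape:
        raise ValueError("delta and W shapes differ")
    wsum = float(np.sum(W))
    if wsum <= 0:
        raise ValueError("weights sum to zero")
    obs = W > 0
    S2 = float(np.sum(W[obs] * delta[obs] ** 2))
    return S2, S2 / wsum


def directional_energy(delta: np.ndarray, W: np.ndarray) -> tuple[float, float]:
    """Split the interaction energy by direction.

    Returns ``(S2_syn, S2_ant)``: the energy carried by synergistic cells
    (``delta < 0``) and antagonistic cells (``delta > 0``).  The two parts
    sum to S2.
    """
    delta = np.asarray(delta, dtype=float)
    W = np.asarray(W, dtype=float)
    syn = float(np.sum(W[(delta < 0) & (W > 0)] * delta[(delta < 0) & (W > 0)] ** 2))
    ant = float(np.sum(W[(delta > 0) & (W > 0)] * delta[(delta > 0) & (W > 0)] ** 2))
    return syn, ant


def inflate_residuals(r: np.ndarray, n_eff: int, df_null: int) -> np.ndarray:
    """Scale null-fit residuals so their resampled variance matches the
    error variance, ``r_tilde = r * sqrt(n_eff / (n_eff - df_null))``.

    Analogous to the n/(n-p) correction in linear-regression variance
    estimation: the null fit passes closer to the data than the true
    surface would, so raw residuals are too small and uncorrected
    resampling would anti-conservatively shrink the bootstrap null.
    """
    if df_null < 1:
        raise ValueError("df_null must be >= 1")
    if n_eff <= df_null:
        raise ValueError(
            f"cannot inflate residuals: n_eff={n_eff} <= df_null={df_null}"
        )
    return np.asarray(r, dtype=float) * np.sqrt(n_eff / (n_eff - df_null))


def _summaries(
    tg: TransformedGrid, iso: MonotoneFit, add: AdditiveFit
) -> InteractionResult:
    delta = interaction_surface(iso, add)
    s_sir = effect_size_viability(iso, add, tg.spec)
    S2, T = interaction_energy(delta, tg.W)
    syn, ant = directional_energy(delta, tg.W)
    return InteractionResult(
        delta=delta, s_sir=s_sir, S2=S2, T=T,
        df_null=add.df_null, n_eff=tg.n_eff, S2_syn=syn, S2_ant=ant,
    )


def wild_bootstrap_test(
    tg: TransformedGrid,
    B: int = 200,
    seed=0,
    tol: float = 1e-8,
) -> BootstrapTest:
    """Test the monotone-additive null with a Rademacher wild bootstrap.

    Fits both models, computes the observed statistic ``T_obs``, then for
    each of ``B`` resamples builds ``Z* = theta_add + xi * r_tilde`` with
    independent per-cell signs ``xi in {-1, +1}``, refits both models on
    ``Z*`` with the original weights, and recomputes ``T*``.  The p-value
    is ``(1 + #{T* >= T_obs}) / (B + 1)``, so the smallest achievable
    value is ``1 / (B + 1)``.

    A resample whose solve fails is retried once, then counted as
    ``T* = +inf`` (conservative).  Deterministic for a fixed seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    I, J = tg.shape
    if I < 2 or J < 2:
        raise ValueError("interaction is undefined on a 1-dimensional dose grid")
    iso = fit_isotonic_2d(tg, tol=tol)
    add = fit_monotone_additive(tg, tol=tol)
    result = _summaries(tg, iso, add)
    T_obs = result.T
    if tg.n_eff <= add.df_null:
        raise ValueError(
            f"n_eff={tg.n_eff} <= df_null={add.df_null}: "
            "too few observed cells to calibrate the bootstrap"
        )
    inflation_ratio = tg.n_eff / (tg.n_eff - add.df_null)
    obs = tg.W > 0
    r = np.where(obs, tg.Z - add.theta_add, 0.0)
    r_t = inflate_residuals(r, tg.n_eff, add.df_null)
    rng = np.random.default_rng(seed)
    T_star = np.empty(B)
    n_failed = 0
    for b in range(B):
        xi = rng.integers(0, 2, size=tg.shape) * 2 - 1
        Zb = np.where(obs, add.theta_add + xi * r_t, np.nan)
        tgb = TransformedGrid(Z=Zb, W=tg.W, eps=tg.eps, tau=tg.tau, spec=tg.spec)
        for attempt in range(2):
            try:
                iso_b = fit_isotonic_2d(tgb, tol=tol)
                add_b = fit_monotone_additive(tgb, tol=tol)
                delta_b = interaction_surface(iso_b, add_b)
                _, T_star[b] = interaction_energy(delta_b, tg.W)
                break
            except SolverError:
                if attempt == 1:
                    warnings.warn(
                        f"bootstrap resample {b} failed to solve; "
                        "counted as T* = +inf (conservative)",
                        stacklevel=2,
                    )
                    T_star[b] = np.inf
                    n_failed += 1
    p = (1 + int(np.sum(T_star >= T_obs - _T_TIE_TOL))) / (B + 1)
    return BootstrapTest(
        T_obs=T_obs, T_star=T_star, p_value=p, B=B, seed=seed,
        inflation=inflation_ratio, n_failed=n_failed,
        result=result, iso=iso, add=add,
    )


def bh_fdr(
    pvalues,
    q: float = 0.05,
    strata=None,
    B: int | None = None,
):
    """Benjamini-Hochberg step-up across a screen of per-matrix p-values.

    Applied within each stratum when ``strata`` labels are given (e.g.
    cell line or plate, where noise levels are more homogeneous), globally
    otherwise.  Returns ``(reject, p_adjusted)`` aligned with the input.
    Warns when the resolution limit of the bootstrap makes the requested
    FDR level unreachable (``q / M < 1 / (B + 1)``).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject = np.zeros(p.size, dtype=bool)
    p_adj = np.ones(p.size)
    if strata is None:
        groups = [np.arange(p.size)]
    else:
        strata = np.asarray(strata)
        groups = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    for idx in groups:
        if idx.size == 0:
            continue
        if B is not None and q / idx.size < 1.0 / (B + 1):
            warnings.warn(
                f"q/M = {q / idx.size:.2e} is below the bootstrap resolution "
                f"1/(B+1) = {1 / (B + 1):.2e}; increase B",
                stacklevel=2,
            )
        rej, padj, _, _ = multipletests(p[idx], alpha=q, method="fdr_bh")[:4]
        reject[idx] = rej
        p_adj[idx] = padj
    return reject, p_adj
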