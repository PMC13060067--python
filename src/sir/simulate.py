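"""Synthetic dose-response generation and the calibration/power studies.

Null grids are exact members of the monotone-additive class A: an
intercept plus non-increasing row and column effects built from
cumulative non-positive dose steps.  Alternatives add a localized
Gaussian bump (toward synergy, i.e. lower viability) and project the sum
back onto the monotone cone M so the departure from additivity is
model-consistent.  Observations are the surface plus i.i.d. Gaussian
noise on the logit scale.

All randomness flows from one master seed through per-simulation
substreams, so studies are reproducible and order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._solvers import grid_constraint_pairs, isotonic_project
from .fit import fit_monotone_additive
from .grid import TransformedGrid
from .inference import inflate_residuals, wild_bootstrap_test

__all__ = [
    "SimulationConfig",
    "NullSurface",
    "CalibrationReport",
    "PowerReport",
    "generate_null_surface",
    "inject_interaction",
    "add_noise",
    "pseudo_null_from_fit",
    "run_calibration_study",
    "run_power_study",
]

# default bump amplitudes on the logit scale; the largest is calibrated to
# give near-complete power at sigma = 0.1 on an 8x8 grid
DEFAULT_STRENGTHS = (0.5, 1.0, 1.5, 2.0, 2.5)


@dataclass
class SimulationConfig:
    """Stated world of the simulation studies.

    8 x 8 grids, Gaussian noise with sigma = 0.1 on the logit scale,
    B = 200 bootstrap resamples, 200 null simulations for calibration and
    30 per strength for power, tested at alpha = 0.05.
    """

    I: int = 8
    J: int = 8
    sigma: float = 0.1
    B: int = 200
    n_null_sims: int = 200
    n_power_sims: int = 30
    strengths: tuple = DEFAULT_STRENGTHS
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be positive")
        s = tuple(self.strengths)
        if any(x < 0 for x in s) or list(s) != sorted(s):
            raise ValueError("strengths must be nonnegative and ascending")
        self.strengths = s


@dataclass
class NullSurface:
    """An exact member of the monotone-additive class A."""

    alpha: float
    u: np.ndarray
    v: np.ndarray
    theta: np.ndarray


@dataclass
class CalibrationReport:
    pvalues: np.ndarray
    alpha: float
    rejection_rate: float
    dkw_eps: float
    dkw_ok: bool
    config: SimulationConfig = field(repr=False, default=None)


@dataclass
class PowerReport:
    strengths: np.ndarray
    power: np.ndarray
    n_sims: int
    alpha: float
    config: SimulationConfig = field(repr=False, default=None)


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_null_surface(I: int, J: int, seed=0) -> NullSurface:
    """Draw a random additive monotone surface.

    The intercept is Uniform(0.5, 2.0) logit units (viability roughly
    0.62-0.88 in the untreated corner); row and column effects are
    cumulative sums of non-positive dose steps ``-max(N(0.1, 0.1^2), 0)``.
    Steps are deliberately on the scale of the assay noise (sigma = 0.1)
    and about 16% of them are exactly zero: real dose ranges include
    sub-threshold and saturating doses, producing plateaus where the
    monotone constraint actively pools levels.  That is the regime the
    shape constraint is designed for; with much larger steps the
    constraint never binds, both fits interpolate, and the bootstrap test
    degenerates.
    """
    if I < 2 or J < 2:
        raise ValueError("grid must be at least 2x2")
    rng = _rng(seed)
    alpha = rng.uniform(0.5, 2.0)
    u = -np.concatenate([[0.0], np.cumsum(np.maximum(rng.normal(0.1, 0.1, I - 1), 0.0))])
    v = -np.concatenate([[0.0], np.cumsum(np.maximum(rng.normal(0.1, 0.1, J - 1), 0.0))])
    theta = alpha + u[:, None] + v[None, :]
    return NullSurface(alpha=alpha, u=u, v=v, theta=theta)


def inject_interaction(
    null_surface: np.ndarray,
    strength: float,
    center: tuple | None = None,
    width: float | None = None,
) -> np.ndarray:
    """Add a localized synergy bump and project back onto the monotone cone.

    The bump is a Gaussian kernel ``G`` of width ``I / 4`` centred in the
    high-dose quadrant (at 3/4 of each dose axis, where combination
    effects concentrate pharmacologically); ``-strength * G`` lowers
    viability locally.  The sum is projected onto M (unit weights) so the
    alternative remains a valid monotone surface; at strength 0 the null
    surface is returned exactly.  A grid-midpoint centre loses most of
    its energy to the cone projection (the bump's far-side recovery is
    non-monotone and gets clipped), which is why the default sits in the
    high-dose quadrant.
    """
    theta = np.asarray(null_surface, dtype=float)
    if strength < 0:
        raise ValueError("strength must be >= 0")
    I, J = theta.shape
    ci, cj = center if center is not None else (0.75 * (I - 1), 0.75 * (J - 1))
    w = width if width is not None else I / 4.0
    ii, jj = np.meshgrid(np.arange(I), np.arange(J), indexing="ij")
    G = np.exp(-((ii - ci) ** 2 + (jj - cj) ** 2) / (2.0 * w**2))
    bumped = theta - strength * G
    pairs = grid_constraint_pairs(theta.shape)
    flat, _ = isotonic_project(bumped.ravel(), np.ones(theta.size), pairs)
    return flat.reshape(theta.shape)


def add_noise(surface: np.ndarray, sigma: float, seed=0) -> np.ndarray:
    """i.i.d. Gaussian noise on the transformed scale, seeded."""
    if not sigma > 0:
        raise ValueError("sigma must be positive")
    surface = np.asarray(surface, dtype=float)
    return surface + _rng(seed).normal(0.0, sigma, surface.shape)


def pseudo_null_from_fit(tg: TransformedGrid, seed=0) -> np.ndarray:
    """Generate a pseudo-null response matrix from a fitted additive null.

    Fits the monotone-additive model, inflates its residuals by the
    degrees-of-freedom factor, flips their signs with i.i.d. Rademacher
    variables, and returns ``theta_add + xi * r_tilde``.  By construction
    the output contains no true interaction, so re-running the full test
    on it probes p-value calibration on real noise structure.
    """
    add = fit_monotone_additive(tg)
    if tg.n_eff <= add.df_null:
        raise ValueError(
            f"n_eff={tg.n_eff} <= df_null={add.df_null}: cannot build pseudo-null"
        )
    obs = tg.W > 0
    r = np.where(obs, tg.Z - add.theta_add, 0.0)
    r_t = inflate_residuals(r, tg.n_eff, add.df_null)
    xi = _rng(seed).integers(0, 2, size=tg.shape) * 2 - 1
    return np.where(obs, add.theta_add + xi * r_t, np.nan)


def _simulate_pvalue(cfg: SimulationConfig, sim_index: int, strength: float) -> float:
    """One simulation draw: null surface, optional bump, noise, full test."""
    rng = np.random.default_rng([cfg.seed, sim_index])
    surface = generate_null_surface(cfg.I, cfg.J, rng).theta
    if strength > 0:
        surface = inject_interaction(surface, strength)
    Z = add_noise(surface, cfg.sigma, rng)
    tg = TransformedGrid.from_arrays(Z)
    boot_seed = int(rng.integers(2**31))
    return wild_bootstrap_test(tg, B=cfg.B, seed=boot_seed).p_value


def run_calibration_study(cfg: SimulationConfig) -> CalibrationReport:
    """Type-I-error calibration under the additive null.

    Runs ``n_null_sims`` independent null grids through the full test and
    checks that the p-value ECDF stays inside the 95% DKW band of
    Uniform(0, 1) and that the rejection rate at ``alpha`` is nominal.
    """
    p = np.array([
        _simulate_pvalue(cfg, i, 0.0) for i in range(cfg.n_null_sims)
    ])
    n = p.size
    eps = np.sqrt(np.log(2.0 / 0.05) / (2.0 * n))
    grid = np.sort(p)
    ecdf = np.arange(1, n + 1) / n
    # sup-distance of the ECDF from the U(0,1) CDF
    ks = max(np.max(ecdf - grid), np.max(grid - (ecdf - 1.0 / n)))
    return CalibrationReport(
        pvalues=p,
        alpha=cfg.alpha,
        rejection_rate=float(np.mean(p <= cfg.alpha)),
        dkw_eps=float(eps),
        dkw_ok=bool(ks <= eps),
        config=cfg,
    )


def run_power_study(cfg: SimulationConfig) -> PowerReport:
    """Rejection rate at ``alpha`` as a function of injected bump strength."""
    power = []
    for k, strength in enumerate(cfg.strengths):
        p = np.array([
            _simulate_pvalue(cfg, 1_000_000 + k * cfg.n_power_sims + i, strength)
            for i in range(cfg.n_power_sims)
        ])
        power.append(float(np.mean(p <= cfg.alpha)))
    return PowerReport(
        strengths=np.asarray(cfg.strengths, dtype=float),
        power=np.asarray(power),
        n_sims=cfg.n_power_sims,
        alpha=cfg.alpha,
        config=cfg,
    )
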