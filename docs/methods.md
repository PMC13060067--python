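# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic test battery establishes.

## Model classes and estimation

Viability `Y ∈ [0,1]` on an `I × J` dose grid is transformed to
`Z = logit(clamp(Y, ε, 1−ε))`, `ε = 1e-6`. The logit is the default because
it maps bounded viability to ℝ, stabilizes variance near the boundaries,
and defines additivity as equal log-odds increments of survival; `identity`,
`asinh` and `log` are available for sensitivity checks, with the effect-size
surface then reported on that transform's natural response scale.

Weights are `w = m / max(s², τ)` with `τ = 1e-6` (per-cell replicate count
`m` and unbiased variance `s²`), Winsorized per matrix at the 99th
percentile of positive weights. A matrix with no replicate information gets
uniform weights `1/τ`; single-replicate cells inside a replicated matrix
also get `1/τ` (they carry no variance information of their own). The test
statistic `T = S²/Σw` is invariant to rescaling all weights, so the uniform
value itself is immaterial.

Both fits are projections onto closed convex cones and therefore exist and
are unique for any input — the reason this pipeline has no failure mode
analogous to a non-converging Hill fit:

* **Monotone cone M**: minimize `Σ w (Z − θ)²` subject to
  `θ[i+1,j] ≤ θ[i,j]` and `θ[i,j+1] ≤ θ[i,j]`. Solved exactly through the
  dual: projection onto `{θ : Aθ ≤ 0}` in the `W`-norm is equivalent to the
  nonnegative least-squares problem
  `min_{λ≥0} ‖W^{-1/2}Aᵀλ − W^{1/2}Z‖²` with `θ = Z − W^{-1}Aᵀλ`, solved by
  the finite active-set NNLS algorithm (no iterative tolerance tuning).
* **Monotone-additive class A**: `θ = α + u_i + v_j`, `u, v` non-increasing,
  `u_1 = v_1 = 0`. Reparametrized with nonnegative dose-step increments
  (`u_i = −Σ_{k<i} a_k`, `a ≥ 0`) the constraints become simple bounds,
  solved exactly by bounded-variable least squares. The identifiability
  constraints and monotonicity then hold exactly, not merely to tolerance.

Solutions are accepted only if the fitted surface violates no constraint by
more than `max(tol, 1e-7)·scale` (default `tol = 1e-8`); otherwise a
`SolverError` is raised rather than returning an infeasible surface.

### Missing wells

Cells with `w = 0` are free variables of the cone projection. The fit is
computed over observed cells under the induced partial order (covering
pairs of the componentwise dominance order restricted to observed cells —
exact, because a free cell can always interpolate along a monotone
staircase). Each free cell is then resolved deterministically to the
midpoint of its monotone envelope `[max(fitted values at higher doses),
min(fitted values at lower doses)]`, computed by two corner-to-corner
sweeps; a one-sided envelope (fully missing leading row/column) falls back
to the single available bound with a warning. On a noiseless additive
surface with uniform row step `a` and column step `b`, the envelope of an
interior cell is `[θ − min(a,b), θ + min(a,b)]`, so the midpoint recovers
the true value exactly — the property the holdout benchmark tests.

## Effective degrees of freedom and residual inflation

Monotone regression pools adjacent dose levels that violate monotonicity,
so its parameter count is data dependent. `df_null` is the number of
distinct fitted levels in `û` plus that in `v̂` minus one (the shared
intercept), clamped to ≥ 1; on a 5×5 grid with fully distinct marginals
this gives 9, the full parameter count `1 + 4 + 4`. Levels within `1e-6`
(logit scale) are merged because the QP returns near-ties where an exact
pool-adjacent-violators pass would return exact ties.

Because the null fit absorbs noise, raw residuals underestimate the error
scale. Before resampling they are inflated as
`r̃ = r · sqrt(n_eff / (n_eff − df_null))`, so the resampled error
*variance* carries the factor `n_eff/(n_eff − df_null)` — the direct
analogue of the `n/(n−p)` variance correction in linear regression
(`25/16 ≈ 1.56` for the 5×5 case above). The test refuses to run when
`n_eff ≤ df_null`.

## Wild bootstrap

Each of `B` resamples is `Z* = θ̂add + ξ·r̃` with i.i.d. per-cell Rademacher
signs `ξ`, keeping the original weights fixed (residuals are resampled on
the logit scale only; weights are design information). Both models are
refit on every `Z*` and `p = (1 + #{T* ≥ T_obs})/(B+1)`. Numerical choices:

* `T* ≥ T_obs` is evaluated with an absolute tolerance of `1e-10` so that
  exactly-additive noiseless data (where both statistics are zero up to
  round-off) yields `p = 1` rather than a round-off-determined count.
* A resample whose solve fails is retried once and then counted as
  `T* = +∞` — inflating, never deflating, the p-value.
* `df_null` is computed once on the original fit; it enters only the
  inflation factor.
* Default `B = 200` (exploratory; resolution `1/201 ≈ 0.005`); use
  1,000–5,000 for confirmatory work.

Degenerate `1 × J` / `I × 1` grids are rejected at the test level:
interaction is undefined without two varying doses (the fitting routines
still accept them, which the 1D PAVA oracle tests rely on).

## Synthetic data generator

Null surfaces are exact members of A: `α ~ Uniform(0.5, 2.0)` logit units
and `u, v` cumulative sums of non-positive steps `−max(N(0.1, 0.1²), 0)`.
Two properties of this choice matter:

* **Step scale ≈ noise scale.** With observation noise `σ = 0.1` and steps
  of the same order (≈16% exactly zero — sub-threshold or saturating
  doses), the monotone constraints genuinely bind and the fits pool levels.
  This is the regime the shape constraint is designed for. With much larger
  steps (e.g. 0.4 ± 0.2) the constraints never bind, both fits interpolate
  the data, `δ` collapses onto the raw residuals, and sign-flipping leaves
  `T* ≈ T_obs`: the bootstrap p-value degenerates toward ½ and the test
  loses all calibration *and* all power. The generator deliberately avoids
  that vacuous regime.
* **Alternatives stay model-consistent.** Interaction is injected by
  subtracting `strength · G` — `G` a Gaussian kernel of width `I/4`
  centred at 3/4 of each dose axis — and projecting back onto M with unit
  weights. The high-dose-quadrant centre is where combination effects
  concentrate pharmacologically; a grid-midpoint centre loses most of its
  energy to the projection (the bump's far-side recovery is non-monotone
  and gets clipped) and cannot reach high power at any plausible amplitude.
  At strength 0 the projection returns the null surface exactly. The
  default strength grid is {0.5, 1.0, 1.5, 2.0, 2.5} logit units; at
  `σ = 0.1` on 8×8 grids the largest strength rejects essentially always.

All study randomness flows from one master seed through per-simulation
substreams (`default_rng([seed, index])`), so studies are reproducible and
order-independent; per-matrix screen seeds are likewise derived from the
master seed and the sorted block-id rank.

What a green synthetic battery does **not** establish: behaviour under
plate-effect or spatially correlated noise (the bootstrap assumes per-cell
independence), hormetic/biphasic dose responses (monotonicity is violated
by construction there), replicate-derived heteroscedastic weights at scale,
or performance on real screening databases.

## Calibration behaviour

At the defaults (8×8, `σ = 0.1`, `B = 200`, 200 null simulations) the
rejection rate at `α = 0.05` sits slightly below nominal — the test is
mildly conservative, which is the preferred direction in screening. The
full p-value ECDF shows mild under-dispersion in the *middle* of the
distribution (too few values near 0 and near 1) and can brush or cross the
95% DKW band of Uniform(0,1). The mechanism is inherent to a
magnitude-preserving wild bootstrap: resamples condition on the realized
residual magnitudes `|r̃|`, and the two-point sign-flip distribution has
different tail behaviour than Gaussian noise, slightly biasing the pooling
rate of the refits. The acceptance suite asserts the strict DKW criterion
and reports this honestly rather than tuning the world to pass it.

## Baselines and benchmarks

Bliss (`E = yA·yB`) and HSA (`E = min(yA, yB)`) excess surfaces use the
first row/column as monotherapy anchors — explicit zero-dose rows when the
design has them, otherwise the lowest dose as the standard screening
approximation. Excess is reported on the viability scale with positive =
synergy, matching `S_SIR`'s orientation (note: opposite of the
inhibition-scale convention some screening software uses). Loewe and ZIP
are deliberately out of scope: they require the parametric marginal fits
this framework exists to avoid. Concordance utilities (replicate Pearson
correlation, sign-disagreement rate, top-k Jaccard) and the interior-well
holdout benchmark operate on any user-supplied matrices or score vectors.

## Known limitations

* The df-corrected wild bootstrap is mildly conservative at small p and
  under-dispersed mid-distribution (above).
* Very small grids (3×3) leave few cells beyond `df_null`; the test runs
  but has limited power.
* The monotone-additive null treats each drug's effect as an arbitrary
  monotone function — on tiny grids this is generous to the null.
* Monotonicity itself can fail (hormesis); such matrices should be flagged
  upstream rather than force-fit.
* The bump kernel and null-surface distribution of the simulation module
  are a declared stand-in for the real screening populations they emulate;
  absolute power numbers depend on them, the qualitative monotone
  power curve does not.
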