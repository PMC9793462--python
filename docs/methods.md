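# Methods

## Model

`nanodiss` simulates diffusion-limited dissolution of a polydisperse
population of spherical drug nanocrystals in a closed, perfectly mixed,
isothermal liquid volume. The state is the per-class particle diameter
`x_i(t)` (class particle counts `N_i` fixed) and the solution
concentration `c_l(t)`.

**Size-dependent solubility.** Each class dissolves against its own
apparent solubility from the Ostwald–Freundlich relation

    s_app(x) = s0 · exp(4 σ_sl V_m / (x R T))

(equivalently `2 σ_sl V_m/(r R T)` with the particle radius `r = x/2`).
The quantity `L = 4 σ_sl V_m / (R T)` — 18.2 nm for the reference
compound at 30 mJ/m² — is the diameter at which the solubility
enhancement is a factor *e*; the enhancement is ~20 % at 100 nm and ~2×
at 26 nm.

**Flux.** Per particle, the Noyes–Whitney / Nernst-Brunner rate
`dm_p/dt = −π x² D (s_app(x) − c_l)/δ` with boundary layer `δ = x/2`,
i.e. a Sherwood number of 2, appropriate for sub-micron particles that
follow the liquid flow. This collapses to the shrinking-sphere law
`dx/dt = −4 D (s_app − c_l)/(ρ x)`. An optional cap `δ_max` is exposed
for sensitivity studies on coarse particles; the default is uncapped
(the same engine simulates the 2.4 µm batch). `D` comes from
Stokes–Einstein with the molecular hydrodynamic radius
`(3 V_m / 4π N_A)^{1/3}`. Note that `D`, `η` and any global rescaling of
the flux only rescale time: mass conservation ties the concentration
rise to the shrinkage, so the *equilibrium* state is invariant to them.
The equilibrium depends only on the PSD shape, the dose number and `L`.

**Assumptions.** Spherical particles, ideal dispersion, linear gradient
across the boundary layer, no precipitation/growth/ripening/
agglomeration (classes with `s_app ≤ c_l` freeze permanently), no
absorption or volume change. These match the closed-vessel solubility
experiments the model is calibrated against; they deliberately exclude
in-vivo processes (permeation, gastric emptying, pH dynamics).

## PSD representation

Volume-based (Q3) percentiles are fitted by unweighted least squares of
`ln x` against the probit of the cumulative fraction — exact when the
data are log-normal, and matching the reference batch parameters to
±0.01 in σ from the printed x10/x50/x90 triplets. The fitted
distribution is discretized into `n` classes at the volume quantiles
`k/(n+1)`, each with volume fraction `1/n`; `n = 999` places classes at
0.1 %…99.9 % in 0.1 % steps. The log-normal is extrapolated beyond the
measured x10–x90 range, which over-weights the fine tail if the true
distribution is sub-log-normal there — the dominant input uncertainty
for high-dose-number predictions. Per-class counts are
`N_i = w_i m / (ρ π/6 x_i³)`; fractional counts are intentional (classes
are statistical weights, not literal particles).

## Integration

Explicit Euler with an adaptive step, chosen each iteration as the
minimum of:

- *shrink rule*: no class shrinks more than 0.5 % in diameter per step;
- *concentration rule*: the concentration increment is at most 1 % of
  the largest remaining `s_app − c_l` gap. (Using the *smallest* gap
  would stall as classes approach their freeze point; the largest-gap
  form bounds the same per-step error with a finite step count.)

`c_l` is recomputed from the solid-phase mass balance every step, so
mass is conserved to rounding (tests assert 1e-9 relative; observed
drift is ~1e-15). Classes driven below 2 nm — sub-unit-cell sizes where
the continuum picture is meaningless — are emptied exactly, their
remaining mass credited to solution (≤1e-6 of the total per event).
A class freezes when its gap falls below `rel_tol · c_l`
(default 1e-6); the run terminates when every class is frozen or empty.
A fixed-Δt mode exists for step-size studies. Halving the step or
doubling the class count moves the equilibrium concentration by <0.1 %
and <0.05 % respectively for the finest reference batch.

At equilibrium with remaining solid, `c_eq` equals the apparent
solubility of the smallest surviving class up to the solution-mass of
the few finest classes that empty after that class froze (≈3 class
masses for the finest reference batch; the bound shrinks as `1/n`).

## Interfacial-energy calibration

`σ_sl` of a stabilized nanocrystal is not directly measurable; it is
selected by deterministic grid search (default 10–60 mJ/m² in 10 mJ/m²
steps, mirroring a "selected candidates" study design) minimizing the
sum of squared relative errors between simulated equilibrium
concentrations and measured apparent solubilities, ties to the smaller
candidate. Simulations are memoized per distinct scenario, so noisy
refits and Monte-Carlo recovery studies cost one engine run per
(PSD, dose, candidate).

On the bundled reference measurements this procedure selects 50 mJ/m²
(all eight constant-dose batches then within ±10 %), whereas the
published analysis of the same data reports 30 mJ/m². At 30 mJ/m² this
implementation reproduces the published *qualitative* structure across
dose number — under-prediction at low Do, over-prediction at high Do
with a crossover near Do ≈ 45 — but under-predicts the sub-150 nm
batches by 14–18 % rather than <10 %. The engine has been verified
against an analytic monodisperse oracle, an independent RK4 integration
and dt/class-count refinement, and the equilibrium is provably invariant
to global rate factors, so this gap reflects a genuine difference from
the original (spreadsheet) implementation of the same equations that we
cannot reconstruct from the printed data. The package reports what the
stated model actually yields.

## Synthetic data

`nanodiss.synthetic` generates exact log-normal percentile tables
(machine-precision fit round-trips) and pseudo-experimental solubility
datasets: the engine is run at a known `σ_sl` and the equilibrium
concentrations perturbed with seeded multiplicative Gaussian noise,
default relative SD 3 % — matching the ≤4 % duplicate-assay spread of
the reference HPLC measurements. Ground truth (seed, true `σ_sl`,
noiseless values) is always emitted alongside. These fixtures exercise
estimator *consistency* (recovery of parameters the model itself
generated); they do not test model adequacy against real suspensions,
which only measured data can.

## Solid-state estimators

- **Core–shell surface amorphicity**: concentric spheres, amorphous
  shell `Z` unit-cell diameters thick:
  `AM(x) = 100·(1 − ((x − 2 Z D_cell)/x)³)`, capped at 100 % for
  `x ≤ 2 Z D_cell`. The effective cell diameter `D_cell` defaults to
  1.058 nm, solved in closed form from the reference compound's
  20 nm / one-layer / 28.5 % anchor (its true unit cell is unpublished);
  with that single anchor the whole printed single-size table reproduces
  to ±0.1 point. Whole-PSD amorphicity is the volume-fraction-weighted
  class mean. The printed whole-PSD values for the 111 nm batch
  reproduce to 0.05 points; the 79 nm batch's printed row is uniformly
  ≈7 % (relative) above what its stated PSD parameters yield — an
  internal inconsistency of the source documented in the tests.
- **Scherrer size**: `τ = K λ / (β cos θ)`; defaults K = 0.9 and
  Cu Kα (1.5406 Å).
- **XRPD calibration**: OLS of baseline intensity vs crystalline mass
  fraction; crystallinity prediction inverts the line with a
  t-distribution prediction interval propagated through the slope;
  `w_amorph = 100 − w_cryst`.
- **Detection limit**: OLS of peak height vs log10(size); the root
  `10^(−b/a)` estimates the size where the peak merges into the
  amorphous background. On the four bundled reference peaks this gives
  25.8 nm (the source quotes ≈21 nm from an unstated fit variant).

## Problem sizes and defaults

Acceptance-grade runs use the full 999-class discretization throughout
(one closed-vessel scenario integrates in ~1–30 s on one CPU; the
48-simulation calibration grid in ~1 min via the cache). Unit tests use
29–199 classes, which the refinement property shows is within 0.5 % of
the 999-class equilibrium for the quantities asserted. Temperature
defaults to 295.15 K (the 22 °C equilibration temperature of the
reference experiments); all internal units are SI, with nm / mg/L /
mJ/m² / g / mL conversions only at the CLI and CSV boundary.

## Known limitations

- Media enter only through `s0`; pH is metadata. Scenarios at media
  whose `s0` is unpublished require a user-supplied value.
- No Prandtl boundary layer for stirred coarse particles (the `δ_max`
  cap is a crude stand-in for sensitivity studies).
- Log-normal-only PSD family; the fine-tail extrapolation dominates
  high-Do uncertainty.
- Equilibria, not absolute kinetics, are the validated output: rate
  constants rescale time and are untestable against the bundled
  (equilibrium-only) measurements.
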