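# Methods

## Freezing-equilibrium model

The core model treats a partially frozen aqueous solution as three water
pools: ice, free serum water, and hydration-bound water. At absolute
temperature *T* the serum must hold the equilibrium solute mole fraction

    x_s(T) = 1 − exp(a − b/T),   b = ΔH_fus/R = 722.8 K,   a = b/T_water

which follows from equating the chemical potentials of ice and of water in
an ideal solution and linearising the enthalpy of fusion over the relevant
range. Each mole of solute binds *h* moles of water (the *effective*
hydration number — an empirical lump that also absorbs non-ideality:
solute clustering, altered hydrogen-bond networks, excluded volume). Moles
of ice are then total water minus equilibrium serum water minus bound
water:

    n_ice = n_water − (1/x_s − 1)·n_s − Σ_s n_s·h_s

Assumptions worth stating plainly:

- **Ideal mixing** in the serum phase; all non-ideality is pushed into
  *h*, which is why fitted *h* values are temperature- and
  concentration-dependent rather than molecular constants.
- **Ice content basis.** `%ice` is a percentage of *total sample mass*
  (water + solutes). This basis is forced by the freeze-concentration
  identity: serum concentration `100·m_s/(m_total − m_ice)` round-trips the
  measured premix/serum concentration pairs exactly on this basis and on no
  other.
- **Mixtures.** The equilibrium term uses total solute moles and bound
  water sums over solutes; for a single solute this reduces bit-for-bit to
  the one-solute expression.
- **Electrolytes.** The colligative law takes a dissociation degree *i*
  (ideal NaCl: 2). Measured freezing points of NaCl solutions are known to
  run shallower; `fit_dissociation_degree` provides a least-squares
  effective *i* (≈1.57 over the bundled reference series) as an explicit
  calibration — it is never substituted silently.

## Parameters and defaults

| parameter | value | units | why |
|---|---|---|---|
| K_k | 1.86 | K·kg·mol⁻¹ | cryoscopic constant of water |
| b = ΔH_fus/R | 722.8 | K | sets the x_s(T) scale |
| a | b/273.15 = 2.64617 | – | computed, not the rounded 2.646; a `use_printed_a` switch restores the rounded value (x_s differs < 0.02 %) |
| ΔH ice | 334 | J·g⁻¹ | enthalpy of fusion of pure ice; DSC normalisation |
| MW water | 18.015 | g·mol⁻¹ | |
| ethanol MW | 46.5 | g·mol⁻¹ | registry value; reproduces the reference freezing points at 2 dp, where 46.07 would not |

## Numerical choices

- **Forward vs. inverse paths.** The forward ice content clamps negative
  raw values to 0 and flags them `valid=False` (temperatures above the
  melting point). The closed-form inversion and the melting-point root
  search both use the *raw unclamped* expression, so the algebra stays
  exact: forward→inverse round-trips agree to better than 1e-9 in *h*.
- **Melting point** is found with Brent's method on [−40, 0) °C, tolerance
  1e-6 °C — derivative-free and deterministic. Pure water short-circuits
  to 0 °C (the root expression is solute-normalised).
- **Negative fitted h** marks a measurement inconsistent with the model
  (more ice than even h = 0 allows). Cells are reported with a flag and
  excluded from interpolation; clamping them to 0 would bias the surface.
- **Hydration-table interpolation** defaults to nearest-cell (only
  discrete cells are ever measured); linear-in-T and bilinear policies are
  opt-in. Lookups outside the fitted hull raise unless extrapolation is
  requested explicitly.
- **Replicate handling** in `fit_hydration_table` defaults to
  mean-then-invert (average replicate ice contents, invert once), matching
  the convention that published hydration tables are computed from averaged
  measurements; invert-then-mean is selectable. The two coincide exactly
  in the noiseless case because the inversion is affine in ice content.
- **DSC integration** subtracts a straight baseline joining the
  integration-window endpoints and integrates over time with the
  trapezoidal rule. Sigmoidal baselines and overlapping
  solute-crystallisation peaks (the known failure mode for concentrated
  NaCl) are out of scope; the baseline-crossing warning flags suspicious
  windows. Integration limits are a user input — instrument software
  choices vary and no single window is canonical.
- **Rounding for table reproduction**: freezing points at 2 decimals,
  serum concentrations at nearest integer (half-up), matching the
  precision of the reference tables.

## Melting-curve parameter extraction

Total melting time is the first time the cumulative drip mass reaches
99.5 % of its final value ("the last droplet" is not machine-detectable;
ε = 0.5 % is the deterministic surrogate). The melting rate is the OLS
slope of drip mass (% of initial mass) vs. time over the central fast
phase, bounded at 20–80 % of final drip mass (the fast phase has no
canonical limits; a central band is standard practice and configurable).

**Lag time is the x-intercept of the fast-phase line**, not the first
threshold crossing. A fixed mass threshold (default 0.5 g, used only to
decide whether melting occurred) is systematically late by
threshold/slope — ~50 s for a 60 g sample melting at 1 %/min, five times
the 10 s sampling interval — whereas back-extrapolating the linear phase
recovers the true onset to within one sample on the synthetic shapes and
is translation-exact (prepending dead time shifts the lag by exactly that
time). Onset temperature is the core temperature, smoothed with a 3-point
edge-corrected moving average, interpolated at the lag time.

Hardness is the stress (force / probe-tip area, 4-mm cylinder by default)
at the *first* force peak, detected on a 3-point-smoothed copy of the
trace; traces without an interior peak fall back to the global maximum
with a warning.

## Synthetic generators

The generators emulate the study conditions, not the instruments'
physics:

- **Ice-content datasets**: forward-model truth per (solute, c, T) cell
  from a ground-truth h-surface, triplicate replicates, additive Gaussian
  noise of 1 % ice (absolute) by default — the magnitude of typical
  replicate standard deviations — clamped to [0, 100].
- **Melting curves**: 60 g samples logged every 10 s; drip mass zero until
  the lag, linear at the set rate until the total time, plateau after;
  the implied melted fraction must be feasible (≤ 100 %). The core
  temperature saturates exponentially toward the melting plateau (within
  2 % of it by the lag time) and relaxes toward ambient after melt-out —
  a smooth profile, since a thermocouple in a melting sample shows no
  kink. Balance noise 0.1 g, thermocouple noise 0.1 °C; cumulative mass
  is forced non-decreasing after noise.
- **DSC traces**: a 1 °C/min final heating ramp with a Gaussian endotherm
  whose analytic time-integral equals `%ice·334/100` J/g, on a linear
  drift baseline, heat-flow noise 2·10⁻⁴ J·s⁻¹·g⁻¹ (a few µW on an
  ~11 mg sample).

What the generators do *not* reproduce: thermal lag and pan effects in
DSC, solute crystallisation exotherms, droplet discreteness and ambient
fluctuations in melting tests, non-Gaussian or drifting measurement error.
Passing recovery tests therefore demonstrates the correctness and noise
robustness of the estimators under the stated error model — not immunity
to instrument artefacts in real data.

## Problem sizes

The self-consistency measurements use 1,000 random (composition, h, T)
draws for inversion exactness, 500 for oracle agreement, an 18-cell
hydration surface (3 concentrations × 6 temperatures, 3 replicates) for
recovery, and 100 synthetic melting curves spanning lags of 5–20 min and
rates of 1–1.75 %/min — the ranges the reference measurements cover.

## Known limitations

- Single-temperature-independent *h* cannot fit real ice curves (the data
  demand h(T)); the package fits per-cell tables rather than parametric
  h(T, c) models by design.
- Activity-coefficient and state-diagram approaches, glass transitions,
  and ice-crystal-size effects are out of scope.
- The effective-i calibration for NaCl is a pragmatic bridge, not a
  mechanistic treatment of ion pairing at freezing temperatures.
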