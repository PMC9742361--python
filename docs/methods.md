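# Methods

## Model and assumptions

`flashox` models radiolytic oxygen depletion as a continuum
reaction–diffusion process between blood vessels:

    ∂O/∂t = −K₁ Ḋ O/(O + l) − K₂ O/(O + λ) + K₃ ∇²O

* **Radiolytic depletion** −K₁ Ḋ O/(O+l): oxygen is consumed by
  radiation chemistry in proportion to the dose rate, with G-value K₁
  (μM/Gy).  The factor O/(O+l) saturates the depletion away at very low
  oxygen (little oxygen left to scavenge); l is small (0.29 μM) so the
  term is near-linear in Ḋ over most of the physiological range.  K₁ is
  a phenomenological constant, identical for CONV and UHDR deliveries —
  no track-overlap chemistry is modeled.
* **Metabolism** −K₂ O/(O+λ): Michaelis–Menten consumption, constant
  rate K₂ at normoxia, shutting off below the Michaelis constant λ.
* **Diffusion** K₃ ∇²O with constant, isotropic K₃.
* **Vasculature**: vessels are fixed-concentration (Dirichlet) sources
  at their walls; the vasculature is static (no radiation damage to
  vessels, no flow modeling).  Multi-vessel blocks use zero-flux
  (Neumann) outer faces, i.e. the block tiles space periodically.
* **Delivery**: the dose rate is a spatially uniform step function in
  time (the interface accepts per-node dose rates, but all built-in
  scenarios use a constant).  LET enters only the radiobiological layer.

The radiobiological layer is pointwise and memoryless: the hypoxia
reduction factor HRF(LET, O) (bounded in [1, M], maximal at anoxia and
low LET) is evaluated on the instantaneous local oxygen, and the
cumulative normoxic-equivalent dose CNED = Ḋ ∫ dt/HRF is accumulated
over the delivery.  FEDMF = CNED_CONV/CNED_UHDR compares paired
deliveries started from the identical equilibrium; FEDMF ≥ 1.20 is the
conventional cut for a FLASH effect.  No survival-curve (LQ) modeling
and no dose-rate dependence of the HRF itself are included.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| K₁ | radiolytic depletion G-value | 0.5 | μM/Gy |
| l | depletion saturation scale | 0.29 | μM |
| K₂ | maximal metabolic rate | 18.9 | μM/s |
| λ | Michaelis constant | 3.15 | μM |
| K₃ | oxygen diffusion coefficient | 2000 (= 2×10⁻⁵ cm²/s) | μm²/s |
| M | anoxic HRF maximum | 3.0 | — |
| γ | LET exponent | 3 | — |
| a | LET scale | 8.27×10⁵ | (keV/μm)ᵞ |
| b | HRF oxygen scale | 2.4 | μM |
| O_v | vessel oxygen supply | scenario (5.4–50.4) | μM |
| Ω | inter-vessel spacing | scenario (25–1000) | μm |
| Ḋ | dose rate | 0.5 (CONV), 125/285 (UHDR) | Gy/s |
| α, τ | recruitment amplitude / time constant | 0.2, 10 | —, s |

Canonical units are μm / s / μM / Gy everywhere; the single unit
conversion (K₃ from cm²/s) happens at configuration load.  The vessel
radius in 2D/3D geometries is not constrained by the model and defaults
to 5 μm (capillary scale); the FEDMF volume fraction in the cuboid is
quite sensitive to it (±2.5 μm moves the fraction by >10 points), so it
is an explicit, documented parameter.

## Numerics

* **Scheme**: IMEX — backward-Euler diffusion (unconditionally stable,
  so dt follows the stage duration rather than the grid: the diffusion
  CFL at dx = 0.5 μm would demand dt ≈ 6×10⁻⁵ s) with the non-stiff
  reaction terms explicit at the current state.  Fields are floored at
  zero after each step and Dirichlet nodes overwritten with their supply
  values evaluated at the new time.  A warning fires when dt approaches
  the worst-case (anoxic) reaction slope K₁Ḋ/l + K₂/λ.
* **Stencils**: standard 3/5/7-point Laplacian on node-centered
  structured grids; zero-flux faces via mirror ghost nodes.  The IMEX
  fixed point is exactly the discrete steady state, so equilibria are
  independent of the internal time step.
* **Stages**: irradiation ([0, T], T = D/Ḋ) and recovery (default 10 s
  — replenishment completes within a few seconds for ≤175 μm spacings)
  each take 1500 uniform steps by default.  The pre-irradiation
  equilibration is defined by its stopping rule, not a duration: it
  marches at dt = recovery_duration/steps_per_stage until the per-step
  change satisfies max |ΔO| < 10⁻⁴·max(O, 0.1 μM) *and* the steady-state
  residual |K₃∇²O − K₂O/(O+λ)| falls below 10⁻³ μM/s.  The residual
  condition matters: with small dt the per-step criterion alone triggers
  several μM away from steady state.  The 0.1 μM floor keeps the
  relative criterion meaningful in anoxic cores.
* **Quadrature**: CNED uses the trapezoidal rule.  It is always
  accumulated online at full step resolution (an observer runs inside
  the time loop), so snapshot thinning — used to bound memory in 2D/3D —
  never degrades the integral.  Doubling the snapshot density moves
  1D CNED fields by <0.1%.
* **Resolution**: dx = 0.5 μm in 1D (halving dx and doubling steps moves
  the end-of-irradiation midpoint by <0.5%).  The cuboid uses
  dx = 1.25 μm in-plane: the 5 μm vessel disks are staircase-rasterized,
  and at dx = 2.5 μm the FEDMF volume fraction is still ~5 points from
  its converged value (79.0% → 74.4% → 72.0% over dx = 2.5/1.25/0.625).
* **Cuboid height**: the five vessels are vertical, the top/bottom faces
  are zero-flux and the initial state is z-uniform, so the discrete
  solution is *exactly* invariant along z (verified by a test).  All
  volume fractions are therefore height-independent, and the
  reproduction scenario carries a short 3-layer stack instead of a full
  cube — a tall cuboid only adds sparse-factorization fill-in.
* **Degenerate inputs**: zero-dose protocols return the equilibrium in
  all stages and define FEDMF ≡ 1 (the limit of equal CNEDs); K₃ = 0 is
  accepted by the solver (nodes decouple; used to validate the stepper
  against an adaptive ODE integration) but rejected in configuration
  files.

## What the scenario generator emulates — and what it does not

Built-in geometries emulate idealized vasculature: two parallel planes
(1D), a rectangle fed by border plus internal capillary segments (2D),
and a space-tiling cuboid with five vertical vessels (3D).  Real
capillary networks are tortuous, irregularly spaced, and perfused with
varying blood oxygen; vessel walls here are hard Dirichlet boundaries
with no transport resistance.  Dose and LET are uniform scalars, whereas
real proton fields carry spatial dose/LET structure.  Passing tests
therefore demonstrate the internal consistency of the
depletion–replenishment–HRF pipeline under controlled conditions, not
the fidelity of any particular tissue prediction; quantitative use
requires measured vessel spacings and supplies for the tissue at hand.

## Design choices on open points

* The cuboid cross-section is a square of side √2 × (center-to-edge
  distance), which reproduces all three quoted center-to-edge distances
  (88.4/123.7/176.8 μm ↔ sides ≈ 125/175/250 μm); the height is free
  (see z-invariance above).
* Percent-of-region metrics count non-vessel grid nodes, unweighted —
  on uniform grids this approximates the length/volume measure of the
  inter-vessel space while excluding the sources themselves.
* Threshold comparisons are inclusive for FEDMF (≥ 1.20) and
  strict-below for hypoxia (< 18.9 μM).
* The 3D midpoint probe sits midway between the center and one edge
  vessel at half height.
* CONV runs use the same 1500 steps as UHDR runs despite their much
  longer duration; the quasi-static CONV fields make the coarser dt
  harmless (grid-refinement tests cover this).
* Transient recruitment switches on at the start of irradiation for
  both deliveries and persists through recovery.

## Known limitations

* Four benchmark values in the reproduction suite disagree with their
  published reference numbers beyond tolerance, and deliberately remain
  failing: the 250 μm / 50.4 μM equilibrium summary (computed mean
  17.0 μM / 62.7% hypoxic vs 24.1 μM / 45%) and the three midpoint-trace
  endpoints (computed 2.65 / 5.31 / 41.8 μM vs 3.7 / 4.3 / 43.0 μM).
  The solver itself is corroborated at those operating points by an
  independent adaptive ODE/BVP integration, by closed-form equilibria,
  by grid-refinement checks, and by the adjacent equilibrium values
  (midpoints 47.6, 8.0, 2.5, <0.1 μM) and all eight FEDMF-fraction
  benchmarks, which match their references closely.  The computed
  midpoint passes 3.7 μM within ~0.03 s after the FLASH delivery ends,
  so reference values read slightly into the recovery phase would
  reproduce the discrepancy pattern exactly.
* K₁ constant across dose rates: measured G-values appear to drop at
  ultra-high dose rates, which this model ignores.
* No inter-track chemistry, no immune/vascular biology, no LQ survival
  mapping — FEDMF is an effective-dose ratio, not an outcome model.
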