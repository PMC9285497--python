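# Methods

`ooablate` simulates non-cooled, temperature-controlled radiofrequency
ablation (RFA) of an osteoid osteoma (OO) with axisymmetric finite
elements, and reproduces an in-silico study design: ablation-radius
dynamics versus control temperature, ablation time and the tissue
background surrounding the tumour.

## Physical model

**Thermal problem.** Tissue temperature obeys the Pennes bioheat equation
written in enthalpy form,

    dh/dt = div( k(T) grad T ) + Q_RF - Q_p ,

where `h(T)` is the volumetric enthalpy (J/m³), `k(T)` the thermal
conductivity, `Q_RF` the resistive heat source and
`Q_p = ω ρ_b c_b (T - T_b)` the blood-perfusion sink. The enthalpy method
absorbs the latent heat of water vaporization: below 99 °C `h` is the
sensible `ρ c (T - 37 °C)`; across 99–100 °C it ramps by `ρ h_fg C`
(`h_fg = 2.25 MJ/kg`, `C` the tissue water fraction); above 100 °C the
slope is `ρ_vap c_vap` (370 kg/m³ × 2156 J/kg·K). Materials with `C = 0`
(electrode metal, insulation) stay on the sensible branch at all
temperatures so the apparent heat capacity never vanishes.

**Electric problem.** At ~500 kHz the tissue is essentially resistive, so
the r.m.s. potential satisfies the generalized Laplace equation
`div( σ(T) grad V ) = 0`, refreshed every thermal step, with
`Q_RF = σ |grad V|²`. Electrical conductivity rises 1.5 %/°C of its 37 °C
baseline up to 100 °C, then collapses linearly over 100–105 °C to the
vaporized value `σ_vap = 0.01 S/m`. Thermal conductivity rises by an
absolute 0.003 W/(m·K) per °C and is capped at its 100 °C value (a config
switch selects a relative reading of the slope instead; the absolute
reading is the default).

**Boundary conditions.** Outer domain boundary: grounded (0 V) and held
at the body-core temperature (37 °C; 35 °C in the ex-vivo layout).
Symmetry axis: natural zero-flux for both problems. Electrode active tip:
Dirichlet at the applied r.m.s. voltage; the metal is excluded from the
electric solve (it is an equipotential region) but kept in the thermal
solve with its tabulated properties.

**Voltage control.** A discrete PI controller regulates the tip
temperature: `V = Kp e + Ki ∫ e dt`, `e = T_target - T_tip`, with
`Kp = 1.15 V/K` and `Ki = 0.06 V/(K·s)`. The integral uses a
left-endpoint rectangle rule at the heating time step; the first update
therefore acts with zero accumulated integral ("initial voltage zero").
The output is clamped at 0 V with the integrator frozen while clamped
(anti-windup; the underlying study is silent on windup handling and an
unfrozen integrator distorts the transient). The tip sensor is the node
at the distal apex of the active tip on the symmetry axis.

**Cell death.** Damage accumulates at every node by the Arrhenius
integral `Ω(t) = ∫ A exp(-ΔE / R T) dτ` with osteocyte kinetics
`A = 8.99e133 s⁻¹`, `ΔE = 838 kJ/mol`. The rate is evaluated in log space
(`ln A - ΔE/RT`, then exponentiated) because `A` overflows naive
double-precision products. `Ω ≥ 4.6` (99 % death probability,
`1 - exp(-Ω)`) marks death; an element whose mean nodal `Ω` crosses the
threshold loses its perfusion permanently. Each step uses the trapezoidal
mean of the endpoint temperatures; the choice is validated against
10×-finer arbitrary-precision quadrature in the test suite. After the
heating phase every simulation coasts through a 5-minute cooldown with
the generator off, during which damage keeps accruing while the tissue is
still hot.

**Outcome measure.** The cell-death radius is the outermost `Ω = 4.6`
crossing along two rays from the active-tip centre: perpendicular (+r)
and parallel (upwards, +z). The symmetry axis above the tip lies inside
the needle for all z, so the parallel ray runs just outside the shaft
insulation and reports axial distance from the tip centre. Because `Ω`
decays near-exponentially with distance, the nodal field is interpolated
in log space along the rays (sampled every 0.05 mm); interpolating `Ω`
itself across far-field elements overshoots by orders of magnitude and
would inflate the radius on coarse meshes.

## Tissue data

Seven materials (electrode, plastic, nidus, sclerotic layer, trabecular
bone, cortical bone, muscle) with density, baseline electrical and
thermal conductivity at 37 °C, specific heat, perfusion coefficient and
water fraction are shipped as a CSV registry
(`src/ooablate/data/tissue_properties.csv`); overrides are data, not
code. Blood properties are not part of that table and default to
`ρ_b = 1050 kg/m³`, `c_b = 3617 J/(kg·K)`, `T_b = 37 °C` — standard
values in the RFA-modelling literature, exposed in `ModelConstants` so
sensitivity to the choice is checkable.

## Scenario geometries (the synthetic-input generator)

The scenario factory emulates typical OO anatomies as 2-D axisymmetric
(r, z) half-planes, origin at the centre of the electrode active tip, all
dimensions configurable:

* common: 1 cm nidus sphere (half-disc of radius 5 mm); gauge-17
  electrode (0.7365 mm radius) with a 7.5 mm active tip centred on the
  nidus; 40 mm domain radius and half-height; outer layer of muscle.
* **a** — nidus + 1 mm sclerotic shell + trabecular bone out to r = 10 mm
  + 4 mm cortical wall + muscle.
* **b** — nidus in trabecular bone with a 1 mm gap to the 4 mm cortical
  wall (no sclerosis) + muscle.
* **c** — intracortical nidus: a cortical slab occupying r ≤ 30 mm,
  z ≤ 12 mm surrounds the tumour; muscle lies above and beyond the slab.
  The perpendicular ray thus travels through cortical bone (the
  longitudinal direction of the bone), while the parallel ray meets
  muscle 7 mm above the nidus.
* **validation** — ex-vivo bench layout: nidus cavity in bone behind a
  cortical lamella (3 mm default), soft tissue outside, probe points at
  0/5/10 mm from the periosteum, 35 °C initial and boundary temperature,
  perfusion disabled (ex-vivo tissue has no blood flow). The cavity
  filler reuses nidus properties; the real bench experiments used 0.8 %
  agarose gel, whose constants are not tabulated here — probe traces are
  therefore qualitative.

Only the topology and the headline dimensions of these layouts (1 cm
nidus, 7.5 mm tip, gauge 17, lamella 3 mm) are prescribed by the study
design; the remaining dimensions are this package's declared assumptions.
They were fixed so the model reproduces the qualitative behaviour
expected of these ablations (no vaporization at 90 °C control; smallest
radius in b, largest in c; lateral spread overtaking axial spread in c),
not tuned to any quantitative target. Two such choices deserve emphasis:

* the needle shaft above the active tip is modelled entirely as insulator
  (metal only in the tip). A full-radius steel core would act as a
  thermal fin that drags the ablation zone several millimetres up the
  shaft and makes the axial radius dominate in every scenario, at odds
  with the near-isotropic zones these procedures produce when the tumour
  sits in trabecular bone (scenarios a/b);
* scenario c's cortical slab extends far laterally with a 7 mm roof above
  the nidus: a thin roof lets current escape into the muscle and
  overheats the tissue pocket beside the insulated shaft past 100 °C.

## Discretization and numerics

* **Meshing.** Deterministic in-house mesher: region boundaries (shapely
  polygons; circular interfaces discretized at ≤ 0.12 mm) are resampled
  at a graded spacing `h(x) = clip(h_min + 0.35 d_tip, h_min, h_max)`
  with a curvature cap (≤ 0.12 rad of turning per segment) and a cap of
  0.45 mm near the electrode column so the thin shaft stays resolved at
  every level; interior points come from a graded quadtree (deterministic
  jitter breaks co-circular ties); Delaunay triangulation plus two
  pinned-boundary Laplacian smoothing passes; triangles are labelled by
  centroid location in the polygonized boundary network. Ladder of
  near-tip/far-field sizes: coarse 0.8/3.0, medium 0.4/2.4, fine 0.2/1.9,
  finest 0.1/1.5 mm. Per-region mesh areas match the analytic region
  areas to < 1 %. `fine` is the default working resolution.
* **Space.** P1 triangles, axisymmetric weak form with exact first-order
  volume weighting (`∫ r dA = A r_c` per element). Mass (apparent heat
  capacity) and perfusion terms are lumped.
* **Time.** Backward Euler: dt = 0.25 s during heating (also the
  controller update interval) and 1 s during cooldown, both configurable
  and validated by a dt-halving invariance test (< 1 % radius change).
  The enthalpy nonlinearity is resolved by Picard iteration (tolerance
  `max |ΔT| < 1e-3 °C`, at most 5 iterations) using the chord (secant)
  apparent capacity per element-node pair, exactly consistent with the
  nodal enthalpy residual; the tangent capacity is the fallback for
  vanishing increments and an oscillating iteration is damped by
  averaging. The chord form is what keeps nodes stable while crossing the
  stiff 99–100 °C latent ramp.
* **Coupling order per step:** read tip temperature → PI update → electric
  solve with σ(T) (values reassembled on a fixed sparsity pattern) →
  implicit thermal step → damage and viability update.
* **Linear algebra.** Reduced systems (Dirichlet rows eliminated via
  precomputed scatter maps) solved with SuperLU each step.
* **Degenerate inputs.** Zero heating time yields zero radii and an
  untouched temperature field; a probe outside the domain, an unknown
  scenario/tissue/level, non-positive conductivity or time step are all
  rejected with named errors; non-finite temperatures or a diverging
  Picard iteration abort the run.

## Verification

Independent oracles (no code shared with the solvers): concentric-
cylinder potential/conductance closed form (< 0.5 % at working
resolution, error ratio ≳ 3 per mesh halving); fundamental conduction
eigenmode of a finite cylinder via the first Bessel zero, cross-checked
by a 1-D radial finite-difference eigensolver (0.03 % agreement);
arbitrary-precision (mpmath, 50 digits) Arrhenius rates and damage
quadrature. Per-step energy balance (lumped enthalpy change vs RF input,
perfusion loss and boundary flux) closes to < 1 %. Robustness checks:
halving dt, doubling the domain and refining the mesh each move the final
radius by ≲ 1–2 %.

The test suite scales the study down where full length is not the point:
the scenario × temperature grid runs 5 min of heating on the coarse mesh,
the sensitivity sweep uses the medium mesh with a 0.5 s heating step, and
the convergence check heats for 3 min. Full 15 + 5 min fine-mesh runs are
kept where the claim is about the full procedure (vaporization bound,
tumour coverage, set-point hold). Passing on these synthetic anatomies
shows the solver and study logic are sound; it does not validate the
model against clinical imaging or in-vivo temperatures, and the
simplified rectangular-bone anatomy, literature property values and the
absence of the agarose filler bound what the ex-vivo comparison can show.

## Known limitations

* Radii are measured from the electrode centre; the parallel ray is
  offset to just outside the 0.74 mm shaft rather than on the axis.
* The quasi-static electric model has no generator impedance limits,
  power cap or pulsing; the controller output is unbounded above.
* The nidus conductivity sensitivity of the final perpendicular radius
  is about +10 % / −12 % here (comparable computational studies report
  ≈ ±15 %); the absolute radii are correspondingly somewhat larger than
  typical published necrosis-zone sizes, which we attribute to the
  background-geometry dimensions this package had to assume.
* No tissue shrinkage, water transport, or alternative damage models
  (CEM43, two-state); perfusion is binary-gated by viability.
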