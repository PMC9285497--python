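# ooablate

Finite-element modelling of temperature-controlled radiofrequency
ablation (RFA) of osteoid osteoma (OO).

RFA is the standard treatment for osteoid osteoma: a gauge-17 electrode
with a 7.5 mm active tip is advanced into the 1 cm tumour core (the
*nidus*) and the generator holds the tip at a control temperature
(commonly 90 °C) for several minutes. How large the resulting ablation
zone becomes — and whether it reliably covers the tumour — depends not
only on the protocol (control temperature, ablation time) but strongly on
the tissue *behind* the tumour: sclerotic rim, trabecular bone, or a
fully intracortical position. `ooablate` is a research code for exploring
exactly that, aimed at computational-biophysics and treatment-planning
researchers.

## Model

Axisymmetric (r, z) coupled electric–thermal problem:

* quasi-static potential, `∇·(σ(T) ∇V) = 0`, electrode tip at the applied
  r.m.s. voltage, grounded outer boundary; Joule heating `Q_RF = σ|∇V|²`;
* Pennes bioheat equation in enthalpy form,
  `∂h/∂t = ∇·(k(T)∇T) + Q_RF − Q_p`, with the perfusion sink
  `Q_p = ω ρ_b c_b (T − T_b)` and the enthalpy method for the latent heat
  of vaporization (99–100 °C ramp);
* discrete PI control of the electrode voltage,
  `V = K_p e + K_i ∫e dt`, `e = T_target − T_tip`
  (`K_p = 1.15 V/K`, `K_i = 0.06 V/K/s`);
* Arrhenius cell-death integral `Ω = ∫A e^{−ΔE/RT} dt`
  (`A = 8.99·10¹³³ s⁻¹`, `ΔE = 838 kJ/mol`); `Ω ≥ 4.6` (99 % death
  probability) defines the ablation boundary, and dead tissue stops
  perfusing. Every run ends with a 5-min generator-off cooldown during
  which damage keeps accruing.

Four built-in anatomies: **a** (nidus + sclerotic rim + trabecular +
cortical + muscle), **b** (no rim, trabecular background), **c**
(intracortical nidus), and an ex-vivo **validation** bench layout with
temperature probes at 0/5/10 mm from the periosteum. Meshing, property
tables, solvers and the study pipeline are all part of the package — no
external input data are needed. See `docs/methods.md` for assumptions,
numerics and limitations.

## Worked example

Simulate the standard protocol (90 °C, 15 min + 5 min cooldown) for the
sclerotic-rim anatomy:

```sh
ooablate run --scenario a --control-temp 90 --heat-time 900 \
             --cool-time 300 --resolution fine --out results/a90
```

which prints

```
ooablate run report
===================
scenario           : a
control temperature: 90.0 C
heating / cooldown : 900.0 s / 300.0 s
mesh               : fine (1283 nodes, 2335 triangles)
time steps         : 0.25 s heat, 1.0 s cool
seed               : 0

peak temperature anywhere     : 91.99 C
final tip temperature         : 50.93 C
final perpendicular radius    : 13.00 mm
final parallel radius         : 14.18 mm
final ablation diameter (perp): 26.00 mm
```

Reading: the controller held the tip at 90 °C without any tissue reaching
the 100 °C vaporization point (peak 92.0 °C); after 15 min of heating and
5 min of passive cooling the Ω = 4.6 cell-death isoline lies 13.0 mm from
the electrode axis — an ablation diameter of 2.6 cm, comfortably covering
the 1 cm tumour. `results/a90/` also holds the full time series
(voltage, tip/max temperature, both radii every 5 s) as CSV and VTU field
snapshots viewable in ParaView.

The study pipeline is available both from Python
(`ooablate.experiments`) and the CLI: `ooablate grid` (scenario ×
temperature radius table), `ooablate sweep` (nidus conductivity/perfusion
sensitivity), `ooablate converge` (mesh ladder), `ooablate profiles`
(Q_RF and temperature line profiles).

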