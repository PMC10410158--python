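# Methods

## Model

The network is a symmetric rooted binary tree of straight cylindrical
segments: an inlet channel followed by `n` bifurcation generations
(default `n = 3`, giving 15 segments and 8 outlets). Radii follow a
generalized Murray taper with equal daughters, `r_child =
r_parent · 2^(−1/m)` per generation. Flow is steady, laminar,
incompressible and Newtonian; each segment is a Hagen–Poiseuille
resistor `R = 8μL/(πr⁴)` and the network is solved as a sparse symmetric
nodal-pressure system (mass conservation at junctions, prescribed inlet
flow, one reference pressure shared by all open outlets, exact zero flow
through occluded terminals). Wall shear stress uses the fully developed
closure `τ = 4μQ/(πr³)`; cross-scenario WSS prediction rescales a
reference table by branch flow-fraction ratios, which is exact for any
flow-linear WSS measure at fixed geometry.

These assumptions are appropriate for the regime modeled: water at room
temperature in sub-millimetre channels at ~200 µL/min gives tube
Reynolds numbers of order 10 at the inlet and below 5 in the branches,
far from transition, and pulsatility is neglected because arteriolar
flow is heavily damped. Vessel compliance, non-Newtonian rheology and 3D
junction effects are out of scope.

## Parameters

| parameter | default | units | rationale |
|---|---|---|---|
| inlet diameter | 1.0e-3 | m | fabricated device inlet |
| outlet diameter | 0.4e-3 | m | fabricated device outlets |
| generations | 3 | — | 8 outlets |
| total path length | 1.0e-2 | m | in-to-out length of the device |
| length fractions | equal | — | no length grading evident in the device; configurable |
| Murray exponent | inferred (≈2.2694) | — | see below |
| bifurcation half-angle | 30 | deg | layout/export only; a 0D model is angle-independent |
| density | 1000 | kg/m³ | water, ~20 °C nominal |
| viscosity | 1.0e-3 | Pa·s | water, ~20 °C nominal |
| inlet velocity | 0.012 | m/s | measured boundary condition (velocity mode) |
| inlet flowrate | 3.25e-9 | m³/s | 195 µL/min pump setting (flowrate mode) |

The printed endpoint diameters (1 mm → 0.4 mm over three generations)
are inconsistent with the strict exponent-3 Murray taper, which would
end at 0.5 mm. The default therefore infers the exponent that honors
both printed diameters, `m = n·ln2/ln(d_in/d_out) ≈ 2.2694`; passing
`murray_exponent=3.0` selects the strict taper (making the outlet
diameter nominal). Both modes are first-class because the fabricated
device's intent cannot be recovered from the published dimensions.

Two further documented inconsistencies are retained rather than
reconciled: the inlet velocity (0.012 m/s ≈ 565 µL/min through a 1 mm
tube) and the pump rate (195 µL/min) disagree, so both are independent
config constants selected by `FlowBC.inlet_mode`; and the computed
maximum Reynolds number under the stated conditions is 12, not the 0.018
sometimes quoted for this regime — the package always reports computed
Re per segment.

## Measured tables and scenario reconstruction

The packaged out-split table records, per scenario, each outlet's
collected flowrate and its dimensionless out-split. Its flowrate
magnitudes are treated as relative readings: the declared unit is not
physically consistent with the pump setting, so only the out-splits feed
the model, with absolute inlet flow taken from configuration. Printed
out-splits are used raw by default (`case_3/8` sums to 1.01 from
rounding); a `renormalized()` view exists but is off because raw values
reproduce the reference WSS table best. The occlusion sets of the
built-in scenarios ({}, {O3}, {O1,O2,O3}, {O1,O2,O3,O5,O8}) are
reconstructed from the zero rows of the split table and cross-checked in
tests against the near-zero entries of the reference WSS table; the
branch↔outlet topology (`Cg-Bk` labeled left-to-right, terminal `Bk`
draining `Ok`) is an assumption consistent with both tables.

## Absolute versus rescaled WSS

The Poiseuille closure gives 0.096 Pa for the inlet channel at
0.012 m/s, whereas the reference 3D CFD value for that branch is
0.36 Pa — a factor ≈3.75 attributable to entrance effects under a flat
inlet profile and to 3D junction flow, which a fully developed 0D
closure cannot represent. Absolute Poiseuille values are therefore
emitted with `model` provenance for transparency but are not validated;
validated cross-scenario predictions come from the rescaling route,
whose fraction ratios cancel geometry-dependent prefactors. Reference
fractions default to the measured control out-splits rather than the
idealized 0.125, because the reference WSS table was computed with
measured splits.

## Numerical choices

* Linear solve: scipy sparse `spsolve` on the nodal conductance matrix;
  solutions are checked for finiteness and global mass closure at 1e-10
  relative. Occlusion is an exact constraint (the blocked terminal is
  removed from the system and assigned zero flow, its dead-end node the
  parent pressure), not a large finite resistance — this keeps the
  matrix well-conditioned for any pattern.
* Split mode computes no pressures (`node_pressure = None`): with flows
  prescribed everywhere the pressure field is overdetermined unless the
  splits happen to satisfy the resistance model.
* Table reproduction rounds half-away-from-zero to 2 decimals, matching
  the reference table's formatting; `wss_summary` treats values at or
  below 0.05 Pa as zero when counting unperfused branches, absorbing the
  0.01–0.02 Pa numerical residue the reference CFD leaves in occluded
  branches.
* Report files are written with fixed float formatting and sorted keys
  so identical inputs give byte-identical output.

## Synthetic data

`simulate_measurements` emulates the volume-collection experiment: solve
the resistance network at the pump rate (default 195 µL/min), convert
outlet flows to volumes over the collection time (default 60 s), apply
multiplicative measurement noise per outlet, zero occluded outlets
exactly, and normalize by the measured total. Noise is multiplicative
because pipetting and meniscus-reading errors scale with volume; the
default relative sd of 0.03 is calibrated to the spread of the measured
control out-splits (0.121–0.129 around 0.125). A truncated-Gaussian
factor is the default, with a mean-one lognormal option. Fabrication
jitter perturbs each segment radius by half a Gaussian width deviation
whose sd places the reported 20 µm maximum width variability at the
~99th percentile. All draws descend from one seed through per-outlet
(per-segment) substreams derived by counter, so enlarging the tree never
reshuffles existing draws.

The generator reproduces the statistical structure the analysis assumes
— multiplicative noise, exact zeros at blocked outlets, radius jitter —
but not features of the real bench data it does not model: leak flows,
temporal drift of the pump, correlated pipetting errors, or deviation of
the true error law from the assumed families. Passing recovery tests
therefore demonstrate internal consistency of the estimator under the
assumed noise model, not bounds on real measurement error.

## Problem sizes

The default study is the full published configuration: the 15-segment,
8-outlet tree, all four scenarios, and the exhaustive 255-pattern
occlusion sweep for the solver/oracle equivalence check. Monte-Carlo
checks use 200 replicates for split recovery and tens of replicates per
pattern for occlusion detection; everything runs in seconds on one CPU.

## Limitations

A 0D network cannot resolve spatial WSS fields, entrance regions,
junction secondary flows, or oscillatory WSS metrics; absolute WSS from
the Poiseuille closure is biased low in short branches (see above).
Compliance, pulsatility and blood rheology are excluded by construction.
The branch↔outlet labeling is inferred, not documented by the source
tables; if a future dataset contradicts it, only the label mapping —
not the solver — needs changing.
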