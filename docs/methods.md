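# Methods

## Model

`cryopvi` simulates cryoballoon pulmonary-vein isolation (PVI): a
refrigerant-cooled balloon occludes a pulmonary vein (PV) ostium and freezes
the surrounding tissue, creating a circumferential necrotic lesion that
blocks the ectopic triggers of atrial fibrillation.

Tissue temperature obeys the Pennes bioheat equation

    rho c dT/dt = div(k grad T) + Wb Cb (Ta - T) + Qm

with density `rho`, specific heat `c`, conductivity `k`, blood perfusion
mass rate `Wb = omega * rho_blood` (volumetric perfusion
`omega = 0.012 mL s^-1 cm^-3`), blood specific heat `Cb`, arterial
temperature `Ta = 310.15 K`, and metabolic heat `Qm` (zero by default: it is
explicitly zero for the solid polyurethane balloon and no tissue value is
specified, consistent with near-quiescent vascular tissue on the timescale
of a 240 s freeze).

Material regions and their properties (SI):

| region            | k (W/mK) | c (J/kgK) | rho (kg/m^3) | T0 (K) |
|-------------------|---------:|----------:|-------------:|-------:|
| blood             | 0.54     | 4000      | 1057         | 310.15 |
| vascular wall     | 1.3      | 3600      | 1200         | 310    |
| polyurethane      | 0.02     | 1500      | 1110         | 198.15 |
| pulmonary tissue  | 0.03     | 2963      | 1000         | 311    |

### Geometry

The vein is modeled as concentric cylinders 60 mm long, rotationally
symmetric about its axis, so the computation is a 2-D axisymmetric (r, z)
problem. Radially: the blood-filled lumen (ostium radius per vein preset),
then a pulmonary-tissue layer, then the vascular wall outermost. This
layer ordering follows the source model's description and is the only
arrangement consistent with its reported measurements: the balloon-to-wall
distances (~3.9-4.1 mm) exceed the lesion half-depths (~1.5-2.1 mm), i.e.
the freeze front stops inside an insulating tissue layer *before* reaching
the wall, and thicker balloon-to-wall distances pair with shallower depths.
A configuration switch (`layer_order`) selects the anatomically conventional
wall-adjacent ordering instead; with it, the balloon contacts the
high-conductivity wall directly and lesions come out roughly twice as deep.

The pulmonary-layer thickness is not specified by the clinical tables we
reproduce; the default is 10 mm, large enough to contain the -15 degC front
in every therapy. Because the front never reaches the wall, the simulated
depths are insensitive to this choice (identical to 3 significant figures
between 4 mm and 10 mm layers).

The cryoballoon is an ellipsoid, 23 mm across the equator and 20 mm pole to
pole, centered on the axis. It is wider than every ostium (12-19 mm), so the
ellipsoid is clipped by the lumen cylinder, producing a direct contact band
against the innermost tissue layer — the clinical intent of occlusive
positioning. The contact-band half-height is
`(H/2) sqrt(1 - (r_lumen / (D/2))^2)` (e.g. 8.53 mm for a 12 mm ostium).

Four vein presets (ostium diameter / wall thickness, mm): right superior
18/2.7, right inferior 12/1.8, left superior 19/2.8, left inferior 13/1.9.
The clinical records do not state which vein each patient received, so the
default cohort vein is the left superior PV — the largest preset and
conventionally the first vein treated in cryoballoon PVI.

### Boundary forcing: the therapy schedule

Each patient's log supplies thermocouple milestones: TZ (0 degC), TI
(-30 degC), TM (maximum cold, "time to isolation"), the maximum temperature,
and the total time TT = 240 s. The balloon surface temperature is
interpolated piecewise-linearly through (0 s, 36.7 degC), (TZ, 0), (TI,
-30), (TM, max), held at the maximum until TT - 30 s, then returned linearly
to body temperature (36.7 degC) at TT. The 30 s rewarm duration is a
configurable default; the records pin only the endpoint. Two identical
freeze/thaw cycles are concatenated (one milestone set is recorded per
patient, so the second cycle duplicates the first).

The schedule is imposed as a Dirichlet condition *on the balloon surface*
(the balloon-adjacent cell faces), since the thermocouple reads the surface:
interposing the polyurethane's own resistance would re-insulate a measured
boundary temperature. The balloon interior is slaved to the same value, and
initialized at 36.7 degC (the thermocouple reading at insertion), not at the
polyurethane library default of 198.15 K, which applies to the opt-in flux
mode. That alternative Neumann mode applies the reported surface flux
magnitude (-151,924.04, interpreted as W m^-2; the printed unit is
dimensionally inconsistent) over the contact surface.

### Perfusion switching

The perfusion sink `Wb Cb (Ta - T)` acts in the vascular wall and pulmonary
tissue only while the local temperature is above 0 degC: capillary flow
ceases in frozen tissue. In the lumen, the same sink is the stand-in for
advection by flowing blood (the full CFD of intraluminal flow is out of
scope) and therefore stays on at all temperatures — flow past the balloon
does not stop because a cell's temperature crossed 0 degC. Applying the
cutoff to lumen blood turns the frozen boundary layer into a sink-free
high-conductivity conduit that carries cold along the balloon surface and
inflates lesion depths by ~2 mm; the distinction matters.

## Numerics

Cell-centered finite volumes on a uniform (r, z) grid fitted exactly to the
geometry; harmonic-mean conductivity at material interfaces (exact steady
flux across discontinuities); symmetry at r = 0 (zero-area face); insulated
far z-ends; exterior radial boundary held at the undisturbed initial
temperature of the outermost layer.

Time integration is backward Euler by default (Crank-Nicolson optional) in
the conduction operator. The perfusion sink is treated explicitly with a
lagged frozen-state mask: its rate constant `Wb Cb / (rho c)` is ~0.01-0.02
s^-1, so at dt <= 0.5 s the explicit coupling is far from any stability
limit, and it keeps the system matrix constant across a run — one sparse LU
factorization serves all ~4800 steps. Steady-state solves (used by the
verification oracles) treat perfusion fully implicitly and iterate the
frozen mask to a fixed point.

Verification, all exercised in the test suite:

- steady quasi-1-D solution vs the closed form
  `T = Ta + (Ts - Ta) exp(-x/delta)`, `delta = sqrt(k/(Wb Cb))`:
  L-inf relative error 0.04% at 0.1 mm cells;
- manufactured axisymmetric solution: observed spatial order 2.00;
- discrete energy conservation (perfusion off): enthalpy change matches the
  time-integrated boundary heat rate to ~1e-12 relative;
- maximum principle and monotone freeze-phase cooling on all patient runs;
- bitwise determinism of repeated runs.

Default resolution: 0.15 mm cells, dt = 0.1 s, chosen by convergence study
on the lesion depth. Depths are timestep-converged at dt = 0.1 s (identical
to 3 decimals vs dt = 0.05). Spatially, 0.25 mm under-resolves the front by
~0.5 mm, 0.15 mm sits within ~0.15 mm of the Richardson-extrapolated value,
and 0.1 mm buys ~0.1 mm more at ~3x the cost; a full two-cycle patient run
at defaults takes roughly one minute on one CPU (grid ~149 x 400).

An optional apparent-heat-capacity latent-heat term (250 kJ/kg spread over
the 2 degC below freezing) is available for sensitivity studies and off by
default, matching the base model, which treats freezing through the
perfusion cutoff and temperature-independent properties only.

## Lesion measurement

Cryoinjury is classified by temperature band: 0 to -15 degC
membrane-resistant (the membrane blocks ice nucleation over short
exposures); -15 to -20 extracellular ice (heterogeneous nucleation, onset of
persistent damage); -20 to -30 intracellular ice; -30 vasoconstriction
marker; at or below -40 homogeneous nucleation and irreversible cell death.
Boundaries belong to the colder zone.

The lesion front is the -15 degC isotherm restricted to tissue, extracted
per axial row as the outermost linear-interpolated crossing (cross-checked
against marching-squares contours in the tests); the 0 degC contour is
retained as the display boundary of thermally affected tissue. Because
freezing injury is irreversible, the lesion is evaluated at the end of the
final freeze phase (t = cycles*TT - rewarm, 450 s by default) — at the end
of the thaw the warmer therapies' isotherms have vanished even though their
tissue was frozen for minutes.

Lesion depth A is twice the largest normal distance from the clipped balloon
surface to the front; width B is fixed at 23 mm, the inflated balloon
diameter (the second-generation balloon's equatorial cooling band makes
lesion width position-independent). The cross-section area is the ellipse
formula `area = pi (A/2) (B/2)`. The library computes with full-precision
pi; `printed_lesion_area` reproduces the clinical reporting convention (pi
to two decimals, half-up rounding to two decimals, in exact decimal
arithmetic). Cohort statistics are mean +/- population (divisor-n) standard
deviation, the only form consistent with both reported cohort spreads.

The reported balloon-to-wall distance is a diagnostic: the distance from the
balloon surface to the nearest vascular-wall cell at the axial level of
deepest front penetration. The construction behind the clinical table's
corresponding column is unpublished, so this column is reported, not
matched.

## Synthetic therapy logs

`generate_fixture_logs` draws integer milestones uniformly from the observed
cohort ranges (TZ 8-13 s, TI 23-36 s, TM 32-42 s, maximum temperature -63 to
-41 degC, TT = 240 s), rejection-sampling until TZ < TI < TM. These emulate
the recorded therapy conditions only; they do not model correlations between
milestones and maximum temperature, thermocouple lag, or within-patient
cycle-to-cycle variation, so passing tests on synthetic logs demonstrate
pipeline correctness under realistic magnitudes, not clinical predictive
validity.

## Known limitations

- Intraluminal blood flow is a volumetric sink, not advection; near-balloon
  convective patterns are not represented.
- Homogeneous layers and perfect coaxial balloon positioning; no balloon
  deformation or patient-specific anatomy.
- Thermal properties are temperature-independent; latent heat is off by
  default.
- One patient record (maximum -63 degC) yields a simulated depth of 4.63 mm,
  slightly above the 4.5 mm upper edge of the physiologic comparison band
  used in the acceptance tests; the two clinical tables disagree on that
  patient's maximum (-63 vs -61 degC), and the colder value is used.
- The two clinical cycles are assumed identical; only one milestone set per
  patient is recorded.
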