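# Methods

`airwayrfa` simulates radiofrequency ablation delivered through a liquid-metal
electrode cast inside the bronchial tree: a gallium–indium eutectic
(σ = 3.4×10⁶ S/m, k = 9.8 W·m⁻¹·K⁻¹) injected into the airway lumen turns the
branching bronchus into a temporary, anatomy-conforming RF electrode.  This
note records the model, its assumptions, the parameters that matter, and the
choices made where the design was genuinely open.

## Model

**Electrostatics.**  At 480 kHz with centimetre-scale geometry the drive
wavelength is metres, so the field is quasi-static: the potential solves the
variable-coefficient conduction problem ∇·(σ∇φ) = 0 with Dirichlet φ = V₀ on
the source set and φ = 0 on the grounded face, homogeneous Neumann elsewhere.
Displacement currents, capacitive coupling and full-wave effects are ignored.
The discretisation is a 7-point finite-volume stencil on the isotropic voxel
grid with harmonic-mean face conductivities (the correct series-resistance
composition across material interfaces), solved by Jacobi-preconditioned
conjugate gradients to a relative residual of 10⁻⁸.  The discrete operator is
an M-matrix, so the maximum principle holds voxel-wise; source-to-ground
current conservation closes to the solver residual (≲10⁻⁷ relative).

The metal cast is imposed as an equipotential Dirichlet set rather than
meshed: its conductivity is six to seven orders above tissue, and meshing it
would poison the conditioning for no physical gain.  The harmonic-mean face
between a Dirichlet metal voxel and tissue naturally reduces to "half a
tissue cell of resistance", i.e. no drop inside the conductor.  A
conductive-*fluid* cast (saline 0.113 S/m, gold-nanoparticle suspension
0.138 S/m) is instead driven only at the injection-point voxel, so the drive
sags along the resistive fluid column — the physical reason such infusates
make poor electrodes.

**Heat source.**  The time-averaged volumetric deposition of a sinusoidal
drive of amplitude E is U = σ|E|²/2 (W/m³).  E comes from central differences
of φ; inside the equipotential cast E ≡ 0 (field-free conductor).  Total
power is P = ΣU·v and the generator-seen impedance Z = V₀²/(2P).  The
volume-integral P differs from the flux power V₀I/2 by the discretisation
error of the gradient (a few percent at 1 mm); all lumped quantities are
defined consistently from P.

**Bioheat.**  Temperature follows the Pennes equation

ρc ∂T/∂t = ∇·(k∇T) + ρQ + U − ρ_b c_b ω (T − T_b),

with harmonic-mean face conductivities, Dirichlet T = T_b (37 °C body-core
bath) on all domain faces by default, and an insulated (Neumann) variant for
energy-balance checks.  The published form of the perfusion term in the
source literature carries a typographical extra density factor; the standard
Pennes sink ρ_b c_b ω (T−T_b) with ω in s⁻¹ is used.  Two integrators are
provided: explicit Euler with an automatic step obeying
dt ≤ min(ρc·h²/(6k)) (transparent, used by the oracle tests), and backward
Euler via a conjugate-gradient solve per step (unconditionally stable, used
for production runs where lumen air — thermal diffusivity two orders above
tissue — makes the explicit bound impractically small).  With the insulated
boundary the explicit scheme conserves energy to round-off by construction.

**Sensor.**  The catheter thermocouple sits in the metal column at the
distal tip.  Because the cast conducts heat well, its volume-mean temperature
tracks the average of the ablated tissue; the primary sensor reading is
therefore the volume mean of T over the cast, with the tip-voxel point
reading reported alongside.  Whether the original device telemetry is better
modelled as a point probe or an average is not stated anywhere authoritative;
both are exposed.

**Generator.**  The temperature-controlled mode holds the sensor at the
80 °C set-point by a clamped integrating update, V₀ ← clip(V₀ + K_p·(80 −
sensor), 50, 80) V with K_p = 0.5 V/°C at a 1 s control interval, starting
from the 50 V lower bound (soft start).  With constant σ the field is solved
once at unit amplitude and rescaled by V₀² (exact for the linear problem);
with the temperature-dependent model the conductivity grid is rebuilt from
the current temperature and the solve warm-started every interval.  A run
terminates at the preset time (300/600/900 s) or when the impedance rises
over 250 Ω.  "Rises" is taken literally: the cut-off fires only when Z
exceeds both the threshold and 1.05× its starting value, so a barely
conducting configuration with a large but constant impedance runs to its
time limit rather than tripping at t = 0.

**Conductivity roll-off.**  Tissue σ(T) = σ₀(1 + 0.015(T−37)) below 99 °C
and 0.01σ₀ at and above it.  The linear term is the usual ionic-mobility
slope; the collapse is a deliberately simple surrogate for desiccation, the
mechanism that makes the 250 Ω cut-off reachable.  It is applied to the
instantaneous temperature; in an over-driven run the peri-electrode shell
does not cool while driven, so the collapse is effectively irreversible
there.

**Lesion classes.**  Peak temperature is thresholded: Tmax ≥ 60 °C = necrotic
CORE (cell death nearly instantaneous), 42–60 °C = TRANSITIONAL
(mixed-viability rim, the ground-glass halo on imaging), below 42 °C =
UNAFFECTED.  Both bounds are inclusive at the lower edge; making 60 °C
inclusive for CORE matches the "60 °C or higher" efficacy convention and is a
convention, not a derived fact.  An Arrhenius/CEM43 dose integral would be
the natural refinement; thresholds are exposed as parameters so such a hook
can be added, but temperature thresholding is the primary model because the
source reasoning is entirely in temperature thresholds.

## Synthetic geometry

The airway generator produces a seeded binary tree with geometric taper:
generation-g segments have proximal radius r₀·ρ^g and length L₀·λ^g with
defaults r₀ = 1.5 mm, ρ = 0.8, λ = 0.75, branch angle 35°, trunk length
20 mm.  Depth 3 gives 15 segments, distal radii 0.77 mm, and a total lumen
volume of 0.43 ml — deliberately at the scale of the ~0.46 ml mean injected
dose of the study conditions.  Jitter perturbs lengths and angles only, never
radii, so the taper invariants hold for every seed.  The electrode fill
advances proximal-to-distal, splitting equally at bifurcations with
redistribution when a subtree saturates; partial fills solve the frustum
cubic exactly, so the filled volume matches the request to ≪1 %.

Rasterisation labels voxel centres inside the flat-capped frusta, stamps a
face-connected chain of voxels along each filled axis (thin branches would
otherwise fragment at coarse spacing), and applies the precedence
ELECTRODE > TUMOR > MUSCLE/ORGAN > AIRWAY_AIR > PARENCHYMA.  Coordinates are
0-based voxel indices with voxel-centre positions and half-open physical
extent.

**Catheter sheath.**  The injection end of a real cast is not bare metal:
the liquid column enters through an insulated balloon-tipped guiding
catheter.  A bare flat proximal cap in the model is a strong artificial
field concentrator (edge singularity) that the device does not have, so
`rasterize` can wrap the proximal portion of the trunk in an insulating ring
plus back-cap (`sheath_length`, default 5 mm in the experiment configs; the
branched reference config sheathes the whole 20 mm trunk, i.e. the balloon
sits at the first carina).  With the sheath in place the field concentrators
are the sharp terminal tips, as they should be.

**Resolution.**  Production experiments run at 1 mm spacing (domains of
2–4×10⁵ voxels).  The tip-first-heating analysis runs at 0.5 mm because the
0.77 mm terminal radii are unresolved at 1 mm — there the discrete hot spot
can land on a staircase edge of the sheath instead of a tip.  Rasterisation
refuses spacings that do not put at least one voxel across the smallest
filled diameter.

## Material table

Defaults (config, not constants — every experiment logs its table):

| label | σ (S/m) | k (W/m/K) | ρ (kg/m³) | c (J/kg/K) | ω (1/s) |
|---|---|---|---|---|---|
| parenchyma (inflated lung) | 0.10 | 0.39 | 394 | 3886 | 0.001 |
| airway air | 10⁻⁵ (floor) | 0.03 | 1.2 | 1005 | 0 |
| electrode (Ga-In) | 3.4×10⁶ | 9.8 | 6250 | 404 | 0 |
| conductive fluid | 0.113 / 0.138 | 0.60 | 1000 | 4180 | 0 |
| tumor (muscle-like) | 0.45 | 0.52 | 1079 | 3540 | 0.0009 |
| muscle / organ | 0.45 | 0.49 | 1090 | 3421 | 0.0007 |

Blood: ρ_b = 1050 kg/m³, c_b = 3617 J/kg/K, T_b = 37 °C.  The metal's σ and
k are the published alloy values; the fluid σ values are the published
infusate values; tissue values are literature-style defaults at ~500 kHz.
Metabolic heat defaults to zero (negligible against ablative SAR over
≤15 min).  The conductivity floor on air keeps the operator positive
definite without opening a conductive path; it is a numerical convention,
not air physics.  An ex-vivo variant zeroes all perfusion.

## Experiment configs and their calibration

The study conditions leave the per-run drive amplitude, durations per figure
and the simulated ground geometry unstated; each experiment config pins
them, and the efficacy-limit results are bracketing checks, not point
reproductions.

*Geometry sweeps* (length 3–8 cm at 3 mm diameter; diameter 2–8 mm at 3 cm)
run open loop — fixed V₀ = 80 V, constant σ, 300 s — so the geometric effect
is not masked by control compensation.  The ground pad sits behind the
proximal face (the return path lies behind the injection site), which is
what makes length matter: the farther the tip from the return path, the
weaker its local field.  Effectiveness is judged at a distal evaluation
probe, a 2 mm-radius ball of target tissue centred 3 mm beyond the cast tip
— the nodule the cast is meant to treat.  The tissue gap between the lumen
and the grounded muscle slab (20 mm) and the probe stand-off were calibrated
on the base 3 cm / 3 mm case so that the stated reference configurations are
comfortably effective; with that single scale fixed, the sweeps themselves
produce the limits (largest effective length 3 cm; smallest ineffective
diameter 6 mm).  Open-loop constant-σ runs overshoot physiologic peak
temperatures near the cast (no desiccation brake); they are geometric
probes, and only the distal-probe and threshold quantities are interpreted.

*Branched-versus-straight*, *fluid comparison*, *pseudotumor* and the
*reference run* use a lateral ground (the ex-vivo muscle-wrap analogue) with
a 20 mm gap and the closed-loop 80 °C protocol (fluids: open loop, identical
drive for all three media).  The branched cast is compared against a rod of
identical lumen volume (same root radius, length set by the volume match,
enforced at 2 %).  The branched advantage is a property of
temperature-controlled operation — holding the sensor at the set-point, the
multi-tip cast spreads its regulated power over a larger envelope — and the
comparison runs under that mode accordingly; under a fixed-amplitude drive
the two geometries couple comparable energy and the ratio collapses to ~1.
The mesh-robustness check of the ratio runs on a branched geometry whose
every branch radius spans at least two voxels on both grids compared, so
that the check probes the physics rather than rasterisation volume error.

*Safety distance* places a 5 mm non-target organ slab at increasing
stand-offs beyond the tip under the closed-loop protocol and reports the
smallest stand-off with zero organ necrosis.

*Pseudotumor focusing* is judged on volume means, not voxel-wise maxima:
the discrete near-field of a Dirichlet cast always produces ~100 °C
field-crowding spots in the one-to-two-voxel contact sleeve (carina
crotches, the ground-side sleeve), and a voxel-wise "hottest parenchyma"
comparator is dominated by them no matter where the tumor sits.  The
physical probes of interest are sensors placed in tissue, so
`pseudotumor_focus` excludes the two-voxel contact sleeve from both sides
and reports peak and mean temperatures for the tumor and for the
distance-matched parenchyma band; the focusing statement (tumor hotter
than normal lung at matched distance from the cast) holds on the means.

## What the synthetic data does and does not emulate

The generator reproduces the features the downstream physics needs: a
monotone-tapering rooted airway, a contiguous proximal-to-distal fill at the
study-scale dose, aerated parenchyma, a grounded chest-wall layer, a
muscle-like pseudotumor and a nearby organ surface.  It does not attempt CT
realism: no airway-wall tissue, no deformation or edema (hence no
booster-injection dynamics), no vascular tree or large-vessel heat sink, no
injection fluid dynamics, and lung material properties are homogeneous.
Passing tests therefore demonstrate the electro-thermal mechanism chain on
an idealised anatomy, not patient-level prediction.

## Numerical choices and degenerate inputs

- CG tolerances: 10⁻⁸ (potential), 10⁻¹⁰ (implicit bioheat step), both
  Jacobi-preconditioned and warm-started where a previous solution exists.
- Explicit stability bound is enforced with an error, not silently clipped.
- A zero-volume fill, a zero-drive solve and a tumor sphere that selects no
  voxel centre are all valid degenerate inputs with documented results;
  zero-length electrodes, sub-resolution radii, inverted voltage windows and
  non-finite temperature grids are errors.
- Ties in the fill redistribution are impossible by construction (equal
  split, deterministic order); all experiment runs are bit-reproducible for
  a fixed config and seed.
- Problem sizes: 1 mm sweeps ≈ 2–4×10⁵ voxels and ~45 s per 300 s run;
  the 0.5 mm tip-first analysis ≈ 3.3×10⁶ voxels, solved once and stepped a
  few seconds of simulated time.

## Known limitations

- No vaporisation or phase change: over-driven constant-σ runs report
  super-physical peak temperatures near the cast; the roll-off model caps
  delivery through impedance, not through latent heat.
- The desiccation collapse (1 % of σ₀ at 99 °C) is a step surrogate; real
  desiccation is gradual and partially reversible on rehydration.
- The volume-mean sensor is an idealisation of a single thermocouple.
- Collateral-damage depths in muscle are qualitative: the ex-vivo
  experimental depths (4.2 mm at 5 min, 12.5 mm at 10 min) are animal data
  with their own unmodelled physics; the simulation checks monotonicity in
  time, not the printed millimetres.
- The 0.43 ml full-tree fill is a single anatomy; dose–extent statistics
  across anatomies (the ±0.47 ml spread) are out of scope.
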