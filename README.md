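# airwayrfa

Electro-thermal simulation of lung radiofrequency ablation through a
**liquid-metal electrode cast in the bronchial tree**.

Percutaneous RF ablation of lung nodules needs a rigid electrode in the
tumour centre and risks pneumothorax; the alternative studied here injects a
gallium–indium eutectic (liquid at room temperature, σ = 3.4×10⁶ S/m,
k = 9.8 W·m⁻¹·K⁻¹) through a balloon-tipped bronchoscopic catheter, casting
the airway lumen around the nodule into a temporary, anatomy-conforming,
multi-tined RF electrode.  `airwayrfa` is a voxel-based simulator of that
concept for computational biomedical-physics work: it generates synthetic
branching-airway anatomy, solves the quasi-static RF field, time-steps the
Pennes bioheat equation, emulates the temperature-controlled generator, and
reduces peak-temperature maps to lesion classes and safety margins.

## Model core

On a labelled voxel grid (parenchyma, lumen air, metal cast, conductive
fluid, tumour, chest-wall muscle, non-target organ):

- **Field:** ∇·(σ∇φ) = 0, φ = V₀ on the cast (equipotential Dirichlet set;
  the metal is 10⁶–10⁷× more conductive than tissue), φ = 0 on the ground
  face; 7-point finite volumes, harmonic-mean face conductivities,
  preconditioned CG.
- **Source:** U = σ|E|²/2 (time-averaged SAR of the sinusoidal drive,
  480 kHz, 50–80 V); P = ΣU·v; Z = V₀²/(2P).
- **Heat:** ρc ∂T/∂t = ∇·(k∇T) + ρQ + U − ρ_b c_b ω (T − T_b), explicit or
  backward-Euler stepping, body-core Dirichlet bath.
- **Generator:** temperature-controlled mode at the 80 °C set-point
  (clamped integrating law within 50–80 V), terminating at the preset time
  or when impedance rises over 250 Ω (reached via a desiccation-style
  conductivity collapse at 99 °C).
- **Lesions:** Tmax ≥ 60 °C necrotic core, 42–60 °C transitional rim,
  plus tip-to-cold-zone safety distance and collateral penetration depth.

See `docs/methods.md` for assumptions, parameter provenance and limitations.

## Worked example

A 5-minute temperature-controlled ablation on the depth-3 branched cast
(0.43 ml of liquid metal, 1 mm grid, chest-wall ground):

```python
import airwayrfa as a
from airwayrfa import experiments as exp

domain, tree = exp.reference_branched_domain(seed=0, depth=3,
                                             config={"sheath_length": 20.0})
result = a.run_ablation(domain, a.default_table(),
                        exp.reference_protocol(duration=300.0))
series = result.series
print("cast volume     %.2f ml" % tree.total_lumen_volume_ml())
print("termination     %s, effective=%s" % (result.termination.value,
                                            result.effective))
print("peak sensor     %.1f C" % result.peak_sensor_T)
after = series[series.t >= series[series.sensor_T >= 80.0].t.iloc[0]]
print("at set-point    t=%.0f s, band [%.1f, %.1f] C" % (
    after.t.iloc[0], after.sensor_T.min(), after.sensor_T.max()))
print("safety distance %.1f mm (60 C isotherm)" % a.safety_distance(
    result.Tmax_map, domain.spacing, domain.electrode_tip_voxel, 60.0))
```

prints

```
cast volume     0.43 ml
termination     time_reached, effective=True
peak sensor     82.2 C
at set-point    t=131 s, band [78.4, 82.2] C
safety distance 6.8 mm (60 C isotherm)
```

The controller holds the sensor within ±3 °C of the set-point once reached,
the run is effective by the ≥60 °C sensor criterion, and tissue farther than
~7 mm from the cast tip stays below the necrosis isotherm — inside the
5–10 mm stand-off recommended for sensitive organs.

## Analysis pipeline

The numbered drivers under `analysis/` reproduce the study's in-silico
experiment matrix and write tables under `results/`:

| script | question |
|---|---|
| `01_reference_ablation.py` | closed-loop reference run: regulation, lesion volumes, safety distances |
| `02_tip_first_heating.py` | where heating starts (sharp terminal tips) on a 0.5 mm grid |
| `03_branched_vs_straight.py` | branched cast vs volume-matched rod, two grid spacings |
| `04_efficacy_limits.py` | largest effective length / smallest ineffective diameter |
| `05_fluid_comparison.py` | metal cast vs saline / nanoparticle infusates |
| `06_pseudotumor_focus.py` | heat focusing in an enclosed vs marginal pseudotumor |
| `07_safety_distance.py` | tip-to-organ stand-off preventing collateral necrosis |

A thin CLI wraps the same library: `airwayrfa ablate --config run.yaml --out
out/` and `airwayrfa experiments run-sweep|compare-electrodes|
compare-fluids|pseudotumor ...`.

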