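"""Config-driven in-silico experiment matrix.

Every experiment here builds a synthetic geometry, runs the electro-thermal
ablation model, and reduces the result to the quantity the study design asks
for: efficacy limits of electrode length and diameter, branched-versus-
straight lesion volumes, conductive-fluid comparisons, pseudotumor heat
focusing, and the tip-to-organ safety distance.

Geometry sweeps run open loop (fixed amplitude, constant conductivity) so
that the geometric effect is not masked by control compensation; the closed-
loop variant is a config flag away.  Effectiveness of a geometry is judged
at a distal evaluation probe: a small ball of target tissue at a fixed
stand-off beyond the electrode tip, emulating a temperature sensor placed in
the nodule the cast is meant to treat.  The stand-off (default 3 mm) and
the chest-wall/ground geometry are pinned by the experiment config; the
defaults below describe a peripheral-lung target whose return path to the
ground pad lies behind the injection site.

All experiments are deterministic for a fixed config and seed and log the
config hash and material table they ran with.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .controller import AblationProtocol, AblationResult, run_ablation
from .errors import ConfigurationError
from .geometry import (BronchialTree, VoxelDomain, fill_electrode,
                       generate_tree, make_straight_electrode,
                       place_pseudotumor, rasterize, straight_tree)
from .lesions import LesionClass, classify_lesion, lesion_volume
from .materials import Label, SigmaModel, default_table

__all__ = [
    "SweepVariable", "SweepSpec", "SweepResult",
    "DEFAULT_GEOMETRY", "DEFAULT_PROBE",
    "build_straight_domain", "reference_branched_domain",
    "open_loop_protocol", "reference_protocol",
    "distal_probe_mask", "probe_peak",
    "sweep_length", "sweep_diameter", "sweep_tip_distance",
    "compare_branched_straight", "compare_fluids", "pseudotumor_focus",
]

TISSUE_LABELS = (Label.PARENCHYMA, Label.TUMOR, Label.MUSCLE,
                 Label.NON_TARGET_ORGAN)

#: Study-condition geometry for the length/diameter sweeps: the cast runs
#: from the injection site toward a peripheral target, and the return path to
#: the ground pad lies behind the injection site (proximal face), so the tip
#: field weakens as the cast gets longer — the length-limit mechanism.
#: ``ground_margin`` is the tissue gap between the lumen and the grounded
#: muscle slab; the remaining faces sit ``margins`` mm away in a body-core
#: temperature bath.
DEFAULT_GEOMETRY = {
    "spacing": 1.0,               # mm
    "margins": 20.0,              # mm parenchyma on non-ground faces
    "ground_margin": 20.0,        # mm tissue between lumen and ground slab
    "chest_wall_thickness": 8.0,  # mm muscle slab on the ground face
    "ground_face": "z-",
    "sheath_length": 5.0,         # mm insulated catheter sheath at injection
}

#: Ex-vivo-style reference geometry for the branched runs: grounded muscle
#: wrapped laterally around the lung piece, so the sharp terminal tips are
#: the field concentrators.
REFERENCE_GEOMETRY = {
    "spacing": 1.0,
    "margins": 20.0,
    "ground_margin": 20.0,
    "chest_wall_thickness": 8.0,
    "ground_face": "x-",
    "sheath_length": 5.0,
}

#: Distal evaluation probe: target tissue immediately beyond the cast tip
#: (ball centre 3 mm past the tip), emulating a sensor in the nodule the
#: cast is meant to treat.
DEFAULT_PROBE = {"offset": 3.0, "radius": 2.0}  # mm


class SweepVariable(enum.Enum):
    LENGTH = "length"
    DIAMETER = "diameter"
    TIP_DISTANCE = "tip_distance"
    DURATION = "duration"


@dataclass
class SweepSpec:
    """One-variable sweep over a base experiment config."""

    variable: SweepVariable
    values: list
    base_config: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.variable = SweepVariable(self.variable)
        vals = list(self.values)
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ConfigurationError("sweep values must be strictly increasing")


@dataclass
class SweepResult:
    """Sweep table plus the machine-readable summary of the critical value."""

    table: pd.DataFrame
    summary: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"summary": self.summary,
                       "table": self.table.to_dict(orient="records")}, fh, indent=1)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# geometry + protocol builders


def _materials(cfg: dict):
    """The material table an experiment runs with (logged in its summary)."""
    return cfg.get("table") or default_table()


def _geom(config: dict, base: dict | None = None) -> dict:
    g = dict(base if base is not None else DEFAULT_GEOMETRY)
    g.update({k: config[k] for k in g if k in config})
    return g


def build_straight_domain(length_mm: float, diameter_mm: float,
                          config: dict | None = None,
                          organ_offset: float | None = None) -> VoxelDomain:
    """Fully-cast straight electrode in the standard peripheral-lung setup."""
    g = _geom(config or {})
    return make_straight_electrode(
        length_mm, diameter_mm / 2.0, g["spacing"], margins=g["margins"],
        ground_margin=g["ground_margin"],
        chest_wall_thickness=g["chest_wall_thickness"],
        ground_face=g["ground_face"], organ_offset=organ_offset,
        sheath_length=g["sheath_length"])


def reference_branched_domain(seed: int = 0, depth: int = 3,
                              config: dict | None = None,
                              fill_volume_ml: float | None = None,
                              jitter: float = 0.0
                              ) -> tuple[VoxelDomain, BronchialTree]:
    """Depth-``depth`` branched cast (defaults give ~0.43 ml of liquid metal)."""
    g = _geom(config or {}, base=REFERENCE_GEOMETRY)
    cfg = config or {}
    tree = generate_tree(seed, depth,
                         root_radius=cfg.get("root_radius", 1.5),
                         root_length=cfg.get("root_length", 20.0),
                         radius_ratio=cfg.get("radius_ratio", 0.8),
                         length_ratio=cfg.get("length_ratio", 0.75),
                         branch_angle=cfg.get("branch_angle", 35.0),
                         jitter=jitter)
    volume = fill_volume_ml if fill_volume_ml is not None \
        else tree.total_lumen_volume_ml()
    fill = fill_electrode(tree, volume)
    domain = rasterize(tree, fill, g["spacing"], margins=g["margins"],
                       ground_margin=g["ground_margin"],
                       chest_wall_thickness=g["chest_wall_thickness"],
                       ground_face=g["ground_face"],
                       organ_offset=cfg.get("organ_offset"),
                       sheath_length=g["sheath_length"])
    return domain, tree


def open_loop_protocol(v0: float = 80.0, duration: float = 300.0,
                       scheme: str = "implicit", dt: float | None = 0.5,
                       sigma_model: SigmaModel = SigmaModel.CONSTANT
                       ) -> AblationProtocol:
    """Fixed-amplitude drive: the controller degenerates to a constant V0."""
    return AblationProtocol(v_min=v0, v_max=v0, kp=0.0, max_duration=duration,
                            sigma_model=sigma_model, scheme=scheme, dt=dt,
                            impedance_cutoff=np.inf)


def reference_protocol(duration: float = 300.0,
                       sigma_model: SigmaModel = SigmaModel.CONSTANT,
                       scheme: str = "implicit", dt: float | None = 1.0
                       ) -> AblationProtocol:
    """The clinical temperature-controlled mode (80 degC set-point, 50-80 V)."""
    return AblationProtocol(max_duration=duration, sigma_model=sigma_model,
                            scheme=scheme, dt=dt)


# ---------------------------------------------------------------------------
# evaluation probes


def distal_probe_mask(domain: VoxelDomain, offset: float, radius: float) -> np.ndarray:
    """Ball of target tissue centred ``offset`` mm beyond the deepest tip."""
    if domain.electrode_tip_voxel is None or domain.tip_direction is None:
        raise ConfigurationError("domain has no cast tip to probe beyond")
    center = domain.voxel_center(domain.electrode_tip_voxel) \
        + offset * domain.tip_direction
    idx = np.indices(domain.shape).reshape(3, -1).T
    pos = domain.origin + domain.spacing * idx
    mask = (np.linalg.norm(pos - center, axis=1) <= radius).reshape(domain.shape)
    mask &= np.isin(domain.labels, [int(l) for l in TISSUE_LABELS])
    if not mask.any():
        raise ConfigurationError(
            f"distal probe at {offset} mm stand-off selects no tissue voxel")
    return mask


def probe_peak(Tmax: np.ndarray, domain: VoxelDomain,
               offset: float, radius: float) -> float:
    """Peak temperature inside the distal evaluation probe."""
    return float(Tmax[distal_probe_mask(domain, offset, radius)].max())


def core_volume_ml(result: AblationResult, domain: VoxelDomain) -> float:
    lmap = classify_lesion(result.Tmax_map, domain.spacing)
    return sum(lesion_volume(lmap, LesionClass.CORE, labels=domain.labels,
                             restrict_label=lab) for lab in TISSUE_LABELS)


# ---------------------------------------------------------------------------
# sweeps


def _sweep_run(domain: VoxelDomain, cfg: dict) -> tuple[AblationResult, float]:
    protocol = (reference_protocol(duration=cfg.get("duration_s", 300.0),
                                   sigma_model=cfg.get("sigma_model",
                                                       SigmaModel.CONSTANT))
                if cfg.get("closed_loop", False)
                else open_loop_protocol(v0=cfg.get("v0", 80.0),
                                        duration=cfg.get("duration_s", 300.0),
                                        sigma_model=cfg.get("sigma_model",
                                                            SigmaModel.CONSTANT)))
    result = run_ablation(domain, _materials(cfg), protocol)
    probe = cfg.get("probe", DEFAULT_PROBE)
    distal = probe_peak(result.Tmax_map, domain, probe["offset"], probe["radius"])
    return result, distal


def sweep_length(spec: SweepSpec) -> SweepResult:
    """Straight-electrode length sweep (values in cm) at fixed drive.

    A length is effective when the distal target tissue (evaluation probe)
    reaches the 60 degC efficacy threshold; the summary reports the largest
    effective length.
    """
    if spec.variable is not SweepVariable.LENGTH:
        raise ConfigurationError("spec.variable must be LENGTH")
    cfg = spec.base_config
    threshold = cfg.get("threshold", 60.0)
    rows = []
    for length_cm in spec.values:
        domain = build_straight_domain(length_cm * 10.0,
                                       cfg.get("diameter_mm", 3.0), cfg)
        result, distal = _sweep_run(domain, cfg)
        rows.append({"length_cm": length_cm,
                     "peak_sensor_T": result.peak_sensor_T,
                     "peak_distal_T": distal,
                     "effective": bool(distal >= threshold)})
    table = pd.DataFrame(rows)
    eff = table[table["effective"]]
    summary = {
        "variable": "length_cm",
        "largest_effective_length_cm": (float(eff["length_cm"].max())
                                        if len(eff) else None),
        "threshold_C": threshold,
        "config_hash": config_hash(cfg),
        "seed": spec.seed,
        "materials": _materials(cfg).to_dict(),
    }
    return SweepResult(table, summary)


def sweep_diameter(spec: SweepSpec) -> SweepResult:
    """Electrode diameter sweep (values in mm) at fixed 3 cm length.

    Reports the smallest diameter whose distal heating fails the threshold,
    with its bracketing effective diameter.
    """
    if spec.variable is not SweepVariable.DIAMETER:
        raise ConfigurationError("spec.variable must be DIAMETER")
    cfg = spec.base_config
    threshold = cfg.get("threshold", 60.0)
    rows = []
    for diameter_mm in spec.values:
        domain = build_straight_domain(cfg.get("length_mm", 30.0), diameter_mm, cfg)
        result, distal = _sweep_run(domain, cfg)
        rows.append({"diameter_mm": diameter_mm,
                     "peak_sensor_T": result.peak_sensor_T,
                     "peak_distal_T": distal,
                     "effective": bool(distal >= threshold)})
    table = pd.DataFrame(rows)
    ineff = table[~table["effective"]]
    eff = table[table["effective"]]
    smallest_ineff = float(ineff["diameter_mm"].min()) if len(ineff) else None
    bracket = None
    if smallest_ineff is not None:
        below = eff[eff["diameter_mm"] < smallest_ineff]
        bracket = float(below["diameter_mm"].max()) if len(below) else None
    summary = {
        "variable": "diameter_mm",
        "smallest_ineffective_diameter_mm": smallest_ineff,
        "bracketing_effective_diameter_mm": bracket,
        "threshold_C": threshold,
        "config_hash": config_hash(cfg),
        "seed": spec.seed,
        "materials": _materials(cfg).to_dict(),
    }
    return SweepResult(table, summary)


def sweep_tip_distance(spec: SweepSpec) -> SweepResult:
    """Tip-to-organ offset sweep (values in mm) for collateral safety.

    Each run places a non-target organ slab at the given stand-off beyond the
    electrode tip and reports the organ's peak temperature and necrotic CORE
    volume; the summary names the smallest offset with zero organ CORE (the
    preventing distance).
    """
    if spec.variable is not SweepVariable.TIP_DISTANCE:
        raise ConfigurationError("spec.variable must be TIP_DISTANCE")
    cfg = spec.base_config
    rows = []
    for offset in spec.values:
        domain = build_straight_domain(cfg.get("length_mm", 30.0),
                                       cfg.get("diameter_mm", 3.0), cfg,
                                       organ_offset=float(offset))
        result, _ = _sweep_run(domain, {**cfg, "probe": cfg.get("probe", DEFAULT_PROBE)})
        lmap = classify_lesion(result.Tmax_map, domain.spacing)
        organ_core = lesion_volume(lmap, LesionClass.CORE, labels=domain.labels,
                                   restrict_label=Label.NON_TARGET_ORGAN)
        organ_peak = float(result.Tmax_map[domain.mask(Label.NON_TARGET_ORGAN)].max())
        rows.append({"offset_mm": float(offset),
                     "organ_peak_T": organ_peak,
                     "organ_core_ml": organ_core})
    table = pd.DataFrame(rows)
    safe = table[table["organ_core_ml"] == 0.0]
    summary = {
        "variable": "tip_distance_mm",
        "preventing_distance_mm": (float(safe["offset_mm"].min())
                                   if len(safe) else None),
        "config_hash": config_hash(cfg),
        "seed": spec.seed,
        "materials": _materials(cfg).to_dict(),
    }
    return SweepResult(table, summary)


# ---------------------------------------------------------------------------
# comparisons


def compare_branched_straight(config: dict | None = None) -> dict:
    """Branched cast versus a lumen-volume-matched straight cast.

    Both run under the identical protocol; the branched tree reaches around
    its envelope from many terminal tips while the matched rod heats a single
    sleeve, so the necrotic-core ratio is expected above 1.
    """
    cfg = dict(config or {})
    seed = cfg.get("seed", 0)
    depth = cfg.get("depth", 3)
    branched, tree = reference_branched_domain(seed=seed, depth=depth, config=cfg)
    target_volume = tree.total_lumen_volume_ml()

    radius = cfg.get("root_radius", 1.5)
    rod_length = target_volume * 1000.0 / (np.pi * radius**2)
    rod_tree = straight_tree(rod_length, radius)
    rod_volume = rod_tree.total_lumen_volume_ml()
    if abs(rod_volume - target_volume) > 0.02 * target_volume:
        raise ConfigurationError("lumen volumes failed to match within 2%")
    g = _geom(cfg, base=REFERENCE_GEOMETRY)
    rod_fill = fill_electrode(rod_tree, rod_volume)
    rod = rasterize(rod_tree, rod_fill, g["spacing"], margins=g["margins"],
                    ground_margin=g["ground_margin"],
                    chest_wall_thickness=g["chest_wall_thickness"],
                    ground_face=g["ground_face"],
                    sheath_length=g["sheath_length"])

    table = _materials(cfg)
    protocol = (reference_protocol(duration=cfg.get("duration_s", 300.0))
                if cfg.get("closed_loop", True)
                else open_loop_protocol(duration=cfg.get("duration_s", 300.0),
                                        v0=cfg.get("v0", 80.0)))
    res_b = run_ablation(branched, table, protocol)
    res_s = run_ablation(rod, table, protocol)
    core_b = core_volume_ml(res_b, branched)
    core_s = core_volume_ml(res_s, rod)
    return {
        "core_branched_ml": core_b,
        "core_straight_ml": core_s,
        "ratio": core_b / core_s if core_s > 0 else np.inf,
        "lumen_volume_ml": target_volume,
        "rod_length_mm": rod_length,
        "config_hash": config_hash(cfg),
        "materials": table.to_dict(),
    }


FLUID_MEDIA = ("EGAIN_EQUIPOTENTIAL", "NACL", "AUNP")


def compare_fluids(config: dict | None = None) -> SweepResult:
    """Liquid-metal cast versus conductive-fluid infusates, same geometry.

    The metal cast is an equipotential source over its whole surface; a
    saline or nanoparticle column (sigma ~0.1 S/m) is fed at the injection
    point only, so the drive sags along the resistive column and very little
    power reaches the tissue.  Reports necrotic CORE volume and a lesion
    regularity index (largest connected CORE component over total CORE).
    """
    cfg = dict(config or {})
    g = _geom(cfg, base=REFERENCE_GEOMETRY)
    length = cfg.get("length_mm", 30.0)
    diameter = cfg.get("diameter_mm", 3.0)
    duration = cfg.get("duration_s", 180.0)
    v0 = cfg.get("v0", 80.0)
    tree = straight_tree(length, diameter / 2.0)
    fill = fill_electrode(tree, tree.total_lumen_volume_ml())
    rows = []
    for medium in FLUID_MEDIA:
        label = Label.ELECTRODE if medium == "EGAIN_EQUIPOTENTIAL" \
            else Label.CONDUCTIVE_FLUID
        domain = rasterize(tree, fill, g["spacing"], margins=g["margins"],
                           ground_margin=g["ground_margin"],
                           chest_wall_thickness=g["chest_wall_thickness"],
                           ground_face=g["ground_face"], electrode_label=label,
                           sheath_length=g["sheath_length"])
        table = _materials(cfg)
        if medium == "NACL":
            table = table.with_fluid("nacl")
        elif medium == "AUNP":
            table = table.with_fluid("aunp")
        result = run_ablation(domain, table,
                              open_loop_protocol(v0=v0, duration=duration))
        lmap = classify_lesion(result.Tmax_map, domain.spacing)
        core_mask = (lmap.classes == int(LesionClass.CORE)) & np.isin(
            domain.labels, [int(l) for l in TISSUE_LABELS])
        core_ml = float(core_mask.sum()) * domain.voxel_volume_ml
        if core_mask.any():
            lab, n = ndimage.label(core_mask)
            largest = np.bincount(lab.ravel())[1:].max()
            regularity = float(largest / core_mask.sum())
        else:
            regularity = np.nan
        rows.append({"medium": medium, "core_ml": core_ml,
                     "regularity": regularity,
                     "peak_sensor_T": result.peak_sensor_T})
    table_df = pd.DataFrame(rows)
    summary = {"ordering_ok": bool(
        table_df.loc[0, "core_ml"] > table_df.loc[1, "core_ml"]),
        "config_hash": config_hash(cfg),
        "materials": _materials(cfg).to_dict()}
    return SweepResult(table_df, summary)


def pseudotumor_focus(config: dict | None = None) -> dict:
    """Heat focusing in a pseudotumor enclosed by the branched cast.

    The muscle-like tumor surrogate is more conductive than aerated
    parenchyma, so the inter-branch current prefers it and a tumor inside
    the cast's envelope runs hotter than normal lung at the same distance
    from the cast.  Returns peak and volume-mean temperatures for the tumor
    and for the distance-matched parenchyma band (contact sleeve excluded on
    both sides), plus the tumor CORE coverage fraction used for the
    margin-position contrast.  The volume means are the probe-faithful
    focusing statistic; the voxel-wise peaks are dominated by discrete
    field-crowding spots at the cast surface.
    """
    cfg = dict(config or {})
    seed = cfg.get("seed", 0)
    depth = cfg.get("depth", 3)
    g = _geom(cfg)
    domain, tree = reference_branched_domain(seed=seed, depth=depth, config=cfg)
    tips = [domain.voxel_center(v) for v in domain.tip_voxels]
    center = cfg.get("tumor_center")
    if center is None:
        center = np.mean(tips, axis=0)
    radius = cfg.get("tumor_radius", 8.0)
    domain = place_pseudotumor(domain, center, radius)

    table = _materials(cfg)
    protocol = reference_protocol(duration=cfg.get("duration_s", 300.0))
    result = run_ablation(domain, table, protocol)

    cast = domain.mask(Label.ELECTRODE)
    dist = ndimage.distance_transform_edt(~cast, sampling=domain.spacing)
    tumor_all = domain.mask(Label.TUMOR)
    if not tumor_all.any():
        raise ConfigurationError("pseudotumor labelled no voxels")
    # The temperature probes of interest sit in tissue, not at the metal
    # surface: exclude the two-voxel contact sleeve, where the discrete
    # near-field of the Dirichlet cast dominates, from both sides of the
    # comparison.
    sleeve = 2.0 * domain.spacing
    tumor = tumor_all & (dist > sleeve)
    if not tumor.any():
        tumor = tumor_all
    d_lo, d_hi = float(dist[tumor].min()), float(dist[tumor].max())
    paren = domain.mask(Label.PARENCHYMA) & (dist >= d_lo) & (dist <= d_hi)
    lmap = classify_lesion(result.Tmax_map, domain.spacing)
    coverage = float(((lmap.classes == int(LesionClass.CORE)) & tumor_all).sum()
                     / tumor_all.sum())
    return {
        "tumor_peak_T": float(result.Tmax_map[tumor].max()),
        "parenchyma_peak_T_matched": float(result.Tmax_map[paren].max()),
        "tumor_mean_T": float(result.Tmax_map[tumor].mean()),
        "parenchyma_mean_T_matched": float(result.Tmax_map[paren].mean()),
        "tumor_core_coverage": coverage,
        "tumor_center": [float(c) for c in center],
        "tumor_radius_mm": radius,
        "config_hash": config_hash(cfg),
        "materials": table.to_dict(),
    }
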