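"""Thermal lesion classification and safety geometry.

Peak temperature is thresholded into three classes: coagulative necrosis
begins above 42 degC and cell death is nearly instantaneous above 60 degC,
so voxels with Tmax >= 60 form the necrotic CORE (the central brown /
CT-hypo-enhanced zone), 42 <= Tmax < 60 the TRANSITIONAL mixed-viability
shell (the hyperemic rim / ground-glass halo) and the rest UNAFFECTED.
The 60 degC bound is inclusive, matching the "60 degC or higher" efficacy
convention; that voxel-level convention is a documented choice.

An Arrhenius / CEM43 dose integral would refine the transitional class; the
classifier exposes thresholds as parameters precisely so such a hook can be
added, but temperature thresholding is the primary model.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, AirwayRFAError
from .geometry import VoxelDomain
from .materials import Label

__all__ = ["LesionClass", "LesionMap", "classify_lesion", "lesion_volume",
           "safety_distance", "collateral_depth"]

NECROSIS_ONSET_C = 42.0
INSTANT_DEATH_C = 60.0


class LesionClass(enum.IntEnum):
    UNAFFECTED = 0
    TRANSITIONAL = 1
    CORE = 2


@dataclass
class LesionMap:
    """Per-voxel lesion class plus the grid geometry needed for volumes."""

    classes: np.ndarray
    spacing: float               # mm
    lower: float = NECROSIS_ONSET_C
    upper: float = INSTANT_DEATH_C

    @property
    def voxel_volume_ml(self) -> float:
        return self.spacing**3 / 1000.0

    def class_volumes_ml(self) -> dict[LesionClass, float]:
        return {cls: float(np.count_nonzero(self.classes == int(cls)))
                * self.voxel_volume_ml for cls in LesionClass}


def classify_lesion(Tmax: np.ndarray, spacing: float,
                    lower: float = NECROSIS_ONSET_C,
                    upper: float = INSTANT_DEATH_C) -> LesionMap:
    """Threshold a peak-temperature map into lesion classes (inclusive bounds)."""
    Tmax = np.asarray(Tmax, dtype=float)
    if not np.all(np.isfinite(Tmax)):
        raise ConfigurationError("peak-temperature map contains non-finite values")
    classes = np.zeros(Tmax.shape, dtype=np.uint8)
    classes[Tmax >= lower] = int(LesionClass.TRANSITIONAL)
    classes[Tmax >= upper] = int(LesionClass.CORE)
    return LesionMap(classes=classes, spacing=spacing, lower=lower, upper=upper)


def lesion_volume(lmap: LesionMap, cls: LesionClass,
                  labels: np.ndarray | None = None,
                  restrict_label: Label | None = None) -> float:
    """Volume (ml) of one lesion class, optionally within one tissue label."""
    mask = lmap.classes == int(LesionClass(cls))
    if restrict_label is not None:
        if labels is None:
            raise ConfigurationError("restricting by label requires the label grid")
        mask &= labels == int(restrict_label)
    return float(np.count_nonzero(mask)) * lmap.voxel_volume_ml


def safety_distance(Tmax: np.ndarray, spacing: float, tip,
                    threshold: float = INSTANT_DEATH_C) -> float:
    """Distance (mm) from the cast tip to the nearest low-temperature voxel.

    The low-temperature zone is everything whose peak temperature stayed
    below ``threshold``; its distance from the tip is the margin a sensitive
    structure must keep to escape that isotherm.  Euclidean, voxel centre to
    voxel centre; 0 when the tip voxel itself stayed below threshold.
    """
    Tmax = np.asarray(Tmax, dtype=float)
    tip = np.asarray(tip, dtype=int)
    if np.any(tip < 0) or np.any(tip >= np.asarray(Tmax.shape)):
        raise ConfigurationError(f"tip voxel {tuple(tip)} outside the grid")
    cold = Tmax < threshold
    if not cold.any():
        raise AirwayRFAError(
            "no voxel below the threshold: domain too small or run too hot")
    if cold[tuple(tip)]:
        return 0.0
    pts = np.argwhere(cold)
    d = np.sqrt(((pts - tip) ** 2).sum(axis=1)).min()
    return float(d * spacing)


def _slab_geometry(labels: np.ndarray, label: Label, reference) -> tuple[int, int, int]:
    """(axis, inner_index, direction into the slab) of an axis-aligned slab."""
    mask = labels == int(label)
    if not mask.any():
        raise ConfigurationError(f"label {Label(label).name} absent from domain")
    pts = np.argwhere(mask)
    spans = pts.max(axis=0) - pts.min(axis=0)
    axis = int(np.argmin(spans))
    lo, hi = int(pts[:, axis].min()), int(pts[:, axis].max())
    ref = float(np.asarray(reference, dtype=float)[axis])
    if abs(ref - lo) <= abs(ref - hi):
        return axis, lo, +1    # inner face at lo, depth grows toward hi
    return axis, hi, -1


def collateral_depth(lmap: LesionMap, domain: VoxelDomain, label: Label) -> float:
    """Maximal CORE penetration depth (mm) into a labelled slab.

    Measured normal to the slab's inner face (the face turned toward the
    cast); a slab untouched by necrosis reports 0.  Counting convention: a
    front reaching n voxel layers deep reads n * spacing.
    """
    reference = (domain.electrode_tip_voxel if domain.electrode_tip_voxel
                 is not None else np.asarray(domain.shape) // 2)
    axis, inner, direction = _slab_geometry(domain.labels, label, reference)
    mask = (domain.labels == int(label)) & (lmap.classes == int(LesionClass.CORE))
    if not mask.any():
        return 0.0
    depths = (np.argwhere(mask)[:, axis] - inner) * direction + 1
    return float(depths.max() * lmap.spacing)
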