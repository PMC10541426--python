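"""Synthetic bronchial-tree geometry and voxelization.

The generator emulates the anatomy of a peripheral-lung ablation target: a
binary-branching airway with geometrically tapering lumen radii, embedded in
aerated parenchyma, with a chest-wall muscle slab in front of the grounded
pad face and (optionally) a spherical muscle-like pseudotumor and a planar
non-target organ surface beyond the electrode tip.

All positions are millimetres.  Voxel indices are 0-based; the physical
position of voxel (i, j, k) is ``origin + spacing * (i, j, k)`` where
``origin`` is the centre of voxel (0, 0, 0); the physical extent of the grid
is half-open.  Lumen volumes are conical frusta; 1 ml = 1000 mm^3.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq

from .errors import ConfigurationError, GeometryError, SizingError
from .materials import Label

__all__ = [
    "Segment",
    "BronchialTree",
    "ElectrodeFill",
    "VoxelDomain",
    "generate_tree",
    "fill_electrode",
    "rasterize",
    "place_pseudotumor",
    "make_straight_electrode",
    "frustum_volume_mm3",
]

GROUND_FACES = ("x-", "x+", "y-", "y+", "z-", "z+")


def frustum_volume_mm3(r_prox: float, r_dist: float, length: float) -> float:
    """Volume of a conical frustum, mm^3."""
    return np.pi * length * (r_prox**2 + r_prox * r_dist + r_dist**2) / 3.0


@dataclass(frozen=True)
class Segment:
    """One airway segment: a tapering tube between two tree nodes."""

    id: int
    prox_node: int
    dist_node: int
    r_prox: float       # proximal lumen radius, mm
    r_dist: float       # distal lumen radius, mm
    generation: int


@dataclass
class BronchialTree:
    """Rooted airway tree: nodes (positions, mm) joined by tapering segments."""

    nodes: dict[int, np.ndarray]
    segments: list[Segment]
    root_node_id: int = 0

    def __post_init__(self) -> None:
        self.nodes = {nid: np.asarray(pos, dtype=float) for nid, pos in self.nodes.items()}
        self._by_id = {seg.id: seg for seg in self.segments}
        self._children: dict[int, list[Segment]] = {}
        for seg in self.segments:
            self._children.setdefault(seg.prox_node, []).append(seg)

    # -- structure ---------------------------------------------------------

    def segment(self, seg_id: int) -> Segment:
        return self._by_id[seg_id]

    def children_of(self, seg: Segment) -> list[Segment]:
        return self._children.get(seg.dist_node, [])

    def root_segments(self) -> list[Segment]:
        return self._children.get(self.root_node_id, [])

    def segment_length(self, seg: Segment) -> float:
        return float(np.linalg.norm(self.nodes[seg.dist_node] - self.nodes[seg.prox_node]))

    def segment_direction(self, seg: Segment) -> np.ndarray:
        d = self.nodes[seg.dist_node] - self.nodes[seg.prox_node]
        return d / np.linalg.norm(d)

    def segment_volume_ml(self, seg: Segment) -> float:
        return frustum_volume_mm3(seg.r_prox, seg.r_dist, self.segment_length(seg)) / 1000.0

    def total_lumen_volume_ml(self) -> float:
        return sum(self.segment_volume_ml(s) for s in self.segments)

    def validate(self) -> None:
        """Check the rooted-tree and monotone-taper invariants."""
        if self.root_node_id not in self.nodes:
            raise GeometryError("root node missing from node table")
        parent_count = {nid: 0 for nid in self.nodes}
        for seg in self.segments:
            if seg.r_prox <= 0 or seg.r_dist <= 0:
                raise GeometryError(f"segment {seg.id}: non-positive radius")
            if seg.r_dist > seg.r_prox + 1e-12:
                raise GeometryError(f"segment {seg.id}: distal radius exceeds proximal")
            if self.segment_length(seg) <= 0:
                raise GeometryError(f"segment {seg.id}: zero length")
            parent_count[seg.dist_node] += 1
        for nid, n in parent_count.items():
            if nid == self.root_node_id:
                if n != 0:
                    raise GeometryError("root node has a parent segment")
            elif n != 1:
                raise GeometryError(f"node {nid} has {n} parent segments (want 1)")
        # connectivity + child radius monotonicity
        seen = {self.root_node_id}
        stack = list(self.root_segments())
        while stack:
            seg = stack.pop()
            seen.add(seg.dist_node)
            for child in self.children_of(seg):
                if child.r_prox > seg.r_dist + 1e-12:
                    raise GeometryError(
                        f"segment {child.id}: proximal radius exceeds parent distal radius")
                stack.append(child)
        if seen != set(self.nodes):
            raise GeometryError("tree is not connected")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "root_node_id": self.root_node_id,
            "nodes": {str(nid): list(map(float, pos)) for nid, pos in self.nodes.items()},
            "segments": [
                {"id": s.id, "prox_node": s.prox_node, "dist_node": s.dist_node,
                 "r_prox": s.r_prox, "r_dist": s.r_dist, "generation": s.generation}
                for s in self.segments
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "BronchialTree":
        nodes = {int(nid): np.asarray(pos) for nid, pos in data["nodes"].items()}
        segments = [Segment(**s) for s in data["segments"]]
        return cls(nodes, segments, root_node_id=data["root_node_id"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "BronchialTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class ElectrodeFill:
    """Contiguous proximal-to-distal liquid-metal fill of a tree.

    ``fractions`` maps segment id to the filled length fraction, measured from
    the proximal end.  A segment may be partially filled only if every segment
    on its root path is completely filled.
    """

    fractions: dict[int, float]
    injected_volume_ml: float
    requested_volume_ml: float
    clamped: bool = False

    def fraction(self, seg_id: int) -> float:
        return self.fractions.get(seg_id, 0.0)

    def filled_volume_ml(self, tree: BronchialTree) -> float:
        total = 0.0
        for seg_id, f in self.fractions.items():
            seg = tree.segment(seg_id)
            length = tree.segment_length(seg)
            r_f = seg.r_prox + (seg.r_dist - seg.r_prox) * f
            total += frustum_volume_mm3(seg.r_prox, r_f, length * f) / 1000.0
        return total

    def to_dict(self) -> dict:
        return {
            "fractions": {str(k): v for k, v in self.fractions.items()},
            "injected_volume_ml": self.injected_volume_ml,
            "requested_volume_ml": self.requested_volume_ml,
            "clamped": self.clamped,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ElectrodeFill":
        return cls({int(k): v for k, v in data["fractions"].items()},
                   data["injected_volume_ml"], data["requested_volume_ml"],
                   data["clamped"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ElectrodeFill":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class VoxelDomain:
    """Labelled voxel grid with the metadata downstream stages need.

    ``labels`` holds one :class:`~airwayrfa.materials.Label` per voxel.
    ``ground_face`` names the grounded boundary face ('x-', ..., 'z+') behind
    the chest-wall slab.  ``electrode_tip_voxel`` is the deepest (most distal)
    electrode voxel; ``tip_voxels`` lists every terminal tip of the cast;
    ``tip_direction`` is the unit direction of the deepest filled segment,
    used to place distal evaluation probes and non-target organ slabs.
    """

    labels: np.ndarray
    spacing: float                      # mm, isotropic
    ground_face: str = "x-"
    electrode_tip_voxel: tuple | None = None
    tip_voxels: list = field(default_factory=list)
    injection_voxel: tuple | None = None
    origin: np.ndarray = None           # mm position of voxel (0,0,0) centre
    tip_direction: np.ndarray = None    # unit vector, mm frame

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GeometryError("spacing must be positive")
        if self.ground_face not in GROUND_FACES:
            raise GeometryError(f"ground_face must be one of {GROUND_FACES}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.labels = np.ascontiguousarray(self.labels, dtype=np.uint8)

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.spacing**3 / 1000.0

    @property
    def voxel_volume_m3(self) -> float:
        return (self.spacing * 1e-3) ** 3

    def voxel_center(self, index) -> np.ndarray:
        return self.origin + self.spacing * np.asarray(index, dtype=float)

    def index_of(self, position) -> tuple:
        idx = np.round((np.asarray(position, dtype=float) - self.origin) / self.spacing)
        idx = np.clip(idx, 0, np.asarray(self.shape) - 1).astype(int)
        return tuple(idx)

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == int(label)))

    def label_volume_ml(self, label: Label) -> float:
        return self.count(label) * self.voxel_volume_ml

    def ground_mask(self) -> np.ndarray:
        """Boolean mask of the boundary voxel layer on the ground face."""
        mask = np.zeros(self.shape, dtype=bool)
        axis = "xyz".index(self.ground_face[0])
        sl = [slice(None)] * 3
        sl[axis] = 0 if self.ground_face[1] == "-" else -1
        mask[tuple(sl)] = True
        return mask

    def source_label(self) -> Label:
        """The label acting as the RF source (metal cast, else fed fluid)."""
        if self.count(Label.ELECTRODE):
            return Label.ELECTRODE
        if self.count(Label.CONDUCTIVE_FLUID):
            return Label.CONDUCTIVE_FLUID
        raise ConfigurationError("domain has neither electrode nor conductive-fluid voxels")

    def electrode_components(self) -> int:
        """Number of face-connected components of the cast (source label)."""
        structure = ndimage.generate_binary_structure(3, 1)
        _, n = ndimage.label(self.mask(self.source_label()), structure=structure)
        return n


# ---------------------------------------------------------------------------
# tree generation


def _orthonormal_frame(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(d[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, ref)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return u, v


def generate_tree(seed: int, depth: int, root_radius: float = 1.5,
                  root_length: float = 20.0, radius_ratio: float = 0.8,
                  length_ratio: float = 0.75, branch_angle: float = 35.0,
                  jitter: float = 0.0) -> BronchialTree:
    """Generate a seeded binary airway tree with geometric taper.

    Generation-g segments have proximal radius ``root_radius*radius_ratio**g``
    and nominal length ``root_length*length_ratio**g``; each segment tapers to
    ``radius_ratio`` times its proximal radius, so child radii join the parent
    exactly.  ``branch_angle`` is the full angle between sibling branches; the
    branching plane rotates 90 degrees per generation to fill space.
    ``jitter`` perturbs lengths and angles (never radii) by up to that
    relative amount; jitter = 0 is fully deterministic.
    """
    if depth < 0:
        raise GeometryError("depth must be >= 0")
    if not (0 < radius_ratio <= 1 and 0 < length_ratio <= 1):
        raise GeometryError("radius_ratio and length_ratio must lie in (0, 1]")
    if not 0 <= jitter < 1:
        raise GeometryError("jitter must lie in [0, 1)")
    if root_radius <= 0 or root_length <= 0:
        raise GeometryError("root radius and length must be positive")

    rng = np.random.default_rng(seed)
    nodes = {0: np.zeros(3)}
    segments: list[Segment] = []
    next_node, next_seg = 1, 0

    # (start node, direction, generation)
    trunk_dir = np.array([0.0, 0.0, 1.0])
    frontier = [(0, trunk_dir, 0)]
    while frontier:
        new_frontier = []
        for start, d, gen in frontier:
            length = root_length * length_ratio**gen
            length *= 1.0 + jitter * rng.uniform(-0.5, 0.5)
            r_prox = root_radius * radius_ratio**gen
            r_dist = r_prox * radius_ratio
            end = nodes[start] + length * d
            nodes[next_node] = end
            segments.append(Segment(next_seg, start, next_node, r_prox, r_dist, gen))
            end_node, next_node, next_seg = next_node, next_node + 1, next_seg + 1
            if gen < depth:
                half = np.radians(branch_angle / 2.0) * (
                    1.0 + jitter * rng.uniform(-0.5, 0.5))
                az = np.radians(90.0 * gen + jitter * rng.uniform(-45.0, 45.0))
                u, v = _orthonormal_frame(d)
                w = np.cos(az) * u + np.sin(az) * v
                for sign in (+1, -1):
                    cd = np.cos(half) * d + sign * np.sin(half) * w
                    cd /= np.linalg.norm(cd)
                    new_frontier.append((end_node, cd, gen + 1))
        frontier = new_frontier

    tree = BronchialTree(nodes, segments)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# electrode fill


def _partial_fraction(r_prox: float, r_dist: float, length: float,
                      vol_mm3: float) -> float:
    """Length fraction from the proximal end containing ``vol_mm3``."""
    total = frustum_volume_mm3(r_prox, r_dist, length)
    if vol_mm3 >= total:
        return 1.0
    if vol_mm3 <= 0:
        return 0.0
    if abs(r_prox - r_dist) < 1e-12:
        return vol_mm3 / total

    def partial(f: float) -> float:
        r_f = r_prox + (r_dist - r_prox) * f
        return frustum_volume_mm3(r_prox, r_f, length * f) - vol_mm3

    return brentq(partial, 0.0, 1.0, xtol=1e-12)


def fill_electrode(tree: BronchialTree, volume: float) -> ElectrodeFill:
    """Fill the lumen proximal-to-distal with ``volume`` ml of liquid metal.

    The front advances from the root; at each bifurcation the remaining
    volume splits equally between the subtrees, with any excess beyond a
    subtree's capacity redistributed to its siblings.  A request exceeding
    the total lumen volume is clamped to a full fill (with a warning flag).
    """
    if volume < 0:
        raise GeometryError("injected volume must be >= 0")
    vol_mm3 = volume * 1000.0

    capacity: dict[int, float] = {}

    def subtree_capacity(seg: Segment) -> float:
        if seg.id not in capacity:
            capacity[seg.id] = (
                frustum_volume_mm3(seg.r_prox, seg.r_dist, tree.segment_length(seg))
                + sum(subtree_capacity(c) for c in tree.children_of(seg)))
        return capacity[seg.id]

    roots = tree.root_segments()
    total = sum(subtree_capacity(s) for s in roots)
    clamped = False
    if vol_mm3 > total * (1.0 + 1e-9):
        warnings.warn("injected volume exceeds the tree lumen volume; clamped to full fill")
        vol_mm3, clamped = total, True
    vol_mm3 = min(vol_mm3, total)

    fractions: dict[int, float] = {}

    def share_out(children: list[Segment], amount: float) -> dict[int, float]:
        """Equal split with redistribution, capped by subtree capacities."""
        alloc = {c.id: 0.0 for c in children}
        active = list(children)
        remaining = amount
        while remaining > 1e-12 and active:
            share = remaining / len(active)
            next_active = []
            for c in active:
                room = subtree_capacity(c) - alloc[c.id]
                take = min(share, room)
                alloc[c.id] += take
                remaining -= take
                if room - take > 1e-12:
                    next_active.append(c)
            if len(next_active) == len(active):
                break  # everyone absorbed a full share; loop again
            active = next_active
        return alloc

    def assign(seg: Segment, amount: float) -> None:
        if amount <= 1e-12:
            return
        own = frustum_volume_mm3(seg.r_prox, seg.r_dist, tree.segment_length(seg))
        used = min(amount, own)
        fractions[seg.id] = _partial_fraction(
            seg.r_prox, seg.r_dist, tree.segment_length(seg), used)
        rest = amount - used
        if rest > 1e-12:
            alloc = share_out(tree.children_of(seg), rest)
            for child in tree.children_of(seg):
                assign(child, alloc[child.id])

    for root_seg, amt in share_out(roots, vol_mm3).items():
        assign(tree.segment(root_seg), amt)

    fill = ElectrodeFill(fractions, injected_volume_ml=vol_mm3 / 1000.0,
                         requested_volume_ml=volume, clamped=clamped)
    return fill


# ---------------------------------------------------------------------------
# rasterization


def _paint_tube(labels: np.ndarray, origin: np.ndarray, spacing: float,
                p0: np.ndarray, p1: np.ndarray, r0: float, r1: float,
                value: int, exclude: tuple = ()) -> None:
    """Label voxels whose centres lie inside a flat-capped tapering tube."""
    length = np.linalg.norm(p1 - p0)
    if length <= 0:
        return
    d = (p1 - p0) / length
    rmax = max(r0, r1)
    lo = np.minimum(p0, p1) - rmax
    hi = np.maximum(p0, p1) + rmax
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1,
                    np.asarray(labels.shape))
    if np.any(i0 >= i1):
        return
    grids = np.meshgrid(*(origin[a] + spacing * np.arange(i0[a], i1[a])
                          for a in range(3)), indexing="ij")
    pts = np.stack(grids, axis=-1) - p0
    t = pts @ d
    radial = np.linalg.norm(pts - t[..., None] * d, axis=-1)
    r_at = r0 + (r1 - r0) * np.clip(t / length, 0.0, 1.0)
    inside = (t >= 0.0) & (t <= length) & (radial <= r_at)
    sub = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    if exclude:
        inside &= ~np.isin(sub, exclude)
    sub[inside] = value


def _stamp_axis(labels: np.ndarray, origin: np.ndarray, spacing: float,
                p0: np.ndarray, p1: np.ndarray, value: int) -> None:
    """Stamp a face-connected chain of voxels along the tube axis.

    Guarantees the cast stays one face-connected component even where thin
    branches rasterize to about one voxel across.
    """
    length = np.linalg.norm(p1 - p0)
    n = max(int(np.ceil(length / (spacing / 4.0))), 1)
    shape = np.asarray(labels.shape)
    idx_prev = None
    for s in np.linspace(0.0, 1.0, n + 1):
        p = p0 + s * (p1 - p0)
        idx = np.clip(np.round((p - origin) / spacing).astype(int), 0, shape - 1)
        if idx_prev is not None:
            step = idx.copy()
            cur = idx_prev.copy()
            # bridge axis changes one coordinate at a time
            for axis in range(3):
                while cur[axis] != step[axis]:
                    cur[axis] += np.sign(step[axis] - cur[axis])
                    labels[tuple(cur)] = value
        labels[tuple(idx)] = value
        idx_prev = idx


def _filled_endpoint(tree: BronchialTree, seg: Segment, f: float) -> np.ndarray:
    p0 = tree.nodes[seg.prox_node]
    p1 = tree.nodes[seg.dist_node]
    return p0 + f * (p1 - p0)


def _terminal_tips(tree: BronchialTree, fill: ElectrodeFill) -> list[tuple[np.ndarray, np.ndarray]]:
    """(position, direction) of every terminal tip of the filled cast."""
    tips = []
    for seg_id, f in fill.fractions.items():
        seg = tree.segment(seg_id)
        children = tree.children_of(seg)
        child_filled = any(fill.fraction(c.id) > 0 for c in children)
        if f < 1.0 - 1e-9 or not child_filled:
            tips.append((_filled_endpoint(tree, seg, f), tree.segment_direction(seg)))
    return tips


def rasterize(tree: BronchialTree, fill: ElectrodeFill, spacing: float,
              margins: float = 15.0, chest_wall_thickness: float = 0.0,
              organ_offset: float | None = None, organ_thickness: float = 5.0,
              ground_face: str = "x-", ground_margin: float | None = None,
              electrode_label: Label = Label.ELECTRODE,
              sheath_length: float = 0.0,
              sheath_thickness: float = 1.5) -> VoxelDomain:
    """Rasterize a (partially filled) airway tree to a labelled voxel grid.

    Filled lumen voxels get ``electrode_label`` (``CONDUCTIVE_FLUID`` for the
    infusate experiments), unfilled lumen ``AIRWAY_AIR``, background
    ``PARENCHYMA``.  A ``MUSCLE`` slab of ``chest_wall_thickness`` mm sits on
    the ground face (``ground_margin`` mm of parenchyma between the tree
    bounding box and the slab; defaults to ``margins``); an optional
    ``NON_TARGET_ORGAN`` slab of ``organ_thickness`` mm is placed
    ``organ_offset`` mm beyond the deepest electrode tip, normal to the tip
    direction's dominant axis.

    ``sheath_length`` > 0 models the insulated balloon-tipped guiding
    catheter at the injection site: an insulating ring of
    ``sheath_thickness`` mm around the proximal portion of the trunk plus a
    back-cap disc behind the injection point.  Without it the bare flat
    proximal end of the metal column would be an artificial field
    concentrator that the real (catheter-shielded) device does not have.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    # resolution check: every filled radius must span >= 1 voxel across
    for seg_id, f in fill.fractions.items():
        seg = tree.segment(seg_id)
        r_min = seg.r_prox + (seg.r_dist - seg.r_prox) * f
        if 2.0 * r_min < spacing:
            raise SizingError(
                f"segment {seg_id}: filled diameter {2*r_min:.3f} mm is below "
                f"the voxel spacing {spacing} mm")

    pos = np.array(list(tree.nodes.values()))
    rmax = max((s.r_prox for s in tree.segments), default=1.0)
    lo = pos.min(axis=0) - (rmax + margins)
    hi = pos.max(axis=0) + (rmax + margins)

    tips = _terminal_tips(tree, fill)
    if tips:
        deep_pos, deep_dir = max(
            tips, key=lambda t: np.linalg.norm(t[0] - tree.nodes[tree.root_node_id]))
    else:
        deep_pos = tree.nodes[tree.root_node_id]
        deep_dir = (tree.segment_direction(tree.root_segments()[0])
                    if tree.root_segments() else np.array([0.0, 0.0, 1.0]))

    organ_axis = organ_sign = None
    if organ_offset is not None:
        organ_axis = int(np.argmax(np.abs(deep_dir)))
        organ_sign = 1 if deep_dir[organ_axis] >= 0 else -1
        organ_far = deep_pos[organ_axis] + organ_sign * (organ_offset + organ_thickness)
        if organ_sign > 0:
            hi[organ_axis] = max(hi[organ_axis], organ_far + margins)
        else:
            lo[organ_axis] = min(lo[organ_axis], organ_far - margins)

    gaxis = "xyz".index(ground_face[0])
    gsign = -1 if ground_face[1] == "-" else 1
    if ground_margin is not None:
        # fixed parenchyma gap between the lumen bounding box and the slab
        edge = (pos.min(axis=0)[gaxis] - rmax - ground_margin if gsign < 0
                else pos.max(axis=0)[gaxis] + rmax + ground_margin)
        if gsign < 0:
            lo[gaxis] = edge
        else:
            hi[gaxis] = edge
    if chest_wall_thickness > 0:
        if gsign < 0:
            lo[gaxis] -= chest_wall_thickness
        else:
            hi[gaxis] += chest_wall_thickness

    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int), 1)
    origin = lo + spacing / 2.0
    labels = np.full(shape, int(Label.PARENCHYMA), dtype=np.uint8)

    # ascending precedence: parenchyma < air < muscle/organ < electrode
    for seg in tree.segments:
        p0, p1 = tree.nodes[seg.prox_node], tree.nodes[seg.dist_node]
        _paint_tube(labels, origin, spacing, p0, p1, seg.r_prox, seg.r_dist,
                    int(Label.AIRWAY_AIR))

    if chest_wall_thickness > 0:
        n = max(int(round(chest_wall_thickness / spacing)), 1)
        sl = [slice(None)] * 3
        sl[gaxis] = slice(0, n) if gsign < 0 else slice(shape[gaxis] - n, shape[gaxis])
        labels[tuple(sl)] = int(Label.MUSCLE)

    if organ_offset is not None:
        start = deep_pos[organ_axis] + organ_sign * organ_offset
        a = int(round((min(start, start + organ_sign * organ_thickness)
                       - origin[organ_axis]) / spacing))
        b = int(round((max(start, start + organ_sign * organ_thickness)
                       - origin[organ_axis]) / spacing))
        a, b = max(a, 0), min(b + 1, shape[organ_axis])
        sl = [slice(None)] * 3
        sl[organ_axis] = slice(a, b)
        labels[tuple(sl)] = int(Label.NON_TARGET_ORGAN)

    for seg_id, f in fill.fractions.items():
        seg = tree.segment(seg_id)
        p0 = tree.nodes[seg.prox_node]
        p1 = _filled_endpoint(tree, seg, f)
        r1 = seg.r_prox + (seg.r_dist - seg.r_prox) * f
        _paint_tube(labels, origin, spacing, p0, p1, seg.r_prox, r1,
                    int(electrode_label))
        _stamp_axis(labels, origin, spacing, p0, p1, int(electrode_label))

    if sheath_length > 0 and fill.fractions and tree.root_segments():
        trunk = tree.root_segments()[0]
        if fill.fraction(trunk.id) > 0:
            d0 = tree.segment_direction(trunk)
            p_root = tree.nodes[trunk.prox_node]
            reach = min(sheath_length,
                        tree.segment_length(trunk) * fill.fraction(trunk.id))
            a0 = p_root - (sheath_thickness + spacing) * d0
            a1 = p_root + reach * d0
            r_out = trunk.r_prox + sheath_thickness
            _paint_tube(labels, origin, spacing, a0, a1, r_out, r_out,
                        int(Label.AIRWAY_AIR), exclude=(int(electrode_label),))

    domain = VoxelDomain(labels, spacing, ground_face=ground_face, origin=origin)
    if fill.fractions:
        tip_vox = [domain.index_of(p) for p, _ in tips]
        domain.tip_voxels = tip_vox
        domain.electrode_tip_voxel = domain.index_of(deep_pos)
        domain.tip_direction = deep_dir
        # the tip voxel must carry the cast label
        labels[domain.electrode_tip_voxel] = int(electrode_label)
        for v in tip_vox:
            labels[v] = int(electrode_label)
        domain.injection_voxel = domain.index_of(tree.nodes[tree.root_node_id])
        labels[domain.injection_voxel] = int(electrode_label)
    return domain


def place_pseudotumor(domain: VoxelDomain, center, radius: float) -> VoxelDomain:
    """Relabel a sphere of tissue as TUMOR, preserving the cast.

    The sphere is clipped at the domain boundary.  A radius smaller than half
    the spacing may select no voxel centres; that is a documented degenerate
    case, not an error.  Electrode (and fed-fluid) voxels keep their label.
    """
    center = np.asarray(center, dtype=float)
    lo = domain.origin - domain.spacing / 2.0
    hi = lo + domain.spacing * np.asarray(domain.shape)
    if np.any(center + radius < lo) or np.any(center - radius > hi):
        raise GeometryError("pseudotumor sphere does not intersect the domain")
    labels = domain.labels.copy()
    i0 = np.maximum(np.floor((center - radius - domain.origin) / domain.spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((center + radius - domain.origin) / domain.spacing).astype(int) + 1,
                    np.asarray(domain.shape))
    grids = np.meshgrid(*(domain.origin[a] + domain.spacing * np.arange(i0[a], i1[a])
                          for a in range(3)), indexing="ij")
    dist = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    sub = labels[i0[0]:i1[0], i0[1]:i1[1], i0[2]:i1[2]]
    protect = np.isin(sub, (int(Label.ELECTRODE), int(Label.CONDUCTIVE_FLUID)))
    sub[(dist <= radius) & ~protect] = int(Label.TUMOR)
    out = VoxelDomain(labels, domain.spacing, ground_face=domain.ground_face,
                      electrode_tip_voxel=domain.electrode_tip_voxel,
                      tip_voxels=domain.tip_voxels,
                      injection_voxel=domain.injection_voxel,
                      origin=domain.origin, tip_direction=domain.tip_direction)
    return out


def straight_tree(length: float, radius: float) -> BronchialTree:
    """Single-segment cylindrical 'tree' (a straight electrode lumen)."""
    if length <= 0 or radius <= 0:
        raise GeometryError("straight electrode needs positive length and radius")
    nodes = {0: np.zeros(3), 1: np.array([0.0, 0.0, length])}
    segments = [Segment(0, 0, 1, radius, radius, 0)]
    tree = BronchialTree(nodes, segments)
    tree.validate()
    return tree


def make_straight_electrode(length: float, radius: float, spacing: float,
                            **raster_kwargs) -> VoxelDomain:
    """Fully-filled straight cylindrical electrode, rasterized."""
    tree = straight_tree(length, radius)
    fill = fill_electrode(tree, tree.total_lumen_volume_ml())
    return rasterize(tree, fill, spacing, **raster_kwargs)
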