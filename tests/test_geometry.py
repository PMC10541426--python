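"""Synthetic airway geometry: tree generation, electrode fill, rasterization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import airwayrfa as a
from airwayrfa.errors import GeometryError, SizingError
from airwayrfa.geometry import frustum_volume_mm3, straight_tree


class TestGenerateTree:
    def test_degenerate_depth_zero_is_a_single_trunk(self):
        tree = a.generate_tree(0, depth=0)
        assert len(tree.segments) == 1
        assert len(tree.nodes) == 2

    def test_full_binary_tree_counts(self):
        tree = a.generate_tree(0, depth=3)
        assert len(tree.segments) == 2**4 - 1 == 15
        assert len(tree.nodes) == 16

    def test_geometric_taper_closed_form(self):
        tree = a.generate_tree(0, depth=3, root_radius=1.5, radius_ratio=0.8)
        gen3 = [s for s in tree.segments if s.generation == 3]
        assert len(gen3) == 8
        for seg in gen3:
            assert seg.r_prox == pytest.approx(1.5 * 0.8**3)  # 0.768 mm

    def test_deterministic_for_fixed_seed(self):
        t1 = a.generate_tree(42, depth=3, jitter=0.3)
        t2 = a.generate_tree(42, depth=3, jitter=0.3)
        for s1, s2 in zip(t1.segments, t2.segments):
            assert s1 == s2
        for nid in t1.nodes:
            np.testing.assert_array_equal(t1.nodes[nid], t2.nodes[nid])

    def test_jitter_zero_matches_closed_form_statistics(self):
        tree = a.generate_tree(7, depth=2, root_radius=1.5, root_length=20.0,
                               radius_ratio=0.8, length_ratio=0.75, jitter=0.0)
        expected = sum(
            2**g * frustum_volume_mm3(1.5 * 0.8**g, 1.5 * 0.8**(g + 1),
                                      20.0 * 0.75**g) / 1000.0
            for g in range(3))
        assert tree.total_lumen_volume_ml() == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("kwargs", [
        {"depth": -1}, {"root_radius": 0.0}, {"radius_ratio": 0.0},
        {"radius_ratio": 1.2}, {"jitter": 1.0}, {"root_length": -3.0},
    ])
    def test_non_physical_parameters_rejected(self, kwargs):
        with pytest.raises(GeometryError):
            a.generate_tree(0, **{"depth": 2, **kwargs})

    @given(seed=st.integers(0, 2**31 - 1), depth=st.integers(0, 4),
           jitter=st.floats(0.0, 0.5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_generated_trees_satisfy_invariants(self, seed, depth, jitter):
        tree = a.generate_tree(seed, depth=depth, jitter=jitter)
        tree.validate()  # raises on any broken invariant

    def test_tree_json_round_trip(self, tmp_path):
        tree = a.generate_tree(3, depth=2, jitter=0.2)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        back = a.BronchialTree.from_json(path)
        assert back.to_dict() == tree.to_dict()


class TestFillElectrode:
    def test_zero_volume_gives_empty_fill(self):
        tree = a.generate_tree(0, depth=2)
        fill = a.fill_electrode(tree, 0.0)
        assert fill.fractions == {}
        assert fill.injected_volume_ml == 0.0

    def test_saturation_fills_every_segment(self):
        tree = a.generate_tree(0, depth=2)
        with pytest.warns(UserWarning):
            fill = a.fill_electrode(tree, tree.total_lumen_volume_ml() * 2)
        assert fill.clamped
        assert all(fill.fraction(s.id) == pytest.approx(1.0) for s in tree.segments)

    def test_two_segment_chain_partial_fill_arithmetic(self):
        # trunk 0.30 ml, single child 0.20 ml (cylinders); inject 0.40 ml
        r = 1.5
        L_trunk = 300.0 / (np.pi * r**2)
        L_child = 200.0 / (np.pi * r**2)
        nodes = {0: np.zeros(3), 1: np.array([0, 0, L_trunk]),
                 2: np.array([0, 0, L_trunk + L_child])}
        segs = [a.geometry.Segment(0, 0, 1, r, r, 0),
                a.geometry.Segment(1, 1, 2, r, r, 1)]
        tree = a.BronchialTree(nodes, segs)
        fill = a.fill_electrode(tree, 0.40)
        assert fill.fraction(0) == pytest.approx(1.0)
        assert fill.fraction(1) == pytest.approx(0.5, abs=1e-9)
        assert fill.filled_volume_ml(tree) == pytest.approx(0.40, rel=0.01)

    def test_filled_volume_matches_request_within_one_percent(self):
        tree = a.generate_tree(0, depth=3)
        for frac in (0.2, 0.5, 0.9):
            vol = frac * tree.total_lumen_volume_ml()
            fill = a.fill_electrode(tree, vol)
            assert fill.filled_volume_ml(tree) == pytest.approx(vol, rel=0.01)

    def test_contiguity_from_root(self):
        tree = a.generate_tree(0, depth=3)
        fill = a.fill_electrode(tree, 0.4 * tree.total_lumen_volume_ml())
        for seg in tree.segments:
            if fill.fraction(seg.id) > 0:
                # walk to root: every ancestor must be completely filled
                cur = seg
                while True:
                    parents = [s for s in tree.segments
                               if s.dist_node == cur.prox_node]
                    if not parents:
                        break
                    cur = parents[0]
                    assert fill.fraction(cur.id) == pytest.approx(1.0)

    @given(v1=st.floats(0.0, 0.5), v2=st.floats(0.0, 0.5))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_fill_is_monotone_in_volume(self, v1, v2):
        tree = a.generate_tree(1, depth=3)
        lo, hi = sorted([v1, v2])
        f_lo = a.fill_electrode(tree, lo)
        f_hi = a.fill_electrode(tree, hi)
        for seg in tree.segments:
            assert f_hi.fraction(seg.id) >= f_lo.fraction(seg.id) - 1e-9

    def test_negative_volume_rejected(self):
        with pytest.raises(GeometryError):
            a.fill_electrode(a.generate_tree(0, 1), -0.1)


class TestRasterize:
    def test_cylinder_volume_within_ten_percent(self):
        domain = a.make_straight_electrode(30.0, 2.0, 0.5)
        analytic = np.pi * 2.0**2 * 30.0  # mm^3
        voxel = domain.count(a.Label.ELECTRODE) * domain.spacing**3
        assert voxel == pytest.approx(analytic, rel=0.10)

    def test_empty_fill_has_no_electrode_voxels(self):
        tree = a.generate_tree(0, depth=1)
        domain = a.rasterize(tree, a.fill_electrode(tree, 0.0), 0.5)
        assert domain.count(a.Label.ELECTRODE) == 0
        assert domain.count(a.Label.AIRWAY_AIR) > 0

    def test_cast_is_one_face_connected_component(self):
        tree = a.generate_tree(0, depth=3)
        fill = a.fill_electrode(tree, tree.total_lumen_volume_ml())
        domain = a.rasterize(tree, fill, 1.0)
        assert domain.electrode_components() == 1

    def test_tip_voxel_is_electrode_and_distal(self):
        domain = a.make_straight_electrode(30.0, 1.5, 0.5)
        tip = domain.electrode_tip_voxel
        assert domain.labels[tip] == int(a.Label.ELECTRODE)
        # the tip must lie at the distal (high-z) end of the rod
        zs = np.argwhere(domain.mask(a.Label.ELECTRODE))[:, 2]
        assert tip[2] == zs.max()

    def test_sub_resolution_radius_raises_sizing_error(self):
        tree = straight_tree(20.0, 0.3)
        fill = a.fill_electrode(tree, tree.total_lumen_volume_ml())
        with pytest.raises(SizingError):
            a.rasterize(tree, fill, 1.0)

    def test_zero_length_electrode_rejected(self):
        with pytest.raises(GeometryError):
            a.make_straight_electrode(0.0, 1.5, 0.5)

    @pytest.mark.parametrize("spacing", [1.0, 0.5, 0.25])
    def test_lumen_volume_converges_with_spacing(self, spacing):
        tree = a.generate_tree(0, depth=1)
        fill = a.fill_electrode(tree, tree.total_lumen_volume_ml())
        domain = a.rasterize(tree, fill, spacing)
        voxel = domain.count(a.Label.ELECTRODE) * domain.spacing**3 / 1000.0
        analytic = tree.total_lumen_volume_ml()
        tol = {1.0: 0.35, 0.5: 0.15, 0.25: 0.08}[spacing]
        assert voxel == pytest.approx(analytic, rel=tol)

    def test_muscle_slab_on_ground_face(self):
        domain = a.make_straight_electrode(
            20.0, 1.5, 1.0, chest_wall_thickness=6.0, ground_face="x-")
        assert domain.labels[0].max() == int(a.Label.MUSCLE)
        assert domain.count(a.Label.MUSCLE) > 0

    def test_organ_slab_beyond_tip(self):
        domain = a.make_straight_electrode(20.0, 1.5, 1.0, organ_offset=8.0)
        organ = np.argwhere(domain.mask(a.Label.NON_TARGET_ORGAN))
        assert len(organ) > 0
        tip_z = domain.electrode_tip_voxel[2]
        assert organ[:, 2].min() > tip_z  # slab lies distal to the tip


class TestPseudotumor:
    def test_sphere_volume_within_ten_percent(self):
        domain = a.make_straight_electrode(30.0, 1.5, 0.5, margins=26.0)
        center = domain.voxel_center(domain.electrode_tip_voxel) + [12.0, 0, 0]
        out = a.place_pseudotumor(domain, center, 10.0)
        analytic = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0  # ml
        assert out.label_volume_ml(a.Label.TUMOR) == pytest.approx(analytic, rel=0.10)

    def test_electrode_voxels_preserved(self):
        domain = a.make_straight_electrode(30.0, 1.5, 1.0)
        n_before = domain.count(a.Label.ELECTRODE)
        center = domain.voxel_center(domain.electrode_tip_voxel)
        out = a.place_pseudotumor(domain, center, 6.0)
        assert out.count(a.Label.ELECTRODE) == n_before

    def test_tiny_sphere_may_label_nothing(self):
        domain = a.make_straight_electrode(20.0, 1.5, 1.0)
        center = domain.origin + 0.5 * domain.spacing  # between voxel centres
        out = a.place_pseudotumor(domain, center, 0.2)
        assert out.count(a.Label.TUMOR) in (0, 1)

    def test_disjoint_sphere_rejected(self):
        domain = a.make_straight_electrode(20.0, 1.5, 1.0)
        with pytest.raises(GeometryError):
            a.place_pseudotumor(domain, domain.origin - 500.0, 5.0)


class TestVolumeMatching:
    def test_straight_rod_matches_tree_volume_within_two_percent(self):
        tree = a.generate_tree(0, depth=3)
        target = tree.total_lumen_volume_ml()
        rod_length = target * 1000.0 / (np.pi * 1.5**2)
        rod = straight_tree(rod_length, 1.5)
        assert rod.total_lumen_volume_ml() == pytest.approx(target, rel=0.02)
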