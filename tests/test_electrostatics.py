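"""Quasi-static field solver: analytic oracles and circuit consistency."""

import numpy as np
import pytest

import airwayrfa as a
from airwayrfa.errors import ConfigurationError
from airwayrfa.geometry import VoxelDomain
from airwayrfa.materials import Label


def parallel_plate_domain(nx=21, ny=40, nz=40, spacing=2.5):
    """Electrode slab at x=0, ground face at x+; uniform tissue between."""
    labels = np.full((nx, ny, nz), int(Label.PARENCHYMA), dtype=np.uint8)
    labels[0] = int(Label.ELECTRODE)
    d = VoxelDomain(labels, spacing, ground_face="x+")
    d.electrode_tip_voxel = (0, ny // 2, nz // 2)
    return d


class TestParallelPlates:
    """Uniform slab between two Dirichlet faces: the 1-D Laplace oracle."""

    def test_linear_potential_and_uniform_field(self):
        d = parallel_plate_domain()
        # uniform conductivity everywhere makes the discrete solution exact
        table = a.default_table()
        table = table.with_override(Label.ELECTRODE,
                                    sigma=table[Label.PARENCHYMA].sigma)
        sol = a.solve_potential(d, table, 60.0)
        h_m = d.spacing * 1e-3
        gap = (d.shape[0] - 1) * h_m
        expected_E = 60.0 / gap
        interior = sol.Emag[1:-1]
        assert np.allclose(interior, expected_E, rtol=1e-6)
        # potential is linear in x
        profile = sol.phi[:, 20, 20]
        x = np.arange(d.shape[0])
        fit = np.polyfit(x, profile, 1)
        assert np.allclose(np.polyval(fit, x), profile, atol=1e-6 * 60.0)

    def test_power_and_impedance_match_circuit_theory(self):
        # sigma = 0.1 S/m, A = 1e-2 m^2, d = 0.05 m -> R = d/(sigma A) = 50 Ohm
        d = parallel_plate_domain(nx=21, ny=40, nz=40, spacing=2.5)
        table = a.default_table()
        table = table.with_override(Label.ELECTRODE,
                                    sigma=table[Label.PARENCHYMA].sigma)
        sigma = table[Label.PARENCHYMA].sigma
        h_m = d.spacing * 1e-3
        gap = (d.shape[0] - 1) * h_m
        area = d.shape[1] * d.shape[2] * h_m**2
        R = gap / (sigma * area)
        assert R == pytest.approx(50.0, rel=1e-9)
        sol = a.solve_potential(d, table, 60.0)
        assert sol.P == pytest.approx(60.0**2 / (2 * R), rel=1e-6)  # 36 W
        assert sol.Z == pytest.approx(R, rel=1e-6)
        # P equals the voxel sum of U by construction
        assert sol.P == pytest.approx(float(sol.U.sum() * d.voxel_volume_m3),
                                      rel=1e-12)

    def test_null_drive_gives_null_fields(self):
        d = parallel_plate_domain(nx=9, ny=8, nz=8)
        sol = a.solve_potential(d, a.default_table(), 0.0)
        assert np.all(sol.phi == 0)
        assert np.all(sol.U == 0)
        assert sol.P == 0
        assert np.isinf(sol.Z)


class TestConcentricSpheres:
    """Closed-form Laplace solution between two spherical Dirichlet shells."""

    def test_potential_matches_closed_form_within_5_percent(self):
        spacing = 0.5
        va, vb = 2.0, 20.0  # mm
        n = int(2 * (vb + 1) / spacing)
        labels = np.full((n, n, n), int(Label.PARENCHYMA), dtype=np.uint8)
        center = (n - 1) / 2.0
        idx = np.indices((n, n, n))
        r = np.sqrt(((idx - center) ** 2).sum(axis=0)) * spacing
        labels[r <= va] = int(Label.ELECTRODE)
        ground = r >= vb
        d = VoxelDomain(labels, spacing, ground_face="x-")
        V0 = 50.0
        sol = a.solve_potential(d, a.default_table(), V0, ground_mask=ground)
        exact = V0 * (1.0 / np.maximum(r, va) - 1.0 / vb) / (1.0 / va - 1.0 / vb)
        exact = np.clip(exact, 0.0, V0)
        band = (r > va + spacing) & (r < vb - spacing)
        err = np.abs(sol.phi - exact)[band].max() / V0
        assert err < 0.05

    def test_discrete_maximum_principle(self):
        spacing = 1.0
        n = 30
        labels = np.full((n, n, n), int(Label.PARENCHYMA), dtype=np.uint8)
        labels[12:18, 12:18, 12:18] = int(Label.ELECTRODE)
        d = VoxelDomain(labels, spacing, ground_face="z-")
        sol = a.solve_potential(d, a.default_table(), 70.0)
        assert sol.phi.min() >= -1e-9
        assert sol.phi.max() <= 70.0 + 1e-9


class TestHeatSourceAndImpedance:
    def test_heat_source_pointwise_formula(self):
        E = np.array([[[3.0, 0.0]]])
        sigma = np.array([[[2.0, 2.0]]])
        U = a.compute_heat_source(E, sigma)
        assert U[0, 0, 0] == pytest.approx(9.0)   # sigma/2 * E^2
        assert U[0, 0, 1] == 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            a.compute_heat_source(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))

    def test_impedance_values(self):
        assert a.compute_impedance(60.0, 36.0) == pytest.approx(50.0)
        assert np.isinf(a.compute_impedance(10.0, 0.0))
        with pytest.raises(ConfigurationError):
            a.compute_impedance(10.0, -1.0)

    def test_doubling_voltage_quadruples_power_keeps_impedance(self):
        d = parallel_plate_domain(nx=11, ny=10, nz=10)
        table = a.default_table()
        s1 = a.solve_potential(d, table, 40.0)
        s2 = a.solve_potential(d, table, 80.0)
        assert s2.P == pytest.approx(4.0 * s1.P, rel=1e-9)
        assert s2.Z == pytest.approx(s1.Z, rel=1e-9)


@pytest.fixture(scope="module")
def rod_domain():
    return a.make_straight_electrode(20.0, 1.5, 1.0, margins=12.0,
                                     chest_wall_thickness=5.0,
                                     ground_face="x-")


class TestScalingAndConservation:

    def test_unit_solve_rescaling_matches_fresh_solve(self, rod_domain):
        table = a.default_table()
        unit = a.solve_potential(rod_domain, table, 1.0)
        fresh = a.solve_potential(rod_domain, table, 65.0)
        scaled = unit.rescaled(65.0)
        assert np.allclose(scaled.phi, fresh.phi, atol=65.0 * 1e-7)
        assert scaled.P == pytest.approx(fresh.P, rel=1e-6)
        assert scaled.Z == pytest.approx(fresh.Z, rel=1e-6)

    def test_current_conservation_source_to_ground(self, rod_domain):
        sol = a.solve_potential(rod_domain, a.default_table(), 80.0)
        i_src, i_gnd = a.boundary_currents(sol, rod_domain)
        assert i_src == pytest.approx(i_gnd, rel=0.01)

    def test_missing_source_voxels_is_a_configuration_error(self):
        labels = np.full((8, 8, 8), int(Label.PARENCHYMA), dtype=np.uint8)
        d = VoxelDomain(labels, 1.0, ground_face="x-")
        with pytest.raises(ConfigurationError):
            a.solve_potential(d, a.default_table(), 50.0)
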