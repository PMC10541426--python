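"""Pennes bioheat stepping: analytic oracles, stability, sensor semantics."""

import numpy as np
import pytest

import airwayrfa as a
from airwayrfa.bioheat import BioheatSolver
from airwayrfa.errors import ConfigurationError, StabilityError
from airwayrfa.geometry import VoxelDomain
from airwayrfa.materials import Label, MaterialRecord, MaterialTable


def uniform_domain(shape=(8, 8, 8), spacing=1.0, label=Label.PARENCHYMA):
    labels = np.full(shape, int(label), dtype=np.uint8)
    return VoxelDomain(labels, spacing, ground_face="x-")


def uniform_table(sigma=0.1, k=0.39, rho=1000.0, c=4000.0, omega=0.0):
    rec = MaterialRecord(sigma=sigma, k=k, rho=rho, c=c, omega=omega)
    return MaterialTable({label: rec for label in Label})


class TestEquilibriumAndStability:
    def test_no_source_stays_at_body_temperature(self):
        domain = uniform_domain()
        table = a.default_table()
        solver = BioheatSolver(domain, table)
        state = solver.make_state()
        U = np.zeros(domain.shape)
        for _ in range(10):
            solver.step(state, U, 0.5 * solver.stable_dt)
        assert np.allclose(state.T, table.T_b, atol=1e-12)

    def test_step_rejects_unstable_dt(self):
        domain = uniform_domain()
        solver = BioheatSolver(domain, a.default_table())
        state = solver.make_state()
        with pytest.raises(StabilityError):
            solver.step(state, np.zeros(domain.shape), 2.0 * solver.stable_dt)

    def test_stability_bound_formula(self):
        domain = uniform_domain(spacing=2.0)
        table = uniform_table(k=0.5, rho=1000.0, c=3600.0)
        solver = BioheatSolver(domain, table)
        h = 2.0e-3
        assert solver.stable_dt == pytest.approx(1000 * 3600 * h**2 / (6 * 0.5))

    def test_tmax_is_a_running_maximum(self):
        domain = uniform_domain()
        solver = BioheatSolver(domain, a.default_table())
        state = solver.make_state()
        U = np.zeros(domain.shape)
        U[4, 4, 4] = 5e5
        for _ in range(20):
            solver.step(state, U, 0.5 * solver.stable_dt)
        assert np.all(state.Tmax >= state.T - 1e-12)
        peak = state.Tmax.copy()
        for _ in range(200):  # source off: T relaxes, Tmax must not
            solver.step(state, np.zeros(domain.shape), 0.5 * solver.stable_dt)
        assert np.all(state.Tmax >= peak - 1e-12)


class TestPerfusionDecayOracle:
    def test_exponential_relaxation_to_blood_temperature(self):
        # rho*c = 4e6 J/m^3/K and rho_b*c_b*omega = 4e3 W/m^3/K -> tau = 1000 s
        domain = uniform_domain(shape=(6, 6, 6))
        table = uniform_table(k=1e-9, rho=1000.0, c=4000.0)
        omega = 4.0e3 / (table.rho_b * table.c_b)
        table = MaterialTable(
            {label: MaterialRecord(sigma=0.1, k=1e-9, rho=1000.0, c=4000.0,
                                   omega=omega) for label in Label},
            rho_b=table.rho_b, c_b=table.c_b, T_b=37.0)
        solver = BioheatSolver(domain, table)
        state = solver.make_state(57.0)       # 20 K above blood
        U = np.zeros(domain.shape)
        dt, t_end = 0.5, 10.0
        for _ in range(int(t_end / dt)):
            solver.step(state, U, dt)
        tau = 1000.0
        expected = 37.0 + 20.0 * np.exp(-t_end / tau)
        assert np.allclose(state.T, expected, rtol=1e-3 * 20 / expected)
        # 0.1% accuracy on the decaying excess temperature
        excess = state.T[3, 3, 3] - 37.0
        assert excess == pytest.approx(20.0 * np.exp(-t_end / tau), rel=1e-3)


class TestDiffusionOracle:
    def test_gaussian_profile_follows_heat_kernel(self):
        # 1-D rod, no perfusion, no source: variance grows by 2*alpha*t
        n, spacing = 161, 0.5
        labels = np.full((n, 1, 1), int(Label.PARENCHYMA), dtype=np.uint8)
        domain = VoxelDomain(labels, spacing, ground_face="x-")
        table = uniform_table(k=0.39, rho=394.0, c=3886.0)
        alpha = 0.39 / (394.0 * 3886.0)           # m^2/s
        solver = BioheatSolver(domain, table, boundary="neumann")
        x = (np.arange(n) - (n - 1) / 2.0) * spacing * 1e-3  # metres
        s0 = 3.0e-3
        A = 20.0
        state = solver.make_state(37.0 + A * np.exp(-x**2 / (2 * s0**2))[:, None, None])
        t_end = 10.0
        nsteps = int(np.ceil(t_end / (0.5 * solver.stable_dt)))
        for _ in range(nsteps):
            solver.step(state, np.zeros(domain.shape), t_end / nsteps)
        s2 = s0**2 + 2 * alpha * t_end
        expected = 37.0 + A * s0 / np.sqrt(s2) * np.exp(-x**2 / (2 * s2))
        err = np.abs(state.T[:, 0, 0] - expected).max() / A
        assert err < 0.01

    def test_implicit_scheme_agrees_with_explicit(self):
        domain = uniform_domain(shape=(12, 12, 12))
        table = a.default_table()
        U = np.zeros(domain.shape)
        U[6, 6, 6] = 2e5
        exp_solver = BioheatSolver(domain, table, scheme="explicit")
        imp_solver = BioheatSolver(domain, table, scheme="implicit", dt=0.05)
        se = exp_solver.make_state()
        si = imp_solver.make_state()
        exp_solver.advance(se, U, 5.0)
        imp_solver.advance(si, U, 5.0)
        assert np.abs(se.T - si.T).max() < 0.05 * (se.T.max() - 37.0)


class TestEnergyBalance:
    def test_insulated_domain_energy_balance_closes(self):
        domain = uniform_domain(shape=(10, 10, 10))
        table = uniform_table(omega=0.0)
        solver = BioheatSolver(domain, table, boundary="neumann")
        state = solver.make_state()
        rng = np.random.default_rng(0)
        U = rng.uniform(0, 5e5, domain.shape)
        dt = 0.5 * solver.stable_dt
        for _ in range(20):
            e0 = solver.total_energy(state)
            solver.step(state, U, dt)
            de = solver.total_energy(state) - e0
            expected = float(U.sum() * domain.voxel_volume_m3 * dt)
            assert de == pytest.approx(expected, rel=0.01)


class TestComparisonPrinciple:
    def test_larger_source_never_lowers_temperature(self):
        domain = uniform_domain(shape=(10, 10, 10))
        table = a.default_table()
        rng = np.random.default_rng(1)
        U1 = rng.uniform(0, 1e5, domain.shape)
        U2 = U1 + rng.uniform(0, 1e5, domain.shape)
        s1 = BioheatSolver(domain, table)
        s2 = BioheatSolver(domain, table)
        st1, st2 = s1.make_state(), s2.make_state()
        dt = 0.5 * s1.stable_dt
        for _ in range(30):
            s1.step(st1, U1, dt)
            s2.step(st2, U2, dt)
        assert np.all(st2.T >= st1.T - 1e-12)


class TestSensor:
    def test_uniform_temperature_reads_uniform(self):
        domain = a.make_straight_electrode(20.0, 1.5, 1.0)
        state = a.ThermalState(np.full(domain.shape, 37.0))
        sensor, tip = a.read_sensor(state, domain)
        assert sensor == 37.0 and tip == 37.0

    def test_sensor_is_the_cast_volume_mean(self):
        labels = np.full((4, 1, 1), int(Label.PARENCHYMA), dtype=np.uint8)
        labels[1] = labels[2] = int(Label.ELECTRODE)
        domain = VoxelDomain(labels, 1.0, ground_face="x-",
                             electrode_tip_voxel=(2, 0, 0))
        T = np.full((4, 1, 1), 37.0)
        T[1], T[2] = 50.0, 70.0
        sensor, tip = a.read_sensor(a.ThermalState(T), domain)
        assert sensor == pytest.approx(60.0)  # arithmetic mean of 50 and 70
        assert tip == pytest.approx(70.0)

    def test_heating_never_lowers_the_sensor_below_body(self):
        domain = a.make_straight_electrode(20.0, 1.5, 1.0, margins=10.0)
        table = a.default_table()
        sol = a.solve_potential(domain, table, 60.0)
        solver = BioheatSolver(domain, table, scheme="implicit", dt=0.5)
        state = solver.make_state()
        solver.advance(state, sol.U, 5.0)
        sensor, _ = a.read_sensor(state, domain)
        assert sensor >= table.T_b

    def test_missing_electrode_is_a_configuration_error(self):
        domain = uniform_domain()
        with pytest.raises(ConfigurationError):
            a.read_sensor(a.ThermalState(np.full(domain.shape, 37.0)), domain)
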