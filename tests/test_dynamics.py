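"""Rigid-body integrator: conservation laws, thermostat, free-diffusion MD."""
import numpy as np
import pytest

from pistack.dynamics import (
    IntegrationError,
    IntegratorConfig,
    run_free_md,
    run_md,
    step,
)
from pistack.model import SimSystem
from pistack.structures import DimerGeometry, build_pah, build_stacked_dimer
from pistack.units import KB_KCAL_MOL_K, KCAL_PER_MOL_TO_INTERNAL


def _zero_forces(system):
    return np.zeros((system.n_mobile_atoms, 3)), 0.0


@pytest.fixture()
def nve_dimer(anthracene_opt):
    """Bound anthracene dimer, both molecules free, thermal velocities."""
    system = anthracene_opt.system.copy()
    system.fixed_flags[:] = False
    rng = np.random.default_rng(1)
    system.set_thermal_velocities(0, 300.0, rng)
    system.set_thermal_velocities(1, 300.0, rng)
    return system


class TestStep:
    def test_zero_force_zero_velocity_is_stationary(self, benzene):
        system = SimSystem([benzene])
        x0 = system.x.copy()
        cfg = IntegratorConfig()
        forces = np.zeros((system.n_mobile_atoms, 3))
        for _ in range(10):
            forces, _ = step(system, forces, cfg, _zero_forces)
        assert np.array_equal(system.x, x0)

    def test_constant_force_kinematics(self, anthracene):
        """COM displacement F t^2 / (2 m) under a constant net force."""
        system = SimSystem([anthracene])
        mass = system.mol_masses[0]
        f_total = 2.0  # kcal/(mol*A) along x
        w = anthracene.masses / mass

        def const(sys):
            f = np.zeros((sys.n_mobile_atoms, 3))
            f[:, 0] = w * f_total  # mass-weighted: net force, no torque
            return f, 0.0

        cfg = IntegratorConfig(timestep=0.001)
        forces, _ = const(system)
        t_total = 2.0
        for _ in range(int(t_total / cfg.timestep)):
            forces, _ = step(system, forces, cfg, const)
        expected = f_total * KCAL_PER_MOL_TO_INTERNAL / mass * t_total**2 / 2.0
        assert system.coms[0, 0] == pytest.approx(expected, rel=1e-6)

    def test_fixed_molecule_never_moves(self, anthracene_opt):
        system = anthracene_opt.system.copy()  # molecule 0 fixed
        rng = np.random.default_rng(3)
        system.set_thermal_velocities(1, 300.0, rng)
        res = run_md(system, IntegratorConfig(), 2.0, record_every=1.0)
        assert np.array_equal(
            res.frames[0][1][0], res.frames[-1][1][0]
        )
        assert np.all(system.vels[0] == 0.0)

    def test_nonfinite_force_aborts_with_frame(self, benzene):
        system = SimSystem([benzene])

        def bad(sys):
            f = np.full((sys.n_mobile_atoms, 3), np.nan)
            return f, np.nan

        with pytest.raises(IntegrationError) as err:
            step(system, np.zeros((system.n_mobile_atoms, 3)), IntegratorConfig(), bad)
        assert err.value.frame is not None


class TestConservation:
    def test_nve_energy_drift_below_one_percent(self, nve_dimer):
        res = run_free_md(nve_dimer, IntegratorConfig(thermostat="none"), 50.0, record_every=1.0)
        scale = abs(res.potential.min())
        drift = np.abs(res.total_energy - res.total_energy[0]).max()
        assert drift < 0.01 * scale

    def test_momentum_and_angular_momentum_conserved(self, nve_dimer):
        system = nve_dimer.copy()
        p0 = system.linear_momentum()
        l0 = system.angular_momentum()
        run_md(system, IntegratorConfig(thermostat="none"), 20.0, record_every=20.0)
        p1 = system.linear_momentum()
        l1 = system.angular_momentum()
        assert np.linalg.norm(p1 - p0) < 1e-6 * max(np.linalg.norm(p0), 1.0)
        assert np.linalg.norm(l1 - l0) < 1e-6 * max(np.linalg.norm(l0), 1.0)

    def test_rigid_monomers_do_not_deform(self, nve_dimer):
        system = nve_dimer.copy()
        m = system.molecules[1]
        d0 = np.linalg.norm(m.coords[:, None] - m.coords[None], axis=-1)
        run_md(system, IntegratorConfig(thermostat="none"), 10.0, record_every=10.0)
        d1 = np.linalg.norm(m.coords[:, None] - m.coords[None], axis=-1)
        assert np.abs(d1 - d0).max() < 1e-8

    def test_timestep_halving_reduces_drift_fourfold(self, nve_dimer):
        """Second-order integrator: energy error scales ~dt^2."""
        drifts = {}
        for dt in (0.001, 0.0005):
            system = nve_dimer.copy()
            res = run_free_md(
                system, IntegratorConfig(timestep=dt, thermostat="none"), 10.0, record_every=0.5
            )
            drifts[dt] = np.abs(res.total_energy - res.total_energy[0]).max()
        ratio = drifts[0.001] / drifts[0.0005]
        assert 2.0 < ratio < 8.0


class TestLangevin:
    def test_translational_equipartition(self, anthracene):
        """Long-run translational KE within 20% of (3/2) kT at 300 K."""
        system = SimSystem([anthracene])
        cfg = IntegratorConfig(thermostat="langevin", temperature=300.0, friction=5.0, seed=8)
        samples = []

        def sample(s):
            samples.append(s.translational_kinetic_energy(0))
            return False

        run_md(system, cfg, 200.0, record_every=0.5, force_fn=_zero_forces, stop_when=sample)
        ke = np.mean(samples[40:])  # skip 20 ps burn-in
        target = 1.5 * KB_KCAL_MOL_K * 300.0
        assert abs(ke - target) < 0.2 * target

    def test_cold_start_at_zero_temperature_is_stationary(self, benzene):
        system = SimSystem([benzene])
        cfg = IntegratorConfig(thermostat="langevin", temperature=0.0, friction=1.0, seed=0)
        x0 = system.x.copy()
        run_md(system, cfg, 1.0, record_every=1.0, force_fn=_zero_forces)
        assert np.allclose(system.x, x0, atol=1e-12)

    def test_langevin_requires_generator_in_bare_step(self, benzene):
        system = SimSystem([benzene])
        cfg = IntegratorConfig(thermostat="langevin", seed=None)
        with pytest.raises(ValueError):
            step(system, np.zeros((12, 3)), cfg, _zero_forces, rng=None)


class TestFreeMD:
    def test_com_trace_length(self, benzene):
        sys2 = build_stacked_dimer(benzene, DimerGeometry(8.0))
        res = run_free_md(sys2, IntegratorConfig(), 5.0, record_every=1.0)
        assert len(res.times) == 6  # floor(5/1) + 1
        trace = res.com_trace()
        assert list(trace.columns) == ["time_ps", "distance_A"]

    def test_identical_seed_identical_trajectory(self, benzene):
        sys2 = build_stacked_dimer(benzene, DimerGeometry(6.0))
        cfg = IntegratorConfig(thermostat="langevin", seed=5)
        r1 = run_free_md(sys2, cfg, 3.0, record_every=0.5)
        r2 = run_free_md(sys2, cfg, 3.0, record_every=0.5)
        assert np.array_equal(r1.com_distance, r2.com_distance)
        assert np.array_equal(r1.frames[-1][1][0], r2.frames[-1][1][0])

    def test_duration_must_be_positive(self, benzene):
        with pytest.raises(ValueError):
            run_free_md(SimSystem([benzene]), IntegratorConfig(), 0.0)

    def test_spontaneous_dimerization_capture(self, dimerization_run):
        """Two monomers 15 A apart bind (COM < 6 A) within the 5 ns budget."""
        assert dimerization_run.com_distance.min() < 6.0 or (
            dimerization_run.final_system.com_separation() < 6.0
        )
        assert dimerization_run.times[-1] <= 5000.0
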