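"""Integrator correctness: classical limit, quantum statistics, estimators."""

import math

import numpy as np
import pytest

from nqekit.dynamics import (PIMDState, init_state, kinetic_estimators,
                             normal_mode_frequencies, pimd_step,
                             ring_polymer_covariance, run_trajectory,
                             thermal_energy)
from nqekit.fastpath import run_trajectory_fast, supports_fast_path
from nqekit.potentials import DoubleWellPES, HarmonicPES, RotorBondPES
from nqekit.units import KB, KCAL_TO_INT


def _harmonic(k=50.0, m=1.008):
    return HarmonicPES(k=[k], mass=m), math.sqrt(k * KCAL_TO_INT / m)


class TestThermalEnergy:
    def test_room_temperature_value(self):
        # ~0.6 kcal/mol at 300 K, the torsional-barrier yardstick
        assert thermal_energy(300.0) == pytest.approx(0.001987204259 * 300, rel=1e-9)
        assert thermal_energy(300.0) == pytest.approx(0.6, abs=0.01)

    def test_linearity(self):
        assert thermal_energy(600.0) == 2 * thermal_energy(300.0)
        assert thermal_energy(1e-8) < 1e-10

    def test_domain(self):
        with pytest.raises(ValueError):
            thermal_energy(0.0)
        with pytest.raises(ValueError):
            thermal_energy(-10.0)


class TestInitState:
    def test_classical_limit_positions(self):
        st = init_state([1.0, 2.0, 3.0], [1.0, 1.0, 1.0], 300.0, 1, seed=4)
        np.testing.assert_array_equal(st.q, [[1.0, 2.0, 3.0]])
        assert st.omega_k[0] == 0.0

    def test_determinism(self):
        a = init_state([0.0], [2.0], 250.0, 8, seed=7)
        b = init_state([0.0], [2.0], 250.0, 8, seed=7)
        np.testing.assert_array_equal(a.p, b.p)
        np.testing.assert_array_equal(a.q, b.q)

    def test_maxwell_boltzmann_momentum_variance(self):
        m, T = 3.5, 320.0
        draws = np.concatenate([
            init_state(np.zeros(50), np.full(50, m), T, 1, seed=s).p.ravel()
            for s in range(40)
        ])
        var = draws.var()
        expected = m * KB * T * KCAL_TO_INT
        se = expected * math.sqrt(2.0 / len(draws))
        assert abs(var - expected) < 3 * se

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            init_state([0.0], [1.0], 300.0, 0, seed=1)
        with pytest.raises(ValueError):
            init_state([0.0], [1.0], -5.0, 4, seed=1)


class TestPropagation:
    def test_velocity_verlet_energy_conservation(self):
        """P=1, thermostat off: symplectic drift below 1e-6 kcal/mol/period."""
        pes, omega = _harmonic()
        period = 2 * math.pi / omega
        traj = run_trajectory(pes, [0.3], T=300, P=1, dt=period / 1000,
                              steps=5000, stride=1, seed=1,
                              thermostat_time=None, thermal_spread=False)
        H = traj.records["hamiltonian"]
        periods = 5000 / 1000
        assert abs(H[-1] - H[0]) / periods < 1e-6
        assert np.ptp(H) < 1e-4  # bounded oscillation, no secular drift

    def test_free_particle_momentum_conserved(self):
        pes = HarmonicPES(k=[0.0], mass=2.0)
        st = init_state([0.0], [2.0], 300.0, 4, seed=2)
        p0 = st.p.sum(axis=0).copy()
        provider = lambda x: (0.0, np.zeros(1))
        for _ in range(200):
            pimd_step(st, provider, dt=0.5, thermostat_time=None)
        np.testing.assert_allclose(st.p.sum(axis=0), p0, atol=1e-12)

    def test_invalid_dt(self):
        pes, _ = _harmonic()
        st = init_state([0.0], [1.008], 300.0, 1, seed=0)
        with pytest.raises(ValueError):
            pimd_step(st, lambda x: pes.evaluate(x), dt=0.0)

    def test_nan_forces_abort_with_truncated_trajectory(self):
        class Exploding:
            name = "exploding"
            def masses(self):
                return np.array([1.0])
            def evaluate(self, x):
                if abs(x[0]) > 0.2:
                    return math.nan, np.array([math.nan])
                return 0.0, np.array([0.0])

        traj = run_trajectory(Exploding(), [0.0], T=300, P=1, dt=1.0,
                              steps=2000, stride=1, seed=3,
                              thermostat_time=50.0, thermal_spread=False)
        assert traj.status == "aborted"
        assert 0 < traj.n_frames < 2001


class TestStationaryStatistics:
    @pytest.mark.parametrize("P", [1, 2, 4, 8])
    def test_ring_polymer_covariance_matches_gaussian_integrals(self, P):
        """Sampled bead covariance vs the analytic quadratic-Hamiltonian
        covariance (normal-mode Gaussian integrals)."""
        pes, omega = _harmonic()
        traj = run_trajectory_fast(pes, [0.0], T=300.0, P=P, dt=0.5,
                                   steps=150000, stride=3, seed=10 + P,
                                   thermostat_time=20.0, store_beads=True)
        B = traj.beads[3000:, :, 0]
        cov = np.atleast_2d(np.cov(B.T))
        exact = ring_polymer_covariance(P, 300.0, 1.008, omega)
        assert np.abs(cov - exact).max() / np.abs(exact).max() < 0.08

    def test_classical_equipartition_estimators_exact_at_p1(self):
        pes, _ = _harmonic()
        traj = run_trajectory(pes, [0.0], T=300, P=1, dt=0.5, steps=200,
                              stride=10, seed=5, thermostat_time=20.0)
        kT = KB * 300
        np.testing.assert_allclose(traj.records["kinetic_primitive"], kT / 2)
        np.testing.assert_allclose(traj.records["kinetic_virial"][0], kT / 2)

    def test_primitive_and_virial_agree_in_expectation(self):
        pes, _ = _harmonic()
        traj = run_trajectory_fast(pes, [0.0], T=300.0, P=8, dt=0.3,
                                   steps=200000, stride=5, seed=6,
                                   thermostat_time=20.0)
        est = kinetic_estimators(traj)
        (mp, sp), (mv, sv) = est["primitive"], est["virial"]
        assert abs(mp - mv) < 3 * math.hypot(sp, sv)

    def test_double_well_occupancy_detailed_balance(self):
        """Thermostatted classical sampling reproduces the symmetric-well
        Boltzmann occupancy (1:1) within 3 SE."""
        pes = DoubleWellPES(a=20.0, b=8.0, mass=1.008)  # barrier 0.8 kcal/mol
        traj = run_trajectory_fast(pes, [pes.minima[1]], T=300.0, P=1, dt=0.5,
                                   steps=400000, stride=10, seed=8,
                                   thermostat_time=50.0)
        x = traj.frames[2000:, 0]
        right = (x > 0).astype(float)
        nblocks = 20
        blocks = right[:len(right) // nblocks * nblocks].reshape(nblocks, -1).mean(axis=1)
        se = blocks.std(ddof=1) / math.sqrt(nblocks)
        assert abs(right.mean() - 0.5) < 3 * se

    def test_fast_path_statistically_matches_generic_integrator(self):
        """Same model, same settings, independent noise: equal means."""
        pes = RotorBondPES()
        kw = dict(T=300.0, P=4, dt=0.2, steps=120000, stride=20,
                  thermostat_time=500.0)
        a = run_trajectory(pes, [0.1, 0.0], seed=21, **kw)
        b = run_trajectory_fast(pes, [0.1, 0.0], seed=21, **kw)
        for key in ("potential", "kinetic_virial"):
            xa = a.records[key][600:]
            xb = b.records[key][600:]
            na = len(xa) // 20 * 20
            sa = xa[:na].reshape(20, -1).mean(axis=1).std(ddof=1) / math.sqrt(20)
            sb = xb[:na].reshape(20, -1).mean(axis=1).std(ddof=1) / math.sqrt(20)
            assert abs(xa.mean() - xb.mean()) < 4 * math.hypot(sa, sb), key


class TestTrajectoryBookkeeping:
    def test_zero_steps_single_frame(self):
        pes, _ = _harmonic()
        traj = run_trajectory(pes, [0.4], T=300, P=2, dt=0.2, steps=0,
                              stride=1, seed=0)
        assert traj.n_frames == 1
        np.testing.assert_allclose(traj.frames[0], [0.4])

    def test_seed_reproducibility_bitwise(self):
        pes, _ = _harmonic()
        kw = dict(T=300, P=4, dt=0.2, steps=500, stride=5, seed=42,
                  thermostat_time=50.0)
        a = run_trajectory(pes, [0.0], **kw)
        b = run_trajectory(pes, [0.0], **kw)
        for key in a.records:
            np.testing.assert_array_equal(a.records[key], b.records[key])

    def test_stride_halves_frames(self):
        pes, _ = _harmonic()
        t1 = run_trajectory(pes, [0.0], T=300, P=1, dt=0.2, steps=400,
                            stride=10, seed=1)
        t2 = run_trajectory(pes, [0.0], T=300, P=1, dt=0.2, steps=400,
                            stride=20, seed=1)
        assert t1.n_frames == 41 and t2.n_frames == 21
        np.testing.assert_allclose(t1.times[::2], t2.times)

    def test_state_serialization_roundtrip(self):
        st = init_state([0.1, -0.2], [1.0, 6.0], 300.0, 4, seed=11)
        back = PIMDState.from_dict(st.to_dict())
        np.testing.assert_array_equal(st.q, back.q)
        np.testing.assert_array_equal(st.p, back.p)
        assert back.rng.normal() == st.rng.normal()

    def test_normal_mode_frequencies(self):
        w = normal_mode_frequencies(4, 300.0)
        assert w[0] == 0.0
        assert np.all(np.diff(w) >= 0)
        # doubly degenerate interior modes for even P
        assert w[1] == pytest.approx(w[2], rel=1e-12)

    def test_fast_path_support_detection(self):
        assert supports_fast_path(RotorBondPES())
        assert not supports_fast_path(object())

    def test_bead_ramp_declares_convergence(self):
        """Virial total energy settles along the 1→32 doubling protocol."""
        from nqekit.dynamics import bead_convergence_ramp
        pes, _ = _harmonic(k=50.0)
        records, P_conv = bead_convergence_ramp(
            pes, [0.0], ramp=(1, 4, 8, 16, 32), tol=0.05,
            runner=run_trajectory_fast, T=300.0, dt=0.3, steps=60000,
            stride=5, seed=31, thermostat_time=20.0)
        assert [r["P"] for r in records] == [1, 4, 8, 16, 32]
        energies = [r["energy"] for r in records]
        # quantum energy exceeds the classical kT and grows with P
        assert energies[0] < energies[-1]
        assert P_conv in (8, 16, 32)
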