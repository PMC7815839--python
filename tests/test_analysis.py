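"""Analysis operators: observables, surfaces, fits, dispersion toolkit."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nqekit.analysis import (DrudeOscillator, casimir_polder_c6,
                             detect_localized_states, dihedral_angle,
                             effective_radius,
                             ensemble_interaction_scan,
                             ensemble_polarizability_increment,
                             fit_power_law, free_energy_surface,
                             polarizability_from_radius, time_angle_histogram,
                             vdw_energy)
from nqekit.data import MolecularConfiguration
from nqekit.units import HBAR, KB


class TestDihedral:
    def test_trans_and_cis(self):
        trans = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0.0]])
        cis = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0.0]])
        assert dihedral_angle(trans, 0, 1, 2, 3) == pytest.approx(180.0)
        assert dihedral_angle(cis, 0, 1, 2, 3) == pytest.approx(0.0, abs=1e-12)

    def test_right_handed_quarter_twist_hand_oracle(self):
        """+90° twist, checked against the atan2 cross-product formula
        evaluated by hand: b1=(0,1,0) about b2=(1,0,0) with b3=(0,0,1)
        gives n1=(0,0,-1)? -> atan2(|b2|(n1×n2)·b2 ... = +90."""
        coords = np.array([[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 0, 1.0]])
        assert dihedral_angle(coords, 0, 1, 2, 3) == pytest.approx(90.0)
        # mirrored (left-handed) twist flips the sign
        coords_m = coords * np.array([1, 1, -1.0])
        assert dihedral_angle(coords_m, 0, 1, 2, 3) == pytest.approx(-90.0)

    def test_degenerate_and_invalid(self):
        collinear = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 1, 0.0]])
        with pytest.raises(ValueError, match="collinear"):
            dihedral_angle(collinear, 0, 1, 2, 3)
        with pytest.raises(ValueError, match="distinct"):
            dihedral_angle(collinear, 0, 1, 1, 3)


class TestFreeEnergySurface:
    def test_uniform_density_is_flat(self, rng):
        x = rng.uniform(0, 10, size=200000)
        fes = free_energy_surface(x, bins=10, T=300.0)
        assert float(fes.values.max()) < 0.03
        assert fes.counts.sum() == len(x)

    def test_two_state_delta_f_boltzmann_inversion(self, rng):
        p1, p2 = 0.8, 0.2
        n = 100000
        x = np.where(rng.uniform(size=n) < p1, 0.5, 1.5)
        fes = free_energy_surface(x, bins=2, ranges=(0.0, 2.0), T=300.0)
        expected = -KB * 300 * math.log(p2 / p1)
        assert fes.delta_f((0,), (1,)) == pytest.approx(expected, abs=0.01)

    def test_empty_and_degenerate_inputs(self):
        with pytest.raises(ValueError):
            free_energy_surface([], T=300.0)
        fes = free_energy_surface(np.full(50, 1.7), bins=5, ranges=(0, 2), T=300.0)
        assert (~fes.values.mask).sum() == 1
        assert float(fes.values[~fes.values.mask][0]) == 0.0

    def test_2d_masks_empty_bins(self, rng):
        xy = rng.normal(size=(2000, 2))
        fes = free_energy_surface(xy, bins=30, T=300.0)
        assert fes.values.mask.any()
        assert float(fes.values.min()) == 0.0

    def test_normalization_invariance_under_proportional_counts(self, rng):
        """Scaling every occupied bin's mass by a common factor (here by
        duplicating the sample set) changes F by a bin-independent shift —
        identically zero with max-normalization."""
        x = rng.normal(size=5000)
        edges = np.linspace(-4, 4, 21)
        fes1 = free_energy_surface(x, bins=edges, T=300.0)
        fes2 = free_energy_surface(np.tile(x, 3), bins=edges, T=300.0)
        d = (fes2.values - fes1.values).compressed()
        np.testing.assert_allclose(d, d[0], atol=1e-12)
        assert d[0] == pytest.approx(0.0, abs=1e-12)


class TestTimeAngleHistogram:
    def test_constant_angle_single_row(self):
        counts, _, a_edges = time_angle_histogram(np.full(5000, 33.0), dt=10.0)
        col = np.digitize(33.0, a_edges) - 1
        assert counts[:, col].sum() == 5000
        assert counts.sum() == 5000

    def test_column_sums_are_frames_per_window(self):
        angles = np.linspace(0, 3600, 10000) % 360 - 180
        counts, t_edges, _ = time_angle_histogram(angles, dt=10.0)
        # 5 ps windows of 10 fs frames -> 500 frames per full window
        assert counts.sum(axis=1)[0] == 500

    def test_default_bins_match_convention(self):
        counts, t_edges, a_edges = time_angle_histogram(np.zeros(100), dt=100.0)
        assert t_edges[1] - t_edges[0] == 5000.0   # 5 ps
        assert a_edges[1] - a_edges[0] == 6.0      # 6 degrees

    def test_non_uniform_times_rejected(self):
        with pytest.raises(ValueError, match="non-uniform"):
            time_angle_histogram(np.zeros(4), dt=1.0, times=[0, 1, 2, 4.0])


class TestLocalizedStates:
    def test_embedded_dwell_detected_once_with_correct_duration(self):
        """A 4 ps stop at a well inside free rotation -> one 4 ps record."""
        dt = 10.0  # fs
        pre = np.arange(300) * 3.0 % 360 - 180       # fast rotation
        dwell = np.full(401, 120.0)                   # 4 ps at the 120° well
        post = (np.arange(300) * 3.0 + 60) % 360 - 180
        series = np.concatenate([pre, dwell, post])
        recs, summary = detect_localized_states(series, dt, [0, 120, -120],
                                                tolerance=30.0, min_duration=4000.0)
        assert summary["count"] == 1
        assert recs[0].duration == pytest.approx(4000.0)
        assert recs[0].well_index == 1
        assert recs[0].mean_angle == pytest.approx(120.0)

    def test_free_rotation_yields_no_records(self):
        series = np.arange(5000) * 4.1 % 360 - 180
        _, summary = detect_localized_states(series, 10.0, [0, 120, -120],
                                             30.0, 1000.0)
        assert summary["count"] == 0

    def test_closed_interval_boundary(self):
        dt = 10.0
        dwell_short = np.full(400, 0.0)   # (400-1)*10 = 3990 fs < 4000
        _, s1 = detect_localized_states(dwell_short, dt, [0.0], 30.0, 4000.0)
        assert s1["count"] == 0
        dwell_exact = np.full(401, 0.0)   # exactly 4000 fs, closed interval
        _, s2 = detect_localized_states(dwell_exact, dt, [0.0], 30.0, 4000.0)
        assert s2["count"] == 1

    def test_empty_well_list_rejected(self):
        with pytest.raises(ValueError, match="well"):
            detect_localized_states(np.zeros(10), 1.0, [], 30.0, 2.0)


class TestPowerLaw:
    def test_exact_recovery_r11(self):
        r = np.linspace(3.8, 9.0, 40)
        fit = fit_power_law(r, -5.0 * r ** -11.0)
        assert fit.exponent == pytest.approx(11.0, abs=1e-10)
        assert fit.amplitude == pytest.approx(5.0, rel=1e-10)
        assert fit.sign == -1

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=1.0, max_value=20.0))
    def test_exact_recovery_any_exponent(self, n):
        r = np.linspace(4.0, 12.0, 25)
        fit = fit_power_law(r, 2.7 * r ** -n)
        assert fit.exponent == pytest.approx(n, abs=1e-9)

    def test_window_and_sign_validation(self):
        r = np.linspace(1.0, 10.0, 50)
        E = r ** -6 - 0.001  # sign change inside the default window
        with pytest.raises(ValueError, match="sign"):
            fit_power_law(r, E, r_min=1.0)
        with pytest.raises(ValueError, match="at least 3"):
            fit_power_law(r[:2], (r ** -6.0)[:2], r_min=0.0)

    def test_noisy_monte_carlo_median_within_tolerance(self, rng):
        """200 replicates of 5% multiplicative noise: median n̂ within 0.3."""
        r = np.linspace(3.8, 8.0, 30)
        E = -4.0 * r ** -11.0
        est = []
        for _ in range(200):
            noisy = E * (1 + 0.05 * rng.normal(size=len(r)))
            est.append(fit_power_law(r, noisy).exponent)
        assert abs(np.median(est) - 11.0) < 0.3


class TestCasimirPolder:
    def test_identical_oscillators_london_form(self):
        a = DrudeOscillator(alpha0=10.0, omega0=0.5)
        c6 = casimir_polder_c6(a, a)
        assert c6 == pytest.approx(0.75 * HBAR * 0.5 * 100.0, rel=1e-6)

    def test_distinct_oscillators_and_symmetry_sweep(self):
        """Quadrature vs the two-oscillator London closed form over a
        100-point parameter sweep, ≤1e-6 relative."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = DrudeOscillator(rng.uniform(1, 20), rng.uniform(0.05, 3.0))
            b = DrudeOscillator(rng.uniform(1, 20), rng.uniform(0.05, 3.0))
            exact = 1.5 * HBAR * a.alpha0 * b.alpha0 * a.omega0 * b.omega0 \
                / (a.omega0 + b.omega0)
            c6 = casimir_polder_c6(a, b)
            assert abs(c6 - exact) / exact < 1e-6
            assert casimir_polder_c6(b, a) == pytest.approx(c6, rel=1e-12)

    def test_invalid_oscillator(self):
        with pytest.raises(ValueError):
            DrudeOscillator(alpha0=-1.0, omega0=0.5)

    def test_vdw_energy_scalings(self):
        assert vdw_energy(100.0, 4.0) < 0
        assert vdw_energy(100.0, 8.0) == pytest.approx(vdw_energy(100.0, 4.0) / 64)
        assert vdw_energy(200.0, 4.0) == pytest.approx(2 * vdw_energy(100.0, 4.0))
        with pytest.raises(ValueError):
            vdw_energy(100.0, 0.0)


def _benzene_like(scale=1.0):
    ang = np.linspace(0, 2 * math.pi, 6, endpoint=False)
    ring = np.column_stack([1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(6)])
    return MolecularConfiguration(("C",) * 6, ring * scale)


class TestPolarizabilitySurrogate:
    def test_reference_ensemble_zero_increment(self):
        ref = _benzene_like()
        assert ensemble_polarizability_increment([ref] * 10, ref) == pytest.approx(0.0)

    def test_uniform_dilation_scaling_law(self):
        """R -> s·R implies a 100·(s⁷-1)% polarizability increment when the
        radius proxy scales with the geometry (zero offset)."""
        ref = _benzene_like()
        s = 1.01
        ens = [_benzene_like(s)] * 5
        inc = ensemble_polarizability_increment(ens, ref, offset=0.0)
        assert inc == pytest.approx(100.0 * (s ** 7 - 1.0), rel=1e-10)

    def test_symmetric_fluctuations_positive_increment_mc_oracle(self, rng):
        """Convexity of R⁷: zero-mean radius noise still raises ⟨α⟩; the
        increment matches a direct Monte-Carlo average of R⁷."""
        ref = _benzene_like()
        r0 = effective_radius(ref, offset=0.0)
        scales = 1.0 + 0.03 * rng.normal(size=400)
        ens = [_benzene_like(s) for s in scales]
        inc = ensemble_polarizability_increment(ens, ref, offset=0.0)
        oracle = 100.0 * (np.mean((r0 * scales) ** 7) / r0 ** 7 - 1.0)
        assert inc == pytest.approx(oracle, rel=1e-9)
        assert inc > 0

    def test_tensor_input_isotropic_trace(self):
        ref = np.diag([10.0, 10.0, 10.0])
        ens = [np.diag([11.0, 10.0, 12.0])]
        inc = ensemble_polarizability_increment(ens, ref)
        assert inc == pytest.approx(100.0 * (11.0 / 10.0 - 1.0))


class TestEnsembleScan:
    @staticmethod
    def _c6_pair(a, b, R, offset=0.0):
        alpha_a = polarizability_from_radius(effective_radius(a, offset))
        alpha_b = polarizability_from_radius(effective_radius(b, offset))
        # one-pole dispersion model with a fixed characteristic frequency
        c6 = casimir_polder_c6(DrudeOscillator(alpha_a, 0.5),
                               DrudeOscillator(alpha_b, 0.5))
        return vdw_energy(c6, R)

    def test_degenerate_ensemble_equals_single_curve(self):
        ref = _benzene_like()
        R = np.linspace(4.0, 8.0, 5)
        mean, se = ensemble_interaction_scan([ref] * 6, [ref] * 6, self._c6_pair, R)
        single = np.array([self._c6_pair(ref, ref, r) for r in R])
        np.testing.assert_allclose(mean, single, rtol=1e-12)
        np.testing.assert_allclose(se, 0.0, atol=1e-15)

    def test_dilated_ensemble_uniformly_more_attractive(self, rng):
        """Quantum-like dilation deepens the whole dispersion scan."""
        ref_ens = [_benzene_like(1.0 + 0.01 * rng.normal()) for _ in range(50)]
        dil_ens = [_benzene_like(1.03 + 0.01 * rng.normal()) for _ in range(50)]
        R = np.linspace(4.0, 9.0, 8)
        ref_mean, _ = ensemble_interaction_scan(ref_ens, ref_ens, self._c6_pair, R)
        dil_mean, _ = ensemble_interaction_scan(dil_ens, dil_ens, self._c6_pair, R)
        assert np.all(dil_mean < ref_mean)

    def test_standard_error_shrinks_with_ensemble_size(self, rng):
        def pair(a, b, R):
            return self._c6_pair(a, b, R)
        small = [_benzene_like(1 + 0.02 * rng.normal()) for _ in range(20)]
        large = [_benzene_like(1 + 0.02 * rng.normal()) for _ in range(320)]
        R = np.array([6.0])
        _, se_small = ensemble_interaction_scan(small, small, pair, R)
        _, se_large = ensemble_interaction_scan(large, large, pair, R)
        assert se_large[0] < se_small[0]

    def test_zip_pairing_length_mismatch(self):
        ref = _benzene_like()
        with pytest.raises(ValueError, match="equal ensemble sizes"):
            ensemble_interaction_scan([ref] * 3, [ref] * 4, self._c6_pair, [5.0])
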