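"""Distance profiles, contacts, moments, fits, shape, dynamics, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from dynloop import observables as obs
from dynloop.fixtures import ballistic_trajectory, rod_positions


@pytest.fixture(scope="module")
def gaussian_ensemble():
    """Ideal-chain (random walk) ensemble: pairwise vectors are Gaussian."""
    rng = np.random.default_rng(12)
    steps = rng.normal(0, 2.0, size=(400, 64, 3))
    return np.cumsum(steps, axis=1)


class TestInternalMsd:
    def test_rigid_rod_exact(self):
        ens = rod_positions(n_beads=32, n_frames=40)
        prof = obs.internal_msd(ens.positions)
        np.testing.assert_allclose(prof.R2, (2.0 * prof.s) ** 2)

    def test_too_few_conformations_refused(self):
        ens = rod_positions(n_frames=5)
        with pytest.raises(ValueError):
            obs.internal_msd(ens.positions, min_conformations=30)

    def test_gaussian_chain_scaling(self, gaussian_ensemble):
        # ideal chain: R^2(s) = b^2 s exactly in expectation
        prof = obs.internal_msd(gaussian_ensemble)
        fit = obs.fit_loglog_slope(prof.s, prof.R2, (2, 32))
        assert fit.exponent == pytest.approx(1.0, abs=0.05)

    def test_plateau_ratio_of_rod_reflects_growth(self):
        prof = obs.internal_msd(rod_positions(n_beads=64).positions)
        assert prof.plateau_ratio() == pytest.approx(4.0, rel=0.01)


class TestMomentRatios:
    def test_identical_distances_give_unity(self):
        prof = obs.moment_ratios(rod_positions().positions, min_samples=1)
        np.testing.assert_allclose(prof.ratio4, 1.0)
        np.testing.assert_allclose(prof.ratio6, 1.0)

    def test_gaussian_gives_five_thirds(self, gaussian_ensemble):
        prof = obs.moment_ratios(gaussian_ensemble)
        r4, r6 = prof.pooled(s_min=4, s_max=32)
        assert r4 == pytest.approx(5.0 / 3.0, rel=0.02)
        # <r^6>/<r^2>^3 for a 3-D Gaussian: 105/27
        assert r6 == pytest.approx(105.0 / 27.0, rel=0.05)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 50.0))
    def test_scale_invariance(self, scale, gaussian_ensemble):
        a = obs.moment_ratios(gaussian_ensemble)
        b = obs.moment_ratios(gaussian_ensemble * scale)
        np.testing.assert_allclose(a.ratio4, b.ratio4, rtol=1e-9)

    def test_cauchy_schwarz_bound(self, gaussian_ensemble):
        prof = obs.moment_ratios(gaussian_ensemble)
        assert np.all(prof.ratio4 >= 1.0)
        assert np.all(prof.ratio6 >= prof.ratio4)


class TestContactDistributions:
    def test_loop_size_distribution_by_hand(self):
        stats = obs.loop_size_distribution(np.array([10, 10, 20]))
        lookup = dict(zip(stats.sizes, stats.f_l))
        assert lookup[10] == pytest.approx(2 / 3)
        assert lookup[20] == pytest.approx(1 / 3)
        assert stats.f_l.sum() == pytest.approx(1.0)

    def test_empty_record_rejected(self):
        with pytest.raises(ValueError):
            obs.loop_size_distribution(np.array([]))

    def test_rod_has_no_contacts(self):
        with pytest.raises(ValueError):
            obs.contact_size_distribution(rod_positions().positions)

    def test_contact_counts_match_brute_force(self, rng):
        """Fast per-separation detector equals the O(N^2) pair scan."""
        pos = rng.integers(0, 6, size=(4, 20, 3))
        st = obs.pair_statistics(pos)
        brute = np.zeros(19, dtype=int)
        for f in range(4):
            for i in range(20):
                for j in range(i + 1, 20):
                    d = pos[f, j] - pos[f, i]
                    if (d**2).sum() <= 8:
                        brute[j - i - 1] += 1
        np.testing.assert_array_equal(st["contacts"], brute)

    def test_h_l_masses_sum_to_one(self, gaussian_ensemble):
        h = obs.contact_size_distribution(gaussian_ensemble.round().astype(int))
        assert h.h_l.sum() == pytest.approx(1.0)


class TestSpecificContactProbability:
    def test_rod_zero_beyond_radius(self):
        pc = obs.specific_contact_probability(rod_positions().positions)
        assert np.all(pc.Pc_s[pc.s >= 2] == 0.0)
        assert np.all((pc.Pc_s >= 0) & (pc.Pc_s <= 1))

    def test_counting_identity(self, gaussian_ensemble):
        """sum_s (N-s) Pc(s) equals the mean contact count exactly."""
        ens = gaussian_ensemble.round().astype(int)
        pc = obs.specific_contact_probability(ens)
        N = ens.shape[1]
        total = ((N - pc.s) * pc.Pc_s).sum()
        mean_contacts = obs.mean_contacts_per_conformation(ens, min_sep=1)
        assert total == pytest.approx(mean_contacts, rel=1e-12)


class TestPowerLawFit:
    def test_exact_power_law_recovered(self):
        x = np.arange(1, 50, dtype=float)
        fit = obs.fit_power_law(x, x**-2.0, (1, 49))
        assert fit.exponent == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noisy_power_law_within_error(self):
        rng = np.random.default_rng(7)
        x = np.arange(4, 200, dtype=float)
        y = 5.0 * x**-0.7 * (1.0 + rng.normal(0, 0.05, x.size))
        fit = obs.fit_power_law(x, y, (4, 199))
        assert fit.exponent == pytest.approx(0.7, abs=0.05)

    def test_single_point_range_errors(self):
        x = np.arange(1, 20, dtype=float)
        with pytest.raises(ValueError):
            obs.fit_power_law(x, x**-1.0, (5.0, 5.5))

    def test_nonpositive_values_rejected(self):
        x = np.arange(1, 20, dtype=float)
        y = x**-1.0
        y[3] = 0.0
        with pytest.raises(ValueError):
            obs.fit_power_law(x, y, (1, 19))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(exponent=st.floats(0.2, 3.0), amp=st.floats(0.1, 100.0))
    def test_roundtrip_any_exponent(self, exponent, amp):
        x = np.geomspace(1, 100, 30)
        fit = obs.fit_power_law(x, amp * x**-exponent, (1, 100))
        assert fit.exponent == pytest.approx(exponent, rel=1e-9)
        assert fit.amplitude == pytest.approx(amp, rel=1e-6)


class TestGyrationShape:
    def test_collinear_rod_is_one_dimensional(self):
        shape = obs.gyration_shape(rod_positions(n_beads=16).positions)
        assert shape.eigenvalues[0] > 0
        np.testing.assert_allclose(shape.eigenvalues[1:], 0.0, atol=1e-9)
        assert shape.asphericity == pytest.approx(1.0)

    def test_axis_ratios_are_square_roots_of_eigen_ratios(self, gaussian_ensemble):
        shape = obs.gyration_shape(gaussian_ensemble)
        np.testing.assert_allclose(shape.axis_ratios**2, shape.eigen_ratios, rtol=1e-12)

    def test_printed_ratio_example(self):
        # eigen-ratios 10.2 : 2.6 : 1 correspond to axes 3.19 : 1.61 : 1
        ratios = np.array([10.2, 2.6, 1.0])
        axes = np.sqrt(ratios)
        assert axes[0] == pytest.approx(3.19, abs=0.01)
        assert axes[1] == pytest.approx(1.61, abs=0.01)

    def test_rotation_invariance(self, gaussian_ensemble):
        R = Rotation.from_euler("xyz", [0.3, 1.1, -0.7]).as_matrix()
        a = obs.gyration_shape(gaussian_ensemble)
        b = obs.gyration_shape(gaussian_ensemble @ R.T)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues, rtol=1e-9)

    def test_single_monomer_rejected(self):
        with pytest.raises(ValueError):
            obs.gyration_shape(np.zeros((3, 1, 3)))


class TestDynamics:
    def test_ballistic_exponent_two(self):
        ens = ballistic_trajectory(n_frames=128, velocity=1)
        prof = obs.dynamics_profiles(ens.positions, ens.times, tau_relax=4.0)
        fit = obs.fit_loglog_slope(prof.lag_times, prof.g3, (1, 127))
        assert fit.exponent == pytest.approx(2.0, abs=1e-9)
        np.testing.assert_allclose(prof.g1, prof.g3)  # rigid translation

    def test_lags_exceeding_trajectory_rejected(self):
        ens = ballistic_trajectory(n_frames=3)
        with pytest.raises(ValueError):
            obs.dynamics_profiles(ens.positions, ens.times)


class TestCalibration:
    def test_25_beads_at_400kb_is_10_mb(self):
        prof = obs.internal_msd(rod_positions(n_beads=32).positions)
        cal = obs.calibrate_physical(prof, kb_per_bead=400.0, nm_per_bead=480.0)
        assert cal.genomic_kb[cal.s == 25][0] == pytest.approx(10_000.0)  # 10 Mb

    def test_unit_factors_are_identity(self):
        prof = obs.internal_msd(rod_positions().positions)
        cal = obs.calibrate_physical(prof, 1.0, 1.0)
        np.testing.assert_array_equal(cal.genomic_kb, prof.s)
        np.testing.assert_array_equal(cal.r2_phys, prof.R2)

    def test_round_trip_restores_input(self):
        prof = obs.internal_msd(rod_positions().positions)
        back = obs.decalibrate_physical(obs.calibrate_physical(prof))
        np.testing.assert_array_equal(back.R2, prof.R2)
        assert back.genomic_kb is None

    def test_nonpositive_constants_rejected(self):
        prof = obs.internal_msd(rod_positions().positions)
        with pytest.raises(ValueError):
            obs.calibrate_physical(prof, -400.0, 480.0)

    def test_random_walk_chromosome_extension(self):
        # 100 Mb at 30 kb per 300 nm Kuhn segment: 17.3 um
        assert obs.random_walk_extension(100.0, 30.0, 300.0) == pytest.approx(
            17.32, abs=0.01
        )
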