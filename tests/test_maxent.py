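"""Neighborhood structure, spin-wave partition function, (J, n_c) inference."""

import numpy as np
import pytest
from scipy.special import logsumexp

import flockscale as fs
from flockscale.errors import DisconnectedGraphError, DivergenceError
from flockscale.maxent import (
    compute_cint,
    constraint_J_of_nc,
    fit_maxent,
    least_squares_fit_check,
    meanfield_estimate_J,
    neighborhood_matrix,
    spinwave_log_partition,
)
from flockscale.trajectories import snapshots_from_angles


class TestCint:
    def test_fully_aligned_is_one(self, rng):
        pos = rng.uniform(0, 100, size=(20, 2))
        snap = snapshots_from_angles(np.full((1, 20), 1.1), pos)[0]
        assert compute_cint(snap, 5) == pytest.approx(1.0)

    def test_antiparallel_pair_is_minus_one(self):
        pos = np.array([[0.0, 0.0], [10.0, 0.0]])
        snap = snapshots_from_angles(np.array([[0.0, np.pi]]), pos)[0]
        assert compute_cint(snap, 1) == pytest.approx(-1.0)

    def test_uniform_large_sample_near_zero(self, rng):
        pos = rng.uniform(0, 3000, size=(10_000, 2))
        a = rng.uniform(0, 2 * np.pi, size=10_000)
        snap = snapshots_from_angles(a[None, :], pos)[0]
        assert abs(compute_cint(snap, 10)) < 0.02

    def test_rotation_invariance(self, rng):
        pos = rng.uniform(0, 200, size=(30, 2))
        a = rng.uniform(0, 2 * np.pi, size=30)
        s0 = snapshots_from_angles(a[None, :], pos)[0]
        s1 = snapshots_from_angles((a + 2.5)[None, :] % (2 * np.pi), pos)[0]
        assert compute_cint(s1, 6) == pytest.approx(compute_cint(s0, 6), abs=1e-12)

    def test_out_of_range_nc(self, rng):
        pos = rng.uniform(0, 100, size=(10, 2))
        snap = snapshots_from_angles(np.zeros((1, 10)), pos)[0]
        with pytest.raises(ValueError):
            compute_cint(snap, 10)


class TestNeighborhoodMatrix:
    def test_two_cells_hand_diagonalization(self):
        pos = np.array([[0.0, 0.0], [5.0, 0.0]])
        nbm = neighborhood_matrix(pos, 1)
        np.testing.assert_allclose(nbm.weights, [[0, 1], [1, 0]])
        np.testing.assert_allclose(nbm.laplacian, [[1, -1], [-1, 1]])
        np.testing.assert_allclose(nbm.eigenvalues, [0.0, 2.0], atol=1e-12)

    def test_zero_mode_with_constant_eigenvector(self, positions_100):
        nbm = neighborhood_matrix(positions_100.coordinates, 5)
        assert nbm.eigenvalues[0] == pytest.approx(0.0, abs=1e-8)
        assert np.all(nbm.eigenvalues[1:] > 0)
        const = np.ones(100) / 10
        np.testing.assert_allclose(nbm.laplacian @ const, 0.0, atol=1e-9)
        # row sums of A vanish
        np.testing.assert_allclose(nbm.laplacian.sum(axis=1), 0.0, atol=1e-9)

    def test_collinear_one_way_neighbors_get_half(self):
        # enumerate the kNN relation by hand for 3 collinear cells, n_c = 1:
        # cells at 0, 10, 21 -> 0 and 1 choose each other (mutual, weight 1);
        # end cell 2 chooses middle cell 1, but 1 does not choose 2 -> 1/2
        pos = np.array([[0.0, 0.0], [10.0, 0.0], [21.0, 0.0]])
        w = neighborhood_matrix(pos, 1).weights
        assert w[0, 1] == pytest.approx(1.0)
        assert w[1, 2] == pytest.approx(0.5)
        assert w[2, 1] == pytest.approx(0.5)
        assert w[0, 2] == 0.0
        np.testing.assert_allclose(w, w.T)

    def test_spectrum_invariant_under_relabeling(self, rng, positions_100):
        perm = rng.permutation(100)
        a = neighborhood_matrix(positions_100.coordinates, 8).eigenvalues
        b = neighborhood_matrix(positions_100.coordinates[perm], 8).eigenvalues
        np.testing.assert_allclose(a, b, atol=1e-8)


class TestSpinwaveLogPartition:
    def test_two_cell_closed_form(self):
        pos = np.array([[0.0, 0.0], [5.0, 0.0]])
        nbm = neighborhood_matrix(pos, 1)
        for J in (0.5, 1.0, 4.0):
            assert spinwave_log_partition(J, 1, nbm) == pytest.approx(
                -np.log(J) + J / 2
            )

    def test_convex_with_minimum_at_2N_minus_1_over_nc(self, positions_100):
        nbm = neighborhood_matrix(positions_100.coordinates, 10)
        js = np.linspace(5, 60, 111)
        lz = np.array([spinwave_log_partition(j, 10, nbm) for j in js])
        assert np.all(np.diff(lz, 2) > -1e-9)  # convex in J
        jmin = js[np.argmin(lz)]
        assert jmin == pytest.approx(2 * 99 / 10, abs=1.0)

    def test_disconnected_graph_reports_components(self):
        # two distant mutual pairs, n_c = 1 -> two components
        pos = np.array([[0, 0], [1, 0], [100, 0], [101, 0]], dtype=float)
        nbm = neighborhood_matrix(pos, 1)
        with pytest.raises(DisconnectedGraphError) as exc:
            spinwave_log_partition(1.0, 1, nbm)
        assert exc.value.n_components == 2

    def test_matches_quadrature_up_to_constant(self):
        """Brute-force integral of the model density, N=4 all-to-all, large J."""
        pos = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        nbm = neighborhood_matrix(pos, 3)

        def logz_quad(J, n=180):
            g = np.linspace(0, 2 * np.pi, n, endpoint=False)
            t2 = g[:, None, None]
            t3 = g[None, :, None]
            t4 = g[None, None, :]
            s = (
                np.cos(t2) + np.cos(t3) + np.cos(t4)
                + np.cos(t2 - t3) + np.cos(t2 - t4) + np.cos(t3 - t4)
            )
            h = 2 * np.pi / n
            return logsumexp((J / 4.0) * s) + 3 * np.log(h) + np.log(2 * np.pi)

        J1, J2 = 20.0, 80.0
        sw = [spinwave_log_partition(J, 3, nbm) for J in (J1, J2)]
        quad = [logz_quad(J) for J in (J1, J2)]
        drift = (sw[1] - quad[1]) - (sw[0] - quad[0])
        j_dependent = sw[1] - sw[0]
        assert abs(drift / j_dependent) < 0.05


class TestConstraintAndMeanField:
    def test_critical_anchor(self):
        # disordered data (C_int = 0) with global coupling sits at J_c = 2
        assert constraint_J_of_nc(0.0, 100, 100) == pytest.approx(2.0)
        assert meanfield_estimate_J(0.0) == pytest.approx(2.0)

    def test_half_correlation(self):
        assert constraint_J_of_nc(0.5, 100, 100) == pytest.approx(4.0)
        assert meanfield_estimate_J(0.5) == pytest.approx(4.0)

    def test_perfect_order_diverges(self):
        with pytest.raises(DivergenceError):
            constraint_J_of_nc(1.0, 10, 100)
        with pytest.raises(DivergenceError):
            meanfield_estimate_J(1.0)

    def test_monotone_in_cint(self):
        c = np.linspace(-0.5, 0.9, 50)
        j = [meanfield_estimate_J(v) for v in c]
        assert np.all(np.diff(j) > 0)

    def test_disordered_estimates_hover_at_critical(self, meanfield_200):
        """At or below J_c, the closed form returns ~2 regardless of true J."""
        for J in (1.0, 2.0):
            ens = fs.simulate_xy_ensemble(
                meanfield_200, fs.ModelParameters(J, 199), 25, seed=int(J * 7),
                independent_chains=True, init="ordered",
            )
            jh = [
                meanfield_estimate_J(compute_cint(s, 199))
                for s in snapshots_from_angles(ens.angles, meanfield_200.coordinates)
            ]
            assert abs(np.median(jh) - 2.0) < 0.25

    def test_slightly_supercritical_estimates_accurate(self, meanfield_200):
        """Just above J_c the estimator tracks the true coupling (~15%)."""
        ens = fs.simulate_xy_ensemble(
            meanfield_200, fs.ModelParameters(2.2, 199), 25, seed=31,
            independent_chains=True, init="ordered",
        )
        jh = [
            meanfield_estimate_J(compute_cint(s, 199))
            for s in snapshots_from_angles(ens.angles, meanfield_200.coordinates)
        ]
        assert abs(np.median(jh) - 2.2) / 2.2 < 0.15

    def test_deep_supercritical_bias_is_upward(self, meanfield_200):
        """Known limitation: far above J_c the inversion overestimates J."""
        ens = fs.simulate_xy_ensemble(
            meanfield_200, fs.ModelParameters(3.0, 199), 25, seed=33,
            independent_chains=True, init="ordered",
        )
        jh = [
            meanfield_estimate_J(compute_cint(s, 199))
            for s in snapshots_from_angles(ens.angles, meanfield_200.coordinates)
        ]
        assert np.median(jh) > 3.3


class TestFitMaxent:
    def test_fully_aligned_raises_divergence(self, rng):
        pos = rng.uniform(0, 100, size=(30, 2))
        snap = snapshots_from_angles(np.full((1, 30), 0.2), pos)[0]
        with pytest.raises(DivergenceError):
            fit_maxent(snap, nc_grid=[3, 5])

    def test_uniform_random_flags_low_confidence(self, rng):
        pos = rng.uniform(0, 800, size=(120, 2))
        a = rng.uniform(0, 2 * np.pi, size=120)
        snap = snapshots_from_angles(a[None, :], pos)[0]
        fit = fit_maxent(snap)
        assert fit.low_confidence or "weak_polarization" in fit.flags

    def test_nc_recovery_on_simulated_ordered_data(self, positions_100):
        """n_c is recovered from configurations sampled at known parameters."""
        true_nc = 8
        ens = fs.simulate_xy_ensemble(
            positions_100, fs.ModelParameters(40.0, true_nc), 10, seed=17,
            independent_chains=True, init="ordered",
        )
        snaps = list(snapshots_from_angles(ens.angles, positions_100.coordinates))
        fit = fit_maxent(snaps, nc_grid=[2, 4, 6, 8, 12, 16, 24, 40, 64, 99])
        assert abs(fit.nc_star - true_nc) / true_nc <= 0.5
        assert fit.J_star > 0
        # constraint inversion at the selected n_c reproduces J from C_int
        assert fit.J_star == pytest.approx(
            constraint_J_of_nc(fit.c_int[fit.nc_star], fit.nc_star, 100)
        )

    def test_profile_shape_and_grid_validation(self, positions_100, rng):
        a = rng.uniform(0, 2 * np.pi, size=100)
        snap = snapshots_from_angles(a[None, :], positions_100.coordinates)[0]
        with pytest.raises(ValueError):
            fit_maxent(snap, nc_grid=[1, 5])
        with pytest.raises(ValueError):
            fit_maxent(snap, nc_grid=[5, 100])


class TestLeastSquaresCheck:
    def test_self_comparison_is_noise_floor(self, rng):
        a = np.mod(rng.vonmises(0.5, 3, size=3000), 2 * np.pi)
        assert least_squares_fit_check(a, a) < 1e-10

    def test_mismatched_coupling_increases_residual(self, positions_100):
        strong = fs.simulate_xy_ensemble(
            positions_100, fs.ModelParameters(60.0, 10), 20, seed=5,
            independent_chains=True, init="ordered",
        )
        weak = fs.simulate_xy_ensemble(
            positions_100, fs.ModelParameters(2.0, 10), 20, seed=6,
            independent_chains=True,
        )
        matched = fs.simulate_xy_ensemble(
            positions_100, fs.ModelParameters(60.0, 10), 20, seed=7,
            independent_chains=True, init="ordered",
        )
        # compare single snapshots: independent realizations carry random
        # global directions, which the alignment step absorbs one at a time
        r_matched = least_squares_fit_check(strong.angles[0], matched.angles[0])
        r_mismatch = least_squares_fit_check(strong.angles[0], weak.angles[0])
        assert r_mismatch > r_matched

    def test_uniform_data_vs_ordered_model_no_false_agreement(self, rng, positions_100):
        uniform = rng.uniform(0, 2 * np.pi, size=(20, 100))
        uniform2 = rng.uniform(0, 2 * np.pi, size=(20, 100))
        ordered = fs.simulate_xy_ensemble(
            positions_100, fs.ModelParameters(60.0, 10), 20, seed=8,
            independent_chains=True, init="ordered",
        )
        control = least_squares_fit_check(uniform, uniform2)
        cross = least_squares_fit_check(uniform, ordered.angles)
        assert cross > 0.5 * control  # alignment cannot fake agreement
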