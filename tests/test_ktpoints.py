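"""kT-point design: timing, system matrix, regularized solves, L-curves."""

import numpy as np
import pytest

import ptxkit as pk
from ptxkit.ktpoints import (
    build_system_matrix,
    build_timing,
    design_kt_pulse,
    small_tip_fa,
    solve_weights,
    sweep_lcurve,
    tikhonov_sweep,
)


class TestTiming:
    @pytest.mark.parametrize(
        "n_kt,expected_us",
        [(1, 1000), (2, 420), (3, 253), (4, 170), (5, 120), (6, 87)],
    )
    def test_subpulse_duration_table(self, n_kt, expected_us):
        """The 920 us on+blip budget with 80 us blips reproduces every
        printed subpulse duration; the static case uses the full 1 ms."""
        assert build_timing(n_kt) == expected_us

    def test_total_duration_within_budget(self):
        for n_kt in range(2, 7):
            sub = build_timing(n_kt)
            assert n_kt * sub + (n_kt - 1) * 80 <= 1000

    def test_budget_exhaustion_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            build_timing(13)

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            build_timing(0)


class TestSystemMatrix:
    def test_origin_point_reduces_to_static_shim_columns(self, b1_small, roi_small):
        a = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), 1000.0)
        expected = 10.0 * 1.0 * b1_small.roi_matrix(roi_small)
        np.testing.assert_allclose(a.a, expected, rtol=1e-14)

    def test_uniform_map_gives_identical_rows(self, phantom_small):
        maps = np.ones((1,) + tuple(phantom_small.grid_shape), dtype=complex)
        b1 = pk.B1MapSet(maps, phantom_small, np.ones(1, dtype=bool))
        a = build_system_matrix(b1, phantom_small.roi_mask, np.zeros((1, 3)), 500.0)
        assert np.all(a.a == a.a[0, 0])

    def test_matrix_prediction_matches_raster_integral(self, b1_small, roi_small):
        """Matrix-predicted FA equals a 1 us time-discretized small-tip
        integral with ideal blips to < 0.1 % relative."""
        rng = np.random.default_rng(3)
        ks = np.vstack([rng.uniform(-6, 6, size=(2, 3)), np.zeros(3)])
        sub = build_timing(3)
        a = build_system_matrix(b1_small, roi_small, ks, sub)
        b = rng.normal(size=(a.a.shape[1], 2)) @ np.array([1, 1j]) * 0.02
        fa_matrix = np.abs(a.a @ b)

        # independent oracle: accumulate 1-us raster steps per subpulse
        coords = b1_small.phantom.coordinates_m()[roi_small]
        m = b1_small.roi_matrix(roi_small)
        ca = m.shape[1]
        acc = np.zeros(m.shape[0], dtype=complex)
        for j in range(3):
            ramp = np.exp(1j * coords @ ks[j])
            field = m @ b[j * ca:(j + 1) * ca]
            for _ in range(sub):  # 1 us raster
                acc += 10.0 * 1e-3 * field * ramp
        err = np.abs(fa_matrix - np.abs(acc)) / np.abs(acc).max()
        assert err.max() < 1e-3

    def test_k_max_enforced(self, b1_small, roi_small):
        with pytest.raises(ValueError, match="k_max"):
            build_system_matrix(
                b1_small, roi_small, np.array([[50.0, 0, 0]]), 420.0, k_max=10.0
            )

    def test_empty_roi_rejected(self, b1_small, phantom_small):
        with pytest.raises(ValueError, match="empty ROI"):
            build_system_matrix(
                b1_small, np.zeros(phantom_small.grid_shape, bool),
                np.zeros((1, 3)), 420.0,
            )


class TestSolver:
    def test_fixed_phase_matches_closed_form_tikhonov(self, b1_small, roi_small):
        a = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), 1000.0)
        theta = np.linspace(-1, 1, a.a.shape[0])
        beta = 0.5
        res = solve_weights(a, 10.0, beta, max_iter=1, theta0=theta)
        g = a.a.conj().T @ a.a + beta * np.eye(a.a.shape[1])
        rhs = a.a.conj().T @ (10.0 * np.exp(1j * theta))
        expected = np.linalg.solve(g, rhs)
        np.testing.assert_allclose(res.weights, expected, atol=1e-10)

    def test_huge_beta_suppresses_weights(self, b1_small, roi_small):
        a = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), 1000.0)
        res = solve_weights(a, 10.0, 1e12)
        v = a.a.shape[0]
        assert np.linalg.norm(res.weights) < 1e-6
        assert res.objective == pytest.approx(0.5 * v * 10.0**2, rel=1e-3)

    def test_target_linearity_at_zero_beta(self, b1_small, roi_small):
        a = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), 1000.0)
        theta = np.zeros(a.a.shape[0])
        r1 = solve_weights(a, 5.0, 0.0, max_iter=1, theta0=theta)
        r2 = solve_weights(a, 10.0, 0.0, max_iter=1, theta0=theta)
        np.testing.assert_allclose(2 * r1.weights, r2.weights, atol=1e-9)

    def test_variable_exchange_objective_monotone(self, b1_small, roi_small):
        a = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), 1000.0)
        res = solve_weights(a, 10.0, 1e-3, max_iter=100)
        trace = np.asarray(res.objective_trace)
        assert np.all(np.diff(trace) <= 1e-9 * trace[:-1] + 1e-12)

    def test_tikhonov_sweep_monotonicity(self, b1_small, roi_small):
        """Fixed k and target phase: ||b|| non-increasing and residual
        non-decreasing across the 27-point beta grid."""
        rng = np.random.default_rng(0)
        ks = np.vstack([rng.uniform(-5, 5, size=(1, 3)), np.zeros(3)])
        a = build_system_matrix(b1_small, roi_small, ks, 420.0)
        betas = np.logspace(-10, 3, 27)
        _, norms, residuals = tikhonov_sweep(a, 10.0, betas)
        assert np.all(np.diff(norms) <= 1e-9 * norms[:-1])
        assert np.all(np.diff(residuals) >= -1e-9 * residuals[1:])


class TestDesign:
    def test_single_point_is_static_mag_phase_solve(self, b1_small, roi_small):
        """n_kt=1 collapses to the static magnitude+phase solve: the pulse is
        one 1 ms subpulse at the k-space origin, and the Gram-space objective
        agrees with the dense-matrix objective of the returned weights."""
        pulse, metrics = design_kt_pulse(
            b1_small, roi_small, 1, 1e-2, n_starts=3, seed=0
        )
        assert pulse.n_kt == 1
        assert pulse.subpulse_us == 1000
        np.testing.assert_array_equal(pulse.k_locations, np.zeros((1, 3)))
        a = build_system_matrix(b1_small, roi_small, pulse.k_locations, 1000.0)
        b = pulse.weights[a.active_channels, 0]
        z = a.a @ b
        obj = 0.5 * np.sum((10.0 - np.abs(z)) ** 2) + 0.5 * 1e-2 * np.sum(
            np.abs(b) ** 2
        )
        assert metrics["objective"] == pytest.approx(obj, rel=1e-8)

    def test_extra_point_never_hurts_fixed_phase_objective(
        self, b1_small, roi_small
    ):
        """Adding a column block (extra kT point) at the same subpulse
        duration and target phase can only lower the regularized LS optimum."""
        sub = build_timing(2)
        a1 = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), sub)
        theta = np.angle(a1.a @ np.ones(a1.a.shape[1]))
        r1 = solve_weights(a1, 10.0, 1e-2, max_iter=1, theta0=theta)
        ks2 = np.vstack([[4.0, -3.0, 2.0], np.zeros(3)])
        a2 = build_system_matrix(b1_small, roi_small, ks2, sub)
        r2 = solve_weights(a2, 10.0, 1e-2, max_iter=1, theta0=theta)
        assert r2.objective <= r1.objective + 1e-9 * r1.objective

    def test_design_deterministic(self, b1_small, roi_small):
        p1, m1 = design_kt_pulse(b1_small, roi_small, 2, 1e-2, n_starts=2,
                                 seed=11, local_iters=3)
        p2, m2 = design_kt_pulse(b1_small, roi_small, 2, 1e-2, n_starts=2,
                                 seed=11, local_iters=3)
        np.testing.assert_array_equal(p1.k_locations, p2.k_locations)
        np.testing.assert_array_equal(p1.weights, p2.weights)
        assert m1["cv"] == m2["cv"]

    def test_final_point_at_origin_and_dead_channels_zero(self, b1_small,
                                                          roi_small):
        dead = pk.apply_channel_failures(b1_small, [2, 7])
        pulse, _ = design_kt_pulse(dead, roi_small, 2, 1e-2, n_starts=1,
                                   seed=0, local_iters=2)
        np.testing.assert_array_equal(pulse.k_locations[-1], np.zeros(3))
        assert np.all(pulse.weights[[1, 6], :] == 0)

    def test_invalid_requests(self, b1_small, roi_small):
        with pytest.raises(ValueError):
            design_kt_pulse(b1_small, roi_small, 0, 1e-2, seed=0)
        with pytest.raises(ValueError, match="candidate grid"):
            design_kt_pulse(b1_small, roi_small, 2, 1e-2, seed=0,
                            candidate_grid=np.empty((0, 3)))


class TestLCurve:
    def test_endpoints_and_orientation(self, b1_small, roi_small):
        lc = sweep_lcurve(
            b1_small, roi_small, 2, beta_grid=np.logspace(-10, 3, 6),
            seed=1, n_starts=1, local_iters=2,
        )
        assert lc.betas[0] == pytest.approx(1e-10)
        # the strongly regularized end uses less RF power
        assert lc.power[-1] < lc.power[0]

    def test_negative_beta_rejected(self, b1_small, roi_small):
        with pytest.raises(ValueError):
            sweep_lcurve(b1_small, roi_small, 2, beta_grid=[-1.0, 1.0], seed=0)

    def test_warm_start_consistent_with_cold_reruns(self, b1_small, roi_small):
        """Sweep points agree with independently re-run single-beta designs
        (CV within 2%) at sampled betas - warm starting does not corrupt."""
        betas = np.logspace(-6, 1, 8)
        lc = sweep_lcurve(b1_small, roi_small, 2, beta_grid=betas, seed=3,
                          n_starts=2, local_iters=2)
        for idx in (1, 4, 6):
            pulse, met = design_kt_pulse(
                b1_small, roi_small, 2, betas[idx], n_starts=2, seed=3,
                local_iters=2,
            )
            assert met["cv"] == pytest.approx(lc.cv[idx], rel=0.02, abs=5e-4)
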