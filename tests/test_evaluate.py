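"""FA prediction, Bloch oracle, power/SAR metrics, grouping, analyses."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ptxkit as pk
from ptxkit.evaluate import (
    bloch_oracle,
    check_channel_power,
    cv_at_power,
    default_grouping,
    group_channels,
    integrated_rf_power,
    peak_local_sar,
    power_at_cv,
    predict_fa_smalltip,
    solve_weights_sar,
)
from ptxkit.ktpoints import LCurve, build_system_matrix, build_timing


def uniform_b1(phantom, value=1.0):
    maps = np.full((1,) + tuple(phantom.grid_shape), value, dtype=complex)
    return pk.B1MapSet(maps, phantom, np.ones(1, dtype=bool))


def random_pulse(b1, n_kt, seed, fa_mean_deg=10.0, roi=None):
    rng = np.random.default_rng(seed)
    sub = build_timing(n_kt)
    ks = np.vstack([rng.uniform(-6, 6, size=(n_kt - 1, 3)), np.zeros(3)]) \
        if n_kt > 1 else np.zeros((1, 3))
    w = rng.normal(size=(b1.n_channels, n_kt, 2)) @ np.array([1, 1j])
    w[~b1.active_mask] = 0
    pulse = pk.KTPulse(ks, w, sub)
    mask = b1.phantom.roi_mask if roi is None else roi
    fa = predict_fa_smalltip(pulse, b1, mask)
    scale = fa_mean_deg / fa.fa_deg[mask].mean()
    return pk.KTPulse(ks, w * scale, sub)


class TestSmallTipPrediction:
    def test_uniform_single_channel_closed_form(self, phantom_small):
        b1 = uniform_b1(phantom_small)
        pulse = pk.KTPulse(np.zeros((1, 3)), np.array([[0.5]]), 1000)
        fa = predict_fa_smalltip(pulse, b1)
        # scale 10 deg per unit field per ms at weight 0.5 for 1 ms
        np.testing.assert_allclose(fa.fa_deg[fa.mask], 5.0, rtol=1e-12)

    def test_zero_weights_zero_map(self, b1_small):
        pulse = pk.KTPulse(
            np.zeros((1, 3)), np.zeros((b1_small.n_channels, 1)), 1000
        )
        fa = predict_fa_smalltip(pulse, b1_small)
        assert np.all(fa.fa_deg == 0)

    def test_matches_bloch_oracle_at_ten_degrees(self, b1_small, roi_small):
        pulse = random_pulse(b1_small, 3, seed=2, roi=roi_small)
        fs = predict_fa_smalltip(pulse, b1_small, roi_small)
        fb = bloch_oracle(pulse, b1_small, roi_small)
        rel = np.abs(fs.fa_deg[roi_small] - fb.fa_deg[roi_small]) / np.maximum(
            fb.fa_deg[roi_small], 1e-12
        )
        assert np.median(rel) < 0.01


class TestBlochOracle:
    def test_constant_rf_closed_form(self, phantom_small):
        """On-resonant constant RF for duration tau flips by exactly
        gamma*B1*tau (here: scale 10 deg / unit / ms)."""
        b1 = uniform_b1(phantom_small)
        pulse = pk.KTPulse(np.zeros((1, 3)), np.array([[3.0]]), 1000)
        fa = bloch_oracle(pulse, b1, raster_us=10)
        np.testing.assert_allclose(fa.fa_deg[fa.mask], 30.0, rtol=1e-9)

    def test_subpulse_composition(self, b1_small, roi_small):
        """Two consecutive equal subpulses at k=0 match one subpulse of the
        summed duration."""
        w = b1_small.maps[:, roi_small].mean(axis=1)
        w = 0.02 * w.conj() / np.abs(w).max()
        double = pk.KTPulse(np.zeros((2, 3)), np.tile(w[:, None], 2), 400,
                            blip_us=0)
        single = pk.KTPulse(np.zeros((1, 3)), w[:, None], 800)
        fa2 = bloch_oracle(double, b1_small, roi_small)
        fa1 = bloch_oracle(single, b1_small, roi_small)
        np.testing.assert_allclose(
            fa2.fa_deg[roi_small], fa1.fa_deg[roi_small], rtol=1e-9
        )

    def test_ninety_degree_transverse_shortfall(self, phantom_small):
        """At 90 deg the linear prediction of transverse magnetization
        exceeds the true sin(theta) by theta/sin(theta); the oracle must
        reproduce sin(theta) to 0.5%."""
        b1 = uniform_b1(phantom_small)
        pulse = pk.KTPulse(np.zeros((1, 3)), np.array([[9.0]]), 1000)
        fa, mag = bloch_oracle(pulse, b1, raster_us=10, return_magnetization=True)
        mxy = np.hypot(mag[:, 0], mag[:, 1])
        theta = np.deg2rad(90.0)
        np.testing.assert_allclose(mxy, np.sin(theta), rtol=5e-3)
        assert theta / np.sin(theta) == pytest.approx(np.pi / 2, rel=1e-12)

    def test_raster_must_divide_subpulse(self, b1_small):
        pulse = pk.KTPulse(
            np.zeros((1, 3)), np.ones((b1_small.n_channels, 1)), 253
        )
        with pytest.raises(ValueError, match="raster"):
            bloch_oracle(pulse, b1_small, raster_us=2)


class TestPowerMetric:
    def test_zero_pulse(self, b1_small):
        pulse = pk.KTPulse(np.zeros((1, 3)),
                           np.zeros((b1_small.n_channels, 1)), 1000)
        assert integrated_rf_power(pulse) == 0.0

    def test_unit_weight_one_ms(self):
        pulse = pk.KTPulse(np.zeros((1, 3)), np.array([[1.0]]), 1000)
        assert integrated_rf_power(pulse) == pytest.approx(1e-3)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(theta=st.floats(-np.pi, np.pi))
    def test_global_phase_invariance(self, theta):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(4, 2, 2)) @ np.array([1, 1j])
        ks = np.vstack([[1.0, 2.0, -1.0], np.zeros(3)])
        p1 = pk.KTPulse(ks, w, 420)
        p2 = pk.KTPulse(ks, w * np.exp(1j * theta), 420)
        assert integrated_rf_power(p2) == pytest.approx(
            integrated_rf_power(p1), rel=1e-12
        )


class TestSARMetric:
    def test_zero_pulse(self):
        vops = pk.generate_vops(4, 3, seed=0)
        pulse = pk.KTPulse(np.zeros((1, 3)), np.zeros((4, 1)), 1000)
        assert peak_local_sar(pulse, vops) == 0.0

    def test_identity_vop_reduces_to_mean_power(self):
        vops = pk.VOPSet(np.eye(4)[None])
        rng = np.random.default_rng(1)
        w = rng.normal(size=(4, 3, 2)) @ np.array([1, 1j])
        pulse = pk.KTPulse(
            np.vstack([rng.uniform(-2, 2, (2, 3)), np.zeros(3)]), w, 253
        )
        expected = (np.abs(w) ** 2).sum() / 3
        assert peak_local_sar(pulse, vops) == pytest.approx(expected, rel=1e-12)

    def test_matches_bruteforce_loop(self):
        vops = pk.generate_vops(5, 7, rank=2, seed=3)
        rng = np.random.default_rng(4)
        w = rng.normal(size=(5, 2, 2)) @ np.array([1, 1j])
        pulse = pk.KTPulse(np.vstack([[1, 0, 0], np.zeros(3)]), w, 420)
        best = 0.0
        for q in vops.matrices:
            acc = 0.0
            for j in range(2):
                b = w[:, j]
                acc += (b.conj() @ q @ b).real
            best = max(best, acc / 2)
        assert peak_local_sar(pulse, vops) == pytest.approx(best, abs=1e-12)

    def test_duty_cycle_and_homogeneity(self):
        vops = pk.generate_vops(4, 3, seed=5)
        rng = np.random.default_rng(6)
        w = rng.normal(size=(4, 1, 2)) @ np.array([1, 1j])
        pulse = pk.KTPulse(np.zeros((1, 3)), w, 1000)
        scaled = pk.KTPulse(np.zeros((1, 3)), 2 * w, 1000)
        assert peak_local_sar(scaled, vops) == pytest.approx(
            4 * peak_local_sar(pulse, vops), rel=1e-12
        )
        assert peak_local_sar(pulse, vops, duty_cycle=0.1) == pytest.approx(
            0.1 * peak_local_sar(pulse, vops), rel=1e-12
        )

    def test_channel_mismatch_rejected(self):
        vops = pk.generate_vops(8, 2, seed=0)
        pulse = pk.KTPulse(np.zeros((1, 3)), np.ones((4, 1)), 1000)
        with pytest.raises(ValueError, match="channel count"):
            peak_local_sar(pulse, vops)


class TestGrouping:
    def test_identity_scheme_is_noop(self, b1_small):
        scheme = pk.GroupingScheme(np.arange(b1_small.n_channels),
                                   b1_small.n_channels)
        out = group_channels(b1_small, scheme)
        np.testing.assert_array_equal(out.maps, b1_small.maps)

    def test_group_map_is_exact_complex_sum(self, b1_small):
        n = b1_small.n_channels
        scheme = pk.GroupingScheme(np.arange(n) // 2, (n + 1) // 2)
        out = group_channels(b1_small, scheme)
        np.testing.assert_array_equal(
            out.maps[0], b1_small.maps[0] + b1_small.maps[1]
        )
        assert out.power_budget[0] == pytest.approx(
            np.asarray(b1_small.power_budget)[:2].sum()
        )

    def test_two_identical_channels_double(self, phantom_small):
        maps = np.tile(uniform_b1(phantom_small).maps, (2, 1, 1, 1))
        b1 = pk.B1MapSet(maps, phantom_small, np.ones(2, dtype=bool))
        out = group_channels(b1, pk.GroupingScheme(np.zeros(2, int), 1))
        np.testing.assert_array_equal(out.maps[0], 2 * maps[0])

    def test_empty_group_after_dead_channels_rejected(self, b1_small):
        dead = pk.apply_channel_failures(b1_small, [1, 2])
        mapping = np.arange(b1_small.n_channels) // 2
        with pytest.raises(ValueError, match="empty"):
            group_channels(dead, pk.GroupingScheme(mapping, mapping.max() + 1))

    @pytest.mark.parametrize("n_groups", [8, 16, 20, 32])
    def test_default_schemes_partition_the_array(self, n_groups):
        scheme = default_grouping(n_groups)
        assert scheme.mapping.size == 32
        assert len(np.unique(scheme.mapping)) == n_groups


class TestAnalysisHelpers:
    def test_lcurve_interpolation_roundtrip(self):
        lc = LCurve(
            betas=np.logspace(-3, 1, 5),
            power=np.array([16.0, 8.0, 4.0, 2.0, 1.0]),
            cv=np.array([0.02, 0.04, 0.08, 0.16, 0.32]),
            fingerprint={},
        )
        assert cv_at_power(lc, 4.0) == pytest.approx(0.08)
        assert power_at_cv(lc, 0.16) == pytest.approx(2.0)

    def test_channel_power_compliance_flags(self):
        w = np.zeros((2, 1), dtype=complex)
        w[0, 0] = 1.0  # 1e-3 units*s per TR
        w[1, 0] = 100.0
        pulse = pk.KTPulse(np.zeros((1, 3)), w, 1000)
        df = check_channel_power(pulse, tr_s=1.0, watts_per_unit=1.0)
        assert bool(df.ok_10s[0]) and not bool(df.ok_10s[1])

    def test_sar_penalty_reduces_peak_sar(self, b1_small, roi_small):
        vops = pk.generate_vops(b1_small.n_channels, 12, seed=7)
        a = build_system_matrix(b1_small, roi_small, np.zeros((1, 3)), 1000.0)
        low = solve_weights_sar(a, 10.0, 1e-2, vops)
        high = solve_weights_sar(a, 10.0, 1e3, vops)
        def sar_of(res):
            pulse = pk.KTPulse(np.zeros((1, 3)), a.expand_weights(res.weights),
                               1000)
            return peak_local_sar(pulse, vops)
        assert sar_of(high) < sar_of(low)
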