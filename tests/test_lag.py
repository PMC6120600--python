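"""Lag estimation: reference signal, correlogram, parabolic refinement,
per-subject lag maps and group statistics."""

import numpy as np
import pytest

from hemolag import (
    Correlogram,
    HemodynamicLagModel,
    TimeSeriesVolume,
    compute_lag_map,
    compute_reference,
    cross_correlogram,
    group_lag_stats,
    parabolic_refine,
)
from hemolag.lag import EDGE, LOW_CORRELATION, NO_VARIANCE, ZeroVarianceError
from hemolag.synth import delay_signal

TR = 2.8


def naive_correlogram(s, g, max_shift):
    """Double-loop oracle for the lagged cross-correlation."""
    T = len(g)
    gd, sd = g - g.mean(), s - s.mean()
    sig_g, sig_s = g.std(), s.std()
    out = {}
    for tau in range(-max_shift, max_shift + 1):
        total, n = 0.0, 0
        for t in range(T):
            if 0 <= t + tau < T:
                total += gd[t] * sd[t + tau]
                n += 1
        out[tau] = total / (n * sig_g * sig_s)
    return out


class TestReference:
    def test_identical_voxels_reproduce_their_series(self, ref128):
        data = np.tile(ref128, (2, 2, 2, 1))
        vol = TimeSeriesVolume(data, TR)
        gm = np.ones((2, 2, 2), bool)
        ref = compute_reference(vol, gm)
        np.testing.assert_allclose(ref.g, ref128, atol=1e-12)

    def test_cancelling_pair_raises_zero_variance(self, ref128):
        data = np.stack([ref128, -ref128]).reshape(2, 1, 1, -1)
        vol = TimeSeriesVolume(data, TR)
        with pytest.raises(ZeroVarianceError):
            compute_reference(vol, np.ones((2, 1, 1), bool))

    def test_matches_direct_masked_average(self):
        rng = np.random.default_rng(0)
        vol = TimeSeriesVolume(rng.standard_normal((4, 4, 4, 30)), TR)
        gm = rng.random((4, 4, 4)) > 0.4
        lesion = rng.random((4, 4, 4)) > 0.7
        ref = compute_reference(vol, gm, lesion)
        expected = vol.data[gm & ~lesion].mean(axis=0)
        np.testing.assert_allclose(ref.g, expected, atol=1e-12)

    def test_lesion_voxels_excluded(self, ref128):
        data = np.tile(ref128, (2, 1, 1, 1)).copy()
        data[1, 0, 0] = -5 * ref128  # would wreck the mean if included
        vol = TimeSeriesVolume(data, TR)
        lesion = np.zeros((2, 1, 1), bool)
        lesion[1] = True
        ref = compute_reference(vol, np.ones((2, 1, 1), bool), lesion)
        np.testing.assert_allclose(ref.g, ref128, atol=1e-12)

    def test_empty_intact_set_rejected(self, ref128):
        vol = TimeSeriesVolume(np.tile(ref128, (1, 1, 1, 1)), TR)
        with pytest.raises(ValueError, match="intact"):
            compute_reference(vol, np.zeros((1, 1, 1), bool))


class TestCorrelogram:
    def test_self_correlation_peaks_at_zero_with_unity(self, ref128):
        cg = cross_correlogram(ref128, ref128, max_shift=3)
        k0 = np.flatnonzero(cg.shifts == 0)[0]
        assert cg.values[k0] == pytest.approx(1.0, abs=1e-12)
        assert np.argmax(cg.values) == k0

    def test_integer_planted_shift_peaks_there(self, ref128):
        s = np.roll(ref128, 2)  # arrives 2 frames later
        cg = cross_correlogram(s, ref128, max_shift=3)
        assert cg.shifts[np.argmax(cg.values)] == 2
        assert cg.values.max() > 0.95

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        g = rng.standard_normal(50)
        s = rng.standard_normal(50)
        cg = cross_correlogram(s, g, max_shift=3)
        oracle = naive_correlogram(s, g, 3)
        for tau, val in zip(cg.shifts, cg.values):
            assert val == pytest.approx(oracle[tau], abs=1e-10)

    def test_window_spans_8p4_seconds(self, ref128):
        cg = cross_correlogram(ref128, ref128, max_shift=3)
        assert cg.shifts.min() * TR == pytest.approx(-8.4)
        assert cg.shifts.max() * TR == pytest.approx(8.4)
        np.testing.assert_array_equal(cg.overlap, 128 - np.abs(cg.shifts))

    def test_constant_series_flagged_undefined(self, ref128):
        cg = cross_correlogram(np.ones(128), ref128, max_shift=3)
        assert not cg.defined


class TestParabolicRefine:
    def _cg(self, shifts, values):
        shifts = np.asarray(shifts)
        return Correlogram(
            shifts=shifts,
            values=np.asarray(values, float),
            overlap=100 - np.abs(shifts),
            sigma_s=1.0,
        )

    def test_symmetric_triple_gives_zero(self):
        tau, peak, edge = parabolic_refine(
            self._cg([-1, 0, 1], [0.5, 1.0, 0.5]), TR
        )
        assert tau == pytest.approx(0.0, abs=1e-12)
        assert peak == pytest.approx(1.0, abs=1e-12)
        assert not edge

    def test_closed_form_vertex_recovered_exactly(self):
        # C(tau) = 1 - (tau - 0.4)^2 sampled at -1, 0, +1
        f = lambda x: 1 - (x - 0.4) ** 2
        tau, peak, edge = parabolic_refine(
            self._cg([-1, 0, 1], [f(-1), f(0), f(1)]), tr_s=1.0
        )
        assert tau == pytest.approx(0.4, abs=1e-12)
        assert peak == pytest.approx(1.0, abs=1e-12)

    def test_edge_argmax_flagged(self):
        vals = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]
        tau, peak, edge = parabolic_refine(self._cg(range(-3, 4), vals), TR)
        assert edge
        assert np.isnan(tau)

    def test_flat_collinear_top_falls_back_to_discrete_peak(self):
        # plateau of equal maxima: tie broken toward tau=0, zero curvature
        cg = self._cg([-2, -1, 0, 1, 2], [0.0, 0.6, 0.6, 0.6, 0.0])
        tau, peak, edge = parabolic_refine(cg, tr_s=1.0)
        assert not edge
        assert tau == pytest.approx(0.0)
        assert peak == pytest.approx(0.6)

    def test_vertex_stays_within_one_frame_of_discrete_peak(self, ref128):
        rng = np.random.default_rng(3)
        for _ in range(50):
            s = delay_signal(ref128, rng.uniform(-5.6, 5.6), TR)
            s = s + rng.normal(0, 0.5, size=s.shape)
            cg = cross_correlogram(s, ref128, max_shift=3)
            tau, peak, edge = parabolic_refine(cg, TR)
            if edge:
                continue
            disc = cg.shifts[np.argmax(cg.values)] * TR
            assert abs(tau - disc) <= TR + 1e-9


class TestLagMap:
    def _volume_with_lags(self, ref, lags_s, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        lags = np.asarray(lags_s, float)
        data = delay_signal(ref, lags, TR)
        if noise:
            data = data + rng.normal(0, noise, data.shape)
        return TimeSeriesVolume(data, TR)

    def test_planted_lags_recovered_noiselessly(self, ref128):
        lags = np.linspace(-5.6, 5.6, 27).reshape(3, 3, 3)
        vol = self._volume_with_lags(ref128, lags)
        # anchor the reference with a block of zero-lag voxels
        anchor = np.tile(ref128, (3, 3, 3, 1))
        full = TimeSeriesVolume(
            np.concatenate([vol.data, anchor], axis=0), TR
        )
        gm = np.ones((6, 3, 3), bool)
        lm = compute_lag_map(full, gm, max_shift=3)
        valid = lm.valid[:3]
        err = np.abs(lm.tau_s[:3][valid] - lags[valid])
        assert valid.sum() > 20
        assert err.max() < 0.25 * TR

    def test_pure_noise_voxel_marked_low_correlation(self, ref128):
        rng = np.random.default_rng(0)
        data = np.tile(ref128, (3, 3, 3, 1)).copy()
        data[0, 0, 0] = rng.standard_normal(128)
        lm = compute_lag_map(TimeSeriesVolume(data, TR), np.ones((3, 3, 3), bool))
        assert not lm.valid[0, 0, 0]
        assert lm.reason[0, 0, 0] == LOW_CORRELATION

    def test_uniform_volume_gives_zero_lag_everywhere(self, ref128):
        data = np.tile(ref128, (3, 3, 3, 1))
        lm = compute_lag_map(TimeSeriesVolume(data, TR), np.ones((3, 3, 3), bool))
        assert lm.valid.all()
        np.testing.assert_allclose(lm.tau_s, 0.0, atol=1e-9)
        np.testing.assert_allclose(lm.peak_r, 1.0, atol=1e-9)

    def test_lesioned_and_constant_voxels_get_reason_codes(self, ref128):
        data = np.tile(ref128, (2, 2, 2, 1)).copy()
        data[1, 1, 1] = 5.0  # constant
        lesion = np.zeros((2, 2, 2), bool)
        lesion[0, 0, 0] = True
        lm = compute_lag_map(TimeSeriesVolume(data, TR), np.ones((2, 2, 2), bool), lesion)
        from hemolag.lag import LESIONED

        assert lm.reason[0, 0, 0] == LESIONED
        assert lm.reason[1, 1, 1] == NO_VARIANCE

    def test_edge_peak_invalidated(self, ref128):
        # drive one voxel's lag to the window edge: argmax lands at +3
        data = np.tile(ref128, (2, 2, 2, 1)).copy()
        data[0, 0, 0] = delay_signal(ref128, 3 * TR, TR)
        lm = compute_lag_map(TimeSeriesVolume(data, TR), np.ones((2, 2, 2), bool))
        assert lm.reason[0, 0, 0] == EDGE
        assert not lm.valid[0, 0, 0]

    def test_shift_equivariance(self, ref128):
        """Delaying a voxel's series by +k frames raises its lag by k TR."""
        base_lag = -1.9
        data = np.tile(ref128, (4, 1, 1, 1)).copy()
        s = delay_signal(ref128, base_lag, TR)
        data[1, 0, 0] = s
        data[2, 0, 0] = np.roll(s, 1)
        data[3, 0, 0] = np.roll(s, 2)
        lm = compute_lag_map(TimeSeriesVolume(data, TR), np.ones((4, 1, 1), bool))
        t1, t2, t3 = lm.tau_s[1:, 0, 0]
        assert t2 - t1 == pytest.approx(TR, abs=0.05 * TR)
        assert t3 - t2 == pytest.approx(TR, abs=0.05 * TR)

    def test_antisymmetry_swapping_roles_negates_lag(self, ref128):
        from hemolag import ReferenceSignal, cross_correlogram, parabolic_refine

        s = delay_signal(ref128, 1.3, TR) + np.random.default_rng(5).normal(
            0, 0.2, 128
        )
        cg_fwd = cross_correlogram(s, ref128, 3)
        cg_rev = cross_correlogram(ref128, s, 3)
        tau_fwd = parabolic_refine(cg_fwd, TR)[0]
        tau_rev = parabolic_refine(cg_rev, TR)[0]
        assert tau_fwd == pytest.approx(-tau_rev, abs=0.05 * TR)

    def test_window_bound_holds_everywhere_valid(self, noisy_cohort):
        vol = noisy_cohort.subject_volume(0)
        lm = compute_lag_map(
            vol, noisy_cohort.gm_mask, noisy_cohort.lesions[0], max_shift=3
        )
        assert np.all(np.abs(lm.tau_s[lm.valid]) <= lm.window_s + 1e-9)
        assert np.all(lm.peak_r[lm.valid] >= 0.1)

    def test_matches_per_voxel_correlogram_route(self, ref128):
        """Vectorized map equals the scalar correlogram+refine route."""
        rng = np.random.default_rng(6)
        lags = rng.uniform(-4, 4, (3, 3, 3))
        data = delay_signal(ref128, lags, TR) + rng.normal(0, 0.3, (3, 3, 3, 128))
        vol = TimeSeriesVolume(data, TR)
        gm = np.ones((3, 3, 3), bool)
        lm = compute_lag_map(vol, gm, max_shift=3)
        ref = compute_reference(vol, gm)
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    cg = cross_correlogram(data[i, j, k], ref, 3)
                    tau, peak, edge = parabolic_refine(cg, TR)
                    if lm.valid[i, j, k]:
                        assert lm.tau_s[i, j, k] == pytest.approx(tau, abs=1e-10)
                        assert lm.peak_r[i, j, k] == pytest.approx(peak, abs=1e-10)


class TestGroupStats:
    def _lagmap(self, tau, valid):
        from hemolag import LagMap

        tau = np.asarray(tau, float)
        return LagMap(
            tau_s=tau, peak_r=np.ones_like(tau), valid=np.asarray(valid, bool),
            reason=np.where(valid, 0, 3).astype(np.int8),
            tr_s=TR, affine=np.eye(4),
        )

    def test_pair_mean_and_sd(self):
        a = self._lagmap(np.full((2, 2, 2), 1.0), np.ones((2, 2, 2)))
        b = self._lagmap(np.full((2, 2, 2), -1.0), np.ones((2, 2, 2)))
        mean, sd, n = group_lag_stats([a, b])
        np.testing.assert_allclose(mean, 0.0)
        np.testing.assert_allclose(sd, np.sqrt(2.0))
        np.testing.assert_array_equal(n, 2)

    def test_invalid_subject_excluded_from_count(self):
        valid_b = np.ones((2, 2, 2), bool)
        valid_b[0, 0, 0] = False
        a = self._lagmap(np.full((2, 2, 2), 2.0), np.ones((2, 2, 2)))
        b = self._lagmap(np.full((2, 2, 2), 4.0), valid_b)
        mean, sd, n = group_lag_stats([a, b])
        assert n[0, 0, 0] == 1
        assert mean[0, 0, 0] == 2.0
        assert np.isnan(sd[0, 0, 0])

    def test_matches_masked_statistics_oracle(self):
        rng = np.random.default_rng(7)
        taus = rng.normal(0, 2, (5, 3, 3, 3))
        valids = rng.random((5, 3, 3, 3)) > 0.3
        maps = [self._lagmap(taus[i], valids[i]) for i in range(5)]
        mean, sd, n = group_lag_stats(maps)
        for idx in np.ndindex(3, 3, 3):
            sel = valids[(slice(None),) + idx]
            vals = taus[(slice(None),) + idx][sel]
            assert n[idx] == sel.sum()
            if sel.sum() > 0:
                assert mean[idx] == pytest.approx(vals.mean(), abs=1e-12)
            if sel.sum() > 1:
                assert sd[idx] == pytest.approx(vals.std(ddof=1), abs=1e-12)
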