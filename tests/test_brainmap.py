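"""Lesion-aware voxel-wise correlation: coverage rules, partial-correlation
VBCM, and the lag-behaviour analysis with its inclusion bookkeeping."""

import numpy as np
import pytest

from hemolag import (
    LagBehaviorModel,
    LagMap,
    VBCM,
    coverage_mask,
    lag_behavior_corr,
    partial_corr,
    vbcm,
)
from hemolag.brainmap import CORR_VALID, EXCLUDED_COVERAGE, INSUFFICIENT_N

TR = 2.8
GRID = (5, 5, 5)


def make_lagmap(tau, valid=None):
    tau = np.asarray(tau, float)
    if valid is None:
        valid = np.isfinite(tau)
    valid = np.asarray(valid, bool)
    return LagMap(
        tau_s=np.where(valid, tau, np.nan),
        peak_r=np.where(valid, 0.9, np.nan),
        valid=valid,
        reason=np.where(valid, 0, 2).astype(np.int8),
        tr_s=TR,
        affine=np.eye(4),
    )


class TestCoverage:
    def test_no_lesions_everything_analyzable(self):
        cov = coverage_mask([np.zeros(GRID, bool) for _ in range(10)])
        assert cov.analyzable.all()
        assert cov.damaged_count.max() == 0

    def test_twenty_one_of_thirty_five_excludes_voxel(self):
        lesions = [np.zeros(GRID, bool) for _ in range(35)]
        for m in lesions[:21]:
            m[2, 2, 2] = True
        for m in lesions[:20]:
            m[1, 1, 1] = True
        cov = coverage_mask(lesions, max_damaged=20)
        assert not cov.analyzable[2, 2, 2]  # 21 damaged > 20
        assert cov.analyzable[1, 1, 1]  # exactly 20 is still analyzable

    def test_counts_match_brute_force(self):
        rng = np.random.default_rng(0)
        lesions = [rng.random(GRID) > 0.7 for _ in range(12)]
        cov = coverage_mask(lesions, max_damaged=4)
        expected = sum(m.astype(int) for m in lesions)
        np.testing.assert_array_equal(cov.damaged_count, expected)
        np.testing.assert_array_equal(cov.analyzable, expected <= 4)


class TestVBCM:
    def _cohort(self, n=30, seed=1):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(n)
        volumes = rng.uniform(10, 100, n)
        maps = rng.standard_normal((n,) + GRID)
        return maps, scores, volumes

    def test_orthogonal_covariate_reduces_to_plain_pearson(self):
        rng = np.random.default_rng(2)
        n = 40
        scores = rng.standard_normal(n)
        maps = rng.standard_normal((n,) + GRID)
        # orthogonalize the covariate against scores and every voxel
        cov = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), scores, maps.reshape(n, -1)[:, :10]])
        cov -= X @ np.linalg.lstsq(X, cov, rcond=None)[0]
        res = vbcm(maps, scores, cov, min_n=4)
        for v in range(10):
            plain = np.corrcoef(maps.reshape(n, -1)[:, v], scores)[0, 1]
            assert res.r.ravel()[v] == pytest.approx(plain, abs=1e-10)

    def test_exact_linear_relation_gives_unit_partial_r(self):
        rng = np.random.default_rng(3)
        n = 25
        scores = rng.standard_normal(n)
        volumes = rng.uniform(5, 50, n)
        maps = np.empty((n,) + GRID)
        maps.reshape(n, -1)[:] = (2.0 * scores + 0.5 * volumes)[:, None]
        res = vbcm(maps, scores, volumes, min_n=4)
        assert np.abs(res.r[res.valid]).min() == pytest.approx(1.0, abs=1e-8)

    def test_matches_residualization_oracle(self):
        maps, scores, volumes = self._cohort()
        res = vbcm(maps, scores, volumes, min_n=4)
        n = len(scores)
        Z = np.column_stack([np.ones(n), volumes])
        rs = scores - Z @ np.linalg.lstsq(Z, scores, rcond=None)[0]
        flat = maps.reshape(n, -1)
        for v in range(0, flat.shape[1], 7):
            ry = flat[:, v] - Z @ np.linalg.lstsq(Z, flat[:, v], rcond=None)[0]
            oracle = np.corrcoef(rs, ry)[0, 1]
            assert res.r.ravel()[v] == pytest.approx(oracle, abs=1e-10)

    def test_p_uses_n_minus_3_degrees_of_freedom(self):
        from scipy import stats

        maps, scores, volumes = self._cohort(n=20, seed=4)
        res = vbcm(maps, scores, volumes, min_n=4)
        v = 11
        r = res.r.ravel()[v]
        t = r * np.sqrt((20 - 3) / (1 - r**2))
        assert res.p.ravel()[v] == pytest.approx(2 * stats.t.sf(abs(t), 17), rel=1e-10)

    def test_zero_variance_score_rejected(self):
        maps, scores, volumes = self._cohort()
        with pytest.raises(ValueError, match="variance"):
            VBCM(maps, np.ones_like(scores), volumes)


class TestLagBehavior:
    def _planted(self, n=30, slope=0.5, noise=0.3, seed=5):
        rng = np.random.default_rng(seed)
        scores = rng.standard_normal(n)
        maps = []
        for i in range(n):
            tau = np.zeros(GRID)
            tau += rng.normal(0, noise, GRID)
            tau[2, 2, 2] = slope * scores[i] + rng.normal(0, noise)
            maps.append(make_lagmap(tau))
        return maps, scores

    def test_planted_coupling_recovered_with_correct_sign(self):
        maps, scores = self._planted()
        res = lag_behavior_corr(maps, scores, min_n=15)
        assert res.valid[2, 2, 2]
        assert res.r[2, 2, 2] > 0.3
        assert res.n[2, 2, 2] == 30

    def test_voxel_intact_in_fourteen_patients_is_insufficient(self):
        maps, scores = self._planted(n=20)
        for lm in maps[:6]:  # leave 14 valid at the target voxel
            lm.valid[2, 2, 2] = False
            lm.tau_s[2, 2, 2] = np.nan
        res = lag_behavior_corr(maps, scores, min_n=15)
        assert not res.valid[2, 2, 2]
        assert res.reason[2, 2, 2] == INSUFFICIENT_N
        assert res.n[2, 2, 2] == 0

    def test_extreme_lag_dropped_and_n_decremented(self):
        maps, scores = self._planted(n=25, noise=0.2)
        maps[7].tau_s[2, 2, 2] = 50.0  # 10+ SD above the rest
        res = lag_behavior_corr(maps, scores, min_n=15)
        assert res.n[2, 2, 2] == 24
        base = lag_behavior_corr(
            [m for i, m in enumerate(maps) if i != 7],
            np.delete(scores, 7),
            min_n=15,
        )
        assert res.r[2, 2, 2] == pytest.approx(base.r[2, 2, 2], abs=1e-12)

    def test_score_flagged_patients_excluded_globally(self):
        maps, scores = self._planted(n=25)
        flags = np.zeros(25, bool)
        flags[[3, 9]] = True
        res = lag_behavior_corr(maps, scores, min_n=15, score_flags=flags)
        assert res.n[res.valid].max() <= 23

    def test_coverage_exclusion_reason(self):
        maps, scores = self._planted(n=20)
        lesions = [np.zeros(GRID, bool) for _ in range(20)]
        for m in lesions:
            m[0, 0, 0] = True
        cov = coverage_mask(lesions, max_damaged=10)
        res = lag_behavior_corr(maps, scores, coverage=cov, min_n=15)
        assert res.reason[0, 0, 0] == EXCLUDED_COVERAGE

    def test_lesioned_patients_never_contribute(self, noisy_cohort):
        """Construction check on a synthetic cohort with known lesions."""
        from hemolag import compute_lag_map

        maps = []
        for i in range(noisy_cohort.spec.n_patients):
            lm = compute_lag_map(
                noisy_cohort.subject_volume(i),
                noisy_cohort.gm_mask,
                noisy_cohort.lesions[i],
            )
            maps.append(lm)
            assert not lm.valid[noisy_cohort.lesions[i]].any()
        scores = noisy_cohort.factor_scores_imaging[:, 0]
        res = lag_behavior_corr(maps, scores, min_n=5)
        intact_counts = (~noisy_cohort.lesions).sum(axis=0)
        assert np.all(res.n <= intact_counts)

    def test_n_map_monotone_under_added_lesions(self):
        maps, scores = self._planted(n=25)
        res_before = lag_behavior_corr(maps, scores, min_n=5)
        for lm in maps[:10]:
            lm.valid[2, 2, 2] = False
            lm.tau_s[2, 2, 2] = np.nan
        res_after = lag_behavior_corr(maps, scores, min_n=5)
        assert np.all(res_after.n <= res_before.n)

    def test_recovered_sign_matches_planted_coupling(self):
        """>= 95% correct signs at voxels with |true r| ~ 0.7, n = 30."""
        rng = np.random.default_rng(8)
        n = 30
        scores = rng.standard_normal(n)
        slope, noise = 0.7, 0.7  # population |r| = 0.707
        taus = slope * scores[:, None] + rng.normal(0, noise, (n, 125))
        maps = [make_lagmap(taus[i].reshape(GRID)) for i in range(n)]
        res = lag_behavior_corr(maps, scores, min_n=15)
        signs_ok = (res.r[res.valid] > 0).mean()
        assert signs_ok >= 0.95
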