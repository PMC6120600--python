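"""Voxel-wise brain-behaviour correlation with lesion-aware inclusion rules.

Two analyses share the :class:`CorrelationMap` result type:

* :class:`VBCM` — voxel-based correlational methodology: partial Pearson
  correlation of a continuous per-patient map (e.g. structural intensity)
  with a behavioural factor score, controlling for total lesion volume.
* :class:`LagBehaviorModel` — per-voxel Pearson correlation of hemodynamic
  lag with a factor score, where each voxel's contributing set is the
  patients with intact tissue and a valid lag there, score-outlier
  patients are excluded globally, per-voxel lag outliers (+/-3 SD across
  patients) are dropped, and voxels with fewer than ``min_n`` contributors
  are invalidated.

Coverage: a voxel damaged in more than ``max_damaged`` patients is removed
from analysis altogether, since too few intact observations remain for a
stable correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lag import LagMap

__all__ = [
    "CoverageMask",
    "CorrelationMap",
    "coverage_mask",
    "partial_corr",
    "VBCM",
    "LagBehaviorModel",
    "vbcm",
    "lag_behavior_corr",
    "CORR_REASONS",
]

# per-voxel validity reasons
CORR_VALID = 0
EXCLUDED_COVERAGE = 1
INSUFFICIENT_N = 2
NO_VARIANCE = 3
CORR_REASONS = {
    CORR_VALID: "valid",
    EXCLUDED_COVERAGE: "excluded-coverage",
    INSUFFICIENT_N: "insufficient-n",
    NO_VARIANCE: "no-variance",
}


@dataclass
class CoverageMask:
    """Per-voxel lesioned-patient counts and the analyzable mask."""

    damaged_count: np.ndarray
    analyzable: np.ndarray
    max_damaged: int


def coverage_mask(lesions: list[np.ndarray] | np.ndarray, max_damaged: int = 20) -> CoverageMask:
    """Count lesioned patients per voxel; exclude voxels above ``max_damaged``."""
    stack = np.stack([np.asarray(m) != 0 for m in lesions])
    if stack.ndim != 4:
        raise ValueError("lesions must be a list of 3D masks")
    counts = stack.sum(axis=0)
    return CoverageMask(
        damaged_count=counts,
        analyzable=counts <= max_damaged,
        max_damaged=int(max_damaged),
    )


@dataclass
class CorrelationMap:
    """Per-voxel correlation results.

    Attributes
    ----------
    r, p : 3D float arrays (NaN where invalid)
    n : 3D int array of contributing patients
    valid : 3D bool;  reason : 3D int8 (see CORR_REASONS)
    """

    r: np.ndarray
    n: np.ndarray
    p: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    affine: np.ndarray
    covariate: str | None = None

    def summary(self) -> pd.DataFrame:
        rows = [
            {"reason": name, "n_voxels": int((self.reason == code).sum())}
            for code, name in CORR_REASONS.items()
        ]
        out = pd.DataFrame(rows)
        rr = self.r[self.valid]
        out.attrs["r_max"] = float(np.nanmax(rr)) if rr.size else float("nan")
        out.attrs["r_min"] = float(np.nanmin(rr)) if rr.size else float("nan")
        out.attrs["median_n"] = float(np.median(self.n[self.valid])) if rr.size else float("nan")
        return out


def _r_to_p(r: np.ndarray, n: np.ndarray, n_covariates: int = 0) -> np.ndarray:
    """Two-sided p from the exact t transform, df = n - 2 - n_covariates."""
    df = n - 2 - n_covariates
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    p = np.where(df < 1, np.nan, p)
    p = np.where(np.abs(r) >= 1.0, np.finfo(float).tiny, p)
    return p


def partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial Pearson correlation of x and y controlling z."""
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("covariate fully determines a variable")
    return float((rxy - rxz * ryz) / denom)


class VBCM:
    """Partial correlation of per-patient 3D maps with a behavioural score.

    Parameters
    ----------
    intensity_maps : (n_patients, x, y, z) array or list of 3D arrays
        Continuous per-patient maps (e.g. smoothed structural intensity).
    scores : (n_patients,) array
        Behavioural factor score per patient.
    lesion_volumes : (n_patients,) array
        Total lesion volume per patient, entered as the covariate.
    coverage : CoverageMask, optional
        Voxels outside it are excluded with reason ``excluded-coverage``.
    min_n : int
        Minimum patients per voxel (applies when ``mask_nan`` drops some).
    """

    def __init__(
        self,
        intensity_maps: np.ndarray | list[np.ndarray],
        scores: np.ndarray,
        lesion_volumes: np.ndarray,
        coverage: CoverageMask | None = None,
        min_n: int = 15,
        affine: np.ndarray | None = None,
    ):
        self.maps = np.stack([np.asarray(m, dtype=float) for m in intensity_maps])
        self.scores = np.asarray(scores, dtype=float)
        self.lesion_volumes = np.asarray(lesion_volumes, dtype=float)
        n = self.maps.shape[0]
        if self.scores.shape != (n,) or self.lesion_volumes.shape != (n,):
            raise ValueError("scores and lesion_volumes must be one per patient")
        if n < 4:
            raise ValueError("need at least 4 patients (df = n - 3)")
        if self.scores.std() == 0:
            raise ValueError("behavioural score has zero variance")
        if self.lesion_volumes.std() == 0:
            raise ValueError("lesion-volume covariate has zero variance")
        self.coverage = coverage
        self.min_n = int(min_n)
        self.affine = np.eye(4) if affine is None else np.asarray(affine, dtype=float)

    def fit(self) -> CorrelationMap:
        n, *dims = self.maps.shape
        Y = self.maps.reshape(n, -1)  # patients x voxels
        x = self.scores
        z = self.lesion_volumes

        def zscore(v):
            return (v - v.mean()) / v.std()

        xs, zs = zscore(x), zscore(z)
        Ym = Y.mean(axis=0)
        Ysd = Y.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            Yz = (Y - Ym) / Ysd
            rxy = (Yz.T @ xs) / n
            rzy = (Yz.T @ zs) / n
        rxz = float(np.mean(xs * zs))
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (rxy - rxz * rzy) / np.sqrt((1 - rxz**2) * (1 - rzy**2))

        reason = np.full(Y.shape[1], CORR_VALID, dtype=np.int8)
        reason[Ysd == 0] = NO_VARIANCE
        if self.coverage is not None:
            reason[~self.coverage.analyzable.ravel()] = EXCLUDED_COVERAGE
        if n < self.min_n:
            reason[reason == CORR_VALID] = INSUFFICIENT_N
        valid = reason == CORR_VALID
        r[~valid] = np.nan
        n_map = np.where(valid, n, 0)
        p = _r_to_p(r, n_map.astype(float), n_covariates=1)
        p[~valid] = np.nan

        shape = tuple(dims)
        return CorrelationMap(
            r=r.reshape(shape),
            n=n_map.reshape(shape),
            p=p.reshape(shape),
            valid=valid.reshape(shape),
            reason=reason.reshape(shape),
            affine=self.affine,
            covariate="lesion_volume",
        )


class LagBehaviorModel:
    """Per-voxel Pearson correlation of hemodynamic lag with a factor score.

    Parameters
    ----------
    lagmaps : list of LagMap (one per patient, common grid)
    scores : (n_patients,) behavioural factor score
    coverage : CoverageMask, optional
    min_n : int
        Voxels with fewer contributing patients are invalid (default 15,
        from the power rule for detecting r = 0.75 at alpha 0.01).
    lag_sd_k : float
        Per-voxel lag outlier cut: values beyond mean +/- k SD across the
        contributing patients at that voxel are dropped.
    score_flags : boolean array, optional
        Patients flagged as factor-score outliers; excluded everywhere.
    lag_outlier_mode : 'per-voxel' (default) or 'per-subject'
        Whether the +/-k SD lag exclusion is computed across patients at
        each voxel, or across voxels within each subject's map.
    """

    def __init__(
        self,
        lagmaps: list[LagMap],
        scores: np.ndarray,
        coverage: CoverageMask | None = None,
        min_n: int = 15,
        lag_sd_k: float = 3.0,
        score_flags: np.ndarray | None = None,
        lag_outlier_mode: str = "per-voxel",
    ):
        if len(lagmaps) < 2:
            raise ValueError("need at least 2 patients")
        shape = lagmaps[0].tau_s.shape
        for lm in lagmaps[1:]:
            if lm.tau_s.shape != shape or not np.allclose(lm.affine, lagmaps[0].affine):
                raise ValueError("lag maps are not on a common grid")
        self.lagmaps = lagmaps
        self.scores = np.asarray(scores, dtype=float)
        if self.scores.shape != (len(lagmaps),):
            raise ValueError("one score per patient required")
        self.coverage = coverage
        self.min_n = int(min_n)
        self.lag_sd_k = float(lag_sd_k)
        if lag_outlier_mode not in ("per-voxel", "per-subject"):
            raise ValueError("lag_outlier_mode must be 'per-voxel' or 'per-subject'")
        self.lag_outlier_mode = lag_outlier_mode
        self.score_flags = (
            np.zeros(len(lagmaps), dtype=bool)
            if score_flags is None
            else np.asarray(score_flags, dtype=bool)
        )
        self.affine = lagmaps[0].affine

    def fit(self) -> CorrelationMap:
        keep_pat = ~self.score_flags
        lag = np.stack([lm.tau_s for lm in self.lagmaps])[keep_pat]
        ok = np.stack([lm.valid for lm in self.lagmaps])[keep_pat]
        scores = self.scores[keep_pat]
        n_pat, *dims = lag.shape
        shape = tuple(dims)

        lag = lag.reshape(n_pat, -1)
        ok = ok.reshape(n_pat, -1)

        if self.lag_outlier_mode == "per-subject":
            # +/- k SD across each subject's own valid voxels
            for i in range(n_pat):
                v = lag[i, ok[i]]
                if v.size > 2 and v.std(ddof=1) > 0:
                    z = np.abs(v - v.mean()) / v.std(ddof=1)
                    drop = np.flatnonzero(ok[i])[z > self.lag_sd_k]
                    ok[i, drop] = False
        else:
            # +/- k SD across patients at each voxel
            import warnings

            vals = np.where(ok, lag, np.nan)
            n0 = ok.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                mu = np.nanmean(np.where(n0 > 0, vals, np.nan), axis=0)
                sd = np.nanstd(np.where(n0 > 1, vals, np.nan), axis=0, ddof=1)
                z = np.abs(vals - mu) / sd
            drop = ok & (n0 > 2) & (sd > 0) & (z > self.lag_sd_k)
            ok &= ~drop

        n_map = ok.sum(axis=0)
        reason = np.full(lag.shape[1], CORR_VALID, dtype=np.int8)
        if self.coverage is not None:
            reason[~self.coverage.analyzable.ravel()] = EXCLUDED_COVERAGE
        enough = (n_map >= self.min_n) & (reason == CORR_VALID)
        reason[(n_map < self.min_n) & (reason == CORR_VALID)] = INSUFFICIENT_N

        r = np.full(lag.shape[1], np.nan)
        p = np.full(lag.shape[1], np.nan)
        for v in np.flatnonzero(enough):
            sel = ok[:, v]
            lv, sv = lag[sel, v], scores[sel]
            if lv.std() == 0 or sv.std() == 0:
                reason[v] = NO_VARIANCE
                continue
            r[v] = np.corrcoef(lv, sv)[0, 1]
        valid = reason == CORR_VALID
        n_out = np.where(valid, n_map, 0)
        p[valid] = _r_to_p(r[valid], n_out[valid].astype(float))

        return CorrelationMap(
            r=r.reshape(shape),
            n=n_out.reshape(shape),
            p=p.reshape(shape),
            valid=valid.reshape(shape),
            reason=reason.reshape(shape),
            affine=self.affine,
            covariate=None,
        )


def vbcm(
    intensity_maps: np.ndarray | list[np.ndarray],
    scores: np.ndarray,
    lesion_volumes: np.ndarray,
    **kwargs,
) -> CorrelationMap:
    """Functional wrapper over :class:`VBCM`."""
    return VBCM(intensity_maps, scores, lesion_volumes, **kwargs).fit()


def lag_behavior_corr(
    lagmaps: list[LagMap],
    scores: np.ndarray,
    coverage: CoverageMask | None = None,
    min_n: int = 15,
    lag_sd_k: float = 3.0,
    score_flags: np.ndarray | None = None,
    **kwargs,
) -> CorrelationMap:
    """Functional wrapper over :class:`LagBehaviorModel`."""
    return LagBehaviorModel(
        lagmaps, scores, coverage=coverage, min_n=min_n,
        lag_sd_k=lag_sd_k, score_flags=score_flags, **kwargs
    ).fit()
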