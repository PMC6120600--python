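"""End-to-end orchestration: simulate/ingest -> preprocess -> lag maps ->
behavioural factors -> voxel-wise correlation -> cluster correction.

Every stage logs the thresholds it actually applied (file + stderr), and
all numeric outputs are deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import nifti
from .behavior import BehavioralPCA, FactorModelResults, flag_outlier_scores
from .brainmap import CorrelationMap, CoverageMask, LagBehaviorModel, VBCM, coverage_mask
from .config import PipelineConfig
from .correction import ClusterReport, cluster_extract, fdr_bh, monte_carlo_cluster_threshold, r_map_to_p
from .lag import HemodynamicLagModel, LagMap, group_lag_stats
from .preprocess import combine_dual_echo, preprocess_volume
from .synth import CohortSpec, SyntheticCohort, simulate_cohort
from .volume import TimeSeriesVolume

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger("hemolag")


@dataclass
class PipelineResult:
    """Bundle of everything a pipeline run produced."""

    config: PipelineConfig
    lagmaps: list[LagMap]
    group_mean: np.ndarray
    group_sd: np.ndarray
    group_n: np.ndarray
    factor_model: FactorModelResults
    score_flags: pd.Series
    coverage: CoverageMask
    lag_corr: dict[str, CorrelationMap]
    vbcm_maps: dict[str, CorrelationMap]
    cluster_reports: dict[str, ClusterReport]
    cluster_threshold_voxels: int
    cohort: SyntheticCohort | None = None
    outputs: dict[str, str] = field(default_factory=dict)


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _thresholded_stat(r: np.ndarray, p: np.ndarray, voxel_p: float) -> np.ndarray:
    """r map with sub-threshold voxels zeroed, ready for cluster extraction."""
    out = np.where(np.isfinite(p) & (p < voxel_p), r, 0.0)
    return np.nan_to_num(out, nan=0.0)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Synthetic mode (no input paths): a cohort with planted lags, lesions
    and behaviour is generated, passed through the dual-echo combination
    and the rest of the preprocessing chain, and analyzed exactly as real
    data would be.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    try:
        return _run(config, out_dir)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out_dir: Path) -> PipelineResult:
    config.to_json(out_dir / "config.json")
    logger.info("stage=config seed=%d output=%s", config.seed, out_dir)

    # ---- simulate or ingest ----------------------------------------
    cohort: SyntheticCohort | None = None
    if config.synthetic:
        spec = CohortSpec(
            n_patients=config.n_patients,
            n_behavioral=config.n_behavioral,
            grid_dims=config.grid_dims,
            voxel_size_mm=config.voxel_size_mm,
            n_frames=config.n_frames,
            band_hz=config.band_hz,
            window_frames=config.max_shift,
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        cohort = simulate_cohort(spec)
        gm_mask, csf_mask = cohort.gm_mask, cohort.csf_mask
        lesions = list(cohort.lesions)
        behavior = cohort.behavior
        n_patients = spec.n_patients
        affine = spec.affine
        logger.info(
            "stage=simulate n_patients=%d grid=%s tr_s=%.3g n_frames=%d noise_sd=%.3g",
            n_patients, spec.grid_dims, spec.tr_s, spec.n_frames, spec.noise_sd,
        )

        def get_volume(i: int) -> tuple[TimeSeriesVolume, pd.DataFrame]:
            e1, e2 = cohort.subject_echoes(i)
            return combine_dual_echo(e1, e2), cohort.subject_motion(i)
    else:
        if not (config.gm_mask_path and config.lesion_mask_paths and config.motion_paths
                and config.behavior_table_path):
            raise ValueError("real-data mode needs gm mask, lesions, motion and behaviour paths")
        gm_mask, affine = nifti.read_mask(config.gm_mask_path)
        csf_mask = (
            nifti.read_mask(config.csf_mask_path)[0] if config.csf_mask_path else None
        )
        lesions = [nifti.read_mask(p)[0] for p in config.lesion_mask_paths]
        behavior = pd.read_csv(config.behavior_table_path, sep="\t", index_col=0)
        n_patients = len(config.volume_paths)
        logger.info("stage=ingest n_patients=%d", n_patients)

        def get_volume(i: int) -> tuple[TimeSeriesVolume, pd.DataFrame]:
            vol = nifti.read_volume(config.volume_paths[i], tr_s=config.tr_s)
            motion = pd.read_csv(config.motion_paths[i], sep=r"\s+", header=None)
            return vol, motion

    # ---- preprocess + per-subject lag maps -------------------------
    lagmaps: list[LagMap] = []
    for i in range(n_patients):
        vol, motion = get_volume(i)
        clean, info = preprocess_volume(
            vol, motion,
            csf_mask=csf_mask,
            n_discard=config.n_discard,
            z_thresh=config.z_thresh,
            move_thresh_mm=config.move_thresh_mm,
            low_hz=config.band_hz[0],
            high_hz=config.band_hz[1],
            brain_mask=gm_mask,
        )
        if i == 0:
            logger.info(
                "stage=preprocess n_discard=%d z_thresh=%.3g move_thresh_mm=%.3g "
                "band_hz=%s", info["n_discarded"], info["z_thresh"],
                info["move_thresh_mm"], info["band_hz"],
            )
        lm = HemodynamicLagModel(
            clean, gm_mask, lesions[i],
            max_shift=config.max_shift, min_r=config.min_r,
        ).fit()
        lagmaps.append(lm)
    logger.info(
        "stage=lagmap max_shift=%d window_s=%.3g min_r=%.3g subjects=%d",
        config.max_shift, lagmaps[0].window_s, config.min_r, n_patients,
    )
    g_mean, g_sd, g_n = group_lag_stats(lagmaps)

    # ---- behavioural factors ---------------------------------------
    fm = BehavioralPCA(behavior, eig_threshold=config.eig_threshold).fit()
    imaging_scores = fm.scores.iloc[:n_patients]
    score_flags = flag_outlier_scores(imaging_scores, k_sd=config.outlier_sd)
    logger.info(
        "stage=pca eig_threshold=%.3g retained=%d outlier_sd=%.3g flagged=%d",
        config.eig_threshold, fm.n_retained, config.outlier_sd, int(score_flags.sum()),
    )

    # ---- coverage + correlation maps -------------------------------
    cov = coverage_mask(lesions, max_damaged=config.max_damaged)
    logger.info(
        "stage=coverage max_damaged=%d excluded_voxels=%d",
        config.max_damaged, int((~cov.analyzable).sum()),
    )
    lesion_volumes = np.array([m.sum() for m in lesions], dtype=float)
    # stand-in structural intensity: smoothed intact-tissue indicator
    intensity = np.stack([
        ndimage.gaussian_filter((~m).astype(float), sigma=1.0) for m in lesions
    ])

    lag_corr: dict[str, CorrelationMap] = {}
    vbcm_maps: dict[str, CorrelationMap] = {}
    for fac in fm.scores.columns:
        scores = imaging_scores[fac].to_numpy()
        lag_corr[fac] = LagBehaviorModel(
            lagmaps, scores, coverage=cov,
            min_n=config.min_n, lag_sd_k=config.lag_sd_k,
            score_flags=score_flags.to_numpy(),
        ).fit()
        vbcm_maps[fac] = VBCM(
            intensity, scores, lesion_volumes, coverage=cov,
            min_n=min(config.min_n, n_patients), affine=affine,
        ).fit()
        if not lag_corr[fac].valid.any():
            logger.warning(
                "factor %s: no voxel reached min_n=%d contributing patients; "
                "all voxels invalid", fac, config.min_n,
            )
    logger.info(
        "stage=correlate min_n=%d lag_sd_k=%.3g covariate=lesion_volume",
        config.min_n, config.lag_sd_k,
    )

    # ---- cluster correction ----------------------------------------
    k_min = monte_carlo_cluster_threshold(
        cov.analyzable & np.asarray(gm_mask, bool),
        fwhm_mm=config.fwhm_mm,
        voxel_p=config.voxel_p,
        corrected_p=config.corrected_p,
        n_iter=config.n_iter,
        seed=config.seed + 1,
        voxel_size_mm=config.voxel_size_mm,
        connectivity=config.connectivity,
    )
    logger.info(
        "stage=cluster voxel_p=%.3g corrected_p=%.3g fwhm_mm=%.3g n_iter=%d "
        "connectivity=%d min_cluster_voxels=%d fdr_q=%.3g fdr_min_cluster=%d",
        config.voxel_p, config.corrected_p, config.fwhm_mm, config.n_iter,
        config.connectivity, k_min, config.fdr_q, config.fdr_min_cluster,
    )
    reports: dict[str, ClusterReport] = {}
    for fac, cmap in lag_corr.items():
        stat = _thresholded_stat(cmap.r, cmap.p, config.voxel_p)
        reports[fac] = cluster_extract(
            stat, np.finfo(float).tiny, min_size=k_min,
            affine=affine, connectivity=config.connectivity,
        )
        # FDR variant: voxel-wise BH at fdr_q plus a fixed extent cut
        finite = np.isfinite(cmap.p)
        sig = np.zeros_like(finite)
        if finite.any():
            sig[finite] = fdr_bh(cmap.p[finite], q=config.fdr_q)
        stat_fdr = np.where(sig, np.nan_to_num(cmap.r, nan=0.0), 0.0)
        reports[f"{fac}_fdr"] = cluster_extract(
            stat_fdr, np.finfo(float).tiny, min_size=config.fdr_min_cluster,
            affine=affine, connectivity=config.connectivity,
        )

    # ---- write outputs ---------------------------------------------
    outputs: dict[str, str] = {}

    def _save_map(name: str, data: np.ndarray) -> None:
        outputs[name] = str(nifti.write_map(data, affine, out_dir / f"{name}.nii"))

    _save_map("group_lag_mean_s", np.nan_to_num(g_mean, nan=0.0))
    _save_map("group_lag_sd_s", np.nan_to_num(g_sd, nan=0.0))
    _save_map("group_lag_n", g_n.astype(float))
    _save_map("coverage_damaged_count", cov.damaged_count.astype(float))
    _save_map("coverage_analyzable", cov.analyzable)
    for fac, cmap in lag_corr.items():
        _save_map(f"lagcorr_{fac}_r", np.nan_to_num(cmap.r, nan=0.0))
        _save_map(f"lagcorr_{fac}_n", cmap.n.astype(float))
        _save_map(f"lagcorr_{fac}_p", np.nan_to_num(cmap.p, nan=1.0))
    scores_path = out_dir / "factor_scores.tsv"
    fm.scores.to_csv(scores_path, sep="\t")
    outputs["factor_scores"] = str(scores_path)
    loadings_path = out_dir / "factor_loadings.tsv"
    fm.loadings.to_csv(loadings_path, sep="\t")
    outputs["factor_loadings"] = str(loadings_path)
    for fac, rep in reports.items():
        p = out_dir / f"clusters_{fac}.tsv"
        rep.to_frame().to_csv(p, sep="\t", index=False)
        outputs[f"clusters_{fac}"] = str(p)
    logger.info("stage=report outputs=%d", len(outputs))

    return PipelineResult(
        config=config,
        lagmaps=lagmaps,
        group_mean=g_mean,
        group_sd=g_sd,
        group_n=g_n,
        factor_model=fm,
        score_flags=score_flags,
        coverage=cov,
        lag_corr=lag_corr,
        vbcm_maps=vbcm_maps,
        cluster_reports=reports,
        cluster_threshold_voxels=k_min,
        cohort=cohort,
        outputs=outputs,
    )
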