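"""Multiple-comparison control for voxel-wise statistic maps.

Two routes are provided, mirroring common practice in lesion-symptom and
hemodynamic mapping:

* a Monte Carlo cluster-extent threshold (AlphaSim-style): white Gaussian
  fields are simulated on the analysis mask, smoothed to a nominal FWHM,
  standardized, thresholded at the two-tailed voxel-wise quantile, and the
  null distribution of the maximum suprathreshold cluster size yields the
  smallest cluster extent whose family-wise probability is below the
  corrected level;
* voxel-wise Benjamini-Hochberg FDR combined with a minimum cluster
  extent.

Cluster extraction reports size, volume (size x voxel volume), the
world-mm peak of |stat| and the member voxels, with positive and negative
suprathreshold clusters kept separate.  Connectivity defaults to
18-neighbour (faces + edges), the convention of the AFNI tool family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "Cluster",
    "ClusterReport",
    "monte_carlo_cluster_threshold",
    "fdr_bh",
    "cluster_extract",
    "r_map_to_p",
]

_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None


def _fwhm_to_sigma_vox(fwhm_mm: float, voxel_size_mm: np.ndarray) -> np.ndarray:
    return fwhm_mm / (np.sqrt(8.0 * np.log(2.0)) * voxel_size_mm)


def monte_carlo_cluster_threshold(
    mask: np.ndarray,
    fwhm_mm: float = 0.0,
    voxel_p: float = 0.01,
    corrected_p: float = 0.01,
    n_iter: int = 2000,
    seed: int | np.random.SeedSequence = 0,
    voxel_size_mm: float | tuple[float, float, float] = 3.0,
    connectivity: int = 18,
) -> int:
    """Minimum cluster extent (voxels) controlling family-wise error.

    Simulates ``n_iter`` white Gaussian fields on the mask's bounding box,
    smooths them to ``fwhm_mm`` (0 = no smoothing), standardizes over the
    mask, applies the two-tailed ``voxel_p`` threshold with signed cluster
    separation, and records the maximum suprathreshold cluster size.
    Returns the smallest k with ``P(max cluster >= k) <= corrected_p``.
    """
    mask = np.asarray(mask) != 0
    if mask.ndim != 3 or not mask.any():
        raise ValueError("mask must be a nonempty 3D array")
    if not 0 < voxel_p < 1:
        raise ValueError("voxel_p must be in (0, 1)")
    if not 0 < corrected_p < 1:
        raise ValueError("corrected_p must be in (0, 1)")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    voxel_size = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    struct = _structure(connectivity)
    z_crit = stats.norm.ppf(1.0 - voxel_p / 2.0)
    sigma = _fwhm_to_sigma_vox(fwhm_mm, voxel_size) if fwhm_mm > 0 else None

    rng = np.random.default_rng(seed)
    n_in = int(mask.sum())
    max_sizes = np.zeros(n_iter, dtype=int)
    for it in range(n_iter):
        field = rng.standard_normal(mask.shape)
        if sigma is not None:
            field = ndimage.gaussian_filter(field, sigma=sigma)
        vals = field[mask]
        z = np.zeros_like(field)
        z[mask] = (vals - vals.mean()) / vals.std()
        biggest = 0
        for supra in (z > z_crit, z < -z_crit):
            supra &= mask
            if not supra.any():
                continue
            labels, n_lab = ndimage.label(supra, structure=struct)
            if n_lab:
                sizes = np.bincount(labels.ravel())[1:]
                biggest = max(biggest, int(sizes.max()))
        max_sizes[it] = biggest

    # P(max >= k) as a function of k; smallest k meeting corrected_p
    for k in range(1, n_in + 2):
        if (max_sizes >= k).mean() <= corrected_p:
            return k
    return n_in + 1


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in (0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=q, method="fdr_bh")
    return reject.reshape(p.shape)


@dataclass
class Cluster:
    """One connected suprathreshold component."""

    size_voxels: int
    volume_mm3: float
    peak_world_mm: tuple[float, float, float]
    peak_stat: float
    sign: int  # +1 positive cluster, -1 negative
    members: np.ndarray  # (size, 3) voxel indices


@dataclass
class ClusterReport:
    """Signed suprathreshold clusters, largest first."""

    clusters: list[Cluster]
    stat_threshold: float
    min_size: int
    voxel_volume_mm3: float

    def __len__(self) -> int:
        return len(self.clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "size_voxels": c.size_voxels,
                "volume_mm3": c.volume_mm3,
                "peak_x_mm": c.peak_world_mm[0],
                "peak_y_mm": c.peak_world_mm[1],
                "peak_z_mm": c.peak_world_mm[2],
                "peak_stat": c.peak_stat,
                "sign": c.sign,
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "size_voxels", "volume_mm3", "peak_x_mm", "peak_y_mm",
                "peak_z_mm", "peak_stat", "sign",
            ],
        )


def cluster_extract(
    stat_map: np.ndarray,
    stat_threshold: float,
    min_size: int = 0,
    affine: np.ndarray | None = None,
    connectivity: int = 18,
    two_sided: bool = True,
) -> ClusterReport:
    """Connected suprathreshold components of a statistic map.

    Positive (stat >= threshold) and negative (stat <= -threshold)
    clusters are labelled separately; NaNs never belong to a cluster.
    Each cluster's volume is ``size_voxels * voxel_volume`` with the voxel
    volume taken from the affine (|det| of its 3x3 block), and the peak is
    the member voxel maximizing |stat|, reported in world mm.
    """
    stat = np.asarray(stat_map, dtype=float)
    if stat.ndim != 3:
        raise ValueError("stat_map must be 3D")
    if affine is None:
        affine = np.eye(4)
    affine = np.asarray(affine, dtype=float)
    voxel_volume = float(abs(np.linalg.det(affine[:3, :3])))
    struct = _structure(connectivity)
    finite = np.isfinite(stat)

    clusters: list[Cluster] = []
    sides = [(1, finite & (stat >= stat_threshold))]
    if two_sided:
        sides.append((-1, finite & (stat <= -stat_threshold)))
    for sign, supra in sides:
        labels, n_lab = ndimage.label(supra, structure=struct)
        for lab in range(1, n_lab + 1):
            members = np.argwhere(labels == lab)
            if len(members) < max(min_size, 1):
                continue
            vals = stat[tuple(members.T)]
            peak_i = members[np.argmax(np.abs(vals))]
            world = (affine @ np.append(peak_i, 1.0))[:3]
            clusters.append(
                Cluster(
                    size_voxels=len(members),
                    volume_mm3=len(members) * voxel_volume,
                    peak_world_mm=tuple(float(w) for w in world),
                    peak_stat=float(stat[tuple(peak_i)]),
                    sign=sign,
                    members=members,
                )
            )
    clusters.sort(key=lambda c: (-c.size_voxels, -abs(c.peak_stat)))
    return ClusterReport(
        clusters=clusters,
        stat_threshold=float(stat_threshold),
        min_size=int(min_size),
        voxel_volume_mm3=voxel_volume,
    )


def r_map_to_p(r: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Two-sided p map from an r map with per-voxel sample sizes.

    Uses the exact t transform, ``t = r sqrt((n-2)/(1-r^2))``, df = n - 2.
    Because n varies per voxel, thresholding p (not r) is the correct
    voxel-wise cut.
    """
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
    return np.where(df >= 1, p, np.nan)
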