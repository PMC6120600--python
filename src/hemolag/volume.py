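"""4D BOLD time-series container shared by every pipeline stage.

A :class:`TimeSeriesVolume` is a thin, validated wrapper around an
``(x, y, z, t)`` array plus the two pieces of acquisition metadata the lag
estimator depends on: the repetition time (TR, seconds per frame) and the
voxel-index -> world-mm affine.  Frames can be flagged as dropped without
resampling, so the temporal grid stays uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["TimeSeriesVolume"]


@dataclass
class TimeSeriesVolume:
    """4D signal on a voxel grid with TR and voxel->world affine.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, nt)
        BOLD signal in arbitrary units.
    tr_s : float
        Repetition time in seconds; must be positive.
    affine : ndarray, shape (4, 4)
        Invertible voxel-index (0-based) to world-mm map.
    frame_mask : ndarray of bool, shape (nt,), optional
        Per-frame keep flags.  Defaults to all-kept.
    """

    data: np.ndarray
    tr_s: float
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    frame_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (x, y, z, t), got ndim={self.data.ndim}")
        if not self.tr_s > 0:
            raise ValueError(f"tr_s must be positive, got {self.tr_s}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.n_frames, dtype=bool)
        else:
            self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
            if self.frame_mask.shape != (self.n_frames,):
                raise ValueError("frame_mask length must equal number of frames")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel, |det| of the spatial affine block."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def series(self) -> np.ndarray:
        """Flattened (n_voxels, nt) view of the data."""
        return self.data.reshape(-1, self.n_frames)

    def with_data(self, data: np.ndarray, frame_mask: np.ndarray | None = None) -> "TimeSeriesVolume":
        """New volume with replaced data, preserving TR and affine."""
        out = replace(self, data=np.asarray(data, dtype=float), frame_mask=frame_mask)
        return out

    def same_grid(self, other: "TimeSeriesVolume") -> bool:
        return (
            self.grid_shape == other.grid_shape
            and np.allclose(self.affine, other.affine)
        )

    def world_coords(self, ijk: np.ndarray) -> np.ndarray:
        """World-mm coordinates of 0-based voxel indices (..., 3)."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        homo = np.c_[ijk, np.ones(len(ijk))]
        return (homo @ self.affine.T)[:, :3]


def as_mask(arr: np.ndarray, shape: tuple[int, int, int] | None = None) -> np.ndarray:
    """Binarize a 3D array under the nonzero-is-true rule."""
    mask = np.asarray(arr) != 0
    if mask.ndim != 3:
        raise ValueError(f"mask must be 3D, got ndim={mask.ndim}")
    if shape is not None and mask.shape != tuple(shape):
        raise ValueError(f"mask shape {mask.shape} does not match grid {tuple(shape)}")
    return mask
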