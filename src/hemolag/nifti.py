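"""NIfTI-1 input/output.

4D files load as :class:`~hemolag.volume.TimeSeriesVolume` with the TR
taken from the header's fourth zoom unless the caller overrides it (an
override always wins — acquisition headers are wrong often enough that a
stated TR must take precedence; a mismatch is logged).  3D files load as
boolean masks under the nonzero-is-true rule, or as float maps on request.
"""

from __future__ import annotations

import logging
from pathlib import Path

import nibabel as nib
import numpy as np

from .volume import TimeSeriesVolume

__all__ = ["read_volume", "read_mask", "read_map", "write_volume", "write_map"]

logger = logging.getLogger("hemolag")


def _load(path: str | Path) -> nib.Nifti1Image:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    try:
        return nib.load(str(path))
    except Exception as exc:  # corrupt / wrong format
        raise OSError(f"cannot read NIfTI file {path}: {exc}") from exc


def read_volume(path: str | Path, tr_s: float | None = None) -> TimeSeriesVolume:
    """Load a 4D NIfTI as a TimeSeriesVolume.

    ``tr_s`` overrides the header TR; if the header TR is missing/zero and
    no override is given, an error is raised.
    """
    img = _load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path} is not 4D (shape {data.shape})")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if tr_s is not None:
        if header_tr > 0 and not np.isclose(header_tr, tr_s):
            logger.warning(
                "TR override %.4gs differs from header TR %.4gs in %s; using override",
                tr_s, header_tr, path,
            )
        tr = tr_s
    elif header_tr > 0:
        tr = header_tr
    else:
        raise ValueError(f"{path} has no usable header TR; pass tr_s explicitly")
    return TimeSeriesVolume(data=data, tr_s=tr, affine=np.asarray(img.affine))


def read_mask(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI as (boolean mask, affine); nonzero is true."""
    img = _load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path} is not 3D (shape {data.shape})")
    return data != 0, np.asarray(img.affine)


def read_map(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI as (float map, affine)."""
    img = _load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path} is not 3D (shape {data.shape})")
    return data, np.asarray(img.affine)


def write_volume(vol: TimeSeriesVolume, path: str | Path) -> Path:
    """Write a TimeSeriesVolume as 4D NIfTI-1, recording the TR."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=np.float64), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr_s
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def write_map(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D map (float; booleans stored as uint8) as NIfTI-1."""
    path = Path(path)
    arr = np.asarray(data)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    else:
        arr = arr.astype(np.float64)
    nib.save(nib.Nifti1Image(arr, np.asarray(affine, dtype=float)), str(path))
    return path
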