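"""Time-series cleaning ahead of lag estimation.

Implements the minimal, self-contained preprocessing chain the lag
estimator assumes: dual-echo averaging, discarding initial non-equilibrium
frames, flagging motion/intensity outlier frames, nuisance regression
(CSF mean, Friston-24 motion expansion, per-outlier indicator columns)
and a zero-phase 0.01-0.08 Hz band-pass.  Spatial steps (realignment,
normalisation, segmentation, smoothing) are out of scope: volumes are
assumed already in a common analysis grid.

The band-pass is realized as a zero-phase FFT mask.  A causal filter's
group delay would bias every downstream lag estimate, which is exactly the
quantity under study, so phase linearity here is a correctness requirement
rather than a preference.  Outlier frames are regressed out via indicator
columns rather than deleted: deleting frames would break the uniform
temporal sampling the lagged cross-correlation window relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import InvalidBandError, _check_band
from .volume import TimeSeriesVolume, as_mask

__all__ = [
    "NuisanceSet",
    "combine_dual_echo",
    "discard_initial_frames",
    "detect_outlier_frames",
    "friston24",
    "build_nuisance",
    "nuisance_regress",
    "bandpass",
    "preprocess_volume",
]


@dataclass
class NuisanceSet:
    """Frame x k nuisance design (CSF mean, motion terms, outlier indicators)."""

    regressors: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.regressors = np.atleast_2d(np.asarray(self.regressors, dtype=float))
        if self.regressors.shape[1] != len(self.names):
            raise ValueError("one name per regressor column required")
        if (np.abs(self.regressors).sum(axis=0) == 0).any():
            raise ValueError("constant-zero nuisance column")


def combine_dual_echo(echo1: TimeSeriesVolume, echo2: TimeSeriesVolume) -> TimeSeriesVolume:
    """Voxel-wise arithmetic mean of two simultaneously acquired echoes."""
    if echo1.data.shape != echo2.data.shape:
        raise ValueError(
            f"echo grids differ: {echo1.data.shape} vs {echo2.data.shape}"
        )
    if not np.isclose(echo1.tr_s, echo2.tr_s):
        raise ValueError("echo TRs differ")
    return echo1.with_data(0.5 * (echo1.data + echo2.data))


def discard_initial_frames(vol: TimeSeriesVolume, n: int = 2) -> TimeSeriesVolume:
    """Drop the first ``n`` frames (T1-equilibration period); TR unchanged."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= vol.n_frames:
        raise ValueError(f"cannot discard {n} of {vol.n_frames} frames")
    return vol.with_data(vol.data[..., n:])


def detect_outlier_frames(
    global_mean: np.ndarray,
    motion: pd.DataFrame | np.ndarray,
    z_thresh: float = 2.5,
    move_thresh_mm: float = 1.0,
) -> np.ndarray:
    """Flag frames with extreme global intensity or a large head movement.

    A frame is an outlier if the z-score of the global mean signal exceeds
    ``z_thresh`` in magnitude, or if any translation axis jumps by more than
    ``move_thresh_mm`` relative to the previous frame (framewise delta; the
    first frame has no predecessor and cannot be motion-flagged).

    ``motion`` is a frames x 6 table whose first three columns are
    translations in mm.
    """
    g = np.asarray(global_mean, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 frames")
    sd = g.std()
    if sd == 0:
        raise ValueError("global mean signal has zero variance")
    z_flags = np.abs((g - g.mean()) / sd) > z_thresh

    m = np.asarray(motion, dtype=float)
    if m.ndim != 2 or m.shape[0] != g.size:
        raise ValueError("motion table must have one row per frame")
    trans = m[:, :3]
    delta = np.abs(np.diff(trans, axis=0))
    move_flags = np.zeros(g.size, dtype=bool)
    move_flags[1:] = (delta > move_thresh_mm).any(axis=1)
    return z_flags | move_flags


def friston24(motion: pd.DataFrame | np.ndarray) -> np.ndarray:
    """24-parameter motion expansion: [p, p**2, p(t-1), p(t-1)**2].

    The lagged terms use a zero for the (undefined) frame before the first.
    """
    p = np.asarray(motion, dtype=float)
    if p.ndim != 2 or p.shape[1] != 6:
        raise ValueError("motion must be frames x 6")
    lagged = np.vstack([np.zeros((1, 6)), p[:-1]])
    return np.hstack([p, p**2, lagged, lagged**2])


def build_nuisance(
    vol: TimeSeriesVolume,
    motion: pd.DataFrame | np.ndarray,
    csf_mask: np.ndarray | None = None,
    outlier_flags: np.ndarray | None = None,
) -> NuisanceSet:
    """Assemble the full nuisance design for one subject.

    Columns: mean CSF signal (if a CSF mask is given), the Friston-24 motion
    expansion, and one indicator column per flagged outlier frame.  White
    matter and global means are deliberately absent — removing the global
    signal would remove the reference time course the lag estimator
    correlates against.
    """
    cols, names = [], []
    if csf_mask is not None:
        csf_mask = as_mask(csf_mask, vol.grid_shape)
        if not csf_mask.any():
            raise ValueError("empty CSF mask")
        cols.append(vol.data[csf_mask].mean(axis=0))
        names.append("csf_mean")
    f24 = friston24(motion)
    if f24.shape[0] != vol.n_frames:
        raise ValueError("motion rows must equal frame count")
    cols.extend(f24.T)
    names.extend(
        [f"mot{i + 1}" for i in range(6)]
        + [f"mot{i + 1}_sq" for i in range(6)]
        + [f"mot{i + 1}_lag" for i in range(6)]
        + [f"mot{i + 1}_lag_sq" for i in range(6)]
    )
    if outlier_flags is not None:
        outlier_flags = np.asarray(outlier_flags, dtype=bool)
        for t in np.flatnonzero(outlier_flags):
            ind = np.zeros(vol.n_frames)
            ind[t] = 1.0
            cols.append(ind)
            names.append(f"outlier_t{t}")
    design = np.column_stack(cols) if cols else np.empty((vol.n_frames, 0))
    # drop exactly-zero columns (e.g. all-zero lagged motion at t=0 only)
    keep = np.abs(design).sum(axis=0) > 0
    return NuisanceSet(design[:, keep], [n for n, k in zip(names, keep) if k])


def nuisance_regress(vol: TimeSeriesVolume, nuis: NuisanceSet | np.ndarray) -> TimeSeriesVolume:
    """Per-voxel least-squares residuals against the nuisance design.

    An intercept is always included, so residuals are demeaned.  A
    rank-deficient design falls through to the pseudo-inverse solution
    (still the minimum-norm least-squares fit).
    """
    X = nuis.regressors if isinstance(nuis, NuisanceSet) else np.atleast_2d(np.asarray(nuis, float))
    if X.shape[0] != vol.n_frames:
        raise ValueError("design rows must equal frame count")
    X = np.column_stack([np.ones(vol.n_frames), X])
    Y = vol.series().T  # frames x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return vol.with_data(resid.T.reshape(vol.data.shape))


def bandpass(
    vol: TimeSeriesVolume,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
) -> TimeSeriesVolume:
    """Zero-phase band-pass via an FFT mask on each voxel's series.

    Each series is mirror-extended (reflected at both ends, tripling its
    length) before masking and cropped back afterwards: a brick-wall mask
    applied to the raw finite segment leaks badly at the edges for
    components that are not periodic over the window (slow drifts in
    particular), and reflection removes the edge discontinuity that causes
    it.  The mask is real and symmetric, so no phase is introduced at any
    frequency — a causal filter's group delay would bias the lag estimates
    downstream.  DC is removed by construction.
    """
    _check_band((low_hz, high_hz), vol.tr_s)
    n = vol.n_frames
    ext = np.concatenate(
        [vol.data[..., ::-1], vol.data, vol.data[..., ::-1]], axis=-1
    )
    m = ext.shape[-1]
    freqs = np.fft.rfftfreq(m, d=vol.tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    if not keep.any():
        raise InvalidBandError("no Fourier bins inside the requested band")
    spec = np.fft.rfft(ext, axis=-1)
    spec[..., ~keep] = 0.0
    filtered = np.fft.irfft(spec, n=m, axis=-1)[..., n : 2 * n]
    return vol.with_data(filtered)


def preprocess_volume(
    vol: TimeSeriesVolume,
    motion: pd.DataFrame | np.ndarray,
    csf_mask: np.ndarray | None = None,
    n_discard: int = 2,
    z_thresh: float = 2.5,
    move_thresh_mm: float = 1.0,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    brain_mask: np.ndarray | None = None,
) -> tuple[TimeSeriesVolume, dict]:
    """Standard chain: discard -> outlier flags -> nuisance regression -> band-pass.

    Returns the cleaned volume plus a provenance dict recording the flags
    and thresholds actually applied.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.shape[0] == vol.n_frames:
        motion_kept = motion[n_discard:]
    elif motion.shape[0] == vol.n_frames - n_discard:
        motion_kept = motion
    else:
        raise ValueError("motion rows must match raw or retained frame count")
    vol = discard_initial_frames(vol, n_discard)
    if brain_mask is None:
        global_mean = vol.series().mean(axis=0)
    else:
        global_mean = vol.data[as_mask(brain_mask, vol.grid_shape)].mean(axis=0)
    flags = detect_outlier_frames(global_mean, motion_kept, z_thresh, move_thresh_mm)
    nuis = build_nuisance(vol, motion_kept, csf_mask=csf_mask, outlier_flags=flags)
    vol = nuisance_regress(vol, nuis)
    vol = bandpass(vol, low_hz, high_hz)
    info = {
        "n_discarded": n_discard,
        "outlier_frames": np.flatnonzero(flags).tolist(),
        "z_thresh": z_thresh,
        "move_thresh_mm": move_thresh_mm,
        "band_hz": (low_hz, high_hz),
        "n_nuisance": nuis.regressors.shape[1],
    }
    return vol, info
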