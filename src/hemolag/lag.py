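"""Per-voxel hemodynamic lag estimation by lagged cross-correlation.

The temporal shift of each voxel's resting-state time course is measured
against the mean time course of intact grey matter (the reference signal
``g``).  For voxel series ``s`` the lagged cross-correlation over the
``n_tau`` overlapping frames at integer shift ``tau`` is

    C(tau) = (1 / n_tau) * sum_t  g~(t) * s~(t + tau) / (sigma_g * sigma_s)

with globally demeaned signals ``g~``, ``s~`` and full-series standard
deviations ``sigma_g``, ``sigma_s``.  The shift grid spans +/- ``max_shift``
frames in steps of one TR (default +/-3 frames = +/-8.4 s at TR 2.8 s); the
discrete peak is refined to sub-frame resolution by fitting a parabola
through the peak and its two neighbours.  Positive refined lag ``tau_m``
means the voxel's signal arrives *after* the reference (a lag); negative
means it leads.

Demeaning before the product-sum makes ``C`` a Pearson-type correlation,
which is what the ``r < 0.1`` validity rule presumes; with raw (non-zero
mean) signals the product-sum is dominated by the means and the rule would
be vacuous.  Voxels are marked invalid — with a reason code — when they
are lesioned, outside the analysis mask, constant, peak below ``min_r``,
or peak at the window edge (where the parabola vertex is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .volume import TimeSeriesVolume, as_mask

__all__ = [
    "ReferenceSignal",
    "Correlogram",
    "LagMap",
    "HemodynamicLagModel",
    "compute_reference",
    "cross_correlogram",
    "parabolic_refine",
    "compute_lag_map",
    "group_lag_stats",
    "REASONS",
]

# validity reason codes stored in LagMap.reason
VALID = 0
OUT_OF_MASK = 1
LESIONED = 2
LOW_CORRELATION = 3
EDGE = 4
NO_VARIANCE = 5
REASONS = {
    VALID: "valid",
    OUT_OF_MASK: "out-of-mask",
    LESIONED: "lesioned",
    LOW_CORRELATION: "low-correlation",
    EDGE: "edge",
    NO_VARIANCE: "no-variance",
}


class ZeroVarianceError(ValueError):
    """A signal required to have variance is constant."""


@dataclass
class ReferenceSignal:
    """Mean intact grey-matter time course ``g`` and its SD ``sigma_g``."""

    g: np.ndarray
    sigma_g: float

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 1:
            raise ValueError("reference must be a 1D series")
        if not self.sigma_g > 0:
            raise ZeroVarianceError("reference signal has zero variance")


@dataclass
class Correlogram:
    """C(tau) over the shift window, with per-shift overlap counts."""

    shifts: np.ndarray  # integer frame offsets, -W..W
    values: np.ndarray  # C(tau)
    overlap: np.ndarray  # n_tau = T - |tau|
    sigma_s: float  # voxel-series SD (0 flags an undefined correlation)

    @property
    def defined(self) -> bool:
        return self.sigma_s > 0


def compute_reference(
    vol: TimeSeriesVolume,
    gm_mask: np.ndarray,
    lesion: np.ndarray | None = None,
) -> ReferenceSignal:
    """Frame-wise mean over intact grey matter (grey AND NOT lesioned)."""
    gm = as_mask(gm_mask, vol.grid_shape)
    intact = gm if lesion is None else gm & ~as_mask(lesion, vol.grid_shape)
    if not intact.any():
        raise ValueError("no intact grey-matter voxels in the reference set")
    g = vol.data[intact].mean(axis=0)
    return ReferenceSignal(g=g, sigma_g=float(g.std()))


def cross_correlogram(
    s: np.ndarray,
    ref: ReferenceSignal | np.ndarray,
    max_shift: int = 3,
) -> Correlogram:
    """Lagged cross-correlation of one voxel series against the reference.

    Signals are demeaned globally; the per-shift sum runs over the
    ``T - |tau|`` overlapping frames and is scaled by
    ``1 / (n_tau * sigma_g * sigma_s)`` with full-series SDs.
    """
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    if isinstance(ref, ReferenceSignal):
        g = ref.g
        sigma_g = ref.sigma_g
    else:
        g = np.asarray(ref, dtype=float)
        sigma_g = float(g.std())
        if sigma_g == 0:
            raise ZeroVarianceError("reference signal has zero variance")
    s = np.asarray(s, dtype=float)
    if s.shape != g.shape:
        raise ValueError("series and reference lengths differ")
    T = len(g)
    if max_shift >= T:
        raise ValueError("max_shift must be smaller than the series length")

    gd = g - g.mean()
    sd = s - s.mean()
    sigma_s = float(s.std())
    shifts = np.arange(-max_shift, max_shift + 1)
    overlap = T - np.abs(shifts)
    values = np.zeros_like(shifts, dtype=float)
    if sigma_s > 0:
        for k, tau in enumerate(shifts):
            if tau >= 0:
                prod = gd[: T - tau] @ sd[tau:]
            else:
                prod = gd[-tau:] @ sd[: T + tau]
            values[k] = prod / (overlap[k] * sigma_g * sigma_s)
    return Correlogram(shifts=shifts, values=values, overlap=overlap, sigma_s=sigma_s)


def _argmax_smallest_shift(values: np.ndarray, shifts: np.ndarray) -> int:
    """Index of the max; ties broken toward the smallest |shift| (null bias),
    then toward the negative shift for exact +/- ties."""
    best = np.flatnonzero(values == values.max())
    order = np.lexsort((shifts[best], np.abs(shifts[best])))
    return int(best[order[0]])


def parabolic_refine(
    cg: Correlogram, tr_s: float
) -> tuple[float, float, bool]:
    """Sub-frame peak location by a parabola through the discrete peak.

    Returns ``(tau_m_seconds, peak_r, edge_flag)``.  With peak index ``p``
    and spacing ``delta`` (one frame), the vertex offset is

        tau_m = tau_p + (delta/2) * (C[p-1] - C[p+1]) / (C[p-1] - 2 C[p] + C[p+1])

    If the discrete peak sits at the window edge the vertex is undefined:
    ``edge_flag`` is returned true and tau/peak are NaN.  A collinear triple
    (zero curvature) falls back to the discrete peak itself.
    """
    if len(cg.shifts) < 3:
        raise ValueError("need at least 3 shifts to refine")
    if not cg.defined:
        return float("nan"), float("nan"), False
    p = _argmax_smallest_shift(cg.values, cg.shifts)
    if p == 0 or p == len(cg.shifts) - 1:
        return float("nan"), float("nan"), True
    c_m, c_0, c_p = cg.values[p - 1], cg.values[p], cg.values[p + 1]
    denom = c_m - 2.0 * c_0 + c_p
    if abs(denom) < 1e-12:
        return float(cg.shifts[p]) * tr_s, float(c_0), False
    offset = 0.5 * (c_m - c_p) / denom
    tau_m = (cg.shifts[p] + offset) * tr_s
    peak = c_0 - 0.25 * (c_m - c_p) * offset
    return float(tau_m), float(peak), False


@dataclass
class LagMap:
    """Per-voxel lag estimates for one subject.

    Attributes
    ----------
    tau_s : 3D float array
        Refined temporal shift in seconds (positive = lag, negative = lead);
        NaN where invalid.
    peak_r : 3D float array
        Parabola-vertex correlation at the refined shift; NaN where the
        vertex is undefined (edge peak, zero variance, out of mask).
    valid : 3D bool array
    reason : 3D int8 array
        Reason code per voxel (see :data:`REASONS`).
    """

    tau_s: np.ndarray
    peak_r: np.ndarray
    valid: np.ndarray
    reason: np.ndarray
    tr_s: float
    affine: np.ndarray
    max_shift: int = 3
    min_r: float = 0.1

    @property
    def window_s(self) -> float:
        """Half-width of the search window in seconds (max_shift * TR)."""
        return self.max_shift * self.tr_s

    def summary(self) -> pd.DataFrame:
        """Voxel counts per validity reason plus lag statistics."""
        rows = []
        for code, name in REASONS.items():
            n = int((self.reason == code).sum())
            if n or code == VALID:
                rows.append({"reason": name, "n_voxels": n})
        out = pd.DataFrame(rows)
        tau = self.tau_s[self.valid]
        out.attrs["lag_mean_s"] = float(tau.mean()) if tau.size else float("nan")
        out.attrs["lag_sd_s"] = float(tau.std(ddof=1)) if tau.size > 1 else float("nan")
        out.attrs["window_s"] = self.window_s
        return out


class HemodynamicLagModel:
    """Estimate a per-voxel lag map for one preprocessed subject.

    Parameters
    ----------
    vol : TimeSeriesVolume
        Preprocessed (nuisance-regressed, band-passed) 4D volume.
    gm_mask : 3D mask
        Grey-matter analysis mask.
    lesion_mask : 3D mask, optional
        Voxels excluded as damaged and omitted from the reference.
    max_shift : int
        Search window half-width in frames (+/-3 frames = +/-8.4 s at
        TR 2.8 s).
    min_r : float
        Minimum peak correlation; voxels not positively correlated with the
        reference beyond this are excluded as showing no measurable
        hemodynamic shift.
    reference : ReferenceSignal, optional
        Override the intact grey-matter mean (e.g. a group reference).
    """

    def __init__(
        self,
        vol: TimeSeriesVolume,
        gm_mask: np.ndarray,
        lesion_mask: np.ndarray | None = None,
        max_shift: int = 3,
        min_r: float = 0.1,
        reference: ReferenceSignal | None = None,
    ):
        self.vol = vol
        self.gm_mask = as_mask(gm_mask, vol.grid_shape)
        self.lesion_mask = (
            np.zeros(vol.grid_shape, dtype=bool)
            if lesion_mask is None
            else as_mask(lesion_mask, vol.grid_shape)
        )
        if max_shift < 1:
            raise ValueError("max_shift must be >= 1")
        self.max_shift = int(max_shift)
        self.min_r = float(min_r)
        self.reference = reference

    def fit(self) -> LagMap:
        vol = self.vol
        ref = self.reference or compute_reference(vol, self.gm_mask, self.lesion_mask)
        T = vol.n_frames
        W = self.max_shift
        gd = ref.g - ref.g.mean()

        shape = vol.grid_shape
        tau = np.full(shape, np.nan)
        peak = np.full(shape, np.nan)
        reason = np.full(shape, OUT_OF_MASK, dtype=np.int8)
        reason[self.gm_mask] = VALID
        reason[self.lesion_mask] = LESIONED

        analyze = self.gm_mask & ~self.lesion_mask
        S = vol.data[analyze]  # n_vox x T
        mean_s = S.mean(axis=1, keepdims=True)
        Sd = S - mean_s
        sigma_s = S.std(axis=1)
        shifts = np.arange(-W, W + 1)
        overlap = T - np.abs(shifts)
        C = np.zeros((S.shape[0], len(shifts)))
        with np.errstate(divide="ignore", invalid="ignore"):
            for k, t in enumerate(shifts):
                if t >= 0:
                    prod = Sd[:, t:] @ gd[: T - t]
                else:
                    prod = Sd[:, : T + t] @ gd[-t:]
                C[:, k] = prod / (overlap[k] * ref.sigma_g * sigma_s)

        novar = sigma_s == 0
        # ties toward smallest |shift|: scan shifts in null-first order
        order = np.lexsort((shifts, np.abs(shifts)))
        best = np.full(S.shape[0], order[0])
        best_val = C[:, order[0]].copy()
        for k in order[1:]:
            better = C[:, k] > best_val
            best[better] = k
            best_val[better] = C[better, k]

        at_edge = (best == 0) | (best == len(shifts) - 1)
        interior = ~at_edge & ~novar
        idx = np.flatnonzero(interior)
        c_m = C[idx, best[idx] - 1]
        c_0 = C[idx, best[idx]]
        c_p = C[idx, best[idx] + 1]
        denom = c_m - 2.0 * c_0 + c_p
        flat = np.abs(denom) < 1e-12
        offset = np.zeros_like(c_0)
        np.divide(0.5 * (c_m - c_p), denom, out=offset, where=~flat)
        tau_vox = (shifts[best[idx]] + offset) * vol.tr_s
        peak_vox = c_0 - 0.25 * (c_m - c_p) * offset

        vox_tau = np.full(S.shape[0], np.nan)
        vox_peak = np.full(S.shape[0], np.nan)
        vox_reason = np.zeros(S.shape[0], dtype=np.int8)
        vox_tau[idx] = tau_vox
        vox_peak[idx] = peak_vox  # kept for low-correlation voxels too
        vox_reason[novar] = NO_VARIANCE
        vox_reason[at_edge & ~novar] = EDGE
        low = np.zeros(S.shape[0], dtype=bool)
        low[idx] = peak_vox < self.min_r
        vox_reason[low] = LOW_CORRELATION
        vox_tau[vox_reason != VALID] = np.nan

        tau[analyze] = vox_tau
        peak[analyze] = vox_peak
        r = reason[analyze]
        r[:] = vox_reason
        reason[analyze] = r

        return LagMap(
            tau_s=tau,
            peak_r=peak,
            valid=reason == VALID,
            reason=reason,
            tr_s=vol.tr_s,
            affine=vol.affine,
            max_shift=W,
            min_r=self.min_r,
        )


def compute_lag_map(
    vol: TimeSeriesVolume,
    gm_mask: np.ndarray,
    lesion: np.ndarray | None = None,
    max_shift: int = 3,
    min_r: float = 0.1,
    reference: ReferenceSignal | None = None,
) -> LagMap:
    """Functional wrapper over :class:`HemodynamicLagModel`."""
    return HemodynamicLagModel(
        vol, gm_mask, lesion, max_shift=max_shift, min_r=min_r, reference=reference
    ).fit()


def group_lag_stats(
    lagmaps: list[LagMap],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel mean, SD (ddof=1) and count of valid lags across subjects."""
    if len(lagmaps) < 2:
        raise ValueError("need at least 2 lag maps")
    shape = lagmaps[0].tau_s.shape
    for lm in lagmaps[1:]:
        if lm.tau_s.shape != shape or not np.allclose(lm.affine, lagmaps[0].affine):
            raise ValueError("lag maps are not on a common grid")
    stack = np.stack([lm.tau_s for lm in lagmaps])
    valid = np.stack([lm.valid for lm in lagmaps])
    n = valid.sum(axis=0)
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vals = np.where(valid, stack, np.nan)
        mean = np.nanmean(np.where(n > 0, vals, np.nan), axis=0)
        sd = np.nanstd(np.where(n > 1, vals, np.nan), axis=0, ddof=1)
    mean[n == 0] = np.nan
    sd[n < 2] = np.nan
    return mean, sd, n
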