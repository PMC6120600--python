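"""Synthetic resting-state cohorts with known hemodynamic-lag ground truth.

Real patient volumes are not redistributable, so every downstream stage is
exercised on simulated cohorts: band-limited BOLD-like reference signals,
per-voxel planted temporal shifts (the quantity the lag estimator must
recover), ellipsoidal lesions, per-frame motion traces, and a behavioural
battery drawn from the published 21-task loading structure.

The simulation is purposely minimal.  Each intact voxel carries the shared
reference time course delayed by its planted lag (sub-sample delays applied
as frequency-domain phase shifts, which are exact for these band-limited,
periodically-generated signals) plus white Gaussian noise; lesioned voxels
carry pure noise.  There is no haemodynamic response function model, no
vascular anatomy and no multi-echo T2* physics — the generator plants the
quantities the pipeline estimates, nothing more.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import FACTOR_NAMES, TASK_NAMES, battery_loadings
from .volume import TimeSeriesVolume

__all__ = [
    "CohortSpec",
    "Region",
    "LesionSpec",
    "SyntheticCohort",
    "make_reference_signal",
    "make_subject_volume",
    "make_behavioral_cohort",
    "simulate_cohort",
]


class InvalidBandError(ValueError):
    """Band edges outside (0, Nyquist) or inverted."""


class LagOutOfRangeError(ValueError):
    """A planted lag exceeds the cross-correlation search window."""


def _check_band(band_hz: tuple[float, float], tr_s: float) -> None:
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 < low < high < nyquist):
        raise InvalidBandError(
            f"band {band_hz} Hz must satisfy 0 < low < high < Nyquist ({nyquist:.4f} Hz)"
        )


def make_reference_signal(
    n_frames: int,
    tr_s: float,
    band_hz: tuple[float, float] = (0.01, 0.08),
    seed: int | np.random.SeedSequence = 0,
) -> np.ndarray:
    """Zero-mean, unit-SD band-limited Gaussian signal of length ``n_frames``.

    Built by masking the rFFT of white Gaussian noise to the band, so all
    spectral power lies inside ``band_hz`` by construction.
    """
    _check_band(band_hz, tr_s)
    if n_frames < 16:
        raise ValueError(f"n_frames must be >= 16, got {n_frames}")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_frames)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_frames, d=tr_s)
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise InvalidBandError(
            f"no Fourier bins inside {band_hz} Hz at n={n_frames}, TR={tr_s}s"
        )
    spec[~in_band] = 0.0
    sig = np.fft.irfft(spec, n=n_frames)
    sig -= sig.mean()
    sd = sig.std()
    if sd == 0:
        raise InvalidBandError("degenerate band produced a constant signal")
    return sig / sd


def delay_signal(sig: np.ndarray, lag_s: float | np.ndarray, tr_s: float) -> np.ndarray:
    """Delay ``sig`` by ``lag_s`` seconds via a frequency-domain phase shift.

    Positive lag means the returned series is a *later* copy of ``sig``
    (content arrives ``lag_s`` after the original).  The shift is circular,
    which is exact for signals synthesized as periodic band-limited noise.
    Vectorized: ``lag_s`` may be an array, giving one delayed copy per entry
    with shape ``lag_s.shape + (len(sig),)``.
    """
    n = len(sig)
    spec = np.fft.rfft(sig)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    lags = np.asarray(lag_s, dtype=float)
    phase = np.exp(-2j * np.pi * freqs * lags[..., None])
    return np.fft.irfft(phase * spec, n=n)


def make_subject_volume(
    ref: np.ndarray,
    lag_field: np.ndarray,
    lesion: np.ndarray,
    noise_sd: float,
    tr_s: float,
    seed: int | np.random.SeedSequence = 0,
    affine: np.ndarray | None = None,
    max_lag_s: float | None = None,
    signal_mask: np.ndarray | None = None,
) -> TimeSeriesVolume:
    """Assemble one subject's 4D volume from planted per-voxel lags.

    Intact voxels carry ``ref`` delayed by ``lag_field`` (seconds) plus white
    noise of SD ``noise_sd``; lesioned voxels carry pure noise of the same SD.

    Parameters
    ----------
    lag_field : ndarray, 3D
        Planted lag in seconds per voxel; must be finite outside the lesion.
    max_lag_s : float, optional
        Search-window bound; lags beyond it raise :class:`LagOutOfRangeError`.
        Defaults to 3 frames times ``tr_s``.
    signal_mask : 3D mask, optional
        Voxels carrying the BOLD-like signal (e.g. grey matter); everything
        outside it — CSF, background — is pure noise, so nuisance signals
        extracted there do not contain the reference time course.  Default:
        all voxels.
    """
    lag_field = np.asarray(lag_field, dtype=float)
    lesion = np.asarray(lesion, dtype=bool)
    if lag_field.ndim != 3 or lesion.shape != lag_field.shape:
        raise ValueError("lag_field must be 3D and match the lesion mask grid")
    intact = ~lesion
    if signal_mask is not None:
        intact &= np.asarray(signal_mask, dtype=bool)
    if not np.isfinite(lag_field[intact]).all():
        raise ValueError("lag_field must be finite at every intact voxel")
    if max_lag_s is None:
        max_lag_s = 3 * tr_s
    if np.abs(lag_field[intact]).max(initial=0.0) > max_lag_s + 1e-12:
        raise LagOutOfRangeError(
            f"planted |lag| exceeds the {max_lag_s:.2f}s search window"
        )

    n_frames = len(ref)
    rng = np.random.default_rng(seed)
    data = np.empty(lag_field.shape + (n_frames,), dtype=float)
    flat = data.reshape(-1, n_frames)
    intact_flat = intact.ravel()
    flat[intact_flat] = delay_signal(ref, lag_field.ravel()[intact_flat], tr_s)
    flat[~intact_flat] = 0.0
    if noise_sd > 0:
        flat += rng.normal(0.0, noise_sd, size=flat.shape)
    if affine is None:
        affine = np.eye(4)
    return TimeSeriesVolume(data=data, tr_s=tr_s, affine=affine)


def make_behavioral_cohort(
    n_patients: int,
    loadings: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    factor_scores: np.ndarray | None = None,
    standardize: bool = True,
    task_names: list[str] | None = None,
) -> pd.DataFrame:
    """Draw a patients x tasks score table from a factor-loading structure.

    Scores follow the common-factor data model ``X = F L' + E`` with
    orthonormal standard-normal factor draws ``F`` and independent per-task
    residuals of variance ``1 - communality``, so the population correlation
    matrix of the tasks is ``L L' + diag(1 - h^2)``.

    Parameters
    ----------
    loadings : (n_tasks, k) array, optional
        Defaults to the published 21-task battery loading matrix.
    factor_scores : (n_patients, k) array, optional
        Use these factor draws instead of sampling them (links behaviour to
        other planted quantities in a cohort simulation).
    standardize : bool
        Z-score each task column of the returned table (default).
    """
    if loadings is None:
        loadings = battery_loadings()
        task_names = task_names or list(TASK_NAMES)
    loadings = np.asarray(loadings, dtype=float)
    communality = (loadings**2).sum(axis=1)
    if (communality > 1.0 + 1e-9).any():
        raise ValueError(
            f"row communalities must be <= 1, max is {communality.max():.4f}"
        )
    rng = np.random.default_rng(seed)
    n_tasks, k = loadings.shape
    if factor_scores is None:
        factor_scores = rng.standard_normal((n_patients, k))
    else:
        factor_scores = np.asarray(factor_scores, dtype=float)
        if factor_scores.shape != (n_patients, k):
            raise ValueError("factor_scores must be (n_patients, k)")
    resid_sd = np.sqrt(np.clip(1.0 - communality, 0.0, None))
    scores = factor_scores @ loadings.T + rng.standard_normal((n_patients, n_tasks)) * resid_sd
    if standardize:
        scores = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    if task_names is None:
        task_names = [f"task_{i + 1:02d}" for i in range(n_tasks)]
    return pd.DataFrame(
        scores,
        index=pd.RangeIndex(1, n_patients + 1, name="patient_id"),
        columns=task_names,
    )


@dataclass
class Region:
    """Ellipsoidal (or box) region in voxel space carrying a planted lag."""

    center_vox: tuple[float, float, float]
    radii_vox: tuple[float, float, float]
    lag_s: float
    shape: str = "ellipsoid"  # or "box"
    name: str = ""

    def mask(self, grid_dims: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(grid_dims, dtype=float)
        rel = [
            (idx[a] - self.center_vox[a]) / max(self.radii_vox[a], 1e-9)
            for a in range(3)
        ]
        if self.shape == "box":
            return (np.abs(rel[0]) <= 1) & (np.abs(rel[1]) <= 1) & (np.abs(rel[2]) <= 1)
        return rel[0] ** 2 + rel[1] ** 2 + rel[2] ** 2 <= 1.0


@dataclass
class LesionSpec:
    """Per-patient ellipsoidal lesion geometry, drawn per subject.

    Centers are drawn uniformly in a sub-box of the grid (fractional
    coordinates) emulating a single vascular territory, so lesion overlap
    across patients is concentrated and the coverage-mask rules bite.
    """

    center_frac_low: tuple[float, float, float] = (0.15, 0.30, 0.30)
    center_frac_high: tuple[float, float, float] = (0.45, 0.70, 0.70)
    radii_vox_low: tuple[float, float, float] = (2.0, 2.0, 2.0)
    radii_vox_high: tuple[float, float, float] = (5.0, 5.0, 5.0)

    def draw(self, grid_dims: tuple[int, int, int], rng: np.random.Generator) -> Region:
        lo = np.asarray(self.center_frac_low) * np.asarray(grid_dims)
        hi = np.asarray(self.center_frac_high) * np.asarray(grid_dims)
        center = rng.uniform(lo, hi)
        radii = rng.uniform(self.radii_vox_low, self.radii_vox_high)
        return Region(tuple(center), tuple(radii), lag_s=0.0, name="lesion")


def _default_regions() -> list[Region]:
    # three planted-lag territories inside the default 24^3 grey-matter ball
    return [
        Region((7.0, 12.0, 12.0), (3.0, 4.0, 4.0), lag_s=2.8, name="delay"),
        Region((17.0, 12.0, 12.0), (3.0, 4.0, 4.0), lag_s=-2.8, name="advance"),
        Region((12.0, 7.0, 15.0), (3.0, 3.0, 3.0), lag_s=1.4, name="mild_delay"),
    ]


@dataclass
class CohortSpec:
    """Full description of a simulated cohort; fixed seed => identical cohort.

    Defaults mirror the study conditions: TR 2.8 s, 130 acquired frames
    (two discarded downstream), 0.01-0.08 Hz band, a +/-3-frame (8.4 s)
    lag window, 35 imaging patients drawn from a 66-patient behavioural
    cohort, on a desk-scale 24^3 grid at 3 mm.
    """

    n_patients: int = 35
    n_behavioral: int = 66
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    tr_s: float = 2.8
    n_frames: int = 130
    band_hz: tuple[float, float] = (0.01, 0.08)
    window_frames: int = 3
    lag_field_spec: list[Region] = field(default_factory=_default_regions)
    lesion_spec: LesionSpec = field(default_factory=LesionSpec)
    # (region index, factor index, slope seconds per factor-SD)
    coupling_spec: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(0, 0, 0.7), (1, 3, -0.7)]
    )
    lag_jitter_sd: float = 0.7
    noise_sd: float = 1.0
    loadings: np.ndarray = field(default_factory=battery_loadings)
    seed: int = 0

    def __post_init__(self) -> None:
        _check_band(self.band_hz, self.tr_s)
        if self.n_frames < 16:
            raise ValueError("n_frames must be >= 16")
        window_s = self.window_frames * self.tr_s
        for reg in self.lag_field_spec:
            if abs(reg.lag_s) > window_s:
                raise LagOutOfRangeError(
                    f"region lag {reg.lag_s}s beyond +/-{window_s}s window"
                )
        if self.n_behavioral < self.n_patients:
            raise ValueError("behavioural cohort must include the imaging subset")

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        # center the grid on the world origin
        aff[:3, 3] = -0.5 * np.asarray(self.voxel_size_mm) * (np.asarray(self.grid_dims) - 1)
        return aff


class SyntheticCohort:
    """Materialized cohort: masks, planted truth, behaviour and volumes.

    Volumes are synthesized on demand (``subject_volume``) so a 35-patient
    cohort does not need all 4D arrays in memory at once; generation is
    deterministic per (spec.seed, subject index).
    """

    def __init__(self, spec: CohortSpec):
        self.spec = spec
        root = np.random.SeedSequence(spec.seed)
        (self._ss_ref, self._ss_lesion, self._ss_behav, self._ss_jitter,
         self._ss_motion, self._ss_noise) = root.spawn(6)

        dims = spec.grid_dims
        center = (np.asarray(dims) - 1) / 2.0
        radius = 0.42 * min(dims)
        brain = Region(tuple(center), (radius,) * 3, 0.0).mask(dims)
        ventricle = Region(tuple(center), (0.08 * min(dims) + 1,) * 3, 0.0).mask(dims)
        self.gm_mask = brain & ~ventricle
        self.csf_mask = ventricle

        self.region_masks = [r.mask(dims) & self.gm_mask for r in spec.lag_field_spec]
        self.region_labels = np.zeros(dims, dtype=int)
        for i, m in enumerate(self.region_masks):
            self.region_labels[m] = i + 1

        rng_les = np.random.default_rng(self._ss_lesion)
        self.lesions = np.stack(
            [spec.lesion_spec.draw(dims, rng_les).mask(dims) for _ in range(spec.n_patients)]
        )

        # behavioural cohort (imaging subset = first n_patients rows)
        rng_b = np.random.default_rng(self._ss_behav)
        k = spec.loadings.shape[1]
        self.factor_truth = rng_b.standard_normal((spec.n_behavioral, k))
        self.behavior = make_behavioral_cohort(
            spec.n_behavioral,
            spec.loadings,
            seed=self._ss_behav.spawn(1)[0],
            factor_scores=self.factor_truth,
            task_names=list(TASK_NAMES) if spec.loadings.shape[0] == len(TASK_NAMES) else None,
        )

        # planted per-patient lag fields: region base + coupling + jitter
        rng_j = np.random.default_rng(self._ss_jitter)
        window_s = spec.window_frames * spec.tr_s
        fields = np.zeros((spec.n_patients,) + dims)
        for p in range(spec.n_patients):
            for i, reg in enumerate(spec.lag_field_spec):
                lag = reg.lag_s + rng_j.normal(0.0, spec.lag_jitter_sd)
                for r_i, f_i, slope in spec.coupling_spec:
                    if r_i == i:
                        lag += slope * self.factor_truth[p, f_i]
                fields[p][self.region_masks[i]] = lag
            np.clip(fields[p], -window_s, window_s, out=fields[p])
        self.lag_truth = fields

        self.reference = make_reference_signal(
            spec.n_frames, spec.tr_s, spec.band_hz, seed=self._ss_ref
        )
        self._noise_seeds = self._ss_noise.spawn(2 * spec.n_patients)
        self._motion_seeds = self._ss_motion.spawn(spec.n_patients)

    @property
    def factor_scores_imaging(self) -> np.ndarray:
        """Planted factor scores of the imaging subset (n_patients x k)."""
        return self.factor_truth[: self.spec.n_patients]

    def true_coupling_r(self, region_index: int, factor_index: int) -> float:
        """Population correlation between planted lag and factor score."""
        slope = sum(
            s for r_i, f_i, s in self.spec.coupling_spec
            if r_i == region_index and f_i == factor_index
        )
        denom = np.sqrt(slope**2 + self.spec.lag_jitter_sd**2)
        return 0.0 if denom == 0 else slope / denom

    def subject_volume(self, index: int, noise_sd: float | None = None) -> TimeSeriesVolume:
        spec = self.spec
        return make_subject_volume(
            self.reference,
            self.lag_truth[index],
            self.lesions[index],
            noise_sd=spec.noise_sd if noise_sd is None else noise_sd,
            tr_s=spec.tr_s,
            seed=self._noise_seeds[2 * index],
            affine=spec.affine,
            max_lag_s=spec.window_frames * spec.tr_s,
            signal_mask=self.gm_mask,
        )

    def subject_echoes(self, index: int) -> tuple[TimeSeriesVolume, TimeSeriesVolume]:
        """Two echo volumes whose frame-wise average has SD ``noise_sd`` noise."""
        spec = self.spec
        sd = spec.noise_sd * np.sqrt(2.0)
        echoes = []
        for j in range(2):
            echoes.append(
                make_subject_volume(
                    self.reference,
                    self.lag_truth[index],
                    self.lesions[index],
                    noise_sd=sd,
                    tr_s=spec.tr_s,
                    seed=self._noise_seeds[2 * index + j],
                    affine=spec.affine,
                    max_lag_s=spec.window_frames * spec.tr_s,
                    signal_mask=self.gm_mask,
                )
            )
        return echoes[0], echoes[1]

    def subject_motion(self, index: int, spike_frames: int = 1,
                       spike_mm: float = 1.5) -> pd.DataFrame:
        """Six-column motion trace: slow random walk plus rare >1 mm jumps."""
        spec = self.spec
        rng = np.random.default_rng(self._motion_seeds[index])
        steps = rng.normal(0.0, [0.05] * 3 + [0.001] * 3, size=(spec.n_frames, 6))
        motion = np.cumsum(steps, axis=0)
        if spike_frames:
            frames = rng.choice(np.arange(4, spec.n_frames - 1), size=spike_frames,
                                replace=False)
            axes = rng.integers(0, 3, size=spike_frames)
            for t, a in zip(frames, axes):
                motion[t:, a] += spike_mm * rng.choice([-1.0, 1.0])
        return pd.DataFrame(
            motion, columns=["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]
        )


def simulate_cohort(spec: CohortSpec | None = None, **kwargs) -> SyntheticCohort:
    """Build a :class:`SyntheticCohort`; kwargs override :class:`CohortSpec` fields."""
    if spec is None:
        spec = CohortSpec(**kwargs)
    elif kwargs:
        raise TypeError("pass either a CohortSpec or keyword overrides, not both")
    return SyntheticCohort(spec)
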