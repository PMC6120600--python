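"""Pipeline configuration: every threshold in one serializable place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All inputs, thresholds and the seed for one pipeline run.

    With no input paths the pipeline simulates a synthetic cohort; with
    paths it ingests NIfTI volumes/masks and TSV tables instead.  Every
    threshold default is the analysis convention the pipeline is built
    around (TR 2.8 s, discard 2 of 130 frames, 0.01-0.08 Hz band,
    +/-3-frame lag window, r >= 0.1 validity, >=15 intact patients,
    <=20 damaged patients per voxel, +/-3 SD outlier cuts).
    """

    output_dir: str = "hemolag_out"
    seed: int = 0

    # --- inputs (None => synthesize) ---
    volume_paths: list[str] | None = None
    gm_mask_path: str | None = None
    csf_mask_path: str | None = None
    lesion_mask_paths: list[str] | None = None
    motion_paths: list[str] | None = None
    behavior_table_path: str | None = None
    tr_s: float | None = None  # overrides NIfTI header TR

    # --- synthetic cohort ---
    n_patients: int = 35
    n_behavioral: int = 66
    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_frames: int = 130
    noise_sd: float = 1.0

    # --- preprocessing ---
    n_discard: int = 2
    z_thresh: float = 2.5
    move_thresh_mm: float = 1.0
    band_hz: tuple[float, float] = (0.01, 0.08)

    # --- lag estimation ---
    max_shift: int = 3
    min_r: float = 0.1

    # --- behaviour ---
    eig_threshold: float = 1.0
    outlier_sd: float = 3.0

    # --- correlation mapping ---
    min_n: int = 15
    max_damaged: int = 20
    lag_sd_k: float = 3.0

    # --- cluster correction ---
    voxel_p: float = 0.01
    corrected_p: float = 0.01
    fwhm_mm: float = 0.0
    n_iter: int = 1000
    connectivity: int = 18
    fdr_q: float = 0.05
    fdr_min_cluster: int = 50

    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid_dims = tuple(self.grid_dims)
        self.voxel_size_mm = tuple(self.voxel_size_mm)
        self.band_hz = tuple(self.band_hz)
        checks = [
            (self.n_discard >= 0, "n_discard >= 0"),
            (self.max_shift >= 1, "max_shift >= 1"),
            (0 <= self.min_r < 1, "min_r in [0, 1)"),
            (self.min_n >= 2, "min_n >= 2"),
            (self.max_damaged >= 0, "max_damaged >= 0"),
            (self.lag_sd_k > 0, "lag_sd_k > 0"),
            (self.outlier_sd > 0, "outlier_sd > 0"),
            (0 < self.voxel_p < 1, "voxel_p in (0, 1)"),
            (0 < self.corrected_p < 1, "corrected_p in (0, 1)"),
            (0 < self.fdr_q < 1, "fdr_q in (0, 1)"),
            (self.connectivity in (6, 18, 26), "connectivity in {6, 18, 26}"),
            (0 < self.band_hz[0] < self.band_hz[1], "band low < high"),
            (self.n_iter >= 1, "n_iter >= 1"),
            (self.noise_sd >= 0, "noise_sd >= 0"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError("invalid config: " + "; ".join(bad))

    @property
    def synthetic(self) -> bool:
        return self.volume_paths is None

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls(**json.loads(text))
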