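"""Pipeline-wide configuration with JSON round-trip support.

Defaults encode the acquisition and analysis constants of the method: a pixel
pitch of 1.06 um at the 10x objective / 0.63x coupling used for tissue
microarray imaging, a 10-50 um spatial scale window for the box-count
regression, a minimum stained fraction of one half for core evaluability, a
10-year survival horizon, and an even 50/50 split for cross-validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional


@dataclass
class PipelineConfig:
    calibration: float = 1.06  # microns per pixel
    scale_window: tuple[float, float] = (10.0, 50.0)  # microns
    n_thresholds: int = 64
    min_stained_fraction: float = 0.5
    min_outline_pixels: int = 100
    quantile_convention: str = "linear"
    cox_ties: str = "efron"
    horizon_years: float = 10.0
    cv_split: float = 0.5
    seed: int = 0
    stain_threshold: Optional[float] = None  # None -> Otsu on the corrected image
    invert_without_blank: bool = True
    box_ratio: float = 1.25

    def __post_init__(self) -> None:
        self.scale_window = tuple(self.scale_window)  # type: ignore[assignment]
        if self.calibration <= 0:
            raise ValueError("calibration must be positive")
        if not 0 < self.scale_window[0] < self.scale_window[1]:
            raise ValueError("scale_window must be an increasing positive pair")
        if not 0 < self.cv_split < 1:
            raise ValueError("cv_split must lie in (0, 1)")
        if self.cox_ties not in ("efron", "breslow"):
            raise ValueError("cox_ties must be 'efron' or 'breslow'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
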