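"""Whole-pipeline configuration, serializable to plain-text YAML."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .events import EventDetectionParams
from .ringtiming import PhaseTimingParams
from .segmentation import SegmentationParams
from .tracking import TrackingParams

__all__ = ["AnalysisConfig"]


@dataclass(frozen=True)
class AnalysisConfig:
    """All tunable pipeline parameters plus seed and output directory.

    Every block validates its own numeric ranges on construction, so a
    config loaded from file is checked field by field.
    """

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    events: EventDetectionParams = field(default_factory=EventDetectionParams)
    phases: PhaseTimingParams = field(default_factory=PhaseTimingParams)
    seed: int = 0
    out_dir: str = "."

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(
            segmentation=SegmentationParams(**raw.get("segmentation", {})),
            tracking=TrackingParams(**raw.get("tracking", {})),
            events=EventDetectionParams(**raw.get("events", {})),
            phases=PhaseTimingParams(**raw.get("phases", {})),
            seed=int(raw.get("seed", 0)),
            out_dir=str(raw.get("out_dir", ".")),
        )
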