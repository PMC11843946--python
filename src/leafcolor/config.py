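"""Run configuration: one dataclass holding every tunable of the pipeline,
round-tripping losslessly through YAML, with a stable content hash stamped
into output files for provenance."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .curvefit import FAMILIES
from .imaging import SegmentationConfig


@dataclass(frozen=True)
class RunConfig:
    min_pixels: int = 5000
    background_value_floor: float = 0.65
    closing_size: int = 3
    closing_iterations: int = 2
    table1_literal: bool = False
    fit_families: tuple[str, ...] = FAMILIES
    elbow_method: str = "ede_knee"
    refine_nonlinear: bool = False
    seed: int = 0
    log_level: str = "INFO"
    # documented acquisition defaults of the reference rig (metadata only)
    camera_distance_cm: float = 50.0
    exposure_s: float = 1.0 / 100.0
    iso: int = 200

    def segmentation(self) -> SegmentationConfig:
        return SegmentationConfig(
            min_pixels=self.min_pixels,
            background_value_floor=self.background_value_floor,
            closing_size=self.closing_size,
            closing_iterations=self.closing_iterations,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "fit_families" in data:
            data["fit_families"] = tuple(data["fit_families"])
        return cls(**data)

    def content_hash(self) -> str:
        blob = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def provenance_line(self) -> str:
        return f"# leafcolor {__version__} config_hash={self.content_hash()}\n"
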