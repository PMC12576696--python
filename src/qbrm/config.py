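"""Strict pipeline configuration and run manifests.

The config is a nested schema covering every stage default; unknown keys
are rejected before any stage runs, and the effective config is echoed
verbatim into the run manifest so every output is traceable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

CONFIG_VERSION = 1

__all__ = ["PipelineConfig", "RunManifest", "load_config"]


@dataclass
class SimulateSection:
    height_px: int = 384
    width_px: int = 384
    pixel_size_um: float = 1.0
    fiber_orientation_deg: float = 0.0
    fiber_orientation_jitter_deg: float = 6.0
    fiber_density: float = 0.3
    debris_diameter_um_range: tuple[float, float] = (1.0, 10.0)
    noise_sd_frac: float = 0.02
    illumination_angles_deg: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)


@dataclass
class SimulateConfig:
    groups: list[tuple[str, int, float, float]] = field(
        default_factory=lambda: [
            ("6wk", 4, 40.0, 0.3),
            ("12wk", 4, 8.0, 0.3),
            ("control", 3, 5.0, 0.3),
        ]
    )
    sections_per_animal: int = 10
    section_spacing_um: float = 600.0
    profile_peak_um: float = 0.0
    profile_fwhm_um: float = 1800.0
    peak_jitter_um: float = 300.0
    baseline_density_per_mm2: float = 1.0
    section: SimulateSection = field(default_factory=SimulateSection)


@dataclass
class ReconstructConfig:
    retardance_floor: float = 0.01


@dataclass
class DetectConfig:
    tile_px: int = 128
    overlap_frac: float = 0.5
    tta: bool = False
    nms_iou: float = 0.5
    confidence_thr: float = 0.25
    train_sections: int = 8
    train_debris_density_per_mm2: float = 60.0


@dataclass
class StatsConfig:
    alpha: float = 0.01
    match_iou: float = 0.3


@dataclass
class PipelineConfig:
    version: int = CONFIG_VERSION
    seed: int = 0
    out_dir: str = "qbrm_run"
    log_level: str = "INFO"
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    reconstruct: ReconstructConfig = field(default_factory=ReconstructConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _from_dict(cls, data: dict, path: str = ""):
    """Instantiate a (possibly nested) dataclass, rejecting unknown keys."""
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        default = fields[name].default_factory() if fields[name].default_factory is not dataclasses.MISSING else None  # type: ignore[misc]
        if dataclasses.is_dataclass(default):
            kwargs[name] = _from_dict(type(default), value, f"{path}{name}.")
        elif name == "groups":
            kwargs[name] = [tuple(g) for g in value]
        elif isinstance(value, list) and "tuple" in str(ftype):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(source: str | Path | dict) -> PipelineConfig:
    """Load and strictly validate a pipeline config from YAML/JSON/dict."""
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = dict(source)
    cfg = _from_dict(PipelineConfig, data)
    if cfg.version != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {cfg.version}")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Trace of one pipeline run: config echo, stage records, warnings."""

    config: dict
    software_version: str
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record_stage(
        self,
        name: str,
        inputs: list[Path] | None = None,
        outputs: list[Path] | None = None,
        status: str = "ok",
        detail: str = "",
    ) -> None:
        self.stages.append(
            {
                "stage": name,
                "status": status,
                "detail": detail,
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
                "inputs": {str(p): _sha256(Path(p)) for p in (inputs or []) if Path(p).exists()},
                "outputs": {str(p): _sha256(Path(p)) for p in (outputs or []) if Path(p).exists()},
            }
        )

    def write(self, path: str | Path) -> Path:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=1, default=str)
        )
        return Path(path)
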