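"""Run configuration: YAML round-trip and provenance hashing.

One flat YAML file drives a whole synthetic experiment, with one section
per pipeline stage (``geometry``, ``phantom``, ``detector``, ``windows``,
``recon``, ``analysis``) plus a ``seed`` and an ``out_dir``. Keys are the
dataclass field names verbatim. Every output sidecar embeds the SHA-256
hash of the canonical config so artifacts can be traced to the exact
configuration that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .acquisition import DetectorModel
from .geometry import ScanGeometry
from .phantom import DissolutionModel, PhantomState


class ConfigError(ValueError):
    """Raised for malformed configuration input (CLI exit code 2)."""


@dataclass(frozen=True)
class WindowConfig:
    n_window: int = 501
    stride: int = 500
    fine_stride: int | None = 250  # optional overlapping enumeration


@dataclass(frozen=True)
class ReconConfig:
    filter_name: str = "ramp"
    center_offset_px: float = 0.0
    slice_index: int = 0


@dataclass(frozen=True)
class AnalysisConfig:
    # largest-component keeps only the contiguous lesion blob: isolated
    # noise pixels above threshold otherwise bias the volume upward in
    # proportion to the (large) area outside the lesion
    threshold_rule: str = "otsu-final"
    largest_component: bool = True


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to rerun one synthetic fly-scan experiment."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    phantom: PhantomState = field(default_factory=PhantomState)
    detector: DetectorModel = field(default_factory=DetectorModel)
    windows: WindowConfig = field(default_factory=WindowConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    out_dir: str = "flytomo_out"

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["geometry"]["detector_shape"] = list(self.geometry.detector_shape)
        d["phantom"]["grid_shape"] = list(self.phantom.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        try:
            d = dict(d)
            phantom_d = dict(d.get("phantom", {}))
            if "dissolution" in phantom_d:
                phantom_d["dissolution"] = DissolutionModel(**phantom_d["dissolution"])
            if "grid_shape" in phantom_d:
                phantom_d["grid_shape"] = tuple(phantom_d["grid_shape"])
            return cls(
                geometry=ScanGeometry.from_dict(d.get("geometry", {})),
                phantom=PhantomState(**phantom_d),
                detector=DetectorModel(**d.get("detector", {})),
                windows=WindowConfig(**d.get("windows", {})),
                recon=ReconConfig(**d.get("recon", {})),
                analysis=AnalysisConfig(**d.get("analysis", {})),
                seed=int(d.get("seed", 0)),
                out_dir=str(d.get("out_dir", "flytomo_out")),
            )
        except (TypeError, ValueError) as e:
            raise ConfigError(str(e)) from e

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        with open(p) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {p} does not hold a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        """SHA-256 over the canonical JSON form (provenance key)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def demo_config(seed: int = 0, out_dir: str = "flytomo_demo") -> RunConfig:
    """Desk-scale default experiment.

    The full-scale acquisition (15 001 frames at 0.072 deg, 2501-frame
    windows) is scaled down with the identical fence-post arithmetic:
    3001 frames at 0.36 deg — six disjoint 501-frame/180-deg windows —
    on a 160-px detector, so every index/angle/window relation is
    exercised at a size that reconstructs in seconds.
    """
    n_det = 160
    geometry = ScanGeometry(
        angular_step_deg=0.36,
        exposure_s=0.5,
        overhead_s=0.0,
        n_projections=3001,
        detector_shape=(1, n_det),
        pixel_size_um=0.78,
        magnification=10.0,
        n_dark=20,
        n_flat=20,
    )
    phantom = PhantomState(grid_shape=(n_det, n_det), voxel_size_um=0.78)
    return RunConfig(
        geometry=geometry,
        phantom=phantom,
        detector=DetectorModel(),
        windows=WindowConfig(n_window=501, stride=500, fine_stride=250),
        seed=seed,
        out_dir=out_dir,
    )
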