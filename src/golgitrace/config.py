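"""Pipeline configuration with named imaging presets.

Two presets bundle the spacing and thresholds appropriate to the two
supported contrast regimes: ``fmost`` (anisotropic 1 × 1 × 2.5 μm voxels,
8-bit threshold 220) and ``microct`` (0.65 μm isotropic, threshold 40).
Every field can be overridden individually; configs round-trip through
plain YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "PRESETS"]


@dataclass(frozen=True)
class PipelineConfig:
    spacing: tuple[float, float, float] = (2.5, 1.0, 1.0)  # (dz, dy, dx) μm
    polarity: str = "bright"
    threshold: float = 220.0          # denoising intensity threshold
    min_volume: float = 1000.0        # μm³ component-volume floor
    connectivity: int = 26
    snap_radius: float = 5.0          # μm soma-seed snapping
    lambda_: float = 10.0             # trace cost steepness
    gamma: float = 2.0                # trace cost exponent
    cap_factor: float = 10.0          # trace cost cap multiplier
    sholl_step: float = 10.0          # μm between Sholl spheres
    prune_um: float = 3.0             # skeleton spur pruning
    resample_um: float = 2.0          # SWC node arc spacing
    rng_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be positive")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")
        if self.min_volume < 0:
            raise ValueError("min_volume must be >= 0")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.snap_radius < 0 or self.sholl_step <= 0 or self.prune_um < 0:
            raise ValueError("invalid geometric parameter")
        if self.lambda_ <= 0 or self.gamma < 1:
            raise ValueError("invalid trace cost parameters")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["spacing"] = list(self.spacing)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "spacing" in d:
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def override(self, **kwargs) -> "PipelineConfig":
        kwargs = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **kwargs)


PRESETS: dict[str, PipelineConfig] = {
    "fmost": PipelineConfig(spacing=(2.5, 1.0, 1.0), threshold=220.0),
    "microct": PipelineConfig(spacing=(0.65, 0.65, 0.65), threshold=40.0),
}
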