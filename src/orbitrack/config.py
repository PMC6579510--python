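"""Run configuration: grouped parameters, YAML round-trip, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .psf import PSFModel
from .tracking import OrbitConfig

__all__ = ["SegmentationConfig", "WidefieldConfig", "RunConfig"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the angle-autocorrelation segmentation."""

    window: int = 64
    tau_interval: tuple = (0.03, 0.06)
    mode: str = "cosine"
    smooth: int = 5
    n_shuffles: int = 10
    min_active_duration: float = 0.15


@dataclass(frozen=True)
class WidefieldConfig:
    """Parameters of the wide-field colocalization analysis."""

    lag: int = 10
    smooth: int = 5
    n_sigma: float = 5.0
    corridor_half_extent: tuple = (25, 5)
    capture: float = 500.0
    pixel_size: float = 135.0
    psf_sigma: float = 200.0
    bin_size: float = 100.0
    slow_threshold: float = 10.0


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    return cls(**kwargs)


@dataclass
class RunConfig:
    """Full configuration of a simulate/track/segment/colocalize run.

    Every stochastic stage derives its generator from ``seed``; serializing
    and re-parsing a config is the identity, and ``config_hash`` gives a
    stable provenance fingerprint for output headers.
    """

    psf: PSFModel = field(default_factory=PSFModel)
    orbit: OrbitConfig = field(default_factory=OrbitConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    widefield: WidefieldConfig = field(default_factory=WidefieldConfig)
    seed: int = 0
    duration: float = 60.0

    def to_dict(self) -> dict:
        return {
            "psf": asdict(self.psf),
            "orbit": asdict(self.orbit),
            "segmentation": asdict(self.segmentation),
            "widefield": asdict(self.widefield),
            "seed": self.seed,
            "duration": self.duration,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        sections = {"psf": PSFModel, "orbit": OrbitConfig,
                    "segmentation": SegmentationConfig, "widefield": WidefieldConfig}
        unknown = set(data) - set(sections) - {"seed", "duration"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {name: _build(c, data.get(name, {})) for name, c in sections.items()}
        return cls(seed=int(data.get("seed", 0)),
                   duration=float(data.get("duration", 60.0)), **kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
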