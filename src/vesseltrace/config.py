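"""Run configuration: one flat YAML mapping covering every tunable."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .seeds import SeedParams
from .tracer import TracerConfig
from .vesselness import VesselnessParams

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Aggregate configuration with the tuned defaults.

    beta1=1, beta2=16, rho=1.3, tau=0, min segment length 20 px and grid
    spacing 10 px are the tuned operating point; metric deltas default to
    5 px (reporting) and 2 px (coverage).
    """

    vesselness: VesselnessParams = field(default_factory=VesselnessParams)
    tracer: TracerConfig = field(default_factory=TracerConfig)
    seeds: SeedParams = field(default_factory=SeedParams)
    delta_report: float = 5.0
    delta_coverage: float = 2.0
    rng_seed: int = 0

    def to_flat(self) -> dict:
        flat: dict = {}
        for prefix, obj in (("vesselness", self.vesselness), ("tracer", self.tracer),
                            ("seeds", self.seeds)):
            for k, v in asdict(obj).items():
                if isinstance(v, tuple):
                    v = list(v)
                if isinstance(v, (np.floating, np.integer)):
                    v = v.item()
                flat[f"{prefix}.{k}"] = v
        flat["metrics.delta_report"] = self.delta_report
        flat["metrics.delta_coverage"] = self.delta_coverage
        flat["rng_seed"] = self.rng_seed
        return flat

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_flat(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        flat = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_flat(flat)

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        def collect(prefix, klass):
            kwargs = {}
            for key, value in flat.items():
                if key.startswith(prefix + "."):
                    name = key.split(".", 1)[1]
                    if isinstance(value, list):
                        value = tuple(value)
                    kwargs[name] = value
            return klass(**kwargs)

        return cls(
            vesselness=collect("vesselness", VesselnessParams),
            tracer=collect("tracer", TracerConfig),
            seeds=collect("seeds", SeedParams),
            delta_report=flat.get("metrics.delta_report", 5.0),
            delta_coverage=flat.get("metrics.delta_coverage", 2.0),
            rng_seed=flat.get("rng_seed", 0),
        )
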