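"""Run configuration and reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Any subset may be overridden from a YAML file; unknown keys are
    rejected so typos fail loudly.
    """

    # breath / HR editing
    clean_window_breaths: int = 30
    sd_multiplier: float = 2.0
    vo2_bin_s: int = 30
    hr_bin_s: int = 5
    symmetric_hr_criterion: bool = False
    # NIRS events (s from recording start)
    occlusion_start_s: float = 180.0
    cuff_release_s: float = 480.0
    # responder classification
    cv: float = 0.056
    hdi_mass: float = 0.89
    rope_fraction: float = 0.20
    rope_half_width: float | None = None
    error_multiplier: float = math.sqrt(2.0)
    # simulation
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls().__dict__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(out_dir, command: str, config: RunConfig, outputs: list[str]) -> None:
    """Drop a manifest sufficient to reproduce the run bit-identically."""
    import numpy
    import pandas
    import scipy

    from . import __version__

    manifest = {
        "command": command,
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": {
            "trainability": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "outputs": sorted(outputs),
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
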