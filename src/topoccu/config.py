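"""Pipeline configuration (YAML) and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["PipelineConfig", "load_config", "write_manifest"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, loadable from a single YAML file."""

    # paths
    records: str = "records.csv"
    deployments: str = "deployments.csv"
    dem: str = "dem.asc"
    landscape_units: str | None = None
    output_dir: str = "out"

    # terrain / covariates
    latitude: float = -33.6
    buffer_radius: float = 100.0
    class_counts: dict = field(default_factory=lambda: {"slope": 4, "ruggedness": 3, "solar": 4})
    transmittance: float = 0.75
    solar_step_minutes: float = 6.0

    # events / histories
    filter_threshold_minutes: float = 30.0
    occasion_length_days: int = 5
    inclusion_min_events: int = 5

    # model
    variables: list = field(default_factory=lambda: ["aspect", "ruggedness", "slope", "solar"])
    combined: bool = False
    prior_precision: float = 0.001
    community_layer: bool = False

    # mcmc
    chains: int = 3
    iterations: int = 100_000
    burnin: int = 50_000
    thin: int = 10
    seed: int = 1

    def validate(self) -> None:
        for name in ("buffer_radius", "filter_threshold_minutes", "occasion_length_days",
                     "chains", "iterations", "thin"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name} must be positive")
        if self.prior_precision <= 0:
            raise ValueError("prior_precision must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = PipelineConfig(**raw)
    cfg.validate()
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(config: PipelineConfig, out_dir: Path, inputs: list[str | Path]) -> Path:
    """Record config, seeds, versions, and input checksums beside the outputs."""
    manifest = {
        "written": datetime.now().isoformat(timespec="seconds"),
        "config": asdict(config),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {
            str(p): _sha256(Path(p)) for p in inputs if p and Path(p).exists()
        },
    }
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path
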