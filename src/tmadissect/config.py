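"""Run configuration: thresholds, bootstrap counts, seeds, and file paths."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml


@dataclass
class RunConfig:
    """All tunable knobs of a pipeline run.

    Defaults mirror the analysis protocol the package implements: an 85th
    percentile expression threshold, 50 µm tessellation circles, 500
    bootstraps at a 90% stability threshold for both selection screens,
    99th-percentile network thresholding, cell QC at >10 px and >=0.9
    quality, and a 5-year prediction horizon.
    """

    percentile_threshold: float = 85.0
    circle_diameter_um: float = 50.0
    center_spacing_um: Optional[float] = None  # None -> diameter / 10
    n_bootstraps: int = 500
    stability_threshold: float = 0.9
    network_percentile: float = 99.0
    network_bins: int = 40
    min_cell_size_px: float = 10.0
    min_quality: float = 0.9
    horizon_years: float = 5.0
    max_missing_fraction: float = 0.2
    n_eval_splits: int = 500
    intensities_raw: bool = False
    seed: int = 0
    cells_path: Optional[str] = None
    survival_path: Optional[str] = None
    panel: Optional[list] = None
    out_dir: str = "results"

    def __post_init__(self):
        if not 0 < self.percentile_threshold < 100:
            raise ValueError("percentile_threshold must be in (0, 100)")
        if not 0 <= self.network_percentile <= 100:
            raise ValueError("network_percentile must be in [0, 100]")
        if not 0 < self.stability_threshold <= 1:
            raise ValueError("stability_threshold must be in (0, 1]")
        if not 0 <= self.min_quality <= 1:
            raise ValueError("min_quality must be in [0, 1]")
        for name in ("circle_diameter_um", "horizon_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_bootstraps < 1 or self.n_eval_splits < 1:
            raise ValueError("bootstrap counts must be >= 1")

    @property
    def spacing_um(self) -> float:
        return self.center_spacing_um or self.circle_diameter_um / 10.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable short hash of the configuration (for output sidecars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML or JSON file (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    data = config.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, default=str) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))
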