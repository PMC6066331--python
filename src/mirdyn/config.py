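"""Pipeline configuration: every analysis threshold in one serializable place.

The defaults are the study conditions: the 30% maternal-share / density > 1 /
10 RPTS in >= 5 windows / 20% multimapper regression filters, the > 50 RPTS
expression cutoff and k = 4 for profile clustering, adjusted p < 0.01 for the
clustered-miRNA ANOVA, the 0.1 target-allele-frequency bin for avoidance, and
the FPKM > 0.1 expression filter for the population-genetics scan.  Configs
round-trip through YAML so a run manifest documents them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .dynamics import FilterThresholds

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    dataset_dir: str = "."
    out_dir: str = "results"
    seed: int = 0

    # stage toggles
    run_dynamics: bool = True
    run_popgen: bool = True

    # quantification / dynamics
    per_hour_change: bool = False          # z as raw difference (default) or per hour
    clustering_min_rpts: float = 50.0      # max-over-windows expression cutoff
    k_clusters: int = 4
    kmeans_restarts: int = 10
    cluster_min_mean_rpts: float = 5.0     # per-cluster chart preprocessing cutoff
    error_rate_min_level: float = 10.0
    anova_alpha: float = 0.01
    halflife_window_start: float | None = None
    halflife_window_end: float | None = None
    filters: FilterThresholds = field(default_factory=FilterThresholds)

    # population genetics
    avoidance_threshold: float = 0.1
    min_fpkm: float = 0.1
    ks_exact_max_product: int = 400

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("filters"), dict):
            d["filters"] = FilterThresholds(**d["filters"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def digest(self) -> str:
        """Stable hash of the full configuration, recorded in run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def halflife_range(self) -> tuple[float, float] | None:
        if self.halflife_window_start is None or self.halflife_window_end is None:
            return None
        return (self.halflife_window_start, self.halflife_window_end)
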