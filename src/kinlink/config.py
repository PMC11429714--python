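"""Run configuration: thresholds, filter sizes, seed, and input paths.

All procedural constants used downstream live here so a run is fully
described by one config file plus one seed.  Defaults are the values used
throughout the analysis: differential calling at |log2FC| >= 1.5 and
adjusted p <= 0.05, the top-25 kinase percentile filter, the top-3
interaction filter per phosphosite, a minimum overrepresentation
background of 3, and the Chronos essentiality cutoff of -0.5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .errors import ValidationError

#: Admissible transforms for the "min-max normalized adjusted P value"
#: weight entering regulation and activity scores.
P_WEIGHT_TRANSFORMS = ("neglog10", "raw", "one_minus")


@dataclass
class RunConfig:
    """Parameters governing a full pipeline run.

    Attributes
    ----------
    log2fc_min : float
        Minimum |log2 fold change| for a phosphosite to be called
        regulated (inclusive).
    adjp_max : float
        Maximum BH-adjusted p-value for a regulated call (inclusive).
    top_kinase_percentile_count : int
        Number of top-percentile kinases retained per phosphosite.
    top_interactions_per_site : int
        Number of kinase interactions retained per differential site.
    min_background : int
        Minimum number of background members a gene set needs to enter
        the overrepresentation test.
    chronos_essential_max : float
        Chronos dependency score at or below which a gene is essential.
    seed : int
        Root seed for every random operation downstream.
    p_weight_transform : str
        How adjusted p-values are transformed before min-max scaling
        ("neglog10" by default).
    pathway_fraction_percent : bool
        If True, the pathway-score coverage factor is expressed on a
        0-100 scale instead of 0-1.
    paths : dict
        Optional name -> file path mapping for the input tables.
    """

    log2fc_min: float = 1.5
    adjp_max: float = 0.05
    top_kinase_percentile_count: int = 25
    top_interactions_per_site: int = 3
    min_background: int = 3
    chronos_essential_max: float = -0.5
    seed: int = 0
    p_weight_transform: str = "neglog10"
    pathway_fraction_percent: bool = False
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.log2fc_min > 0:
            raise ValidationError(f"log2fc_min must be > 0, got {self.log2fc_min}")
        if not 0 < self.adjp_max <= 1:
            raise ValidationError(f"adjp_max must be in (0, 1], got {self.adjp_max}")
        for name in ("top_kinase_percentile_count", "top_interactions_per_site", "min_background"):
            value = getattr(self, name)
            if not (isinstance(value, int) and value >= 1):
                raise ValidationError(f"{name} must be an integer >= 1, got {value!r}")
        if not isinstance(self.seed, int):
            raise ValidationError(f"seed must be an integer, got {self.seed!r}")
        if self.p_weight_transform not in P_WEIGHT_TRANSFORMS:
            raise ValidationError(
                f"p_weight_transform must be one of {P_WEIGHT_TRANSFORMS}, "
                f"got {self.p_weight_transform!r}"
            )

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)
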