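"""Run configuration: every threshold and mode switch of the pipeline in one
serializable object. Defaults are the method's published operating points.
A resolved copy of the configuration is written alongside every pipeline
output so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .errors import ConfigError
from .stratify import DEFAULT_BANDS


@dataclass
class RunConfig:
    # input handling
    scale: str = "log2"                  # scale of the input matrix: raw | log2
    orientation: str = "genes_in_rows"
    pseudocount: float = 1.0            # used when scale == raw
    degenerate: str = "error"           # min-max on all-equal values: error | zeros
    gene_shift_mode: str = "median"     # median (per-gene summary) | per_value

    # stratification bands (closed intervals on [0, 1])
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})

    # differential expression
    de_test: str = "welch"              # welch | mannwhitney
    de_p: float = 0.0005
    de_fdr: float = 0.05
    de_fc: float | None = None          # None -> 1.25 on log2, 0.25 on shift scale
    de_pairs: list = field(default_factory=lambda: [["low", "high"], ["low", "mid"], ["mid", "high"]])

    # correlation screen
    corr_r_pos: float = 0.75
    corr_r_neg: float = -0.75
    corr_p_max: float = 0.0001
    corr_top_n: int = 50

    # enrichment
    enrich_p_max: float = 0.0001
    enrich_fdr_max: float = 0.05
    enrich_blacklist: list = field(default_factory=lambda: ["disease", "development"])

    # trajectory
    timepoint_order: list = field(default_factory=list)
    kde_grid_size: int = 512
    kde_bandwidth: float | None = None

    seed: int = 0

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ConfigError(f"config scale must be raw or log2, got {self.scale!r}")
        if self.gene_shift_mode not in ("median", "per_value"):
            raise ConfigError(f"gene_shift_mode must be median or per_value, got {self.gene_shift_mode!r}")
        if self.degenerate not in ("error", "zeros"):
            raise ConfigError(f"degenerate policy must be error or zeros, got {self.degenerate!r}")

    def bands_tuples(self) -> dict[str, tuple[float, float]]:
        return {k: (float(v[0]), float(v[1])) for k, v in self.bands.items()}

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
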