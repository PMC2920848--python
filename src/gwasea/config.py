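"""Run configuration: every pipeline parameter, YAML in/out, reproducible runs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .correction import DEFAULT_ENTRY_P, DEFAULT_REMOVAL_P
from .enrichment import (
    DEFAULT_CUTOFF_PERCENTILE,
    DEFAULT_MAX_N_NULL,
    DEFAULT_MIN_SET_SIZE,
    DEFAULT_N_NULL,
)

CORRECTION_METHODS = ("regression", "sidak", "modified_sidak", "permutation", "none")
STATS = ("cutoff", "ranksum")


@dataclass
class RunConfig:
    """All parameters of a scoring/enrichment run.

    A serialized copy is written into every output directory, and re-running
    from that copy reproduces the outputs byte-identically.
    """

    # inputs
    assoc: str = ""
    refflat: str = ""
    gmt: str | None = None
    hotspots: str | None = None
    genetic_map: str | None = None
    ldu_map: str | None = None
    indep_snps: str | None = None
    null_stack: str | None = None  # TSV: gene + one column per null replicate
    genome_build: str | None = None  # label only; logged, never validated

    # gene model
    upstream_bp: int = 110_000
    downstream_bp: int = 40_000
    strand_aware: bool = True
    max_span_bp: int = 1_000_000

    # correction
    correction: str = "regression"
    entry_p: float = DEFAULT_ENTRY_P
    removal_p: float = DEFAULT_REMOVAL_P
    covariates: list[str] | None = None  # None = default five
    missing_covariates: str = "impute"  # or "drop"

    # enrichment
    stat: str = "cutoff"
    cutoff_percentile: float = DEFAULT_CUTOFF_PERCENTILE
    n_null: int = DEFAULT_N_NULL
    adaptive: bool = True
    min_set_size: int = DEFAULT_MIN_SET_SIZE
    max_n_null: int = DEFAULT_MAX_N_NULL
    null_method: str = "auto"

    # run
    seed: int = 0
    out_dir: str = "gwasea_out"
    log_level: str = "INFO"

    def __post_init__(self):
        if self.correction not in CORRECTION_METHODS:
            raise ValueError(f"correction must be one of {CORRECTION_METHODS}")
        if self.stat not in STATS:
            raise ValueError(f"stat must be one of {STATS}")
        if not (0 < self.cutoff_percentile < 100):
            raise ValueError("cutoff_percentile must be in (0, 100)")

    def to_yaml(self, path) -> None:
        with open(path, "wt") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def input_paths(self) -> dict[str, str]:
        paths = {"assoc": self.assoc, "refflat": self.refflat}
        for key in ("gmt", "hotspots", "genetic_map", "ldu_map", "indep_snps", "null_stack"):
            val = getattr(self, key)
            if val:
                paths[key] = val
        return paths
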