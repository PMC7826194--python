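"""Pipeline configuration: thresholds, seed, and paths.

All cutoffs used anywhere in the pipeline live here so that every output
table can carry a complete provenance header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml


@dataclass
class Config:
    """All tunable thresholds of the pipeline.

    Attributes
    ----------
    min_junction_reads:
        Minimum inclusion AND exclusion junction read count a sample must
        show for an event to count as covered (read-coverage filter).
    min_fraction:
        Fraction of samples (per group) that must pass a coverage or
        expression rule. 0.5 means "at least half the individuals".
    fdr:
        Benjamini-Hochberg FDR cutoff for all differential calls.
    delta_psi:
        Minimum |ΔPSI| for a differential-splicing call; ties at exactly
        this value are significant (inclusive rule).
    log2fc:
        Minimum |log2 fold change| for a sex-biased expression call.
    min_logcpm_expr:
        log2-CPM floor for the expression analysis.
    min_logcpm_popgen:
        Stricter log2-CPM floor applied before population-genomic contrasts.
    ds_max:
        Genes with synonymous rate dS above this are dropped from dN/dS
        aggregation (mutational saturation).
    n_boot:
        Bootstrap replicates for confidence intervals and cluster support.
    n_randomizations:
        Replicates of the morph-intermediacy randomization procedure.
    logcpm_offset:
        Pseudo-count added to CPM before taking log2.
    seed:
        Master seed; recorded in every output header.
    """

    min_junction_reads: int = 20
    min_fraction: float = 0.5
    fdr: float = 0.05
    delta_psi: float = 0.1
    log2fc: float = 1.0
    min_logcpm_expr: float = 1.0
    min_logcpm_popgen: float = 2.0
    ds_max: float = 2.0
    n_boot: int = 1000
    n_randomizations: int = 100
    logcpm_offset: float = 0.25
    seed: int = 0
    out_dir: str = "results"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        checks = [
            ("min_junction_reads", self.min_junction_reads >= 0),
            ("min_fraction", 0.0 < self.min_fraction <= 1.0),
            ("fdr", 0.0 < self.fdr <= 1.0),
            ("delta_psi", 0.0 <= self.delta_psi <= 1.0),
            ("log2fc", self.log2fc >= 0.0),
            ("ds_max", self.ds_max > 0.0),
            ("n_boot", self.n_boot >= 1),
            ("n_randomizations", self.n_randomizations >= 1),
            ("logcpm_offset", self.logcpm_offset > 0.0),
            ("seed", int(self.seed) == self.seed),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ValueError(f"config values out of range: {', '.join(bad)}")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
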