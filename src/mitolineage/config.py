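"""Run configuration: every pipeline threshold in one validated object.

Defaults are the published operating points of the method: candidate floor
0.001, bulk reporting cut 1%, homoplasmic cut 0.9, strand rule (>2 reads
per strand, 30-70% balance), any-read single-cell positivity, 40x WT
coverage floor, depth bins of 10, and the contamination screen thresholds.
Unknown keys in a config file are rejected rather than ignored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # candidate calling
    min_vaf: float = 0.001
    min_alt_reads: int = 1
    # filters
    report_cut: float = 0.01
    homoplasmic_cut: float = 0.9
    min_per_strand: int = 2
    strand_low: float = 0.3
    strand_high: float = 0.7
    blacklist_position_only: bool = False
    # contamination screen
    contamination_max_het: int = 30
    contamination_max_overlap_frac: float = 0.5
    # single-cell genotyping
    min_support: int = 1
    wt_coverage: float = 40.0
    bin_width: int = 10
    # lineage inference
    min_cells: int = 3
    exceedance_quantile: float = 0.99
    depth_adjust: bool = False
    # misc
    seed: int = 0

    def __post_init__(self):
        checks = [
            (0 < self.min_vaf <= 1, "min_vaf in (0,1]"),
            (self.min_alt_reads >= 1, "min_alt_reads >= 1"),
            (0 < self.report_cut < self.homoplasmic_cut <= 1,
             "0 < report_cut < homoplasmic_cut <= 1"),
            (self.min_per_strand >= 0, "min_per_strand >= 0"),
            (0 <= self.strand_low < self.strand_high <= 1,
             "0 <= strand_low < strand_high <= 1"),
            (self.contamination_max_het >= 1, "contamination_max_het >= 1"),
            (0 < self.contamination_max_overlap_frac <= 1,
             "contamination_max_overlap_frac in (0,1]"),
            (self.min_support >= 1, "min_support >= 1"),
            (self.wt_coverage > 0, "wt_coverage > 0"),
            (self.bin_width >= 1, "bin_width >= 1"),
            (self.min_cells >= 1, "min_cells >= 1"),
            (0 < self.exceedance_quantile < 1, "exceedance_quantile in (0,1)"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ConfigError("invalid configuration: " + "; ".join(bad))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
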