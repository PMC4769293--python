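"""Run configuration: every pipeline threshold in one YAML-serialisable object.

Defaults are the assay's validated operating points: run QC advisory gates at
30% ISP loading / 30% usable reads, library gates at 800x mean coverage, 80%
on-target and 100,000 mapped reads, triage filters at 100x depth and 5% VAF,
and the detection model's 20 mutant reads at >=10% tumour cells.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    # run-level QC (advisory)
    run_min_isp_pct: float = 30.0
    run_min_usable_pct: float = 30.0
    # library-level QC (gating)
    lib_min_mean_coverage: float = 800.0
    lib_min_on_target_pct: float = 80.0
    lib_min_mapped_reads: int = 100_000
    amplicon_min_mean_coverage: float = 100.0
    # triage
    min_depth: int = 100
    min_vaf: float = 0.05
    germline_af_threshold: float = 0.01
    germline_mode: str = "threshold"  # or "presence"
    review_min_depth: int = 500
    review_min_alt_reads: int = 30
    homopolymer_min_run: int = 4
    strict_review: bool = False
    # detection model
    n_min: int = 20
    ploidy: int = 2
    mutant_copies: int = 1
    safety_factor: float = 2.0
    vaf_floor: float = 0.05
    min_tumour_fraction: float = 0.10
    # statistics
    welch_ttest: bool = True
    # resource paths
    panel_path: str | None = None
    blacklist_path: str | None = None
    population_path: str | None = None
    transcript_path: str | None = None
    reference_path: str | None = None
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "run_min_isp_pct",
            "run_min_usable_pct",
            "lib_min_mean_coverage",
            "lib_min_on_target_pct",
            "lib_min_mapped_reads",
            "amplicon_min_mean_coverage",
            "min_depth",
            "review_min_depth",
            "review_min_alt_reads",
            "homopolymer_min_run",
            "n_min",
            "safety_factor",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("min_vaf", "germline_af_threshold", "vaf_floor",
                     "min_tumour_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigError(f"{name} must be a proportion in [0, 1]")
        if self.germline_mode not in ("threshold", "presence"):
            raise ConfigError("germline_mode must be 'threshold' or 'presence'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
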