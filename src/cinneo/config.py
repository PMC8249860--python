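"""Run configuration: every stage threshold in one serializable object.

Defaults equal the pipeline's published thresholds; the config is written
alongside outputs so any run can be reproduced from its sidecar file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .filters import FilterThresholds

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    input_dir: str = ""
    out_dir: str = ""
    seed: int = 0

    # somatic filter
    min_tumor_depth: int = 14
    min_normal_depth: int = 8
    min_tumor_alt: int = 5
    min_tumor_vaf: float = 0.05
    max_normal_vaf: float = 0.03
    min_vaf_fold: float = 4.0

    # signature refitting
    weight_cutoff: float = 0.06
    improvement_tol: float = 1e-3

    # neoantigen thresholds
    ic50_max: float = 500.0
    rank_max: float = 2.0
    min_tumor_fpkm: float = 0.5
    min_abs_log2_ratio: float = 0.1
    binder_fraction: float = 0.02

    # driver enumeration
    min_cases: int = 3
    driver_catalog_path: str = ""

    # stage toggles
    run_signatures: bool = True
    run_expression_filter: bool = True

    def filter_thresholds(self) -> FilterThresholds:
        return FilterThresholds(
            min_tumor_depth=self.min_tumor_depth,
            min_normal_depth=self.min_normal_depth,
            min_tumor_alt=self.min_tumor_alt,
            min_tumor_vaf=self.min_tumor_vaf,
            max_normal_vaf=self.max_normal_vaf,
            min_vaf_fold=self.min_vaf_fold,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
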