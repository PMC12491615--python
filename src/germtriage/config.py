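"""Pipeline configuration: thresholds, switches and ranking weights.

Loadable from YAML; every threshold is the published default and every
comparison is strict exactly as printed (``>2%``, ``<1%``, ``<5%``,
``<0.3``), with boundary-equal values taking the keep/lenient side.
"""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict

from .ranking import RankingWeights


class PipelineConfig(BaseModel):
    model_config = ConfigDict(frozen=True)

    maf_rare: float = 0.01
    maf_low: float = 0.05
    control_exclude: float = 0.02
    pslf_floor: float = 0.01
    chip_vaf_threshold: float = 0.3
    require_cgi_driver: bool = True
    sift_polyphen_mode: str = "or"  # "or" | "and"
    burden_metric: str = "sum"  # "sum" | "mean"
    recurrence: str = "sum"  # "sum" | "mean"
    callable_mb: float = 2800.0
    loh_af_threshold: float = 0.65
    loh_af_delta: float = 0.15
    ancestry_floor: float = 0.9  # restricted-ancestry prevalence cut (strict >)
    weights: RankingWeights = RankingWeights()

    # optional gene-list overrides (paths to TSV/line files)
    gene_set_file: Optional[str] = None
    known_gt_panel_file: Optional[str] = None
    chip_gene_file: Optional[str] = None
    chip_suspect_gene_file: Optional[str] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.model_validate(data)

    def to_dict(self) -> dict:
        return self.model_dump(mode="json")
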