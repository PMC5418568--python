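"""Run configuration (JSON-backed) for thresholds and correction constants."""
from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, Field

#: Genomic-inflation correction factors (LD-score-regression intercepts) per trait.
#: These are configuration constants of the analysis, keyed by cancer type.
DEFAULT_CORRECTION_FACTORS: dict[str, float] = {
    "colorectal": 1.15,
    "colon": 1.12,
    "rectal": 1.04,
    "endometrial": 1.05,
    "ovarian": 1.04,
    "brain": 1.03,
    "breast": 1.25,
    "bladder": 1.07,
    "esophageal": 1.02,
    "gallbladder_bile_duct": 1.01,
    "gastric": 1.13,
    "liver": 1.02,
    "myelodysplastic_syndrome": 1.00,
    "pancreatic": 1.09,
    "prostate": 1.22,
    "renal_ureteral": 1.01,
    "testicular": 1.03,
}


class ScreeningConfig(BaseModel):
    #: mean promoter methylation (%) at or above which the tumour is hypermethylated
    methylation_threshold: float = 15.0
    #: BRAF rescue also fires when methylation is negative but within this many
    #: percentage points below the threshold and BRAF V600E IHC is positive
    braf_rescue_margin: float = 2.0


class LohBands(BaseModel):
    """Observed/expected VAF ratio cut-offs for the LOH confidence bands."""

    definite: float = 0.90
    likely: float = 0.75
    maybe: float = 0.60


class SomaticConfig(BaseModel):
    #: fraction of unstable microsatellite loci at or above which the tumour is MSI-high
    msi_threshold: float = 0.2
    loh_bands: LohBands = Field(default_factory=LohBands)


class SvScanConfig(BaseModel):
    flank: int = 100_000
    #: discordant insert sizes deviate more than this many SDs from the mean
    insert_sd_multiplier: float = 3.0
    min_mapq_exclusive: int = 0  # drop reads with mapq == 0
    max_mean_basequal_drop: float = 25.0  # drop reads with mean base quality <= this
    cluster_max_gap: int = 500
    min_support: int = 3
    max_control_fraction: float = 0.01
    min_insert_pairs: int = 20  # minimum proper pairs to estimate insert stats
    insert_trim_fraction: float = 0.01  # symmetric trimming of insert sizes


class AnalysisConfig(BaseModel):
    screening: ScreeningConfig = Field(default_factory=ScreeningConfig)
    somatic: SomaticConfig = Field(default_factory=SomaticConfig)
    sv: SvScanConfig = Field(default_factory=SvScanConfig)
    correction_factors: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_CORRECTION_FACTORS)
    )
    schema_version: str = "1"


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load configuration from JSON; defaults when no path given."""
    if path is None:
        return AnalysisConfig()
    return AnalysisConfig.model_validate(json.loads(Path(path).read_text()))


def dump_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(config.model_dump_json(indent=2))
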