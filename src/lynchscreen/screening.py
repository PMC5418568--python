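"""IHC panel logic, MLH1 promoter-methylation calling, and the BRAF V600E fallback.

Universal tumour screening stains the four MMR proteins on resections. When
only biopsy tissue is available, a two-stain panel (MSH6 + PMS2) covers the
two heterodimers: loss of PMS2 reflexes to an MLH1 stain, loss of MSH6 to an
MSH2 stain. Tumours with MLH1 loss are tested for promoter hypermethylation
(mean of four CpG sites, positive at >= 15%); when that assay fails or is
borderline, BRAF V600E immunohistochemistry can stand in as evidence of a
sporadic (hypermethylated) origin.
"""
from __future__ import annotations

from enum import Enum
from statistics import fmean
from typing import Optional

from .config import ScreeningConfig
from .records import (
    BrafIHC,
    IHCResult,
    LossPattern,
    MethylationCall,
    MethylationResult,
    Specimen,
    Stain,
)

FULL_PANEL = frozenset({"MLH1", "MSH2", "MSH6", "PMS2"})
BIOPSY_PANEL = frozenset({"MSH6", "PMS2"})


class BrafInference(str, Enum):
    INFER_MLH1_HM = "infer_mlh1_hm"
    NO_INFERENCE = "no_inference"


def select_panel(
    specimen: Specimen, prior_results: Optional[IHCResult] = None
) -> frozenset[str]:
    """Proteins to stain next.

    Resections get the full four-protein panel. Biopsies start with MSH6 +
    PMS2; a lost PMS2 reflexes to MLH1 and a lost MSH6 to MSH2.
    """
    if specimen is Specimen.RESECTION:
        return FULL_PANEL
    if prior_results is None:
        return BIOPSY_PANEL
    reflex: set[str] = set()
    if prior_results.stain("PMS2") is Stain.ABSENT:
        reflex.add("MLH1")
    if prior_results.stain("MSH6") is Stain.ABSENT:
        reflex.add("MSH2")
    return frozenset(reflex) if reflex else BIOPSY_PANEL


def loss_pattern(ihc: IHCResult) -> LossPattern:
    """Collapse stain calls into the loss pattern used by the cascade.

    Only absent stains drive the pattern; weak-but-present stains count as
    present. Heterodimer pairs take precedence (MLH1/PMS2, then MSH2/MSH6),
    then isolated PMS2 and MSH6 losses (extra missing stains ride along with
    the pattern implied by the absent ones). With no loss at all the result is
    normal when the screening panel is informative (MSH6 and PMS2 assessed),
    otherwise incomplete.
    """
    absent = {p for p, s in ihc.stains.items() if s is Stain.ABSENT}
    if {"MLH1", "PMS2"} <= absent:
        return LossPattern.MLH1_PMS2
    if {"MSH2", "MSH6"} <= absent:
        return LossPattern.MSH2_MSH6
    if "PMS2" in absent:
        return LossPattern.PMS2_ONLY
    if "MSH6" in absent:
        return LossPattern.MSH6_ONLY
    if "MLH1" in absent:
        return LossPattern.MLH1_PMS2
    if "MSH2" in absent:
        return LossPattern.MSH2_MSH6
    assessed = {
        p
        for p, s in ihc.stains.items()
        if s in (Stain.PRESENT, Stain.WEAK_PRESENT)
    }
    if {"MSH6", "PMS2"} <= assessed:
        return LossPattern.NORMAL
    return LossPattern.INCOMPLETE


def call_methylation(
    cpg_levels: list[float], threshold: float = 15.0
) -> MethylationResult:
    """Average per-site methylation percentages and call hypermethylation.

    Positive iff the mean is at or above ``threshold`` (inclusive); an empty
    measurement set is a failed assay.

    Raises
    ------
    ValueError
        If any level lies outside [0, 100].
    """
    for level in cpg_levels:
        if not 0.0 <= level <= 100.0:
            raise ValueError(f"methylation level {level} outside [0, 100]")
    if not cpg_levels:
        return MethylationResult(cpg_levels=[], mean_level=None, call=MethylationCall.FAILED)
    mean = fmean(cpg_levels)
    call = MethylationCall.POSITIVE if mean >= threshold else MethylationCall.NEGATIVE
    return MethylationResult(cpg_levels=list(cpg_levels), mean_level=mean, call=call)


def braf_fallback(
    specimen: Specimen,
    methylation: Optional[MethylationResult],
    braf_ihc: BrafIHC,
    config: Optional[ScreeningConfig] = None,
) -> BrafInference:
    """Infer MLH1 hypermethylation from BRAF V600E when direct testing falls short.

    Fires when BRAF IHC is positive and either (a) the methylation assay
    failed on a biopsy-only case, or (b) the assay was negative but the mean
    sits within ``braf_rescue_margin`` percentage points below the threshold
    (a borderline result a positive BRAF resolves toward hypermethylation).
    """
    cfg = config or ScreeningConfig()
    if braf_ihc is not BrafIHC.POSITIVE:
        return BrafInference.NO_INFERENCE
    if methylation is None or methylation.call is MethylationCall.FAILED:
        if specimen is Specimen.BIOPSY:
            return BrafInference.INFER_MLH1_HM
        return BrafInference.NO_INFERENCE
    if (
        methylation.call is MethylationCall.NEGATIVE
        and methylation.mean_level is not None
        and methylation.mean_level >= cfg.methylation_threshold - cfg.braf_rescue_margin
    ):
        return BrafInference.INFER_MLH1_HM
    return BrafInference.NO_INFERENCE
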