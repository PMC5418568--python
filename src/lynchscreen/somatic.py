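"""Tumour-sequencing interpretation: MSI calling, LOH banding, double-somatic rules.

A tumour is mismatch-repair deficient without a germline explanation when two
somatic hits (or one hit plus loss of heterozygosity) inactivate an MMR gene.
Hits count when pathogenic or likely pathogenic: InSiGHT class 4/5 or
predicted protein truncation. LOH is inferred from the variant allele
fraction (VAF): with tumour purity p, a heterozygous variant whose wild-type
allele was lost is expected at VAF 1/(2-p); the observed/expected ratio is
banded into none / maybe / likely / definite.
"""
from __future__ import annotations

from typing import Optional

from .config import LohBands, SomaticConfig
from .records import (
    Loh,
    MsiCall,
    Origin,
    SomaticProfile,
    SomaticVerdict,
    VariantRecord,
)


def call_msi(msings_score: float, threshold: float = 0.2) -> MsiCall:
    """MSI-high iff the fraction of unstable microsatellite loci >= threshold.

    Raises
    ------
    ValueError
        If the score lies outside [0, 1].
    """
    if not 0.0 <= msings_score <= 1.0:
        raise ValueError(f"mSINGS score {msings_score} outside [0, 1]")
    return MsiCall.MSI_H if msings_score >= threshold else MsiCall.MSS


def infer_loh(
    variant_vaf: float,
    purity: float,
    het_baseline: float = 0.5,
    bands: Optional[LohBands] = None,
) -> Loh:
    """Band the allelic imbalance of a variant into an LOH confidence level.

    Expected VAF under monoallelic (wild-type) loss at tumour purity ``p`` is
    ``1/(2-p)``; the observed/expected ratio maps to definite (>= 0.90),
    likely (>= 0.75), maybe (>= 0.60), else none. Monotone in VAF for fixed
    purity.

    Raises
    ------
    ValueError
        If VAF outside [0, 1] or purity outside (0, 1].
    """
    b = bands or LohBands()
    if not 0.0 <= variant_vaf <= 1.0:
        raise ValueError(f"VAF {variant_vaf} outside [0, 1]")
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"tumour purity {purity} must lie in (0, 1]")
    expected = 1.0 / (2.0 - purity)
    ratio = variant_vaf / expected
    if ratio >= b.definite:
        return Loh.DEFINITE
    if ratio >= b.likely:
        return Loh.LIKELY
    if ratio >= b.maybe:
        return Loh.MAYBE
    return Loh.NONE


def _qualifying_germline(
    germline: list[VariantRecord], second_hit_present: bool
) -> Optional[VariantRecord]:
    """The germline MMR mutation the tumour evidence is judged against.

    Class 4/5, truncating, or designated variants qualify outright. A class-3
    variant qualifies only when the tumour shows a somatic second hit in the
    same gene - the second hit is what argues the variant is pathogenic.
    """
    for v in germline:
        if v.origin is not Origin.GERMLINE:
            continue
        if v.qualifies_germline:
            return v
        if v.path_class == "3" and second_hit_present:
            return v
    return None


def resolve_double_somatic(
    profile: SomaticProfile,
    germline: list[VariantRecord],
    config: Optional[SomaticConfig] = None,
) -> SomaticVerdict:
    """Apply the solved / possibly-solved rules to a tumour profile.

    With a qualifying germline mutation, any somatic hit in the same gene or
    LOH at likely-or-better is the second hit (Lynch syndrome); with none
    detected the tumour arose sporadically in a carrier. Without a germline
    mutation: two pathogenic/likely-pathogenic hits in one gene, or one such
    hit with LOH at likely-or-better, is solved double somatic; one hit with
    possible LOH is possibly solved; anything less is not solved.
    """
    del config  # thresholds already applied upstream of the categorical fields
    if profile.failed:
        return SomaticVerdict.NOT_SOLVED

    germline_mmr = [v for v in germline if v.origin is Origin.GERMLINE]
    # Tumour evidence per germline candidate gene: any somatic variant counts
    # as a second hit once the first hit is in the germline.
    for g in germline_mmr:
        second_mut = bool(profile.somatic_variants(g.gene))
        second_hit = second_mut or profile.loh.rank >= Loh.LIKELY.rank
        qualifying = _qualifying_germline([g], second_hit_present=second_hit)
        if qualifying is None:
            continue
        if second_hit:
            return SomaticVerdict.LYNCH_SECOND_HIT
        return SomaticVerdict.LYNCH_SPORADIC_TUMOUR

    # No qualifying germline mutation: purely somatic interpretation.
    by_gene: dict[str, list[VariantRecord]] = {}
    for v in profile.somatic_variants():
        by_gene.setdefault(v.gene, []).append(v)
    for gene_variants in by_gene.values():
        pathogenic = [v for v in gene_variants if v.is_pathogenic]
        if len(pathogenic) >= 2:
            return SomaticVerdict.SOLVED_DOUBLE_SOMATIC
        if len(pathogenic) == 1:
            if profile.loh.rank >= Loh.LIKELY.rank:
                return SomaticVerdict.SOLVED_DOUBLE_SOMATIC
            if profile.loh is Loh.MAYBE:
                return SomaticVerdict.POSSIBLY_DOUBLE_SOMATIC
    return SomaticVerdict.NOT_SOLVED
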