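"""Domain records for the universal-tumour-screening cascade.

The cascade works on abstracted per-patient evidence: mismatch-repair (MMR)
protein immunohistochemistry (IHC) stain calls, MLH1 promoter-methylation
percentages, BRAF V600E IHC, germline variant records, and tumour-sequencing
profiles (somatic variants, loss of heterozygosity, an MSI instability score).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

MMR_GENES: tuple[str, ...] = ("MLH1", "MSH2", "MSH6", "PMS2")


class Stain(str, Enum):
    PRESENT = "present"
    ABSENT = "absent"
    WEAK_PRESENT = "weak_present"
    NOT_DONE = "not_done"


class Specimen(str, Enum):
    RESECTION = "resection"
    BIOPSY = "biopsy"


class BrafIHC(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NOT_DONE = "not_done"


class LossPattern(str, Enum):
    MLH1_PMS2 = "MLH1_PMS2"
    MSH2_MSH6 = "MSH2_MSH6"
    MSH6_ONLY = "MSH6"
    PMS2_ONLY = "PMS2"
    NORMAL = "normal"
    INCOMPLETE = "incomplete"


ABNORMAL_PATTERNS = (
    LossPattern.MLH1_PMS2,
    LossPattern.MSH2_MSH6,
    LossPattern.MSH6_ONLY,
    LossPattern.PMS2_ONLY,
)


class MethylationCall(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    FAILED = "failed"


class MsiCall(str, Enum):
    MSI_H = "MSI-H"
    MSS = "MSS"


class Loh(str, Enum):
    """Loss-of-heterozygosity confidence band, ordered none < maybe < likely < definite."""

    NONE = "none"
    MAYBE = "maybe"
    LIKELY = "likely"
    DEFINITE = "definite"

    @property
    def rank(self) -> int:
        return _LOH_ORDER[self]


_LOH_ORDER = {Loh.NONE: 0, Loh.MAYBE: 1, Loh.LIKELY: 2, Loh.DEFINITE: 3}


class Origin(str, Enum):
    GERMLINE = "germline"
    SOMATIC = "somatic"


class Etiology(str, Enum):
    PMMR = "pMMR"
    LS = "LS"
    LS_SPORADIC_TUMOUR = "LS_sporadic_tumour"
    MLH1_HM = "MLH1_hm"
    DOUBLE_SOMATIC = "double_somatic"
    POSSIBLY_DOUBLE_SOMATIC = "possibly_double_somatic"
    UNEXPLAINED = "unexplained"


#: Etiology labels counted as Lynch syndrome in prevalence and screening metrics.
LS_LABELS = (Etiology.LS, Etiology.LS_SPORADIC_TUMOUR)
#: Labels counted in the double-somatic column of the cross-tabulation.
DS_LABELS = (Etiology.DOUBLE_SOMATIC, Etiology.POSSIBLY_DOUBLE_SOMATIC)


class SomaticVerdict(str, Enum):
    SOLVED_DOUBLE_SOMATIC = "solved_double_somatic"
    POSSIBLY_DOUBLE_SOMATIC = "possibly_double_somatic"
    LYNCH_SECOND_HIT = "lynch_second_hit"
    LYNCH_SPORADIC_TUMOUR = "lynch_sporadic_tumour"
    NOT_SOLVED = "not_solved"


@dataclass
class IHCResult:
    """Per-protein stain calls with optional percent-positive annotations.

    A weak-but-present stain must come with a percent-positive annotation
    > 1% (convincing nuclear staining in a small fraction of tumour cells);
    a stain without a positive internal control is recorded as not done.
    """

    stains: dict[str, Stain]
    percent_positive_cells: dict[str, float] = field(default_factory=dict)
    internal_control: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for protein, stain in list(self.stains.items()):
            if protein not in MMR_GENES:
                raise ValueError(f"unknown MMR protein {protein!r}")
            if not self.internal_control.get(protein, True):
                self.stains[protein] = Stain.NOT_DONE
            if stain is Stain.WEAK_PRESENT:
                pct = self.percent_positive_cells.get(protein)
                if pct is None or pct <= 1.0:
                    raise ValueError(
                        f"weak_present {protein} requires percent_positive_cells > 1%"
                    )

    def stain(self, protein: str) -> Stain:
        return self.stains.get(protein, Stain.NOT_DONE)

    @property
    def weak_proteins(self) -> list[str]:
        return [p for p, s in self.stains.items() if s is Stain.WEAK_PRESENT]


@dataclass
class MethylationResult:
    """Promoter-methylation assay: per-CpG percentages, their mean, and the call."""

    cpg_levels: list[float]
    mean_level: Optional[float]
    call: MethylationCall

    def __post_init__(self) -> None:
        if (self.call is MethylationCall.FAILED) != (len(self.cpg_levels) == 0):
            raise ValueError("call is failed iff no CpG sites were measured")


@dataclass
class VariantRecord:
    gene: str
    hgvs_c: str = ""
    hgvs_p: str = ""
    origin: Origin = Origin.GERMLINE
    path_class: str = "NK"  # "1".."5" or "NK"
    truncating: bool = False
    vaf: Optional[float] = None
    designated_pathogenic: bool = False  # curated designation (e.g. study founder variants)

    @property
    def is_pathogenic(self) -> bool:
        """Pathogenic / likely pathogenic: class 4 or 5, or predicted truncating."""
        return self.path_class in ("4", "5") or self.truncating

    @property
    def qualifies_germline(self) -> bool:
        """Counts as a Lynch-syndrome germline mutation without further tumour evidence."""
        return self.origin is Origin.GERMLINE and (
            self.is_pathogenic or self.designated_pathogenic
        )


@dataclass
class SomaticProfile:
    """Tumour-sequencing result: somatic variants, LOH band, instability score."""

    variants: list[VariantRecord] = field(default_factory=list)
    loh: Loh = Loh.NONE
    msings_score: Optional[float] = None
    msi_call: Optional[MsiCall] = None
    msh2_methylation: str = "not_done"  # positive | negative | not_done
    failed: bool = False  # assay indeterminate (e.g. low tumour DNA content)

    def somatic_variants(self, gene: Optional[str] = None) -> list[VariantRecord]:
        out = [v for v in self.variants if v.origin is Origin.SOMATIC]
        if gene is not None:
            out = [v for v in out if v.gene == gene]
        return out


@dataclass
class CaseRecord:
    """One colorectal-cancer patient in the screened cohort."""

    case_id: str
    sex: str = "male"  # male | female
    age_dx: float = 70.0
    location: str = "right"  # right | left | rectum
    stage: str = "II"  # I..IV | unknown
    specimen: Specimen = Specimen.RESECTION
    genotyped: bool = True
    ihc: Optional[IHCResult] = None
    methylation: Optional[MethylationResult] = None
    braf_ihc: BrafIHC = BrafIHC.NOT_DONE
    germline_variants: list[VariantRecord] = field(default_factory=list)
    somatic: Optional[SomaticProfile] = None
    true_etiology: Optional[str] = None  # simulation truth; never read by the classifier

    def __post_init__(self) -> None:
        if not self.genotyped and self.germline_variants:
            raise ValueError("genotyped=false implies no germline variant records")


@dataclass
class EtiologyCall:
    """Classifier verdict for one case, with the ordered rule firings behind it."""

    case_id: str
    label: Etiology
    evidence_chain: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label is not Etiology.PMMR and not self.evidence_chain:
            raise ValueError("non-pMMR label requires a non-empty evidence chain")
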