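"""Study input tables: founder mutations, tumour-sequencing rows, association rows.

These are the published inputs the analysis consumes - the mutation catalogue
with carrier frequencies, the thirty tumour-sequencing evidence rows, and the
per-cancer odds-ratio rows with their case/control totals - encoded as data,
not computed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .records import Loh, Origin, VariantRecord

# ---------------------------------------------------------------------------
# Lynch-syndrome mutation catalogue (gene, protein change, class, cohort count,
# population carrier frequency where imputable)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FounderMutation:
    mutation_id: str
    gene: str
    hgvs_c: str
    hgvs_p: str
    path_class: str  # InSiGHT class or "NK"
    truncating: bool
    designated: bool  # study-designated pathogenic (e.g. reclassified class 3)
    n_crc_cohort: int
    carrier_freq: Optional[float]  # fraction; None when private/family-only

    def germline_record(self) -> VariantRecord:
        return VariantRecord(
            gene=self.gene,
            hgvs_c=self.hgvs_c,
            hgvs_p=self.hgvs_p,
            origin=Origin.GERMLINE,
            path_class=self.path_class,
            truncating=self.truncating,
            designated_pathogenic=self.designated,
        )


LS_MUTATIONS: dict[str, FounderMutation] = {
    m.mutation_id: m
    for m in [
        FounderMutation("PMS2_P246fs", "PMS2", "c.736_741del6ins11", "p.Pro246Cysfs*3",
                        "5", True, False, 12, 0.00234),
        FounderMutation("PMS2_M1", "PMS2", "c.2T>A", "p.Met1?",
                        "NK", True, True, 0, 0.00092),
        FounderMutation("MSH6_L585P", "MSH6", "c.1754T>C", "p.Leu585Pro",
                        "3", False, True, 9, 0.00080),
        FounderMutation("MLH1_translocation", "MLH1", "t(3;5) balanced translocation", "",
                        "NK", False, True, 1, None),
        FounderMutation("MSH6_V282fs", "MSH6", "c.843_844insAC", "p.Val282Thrfs*10",
                        "NK", True, False, 1, None),
        FounderMutation("MSH6_F1088fs", "MSH6", "c.3261dupC", "p.Phe1088Leufs*5",
                        "5", True, False, 1, None),
        FounderMutation("MSH6_R1172fs", "MSH6", "c.3514dupA", "p.Arg1172Lysfs*5",
                        "5", True, False, 1, None),
        FounderMutation("MSH2_Y815X", "MSH2", "c.2445T>A", "p.Tyr815*",
                        "NK", True, False, 0, None),
        FounderMutation("PMS2_N71fs", "PMS2", "c.211_214del", "p.Asn71Aspfs*4",
                        "NK", True, False, 1, None),
        FounderMutation("PMS2_E705K", "PMS2", "c.2113G>A", "p.Glu705Lys",
                        "3", False, False, 1, None),
    ]
}

#: Imputable founder mutations with population carrier frequencies.
FOUNDER_CARRIER_FREQS: dict[str, float] = {
    k: m.carrier_freq
    for k, m in LS_MUTATIONS.items()
    if m.carrier_freq is not None
}


# ---------------------------------------------------------------------------
# Tumour-sequencing evidence rows (per-case somatic profiles with outcomes)
# ---------------------------------------------------------------------------


def _som(gene: str, hgvs_c: str, hgvs_p: str = "", truncating: bool = True,
         path_class: str = "NK") -> VariantRecord:
    return VariantRecord(gene=gene, hgvs_c=hgvs_c, hgvs_p=hgvs_p,
                         origin=Origin.SOMATIC, path_class=path_class,
                         truncating=truncating)


@dataclass(frozen=True)
class TumourSeqRow:
    study_id: str
    msings: float
    msi_printed: str  # "MSI-H" | "MSS"
    hm_pct: Optional[float]  # MLH1 promoter methylation mean (%); None = not tested
    pattern: str  # printed absent-stain pattern
    gene: str  # printed gene column ("" for none)
    somatic_variants: tuple[VariantRecord, ...] = ()
    loh: Loh = Loh.NONE
    germline_mutation_ids: tuple[str, ...] = ()  # keys into LS_MUTATIONS
    extra_germline: tuple[VariantRecord, ...] = ()
    msh2_methylation: str = "not_done"
    failed: bool = False
    braf_positive: bool = False
    weak_msh6_pct: Optional[float] = None  # normal IHC with weak MSH6 stain
    outcome: str = ""


TUMOUR_SEQ_ROWS: tuple[TumourSeqRow, ...] = (
    TumourSeqRow("197", 0.4062, "MSI-H", 10, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.493del", "p.A165Lfs*2"),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("237", 0.4531, "MSI-H", 4, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.2237del", "p.L746Rfs*37"),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("466", 0.5538, "MSI-H", 5, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.1684C>T", "p.Q562*"),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("506", 0.5079, "MSI-H", 4, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.199G>A", "p.G67R", truncating=False, path_class="5"),),
                 Loh.DEFINITE, outcome="Double somatic"),
    TumourSeqRow("745", 0.4923, "MSI-H", 10, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.1783_1784del", "p.S595Wfs*14"),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("985", 0.4462, "MSI-H", 10, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.588del", "p.K196Nfs*6"),
                  _som("MLH1", "c.171del;c.299G>A", "p.K57Nfs*2;p.R100Q")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("1034", 0.5538, "MSI-H", 6, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.2142G>A", "p.W714*"),
                  _som("MLH1", "c.670_673dup", "p.R226*")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("1141", 0.4923, "MSI-H", None, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.2206G>T", "p.E736*"),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("246", 0.4769, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.545_552del", "p.D182Vfs*4"),
                  _som("MSH2", "c.1661+1G>A", "splicing")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("1082", 0.3492, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.82del", "p.E28Rfs*36"),
                  _som("MSH2", "c.1310del", "p.V437Gfs*17")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("1049", 0.4754, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.942+3A>T", "splicing"),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("959", 0.5846, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.2459-2A>C", "splicing"),
                  _som("MSH2", "c.2352del", "p.H785Mfs*27")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("951", 0.5156, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.425C>G", "p.S142*"),
                  _som("MSH2", "c.942+3A>T", "splicing")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("509", 0.1587, "MSS", None, "MSH6", "MSH2",
                 (_som("MSH2", "inversion", "", truncating=True),), Loh.MAYBE,
                 extra_germline=(VariantRecord("MSH2", "c.2210+7G>T", "splice region",
                                               Origin.GERMLINE, "NK", False),),
                 outcome="Possibly double somatic"),
    TumourSeqRow("1231", 0.4462, "MSI-H", None, "PMS2", "PMS2",
                 (_som("PMS2", "c.325delG", "p.E109Kfs*3"),
                  _som("PMS2", "c.444delC;c.903+1G>A", "p.Y149Tfs*52;splicing")),
                 Loh.NONE, outcome="Double somatic"),
    TumourSeqRow("1022", 0.2857, "MSI-H", None, "PMS2", "PMS2",
                 (_som("PMS2", "exon 11 homozygous deletion", ""),), Loh.DEFINITE,
                 outcome="Double somatic"),
    TumourSeqRow("427", 0.4462, "MSI-H", None, "PMS2", "PMS2",
                 (), Loh.LIKELY, germline_mutation_ids=("PMS2_E705K",),
                 outcome="Lynch syndrome"),
    TumourSeqRow("1057", 0.5692, "MSI-H", None, "PMS2", "PMS2",
                 (_som("PMS2", "c.2113G>A", "p.E705K", truncating=False, path_class="3"),),
                 Loh.MAYBE, germline_mutation_ids=("PMS2_N71fs",),
                 outcome="Lynch syndrome"),
    TumourSeqRow("339", 0.5626, "MSI-H", 5, "MLH1_PMS2", "MLH1",
                 (_som("MLH1", "c.2041G>A", "p.Ala681Thr", truncating=False),),
                 Loh.NONE, germline_mutation_ids=("MLH1_translocation",),
                 outcome="Lynch syndrome"),
    TumourSeqRow("786", 0.2787, "MSI-H", None, "normal", "MSH6",
                 (_som("MSH6", "c.3509delT", "p.I1170Mfs*14"),), Loh.NONE,
                 germline_mutation_ids=("MSH6_L585P",), weak_msh6_pct=3.0,
                 outcome="Lynch syndrome"),
    TumourSeqRow("30", 0.1228, "MSS", None, "normal", "MSH6",
                 (_som("MSH6", "c.3261del", "p.F1088Serfs*2"),), Loh.NONE,
                 germline_mutation_ids=("MSH6_L585P",), weak_msh6_pct=5.0,
                 outcome="Lynch syndrome"),
    TumourSeqRow("94", 0.4032, "MSI-H", None, "normal", "MSH6",
                 (_som("MSH6", "c.3016T>G", "p.Y1006D", truncating=False),), Loh.NONE,
                 germline_mutation_ids=("MSH6_L585P",), weak_msh6_pct=25.0,
                 outcome="Lynch syndrome"),
    TumourSeqRow("1250", 0.1538, "MSS", None, "normal", "PMS2",
                 (), Loh.NONE, germline_mutation_ids=("PMS2_P246fs",),
                 outcome="Lynch syndrome (sporadic tumour)"),
    TumourSeqRow("873", 0.0615, "MSS", None, "normal", "PMS2",
                 (), Loh.NONE, germline_mutation_ids=("PMS2_P246fs",),
                 outcome="Lynch syndrome (sporadic tumour)"),
    TumourSeqRow("162", 0.5385, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.2458+2delT", "splicing"),), Loh.NONE,
                 msh2_methylation="negative", outcome="Not solved"),
    TumourSeqRow("1127", 0.2188, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.943-1G>C", "splicing"),), Loh.NONE,
                 msh2_methylation="negative", outcome="Not solved"),
    TumourSeqRow("1108", 0.4154, "MSI-H", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.2131C>T", "p.R711*"),), Loh.NONE,
                 extra_germline=(VariantRecord("MSH2", "c.2635-10T>G", "splicing",
                                               Origin.GERMLINE, "NK", False),),
                 msh2_methylation="negative", outcome="Not solved"),
    TumourSeqRow("418", 0.1077, "MSS", None, "MSH2_MSH6", "MSH2",
                 (_som("MSH2", "c.1077-2736T>G", "deep intronic", truncating=False),),
                 Loh.DEFINITE, outcome="Not solved"),
    TumourSeqRow("827", 0.0923, "MSS", 2, "MLH1_PMS2", "",
                 (), Loh.NONE, failed=True, outcome="Not solved"),
    TumourSeqRow("240", 0.2742, "MSI-H", 14, "MLH1_PMS2", "",
                 (), Loh.NONE, braf_positive=True, outcome="MLH1-hm"),
)


# ---------------------------------------------------------------------------
# Founder-mutation association rows (odds ratios per cancer type)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AssociationRow:
    variant_id: str
    carrier_freq: float  # population carrier frequency (fraction)
    cancer: str
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    n_cases: int
    n_controls: int
    info: Optional[float]
    risk_male: Optional[float]  # printed lifetime risk (fraction); None = NA
    risk_female: Optional[float]


ASSOCIATION_ROWS: tuple[AssociationRow, ...] = (
    AssociationRow("MSH6_L585P", 0.00080, "endometrial", 32.8, (13.5, 80.0), 1.61e-14,
                   923, 115_104, 0.92, None, 0.492),
    AssociationRow("MSH6_L585P", 0.00080, "colorectal", 10.1, (5.1, 20.1), 4.19e-11,
                   3834, 262_425, None, 0.364, 0.253),
    AssociationRow("MSH6_L585P", 0.00080, "colon", 7.5, (3.3, 17.0), 1.89e-6,
                   2793, 263_466, None, 0.179, 0.127),
    AssociationRow("MSH6_L585P", 0.00080, "rectal", 12.4, (4.4, 34.8), 1.79e-6,
                   1082, 260_587, None, 0.161, 0.099),
    AssociationRow("MSH6_L585P", 0.00080, "brain", 8.9, (2.2, 36.2), 2.19e-3,
                   702, 358_789, None, 0.134, 0.107),
    AssociationRow("PMS2_P246fs", 0.00234, "endometrial", 9.9, (4.9, 19.8), 1.30e-10,
                   923, 115_104, 0.99, None, 0.148),
    AssociationRow("PMS2_P246fs", 0.00234, "colorectal", 3.6, (2.2, 5.9), 7.64e-7,
                   3834, 262_425, None, 0.129, 0.090),
    AssociationRow("PMS2_P246fs", 0.00234, "colon", 3.8, (2.2, 6.6), 1.7e-7,
                   2793, 263_466, None, 0.092, 0.065),
    AssociationRow("PMS2_P246fs", 0.00234, "rectal", 2.3, (0.8, 6.9), 1.2e-1,
                   1082, 260_587, None, 0.030, 0.019),
    AssociationRow("PMS2_P246fs", 0.00234, "ovarian", 3.9, (1.3, 11.9), 1.53e-2,
                   779, 121_299, None, None, 0.035),
    AssociationRow("PMS2_M1", 0.00092, "endometrial", 7.5, (2.4, 23.5), 5.53e-4,
                   923, 115_104, 0.99, None, 0.113),
    AssociationRow("PMS2_M1", 0.00092, "colorectal", 2.2, (0.94, 5.3), 7.01e-2,
                   3834, 262_425, None, 0.080, 0.055),
    AssociationRow("PMS2_M1", 0.00092, "colon", 2.7, (1.1, 6.8), 3.7e-2,
                   2793, 263_466, None, 0.064, 0.046),
    AssociationRow("PMS2_M1", 0.00092, "rectal", 0.9, (0.13, 6.7), 5.4e-1,
                   1082, 260_587, None, 0.012, 0.008),
    AssociationRow("PMS2_M1", 0.00092, "ovarian", 6.6, (1.8, 24.3), 4.16e-3,
                   779, 121_299, None, None, 0.060),
)
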