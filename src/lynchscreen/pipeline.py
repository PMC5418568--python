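"""Orchestration of the dMMR etiology cascade and cohort-level arithmetic.

Each screened case runs through: IHC loss pattern -> (for MLH1/PMS2 loss)
methylation and BRAF fallback -> germline genotype -> tumour-sequencing
resolution. The cohort-level outputs are the pattern x etiology
cross-tabulation, screening performance (sensitivity/specificity/PPV/NPV of
abnormal IHC for Lynch syndrome on the genotyped subset), and prevalence /
proportion arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .config import AnalysisConfig
from .records import (
    ABNORMAL_PATTERNS,
    DS_LABELS,
    LS_LABELS,
    CaseRecord,
    Etiology,
    EtiologyCall,
    LossPattern,
    MethylationCall,
    SomaticVerdict,
)
from .screening import BrafInference, braf_fallback, loss_pattern
from .somatic import resolve_double_somatic

#: Germline genes concordant with each abnormal IHC loss pattern
#: (protein-partner biology: PMS2 loss can reflect MLH1 mutation, MSH6 loss
#: can reflect MSH2 mutation).
CONCORDANT_GENES: dict[LossPattern, frozenset[str]] = {
    LossPattern.MLH1_PMS2: frozenset({"MLH1", "PMS2"}),
    LossPattern.MSH2_MSH6: frozenset({"MSH2", "MSH6"}),
    LossPattern.MSH6_ONLY: frozenset({"MSH6"}),
    LossPattern.PMS2_ONLY: frozenset({"PMS2", "MLH1"}),
}

_VERDICT_TO_LABEL = {
    SomaticVerdict.SOLVED_DOUBLE_SOMATIC: Etiology.DOUBLE_SOMATIC,
    SomaticVerdict.POSSIBLY_DOUBLE_SOMATIC: Etiology.POSSIBLY_DOUBLE_SOMATIC,
    SomaticVerdict.LYNCH_SECOND_HIT: Etiology.LS,
    SomaticVerdict.LYNCH_SPORADIC_TUMOUR: Etiology.LS_SPORADIC_TUMOUR,
    SomaticVerdict.NOT_SOLVED: Etiology.UNEXPLAINED,
}


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (printed-report convention)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _qualifying_germline_genes(case: CaseRecord) -> set[str]:
    return {v.gene for v in case.germline_variants if v.qualifies_germline}


def classify_case(
    case: CaseRecord, config: Optional[AnalysisConfig] = None
) -> EtiologyCall:
    """Run the full etiology cascade for one case.

    Decision order: (1) normal/incomplete IHC - a qualifying germline
    mutation makes the case Lynch syndrome (with tumour sequencing deciding
    second-hit vs sporadic tumour), otherwise MMR-proficient. (2) MLH1/PMS2
    loss - positive or BRAF-inferred methylation is sporadic
    hypermethylation; else germline, then tumour sequencing, else
    unexplained. (3) other loss patterns - a qualifying germline mutation in
    a concordant gene, then tumour sequencing, else unexplained.

    Raises
    ------
    ValueError
        If the case has no IHC result.
    """
    cfg = config or AnalysisConfig()
    if case.ihc is None:
        raise ValueError(f"case {case.case_id}: missing IHC result")
    pattern = loss_pattern(case.ihc)
    chain: list[str] = [f"ihc_pattern={pattern.value}"]

    if pattern in (LossPattern.NORMAL, LossPattern.INCOMPLETE):
        if case.somatic is not None:
            verdict = resolve_double_somatic(
                case.somatic, case.germline_variants, cfg.somatic
            )
            if verdict in (
                SomaticVerdict.LYNCH_SECOND_HIT,
                SomaticVerdict.LYNCH_SPORADIC_TUMOUR,
            ):
                chain.append(f"somatic_resolution={verdict.value}")
                return EtiologyCall(case.case_id, _VERDICT_TO_LABEL[verdict], chain)
        if _qualifying_germline_genes(case):
            # carrier with a normal-staining tumour and no (or untested)
            # somatic second hit: Lynch syndrome, sporadic tumour
            chain.append("germline_qualifying_no_second_hit")
            return EtiologyCall(case.case_id, Etiology.LS_SPORADIC_TUMOUR, chain)
        return EtiologyCall(case.case_id, Etiology.PMMR, [])

    if pattern is LossPattern.MLH1_PMS2:
        if (
            case.methylation is not None
            and case.methylation.call is MethylationCall.POSITIVE
        ):
            chain.append("methylation_positive")
            return EtiologyCall(case.case_id, Etiology.MLH1_HM, chain)
        if (
            braf_fallback(case.specimen, case.methylation, case.braf_ihc, cfg.screening)
            is BrafInference.INFER_MLH1_HM
        ):
            chain.append("braf_inferred_hypermethylation")
            return EtiologyCall(case.case_id, Etiology.MLH1_HM, chain)

    germline_genes = _qualifying_germline_genes(case)
    concordant = CONCORDANT_GENES[pattern]
    if germline_genes & concordant:
        chain.append(f"germline_qualifying={sorted(germline_genes & concordant)}")
        return EtiologyCall(case.case_id, Etiology.LS, chain)

    if case.somatic is not None:
        verdict = resolve_double_somatic(case.somatic, case.germline_variants, cfg.somatic)
        chain.append(f"somatic_resolution={verdict.value}")
        label = _VERDICT_TO_LABEL[verdict]
        if label is Etiology.LS_SPORADIC_TUMOUR:
            # abnormal concordant IHC with a germline mutation and no second
            # hit still reads as LS for an abnormal pattern
            label = Etiology.LS
        return EtiologyCall(case.case_id, label, chain)

    chain.append("tumour_testing_unavailable")
    return EtiologyCall(case.case_id, Etiology.UNEXPLAINED, chain)


def classify_cohort(
    cohort: list[CaseRecord], config: Optional[AnalysisConfig] = None
) -> list[EtiologyCall]:
    cfg = config or AnalysisConfig()
    return [classify_case(c, cfg) for c in cohort]


# ---------------------------------------------------------------------------
# Cohort-level tables and metrics
# ---------------------------------------------------------------------------

_TABLE_PATTERNS = [
    LossPattern.MLH1_PMS2,
    LossPattern.MSH2_MSH6,
    LossPattern.MSH6_ONLY,
    LossPattern.PMS2_ONLY,
]
_TABLE_COLUMNS = ["MLH1_hm", "LS", "double_somatic", "unexplained", "total"]


@dataclass
class CohortTabulation:
    """Pattern x etiology contingency table over abnormal-IHC cases."""

    table: pd.DataFrame  # rows: loss patterns + Total; columns: _TABLE_COLUMNS
    normal_ihc_ls: int  # LS cases with normal IHC, reported separately
    n_cases: int


def tabulate(
    cohort: list[CaseRecord],
    calls: Optional[list[EtiologyCall]] = None,
    config: Optional[AnalysisConfig] = None,
) -> CohortTabulation:
    """Cross-tabulate abnormal-IHC cases by loss pattern and etiology.

    Possibly-double-somatic counts in the double-somatic column;
    LS-sporadic-tumour counts as LS. Normal-IHC LS cases are excluded from
    the table and reported separately.
    """
    cfg = config or AnalysisConfig()
    if calls is None:
        calls = classify_cohort(cohort, cfg)
    counts = {p: dict.fromkeys(_TABLE_COLUMNS, 0) for p in _TABLE_PATTERNS}
    normal_ls = 0
    for case, call in zip(cohort, calls, strict=True):
        pattern = loss_pattern(case.ihc) if case.ihc is not None else LossPattern.INCOMPLETE
        if pattern not in ABNORMAL_PATTERNS:
            if call.label in LS_LABELS:
                normal_ls += 1
            continue
        row = counts[pattern]
        if call.label is Etiology.MLH1_HM:
            row["MLH1_hm"] += 1
        elif call.label in LS_LABELS:
            row["LS"] += 1
        elif call.label in DS_LABELS:
            row["double_somatic"] += 1
        else:
            row["unexplained"] += 1
        row["total"] += 1
    df = pd.DataFrame.from_dict(
        {p.value: counts[p] for p in _TABLE_PATTERNS}, orient="index"
    )
    df.loc["Total"] = df.sum(axis=0)
    return CohortTabulation(table=df, normal_ihc_ls=normal_ls, n_cases=len(cohort))


@dataclass
class ScreeningMetrics:
    """Diagnostic performance of abnormal IHC for Lynch syndrome."""

    tp: int
    fp: int
    tn: int
    fn: int
    n_genotyped: int

    @property
    def sensitivity(self) -> float:
        return self._pct(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return self._pct(self.tn, self.tn + self.fp, "specificity")

    @property
    def ppv(self) -> float:
        return self._pct(self.tp, self.tp + self.fp, "PPV")

    @property
    def npv(self) -> float:
        return self._pct(self.tn, self.tn + self.fn, "NPV")

    @staticmethod
    def _pct(num: int, den: int, name: str) -> float:
        if den == 0:
            raise ZeroDivisionError(f"{name} undefined: zero denominator")
        return 100.0 * num / den

    def rounded(self) -> dict[str, float]:
        return {
            "sensitivity": round_half_away(self.sensitivity),
            "specificity": round_half_away(self.specificity),
            "ppv": round_half_away(self.ppv),
            "npv": round_half_away(self.npv),
        }


def screening_performance(
    cohort: list[CaseRecord],
    calls: Optional[list[EtiologyCall]] = None,
    config: Optional[AnalysisConfig] = None,
) -> ScreeningMetrics:
    """Sensitivity/specificity/PPV/NPV of IHC screening on the genotyped subset.

    Screen-positive: abnormal IHC not explained by MLH1 hypermethylation
    (hypermethylated tumours are resolved as sporadic before genotyping and
    do not trigger the germline work-up). Truth-positive: the case carries a
    Lynch-syndrome mutation (classified LS, including sporadic tumours in
    carriers).
    """
    cfg = config or AnalysisConfig()
    if calls is None:
        calls = classify_cohort(cohort, cfg)
    tp = fp = tn = fn = n = 0
    for case, call in zip(cohort, calls, strict=True):
        if not case.genotyped:
            continue
        n += 1
        pattern = loss_pattern(case.ihc) if case.ihc is not None else LossPattern.INCOMPLETE
        screen_pos = pattern in ABNORMAL_PATTERNS and call.label is not Etiology.MLH1_HM
        truth_pos = call.label in LS_LABELS
        if screen_pos and truth_pos:
            tp += 1
        elif screen_pos:
            fp += 1
        elif truth_pos:
            fn += 1
        else:
            tn += 1
    return ScreeningMetrics(tp=tp, fp=fp, tn=tn, fn=fn, n_genotyped=n)


@dataclass
class Proportion:
    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator if self.denominator else float("nan")

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction


@dataclass
class CohortProportions:
    dmmr: Proportion
    ls_prevalence: Proportion
    mlh1_hm: Proportion
    double_somatic: Proportion
    unexplained: Proportion
    ls_by_gene: dict[str, int] = field(default_factory=dict)
    msh6_pms2_share_of_ls: Proportion = None  # type: ignore[assignment]
    ds_hits_mlh1_msh2: Proportion = None  # type: ignore[assignment]


def cohort_proportions(
    cohort: list[CaseRecord],
    calls: Optional[list[EtiologyCall]] = None,
    config: Optional[AnalysisConfig] = None,
) -> CohortProportions:
    """Prevalence and share arithmetic over a classified cohort.

    The gene attribution of double-somatic hits counts definitely solved
    cases only in the numerator (possibly-solved cases lack a confirmed gene)
    over all double-somatic cases.
    """
    cfg = config or AnalysisConfig()
    if calls is None:
        calls = classify_cohort(cohort, cfg)
    n = len(cohort)
    labels = [c.label for c in calls]
    dmmr = sum(
        1
        for case in cohort
        if case.ihc is not None and loss_pattern(case.ihc) in ABNORMAL_PATTERNS
    )
    n_ls = sum(1 for lab in labels if lab in LS_LABELS)
    n_hm = labels.count(Etiology.MLH1_HM)
    n_ds = sum(1 for lab in labels if lab in DS_LABELS)
    n_unexp = labels.count(Etiology.UNEXPLAINED)

    ls_by_gene: dict[str, int] = {}
    for case, call in zip(cohort, calls, strict=True):
        if call.label in LS_LABELS:
            genes = {v.gene for v in case.germline_variants}
            gene = sorted(genes)[0] if genes else "unknown"
            ls_by_gene[gene] = ls_by_gene.get(gene, 0) + 1
    msh6_pms2 = ls_by_gene.get("MSH6", 0) + ls_by_gene.get("PMS2", 0)

    ds_mlh1_msh2 = 0
    for case, call in zip(cohort, calls, strict=True):
        if call.label is Etiology.DOUBLE_SOMATIC and case.somatic is not None:
            genes = {v.gene for v in case.somatic.somatic_variants()}
            if genes & {"MLH1", "MSH2"}:
                ds_mlh1_msh2 += 1

    return CohortProportions(
        dmmr=Proportion(dmmr, n),
        ls_prevalence=Proportion(n_ls, n),
        mlh1_hm=Proportion(n_hm, n),
        double_somatic=Proportion(n_ds, n),
        unexplained=Proportion(n_unexp, n),
        ls_by_gene=ls_by_gene,
        msh6_pms2_share_of_ls=Proportion(msh6_pms2, n_ls),
        ds_hits_mlh1_msh2=Proportion(ds_mlh1_msh2, n_ds),
    )
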