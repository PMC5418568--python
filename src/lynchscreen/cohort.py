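"""Synthetic screened-CRC cohorts and populations.

Two entry points matter here. :func:`generate_cohort` draws a configurable
cohort with the statistical structure the cascade assumes (etiology mixture,
IHC loss patterns conditional on etiology, founder-mutation genotypes, weak
stains and sporadic tumours in carriers). :func:`fixture_cohort` instead
reconstructs, deterministically, the 1,182-case screened cohort whose
marginals match the published cross-tabulations cell by cell - it is the
ground truth the pipeline tests and the screening-performance arithmetic run
against.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import expit, logit

from .records import (
    BrafIHC,
    CaseRecord,
    IHCResult,
    Loh,
    MethylationResult,
    MethylationCall,
    Origin,
    SomaticProfile,
    Specimen,
    Stain,
    VariantRecord,
)
from .screening import call_methylation
from .somatic import call_msi
from .tables import (
    FOUNDER_CARRIER_FREQS,
    LS_MUTATIONS,
    TUMOUR_SEQ_ROWS,
    TumourSeqRow,
)

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

#: Default etiology mixture of the screened cohort (fractions of 1,182).
DEFAULT_ETIOLOGY_MIX: dict[str, float] = {
    "pMMR": 1044 / 1182,
    "LS": 27 / 1182,
    "MLH1_hm": 90 / 1182,
    "double_somatic": 16 / 1182,
    "unexplained": 5 / 1182,
}


class CohortConfig(BaseModel):
    n_cases: int = 1182
    etiology_mix: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_ETIOLOGY_MIX)
    )
    genotyped_fraction_normal_ihc: float = 0.782
    founder_freqs: dict[str, float] = Field(
        default_factory=lambda: dict(FOUNDER_CARRIER_FREQS)
    )
    #: fraction of MSH6-mutant LS cases presenting a weak-but-present stain
    weak_stain_rate: float = 3 / 9
    #: LS carriers whose tumour arose sporadically (normal IHC, no second hit)
    sporadic_in_carrier_count: int = 2
    exact: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "CohortConfig":
        total = sum(self.etiology_mix.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"etiology_mix sums to {total}, expected 1")
        for name, p in self.etiology_mix.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"etiology_mix[{name}]={p} outside [0,1]")
        if not 0.0 <= self.genotyped_fraction_normal_ihc <= 1.0:
            raise ValueError("genotyped_fraction_normal_ihc outside [0,1]")
        if not 0.0 <= self.weak_stain_rate <= 1.0:
            raise ValueError("weak_stain_rate outside [0,1]")
        return self


class PopulationConfig(BaseModel):
    n_individuals: int
    carrier_freq: dict[str, float]
    #: cumulative incidence at age 75 per cancer type per sex, fractions
    cancer_baseline_risk: dict[str, dict[str, float]]
    #: odds ratio per mutation per cancer
    true_or: dict[str, dict[str, float]]
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "PopulationConfig":
        for f in self.carrier_freq.values():
            if not 0.0 <= f <= 1.0:
                raise ValueError("carrier frequency outside [0,1]")
        for per_sex in self.cancer_baseline_risk.values():
            for k in per_sex.values():
                if not 0.0 < k < 1.0:
                    raise ValueError("baseline risks must lie in (0,1)")
        for per_cancer in self.true_or.values():
            for o in per_cancer.values():
                if o <= 0:
                    raise ValueError("true odds ratios must be positive")
        return self


# ---------------------------------------------------------------------------
# Demographic realism (per-etiology distributions; never read by the classifier)
# ---------------------------------------------------------------------------

_DEMOGRAPHICS: dict[str, dict] = {
    # age: (Q1, median, Q3); categorical weights are cohort counts
    "pMMR": dict(age=(61, 71, 78), male=601 / 1044,
                 stage=(193, 282, 298, 230, 41), location=(357, 366, 307)),
    "LS": dict(age=(55, 62, 72), male=22 / 27,
               stage=(5, 16, 4, 2, 0), location=(14, 9, 4)),
    "MLH1_hm": dict(age=(73, 78, 84), male=25 / 90,
                    stage=(9, 47, 24, 6, 4), location=(76, 8, 4)),
    "double_somatic": dict(age=(57, 69, 79), male=9 / 16,
                           stage=(1, 9, 4, 1, 1), location=(13, 2, 1)),
    "unexplained": dict(age=(35, 75, 86), male=2 / 5,
                        stage=(3, 2, 0, 0, 0), location=(2, 1, 2)),
}
_STAGES = ("I", "II", "III", "IV", "unknown")
_LOCATIONS = ("right", "left", "rectum")


def _demographics(etiology: str, rng: np.random.Generator) -> dict:
    d = _DEMOGRAPHICS[etiology]
    q1, med, q3 = d["age"]
    age = float(rng.triangular(q1, med, q3))
    sex = "male" if rng.random() < d["male"] else "female"
    stage_w = np.asarray(d["stage"], dtype=float)
    stage = _STAGES[rng.choice(len(_STAGES), p=stage_w / stage_w.sum())]
    loc_w = np.asarray(d["location"], dtype=float)
    location = _LOCATIONS[rng.choice(len(_LOCATIONS), p=loc_w / loc_w.sum())]
    return dict(sex=sex, age_dx=round(age, 1), stage=stage, location=location)


# ---------------------------------------------------------------------------
# IHC construction helpers
# ---------------------------------------------------------------------------


def _ihc(absent: set[str], weak: dict[str, float] | None = None,
         panel: set[str] | None = None) -> IHCResult:
    panel = panel or {"MLH1", "MSH2", "MSH6", "PMS2"}
    stains: dict[str, Stain] = {}
    pct: dict[str, float] = {}
    for p in panel:
        if p in absent:
            stains[p] = Stain.ABSENT
        elif weak and p in weak:
            stains[p] = Stain.WEAK_PRESENT
            pct[p] = weak[p]
        else:
            stains[p] = Stain.PRESENT
    return IHCResult(stains=stains, percent_positive_cells=pct)


_PATTERN_ABSENT: dict[str, set[str]] = {
    "MLH1_PMS2": {"MLH1", "PMS2"},
    "MSH2_MSH6": {"MSH2", "MSH6"},
    "MSH6": {"MSH6"},
    "PMS2": {"PMS2"},
    "normal": set(),
}

_OUTCOME_ETIOLOGY: dict[str, str] = {
    "Double somatic": "double_somatic",
    "Possibly double somatic": "double_somatic",
    "Lynch syndrome": "LS",
    "Lynch syndrome (sporadic tumour)": "LS",
    "Not solved": "unexplained",
    "MLH1-hm": "MLH1_hm",
}


def case_from_seq_row(row: TumourSeqRow, rng: np.random.Generator) -> CaseRecord:
    """Build the CaseRecord carrying one tumour-sequencing evidence row."""
    weak = {"MSH6": row.weak_msh6_pct} if row.weak_msh6_pct is not None else None
    ihc = _ihc(set(_PATTERN_ABSENT[row.pattern]), weak=weak)
    methylation = None
    if row.hm_pct is not None:
        methylation = call_methylation([float(row.hm_pct)] * 4)
    germline = [LS_MUTATIONS[mid].germline_record() for mid in row.germline_mutation_ids]
    germline.extend(row.extra_germline)
    somatic = SomaticProfile(
        variants=list(row.somatic_variants),
        loh=row.loh,
        msings_score=row.msings,
        msi_call=call_msi(row.msings),
        msh2_methylation=row.msh2_methylation,
        failed=row.failed,
    )
    etiology = _OUTCOME_ETIOLOGY[row.outcome]
    return CaseRecord(
        case_id=row.study_id,
        specimen=Specimen.RESECTION,
        genotyped=True,
        ihc=ihc,
        methylation=methylation,
        braf_ihc=BrafIHC.POSITIVE if row.braf_positive else BrafIHC.NOT_DONE,
        germline_variants=germline,
        somatic=somatic,
        true_etiology=etiology,
        **_demographics(etiology, rng),
    )


def _positive_methylation(rng: np.random.Generator) -> MethylationResult:
    mean = rng.uniform(25, 90)
    levels = np.clip(mean + rng.normal(0, 3, size=4), 0, 100)
    result = call_methylation([round(float(x), 1) for x in levels])
    assert result.call is MethylationCall.POSITIVE
    return result


# ---------------------------------------------------------------------------
# Deterministic fixture cohort
# ---------------------------------------------------------------------------


def fixture_cohort() -> list[CaseRecord]:
    """The deterministic 1,182-case screened cohort.

    Composition (abnormal IHC, 132 cases): 100 MLH1/PMS2 (86 methylation
    positive, 3 biopsy assay failures rescued by BRAF V600E IHC, plus the
    tumour-sequenced rows), 11 MSH2/MSH6, 8 MSH6-only, 13 PMS2-only. Six LS
    cases have normal IHC (three weak MSH6 stains with somatic second hits,
    two sporadic tumours in PMS2 frameshift carriers, one carrier without
    tumour sequencing). 1,044 cases are MMR proficient; 953 cases overall are
    germline genotyped (all abnormal-IHC plus 78.2% of normal-IHC).
    """
    rng = np.random.default_rng(14755)
    cases: list[CaseRecord] = []

    for row in TUMOUR_SEQ_ROWS:
        cases.append(case_from_seq_row(row, rng))

    # methylation-positive MLH1/PMS2 tumours (one also missing the MSH2 stain)
    for i in range(86):
        absent = {"MLH1", "PMS2"} | ({"MSH2"} if i == 0 else set())
        cases.append(
            CaseRecord(
                case_id=f"hm{i:03d}",
                specimen=Specimen.RESECTION,
                genotyped=True,
                ihc=_ihc(absent),
                methylation=_positive_methylation(rng),
                true_etiology="MLH1_hm",
                **_demographics("MLH1_hm", rng),
            )
        )
    # biopsy-only cases: methylation assay failed, BRAF V600E IHC positive
    for i in range(3):
        cases.append(
            CaseRecord(
                case_id=f"hmb{i}",
                specimen=Specimen.BIOPSY,
                genotyped=True,
                ihc=_ihc({"MLH1", "PMS2"}, panel={"MLH1", "MSH6", "PMS2"}),
                methylation=MethylationResult([], None, MethylationCall.FAILED),
                braf_ihc=BrafIHC.POSITIVE,
                true_etiology="MLH1_hm",
                **_demographics("MLH1_hm", rng),
            )
        )

    # LS cases explained by germline genotyping alone (no tumour sequencing)
    def _ls_case(case_id: str, mutation_id: str, absent: set[str]) -> CaseRecord:
        return CaseRecord(
            case_id=case_id,
            specimen=Specimen.RESECTION,
            genotyped=True,
            ihc=_ihc(absent),
            germline_variants=[LS_MUTATIONS[mutation_id].germline_record()],
            true_etiology="LS",
            **_demographics("LS", rng),
        )

    # 9 PMS2 frameshift carriers with PMS2 loss (one also missing MSH6)
    for i in range(9):
        absent = {"PMS2"} | ({"MSH6"} if i == 0 else set())
        cases.append(_ls_case(f"lsp{i}", "PMS2_P246fs", absent))
    # 6 MSH6 p.Leu585Pro carriers with MSH6 loss
    for i in range(6):
        cases.append(_ls_case(f"lsm{i}", "MSH6_L585P", {"MSH6"}))
    # private MSH6 mutations: one MSH6-only, two MSH2/MSH6 (one missing PMS2 too)
    cases.append(_ls_case("lsr0", "MSH6_R1172fs", {"MSH6"}))
    cases.append(_ls_case("lsv0", "MSH6_V282fs", {"MSH2", "MSH6", "PMS2"}))
    cases.append(_ls_case("lsf0", "MSH6_F1088fs", {"MSH2", "MSH6"}))
    # the sixth normal-IHC LS case: carrier without tumour sequencing
    cases.append(_ls_case("lsu0", "PMS2_P246fs", set()))

    # MMR-proficient remainder; 815 of 1,044 germline genotyped
    genotyped_flags = np.zeros(1044, dtype=bool)
    genotyped_flags[rng.permutation(1044)[:815]] = True
    for i in range(1044):
        biopsy = i % 8 == 7  # a fraction screened on biopsy two-stain panels
        cases.append(
            CaseRecord(
                case_id=f"p{i:04d}",
                specimen=Specimen.BIOPSY if biopsy else Specimen.RESECTION,
                genotyped=bool(genotyped_flags[i]),
                ihc=_ihc(set(), panel={"MSH6", "PMS2"} if biopsy else None),
                true_etiology="pMMR",
                **_demographics("pMMR", rng),
            )
        )
    assert len(cases) == 1182
    return cases


# ---------------------------------------------------------------------------
# Configurable cohort generator
# ---------------------------------------------------------------------------


def _apportion_exact(n: int, mix: dict[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n cases across etiologies."""
    keys = list(mix)
    raw = {k: n * mix[k] for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    short = n - sum(counts.values())
    by_remainder = sorted(keys, key=lambda k: (-(raw[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


_DS_GENES = ("MLH1", "MSH2", "PMS2", "MSH6")
_DS_GENE_W = (0.50, 0.31, 0.13, 0.06)
_GENE_PATTERN = {"MLH1": "MLH1_PMS2", "MSH2": "MSH2_MSH6",
                 "MSH6": "MSH6", "PMS2": "PMS2"}


def generate_cohort(config: CohortConfig) -> list[CaseRecord]:
    """Draw a synthetic screened cohort under the configured study conditions.

    Etiology counts follow a multinomial draw (or exact largest-remainder
    apportionment with ``exact=true``). Every LS case carries exactly one
    qualifying germline mutation; hypermethylated cases have positive
    methylation; double-somatic cases carry two somatic hits or one hit with
    LOH; unexplained cases have a single unresolvable somatic hit.
    """
    rng = np.random.default_rng(config.seed)
    mix_keys = list(config.etiology_mix)
    if config.exact:
        counts = _apportion_exact(config.n_cases, config.etiology_mix)
    else:
        draw = rng.multinomial(config.n_cases, [config.etiology_mix[k] for k in mix_keys])
        counts = dict(zip(mix_keys, (int(x) for x in draw)))

    founder_ids = list(config.founder_freqs)
    founder_w = np.asarray([config.founder_freqs[k] for k in founder_ids], dtype=float)
    if founder_w.sum() <= 0 and counts.get("LS", 0) > 0:
        raise ValueError("founder_freqs must have positive total to draw LS cases")

    cases: list[CaseRecord] = []
    serial = 0

    def new_id(prefix: str) -> str:
        nonlocal serial
        serial += 1
        return f"{prefix}{serial:05d}"

    n_sporadic = min(config.sporadic_in_carrier_count, counts.get("LS", 0))
    for i in range(counts.get("LS", 0)):
        mid = founder_ids[rng.choice(len(founder_ids), p=founder_w / founder_w.sum())]
        mut = LS_MUTATIONS[mid]
        germline = [mut.germline_record()]
        somatic = None
        methylation = None
        if i < n_sporadic:
            ihc = _ihc(set())
            somatic = SomaticProfile(msings_score=round(float(rng.uniform(0.02, 0.18)), 4))
        elif mut.gene == "MSH6" and rng.random() < config.weak_stain_rate:
            ihc = _ihc(set(), weak={"MSH6": round(float(rng.uniform(2, 30)), 1)})
            somatic = SomaticProfile(
                variants=[VariantRecord("MSH6", "c.sim_second_hit", origin=Origin.SOMATIC,
                                        truncating=True)],
                msings_score=round(float(rng.uniform(0.22, 0.6)), 4),
            )
        else:
            ihc = _ihc(set(_PATTERN_ABSENT[_GENE_PATTERN[mut.gene]]))
            if mut.gene == "MLH1":
                methylation = call_methylation([round(float(rng.uniform(1, 8)), 1)] * 4)
        if somatic is not None and somatic.msings_score is not None:
            somatic.msi_call = call_msi(somatic.msings_score)
        cases.append(
            CaseRecord(
                case_id=new_id("ls"),
                genotyped=True,
                ihc=ihc,
                methylation=methylation,
                germline_variants=germline,
                somatic=somatic,
                true_etiology="LS",
                **_demographics("LS", rng),
            )
        )

    for _ in range(counts.get("MLH1_hm", 0)):
        cases.append(
            CaseRecord(
                case_id=new_id("hm"),
                genotyped=True,
                ihc=_ihc({"MLH1", "PMS2"}),
                methylation=_positive_methylation(rng),
                true_etiology="MLH1_hm",
                **_demographics("MLH1_hm", rng),
            )
        )

    for _ in range(counts.get("double_somatic", 0)):
        gene = _DS_GENES[rng.choice(len(_DS_GENES), p=_DS_GENE_W)]
        two_hits = rng.random() < 0.5
        variants = [VariantRecord(gene, "c.sim_hit1", origin=Origin.SOMATIC, truncating=True)]
        loh = Loh.NONE
        if two_hits:
            variants.append(
                VariantRecord(gene, "c.sim_hit2", origin=Origin.SOMATIC, truncating=True)
            )
        else:
            loh = Loh.DEFINITE if rng.random() < 0.6 else Loh.LIKELY
        score = round(float(rng.uniform(0.22, 0.6)), 4)
        methylation = None
        if gene == "MLH1":
            methylation = call_methylation([round(float(rng.uniform(1, 10)), 1)] * 4)
        cases.append(
            CaseRecord(
                case_id=new_id("ds"),
                genotyped=True,
                ihc=_ihc(set(_PATTERN_ABSENT[_GENE_PATTERN[gene]])),
                methylation=methylation,
                somatic=SomaticProfile(variants=variants, loh=loh,
                                       msings_score=score, msi_call=call_msi(score)),
                true_etiology="double_somatic",
                **_demographics("double_somatic", rng),
            )
        )

    for _ in range(counts.get("unexplained", 0)):
        score = round(float(rng.uniform(0.22, 0.6)), 4)
        cases.append(
            CaseRecord(
                case_id=new_id("ux"),
                genotyped=True,
                ihc=_ihc({"MSH2", "MSH6"}),
                somatic=SomaticProfile(
                    variants=[VariantRecord("MSH2", "c.sim_single_hit",
                                            origin=Origin.SOMATIC, truncating=True)],
                    msings_score=score, msi_call=call_msi(score),
                    msh2_methylation="negative",
                ),
                true_etiology="unexplained",
                **_demographics("unexplained", rng),
            )
        )

    for _ in range(counts.get("pMMR", 0)):
        biopsy = rng.random() < 0.12
        cases.append(
            CaseRecord(
                case_id=new_id("p"),
                specimen=Specimen.BIOPSY if biopsy else Specimen.RESECTION,
                genotyped=bool(rng.random() < config.genotyped_fraction_normal_ihc),
                ihc=_ihc(set(), panel={"MSH6", "PMS2"} if biopsy else None),
                true_etiology="pMMR",
                **_demographics("pMMR", rng),
            )
        )

    return cases


# ---------------------------------------------------------------------------
# Population genotype/phenotype simulation
# ---------------------------------------------------------------------------


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Simulate carrier genotypes and cancer phenotypes for a population.

    Each individual draws carrier status per mutation (Bernoulli at the
    carrier frequency) and, per cancer type, an affection status from a
    logistic model whose carrier/non-carrier odds ratio equals the configured
    truth; the intercept is the logit of the sex-specific baseline risk.
    Cancers without a baseline for a sex (e.g. endometrial in males) are
    structurally unaffected.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    out: dict[str, np.ndarray] = {}
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    out["sex"] = sex
    carriers = {
        mid: (rng.random(n) < f).astype(np.int8)
        for mid, f in config.carrier_freq.items()
    }
    for mid, carrier in carriers.items():
        out[f"carrier_{mid}"] = carrier
    for cancer, per_sex in config.cancer_baseline_risk.items():
        eta = np.full(n, -np.inf)
        for s, baseline in per_sex.items():
            eta[sex == s] = logit(baseline)
        for mid, per_cancer in config.true_or.items():
            if cancer in per_cancer and mid in carriers:
                eta = eta + np.log(per_cancer[cancer]) * carriers[mid]
        p = expit(eta)
        out[f"affected_{cancer}"] = (rng.random(n) < p).astype(np.int8)
    df = pd.DataFrame(out)
    df.insert(0, "individual_id", [f"i{j:07d}" for j in range(n)])
    return df


def simulate_imputed_direct(
    carrier: np.ndarray,
    error_rate: float,
    missing_rate: float,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """An (imputed, direct) genotype-call pair for the concordance metric.

    The imputed vector flips truth with probability ``error_rate``; the
    direct vector reproduces truth but is missing (NaN) with probability
    ``missing_rate``.
    """
    rng = np.random.default_rng(seed)
    carrier = np.asarray(carrier, dtype=float)
    flips = rng.random(carrier.size) < error_rate
    imputed = np.where(flips, 1.0 - carrier, carrier)
    direct = carrier.copy()
    direct[rng.random(carrier.size) < missing_rate] = np.nan
    return imputed, direct
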