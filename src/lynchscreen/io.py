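"""Cohort TSV serialization: one row per case, variants in a sidecar table."""
from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd

from .records import (
    BrafIHC,
    CaseRecord,
    IHCResult,
    Loh,
    MethylationCall,
    MethylationResult,
    Origin,
    SomaticProfile,
    Specimen,
    Stain,
    VariantRecord,
    MMR_GENES,
)

SCHEMA_VERSION = "1"


def cohort_to_frames(cohort: list[CaseRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a cohort into (cases, variants) DataFrames."""
    case_rows = []
    var_rows = []
    for c in cohort:
        row: dict = {
            "case_id": c.case_id,
            "sex": c.sex,
            "age_dx": c.age_dx,
            "location": c.location,
            "stage": c.stage,
            "specimen": c.specimen.value,
            "genotyped": int(c.genotyped),
            "braf_ihc": c.braf_ihc.value,
            "true_etiology": c.true_etiology or "",
        }
        for g in MMR_GENES:
            stain = c.ihc.stain(g) if c.ihc else Stain.NOT_DONE
            row[f"ihc_{g}"] = stain.value
            pct = c.ihc.percent_positive_cells.get(g) if c.ihc else None
            row[f"pct_{g}"] = "" if pct is None else pct
        row["meth_cpgs"] = (
            ";".join(repr(x) for x in c.methylation.cpg_levels) if c.methylation else ""
        )
        row["meth_done"] = int(c.methylation is not None)
        som = c.somatic
        row["som_tested"] = int(som is not None)
        row["som_loh"] = som.loh.value if som else ""
        row["som_msings"] = "" if som is None or som.msings_score is None else som.msings_score
        row["som_msh2_methylation"] = som.msh2_methylation if som else ""
        row["som_failed"] = int(bool(som and som.failed))
        case_rows.append(row)
        for v in c.germline_variants:
            var_rows.append(_variant_row(c.case_id, v))
        if som is not None:
            for v in som.variants:
                var_rows.append(_variant_row(c.case_id, v))
    cases = pd.DataFrame(case_rows)
    variants = pd.DataFrame(
        var_rows,
        columns=["case_id", "gene", "hgvs_c", "hgvs_p", "origin",
                 "path_class", "truncating", "vaf", "designated"],
    )
    return cases, variants


def _variant_row(case_id: str, v: VariantRecord) -> dict:
    return {
        "case_id": case_id,
        "gene": v.gene,
        "hgvs_c": v.hgvs_c,
        "hgvs_p": v.hgvs_p,
        "origin": v.origin.value,
        "path_class": v.path_class,
        "truncating": int(v.truncating),
        "vaf": "" if v.vaf is None else v.vaf,
        "designated": int(v.designated_pathogenic),
    }


def write_cohort(cohort: list[CaseRecord], cases_path: str | Path,
                 variants_path: Optional[str | Path] = None) -> None:
    cases_path = Path(cases_path)
    if variants_path is None:
        variants_path = cases_path.with_suffix(".variants.tsv")
    cases, variants = cohort_to_frames(cohort)
    for path, df in ((cases_path, cases), (Path(variants_path), variants)):
        with open(path, "w") as fh:
            fh.write(f"#schema_version={SCHEMA_VERSION}\n")
            df.to_csv(fh, sep="\t", index=False)


def read_cohort(cases_path: str | Path,
                variants_path: Optional[str | Path] = None) -> list[CaseRecord]:
    cases_path = Path(cases_path)
    if variants_path is None:
        variants_path = cases_path.with_suffix(".variants.tsv")
    cases = pd.read_csv(cases_path, sep="\t", comment="#",
                        dtype={"case_id": str}, keep_default_na=False)
    variants = pd.read_csv(variants_path, sep="\t", comment="#",
                           dtype={"case_id": str}, keep_default_na=False)
    by_case: dict[str, list[VariantRecord]] = {}
    for _, r in variants.iterrows():
        by_case.setdefault(str(r["case_id"]), []).append(
            VariantRecord(
                gene=r["gene"],
                hgvs_c=r["hgvs_c"],
                hgvs_p=r["hgvs_p"],
                origin=Origin(r["origin"]),
                path_class=str(r["path_class"]),
                truncating=bool(int(r["truncating"])),
                vaf=None if r["vaf"] == "" else float(r["vaf"]),
                designated_pathogenic=bool(int(r["designated"])),
            )
        )
    out: list[CaseRecord] = []
    for _, r in cases.iterrows():
        cid = str(r["case_id"])
        stains = {}
        pct = {}
        for g in MMR_GENES:
            stains[g] = Stain(r[f"ihc_{g}"])
            if r[f"pct_{g}"] != "":
                pct[g] = float(r[f"pct_{g}"])
        ihc = IHCResult(stains=stains, percent_positive_cells=pct)
        methylation = None
        if int(r["meth_done"]):
            levels = [float(x) for x in str(r["meth_cpgs"]).split(";") if x != ""]
            if levels:
                from .screening import call_methylation

                methylation = call_methylation(levels)
            else:
                methylation = MethylationResult([], None, MethylationCall.FAILED)
        case_vars = by_case.get(cid, [])
        germline = [v for v in case_vars if v.origin is Origin.GERMLINE]
        som_vars = [v for v in case_vars if v.origin is Origin.SOMATIC]
        somatic = None
        if int(r["som_tested"]):
            score = None if r["som_msings"] == "" else float(r["som_msings"])
            msi = None
            if score is not None:
                from .somatic import call_msi

                msi = call_msi(score)
            somatic = SomaticProfile(
                variants=som_vars,
                loh=Loh(r["som_loh"]) if r["som_loh"] != "" else Loh.NONE,
                msings_score=score,
                msi_call=msi,
                msh2_methylation=r["som_msh2_methylation"] or "not_done",
                failed=bool(int(r["som_failed"])),
            )
        out.append(
            CaseRecord(
                case_id=cid,
                sex=r["sex"],
                age_dx=float(r["age_dx"]),
                location=r["location"],
                stage=str(r["stage"]),
                specimen=Specimen(r["specimen"]),
                genotyped=bool(int(r["genotyped"])),
                ihc=ihc,
                methylation=methylation,
                braf_ihc=BrafIHC(r["braf_ihc"]),
                germline_variants=germline,
                somatic=somatic,
                true_etiology=r["true_etiology"] or None,
            )
        )
    return out


def write_calls(calls, path: str | Path) -> None:
    rows = [
        {"case_id": c.case_id, "etiology": c.label.value,
         "evidence": "|".join(c.evidence_chain)}
        for c in calls
    ]
    with open(path, "w") as fh:
        fh.write(f"#schema_version={SCHEMA_VERSION}\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
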