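"""Synthetic cohort/population generation, fixture marginals, serialization."""
import numpy as np
import pytest
from scipy.special import expit, logit

from lynchscreen.cohort import (
    CohortConfig,
    PopulationConfig,
    fixture_cohort,
    generate_cohort,
    generate_population,
    simulate_imputed_direct,
)
from lynchscreen.io import cohort_to_frames, read_cohort, write_cohort
from lynchscreen.pipeline import classify_cohort
from lynchscreen.records import Etiology
from lynchscreen.tables import LS_MUTATIONS


class TestFixtureMarginals:
    def test_cohort_size_and_etiology_totals(self, cohort, calls):
        """Etiology column totals of the patient-characteristics table."""
        assert len(cohort) == 1182
        merged = {}
        for c in calls:
            key = {"LS_sporadic_tumour": "LS",
                   "possibly_double_somatic": "double_somatic"}.get(
                c.label.value, c.label.value)
            merged[key] = merged.get(key, 0) + 1
        assert merged == {"pMMR": 1044, "LS": 27, "MLH1_hm": 90,
                          "double_somatic": 16, "unexplained": 5}

    def test_genotyped_count(self, cohort):
        assert sum(1 for c in cohort if c.genotyped) == 953

    def test_abnormal_ihc_count(self, cohort):
        from lynchscreen.records import ABNORMAL_PATTERNS
        from lynchscreen.screening import loss_pattern

        assert sum(1 for c in cohort
                   if loss_pattern(c.ihc) in ABNORMAL_PATTERNS) == 132

    def test_per_mutation_ls_counts(self, cohort):
        """Mutation catalogue counts: carriers per mutation in the CRC cohort."""
        by_mutation: dict[str, int] = {}
        for c in cohort:
            for v in c.germline_variants:
                key = (v.gene, v.hgvs_c)
                by_mutation[key] = by_mutation.get(key, 0) + 1
        for mid, expected in [("PMS2_P246fs", 12), ("MSH6_L585P", 9),
                              ("MLH1_translocation", 1), ("MSH6_V282fs", 1),
                              ("MSH6_F1088fs", 1), ("MSH6_R1172fs", 1),
                              ("PMS2_N71fs", 1), ("PMS2_E705K", 1)]:
            m = LS_MUTATIONS[mid]
            assert by_mutation.get((m.gene, m.hgvs_c), 0) == expected, mid

    def test_normal_ihc_ls_composition(self, cohort, calls):
        """Six normal-IHC LS cases: 3 weak MSH6 with second hits, 2 sporadic
        tumours in frameshift carriers, 1 untested carrier."""
        from lynchscreen.records import ABNORMAL_PATTERNS, LS_LABELS
        from lynchscreen.screening import loss_pattern

        normal_ls = [c for c, call in zip(cohort, calls)
                     if call.label in LS_LABELS
                     and loss_pattern(c.ihc) not in ABNORMAL_PATTERNS]
        assert len(normal_ls) == 6
        weak = [c for c in normal_ls if c.ihc.weak_proteins == ["MSH6"]]
        assert len(weak) == 3
        assert all(c.somatic is not None and c.somatic.somatic_variants("MSH6")
                   for c in weak)
        untested = [c for c in normal_ls if c.somatic is None]
        assert len(untested) == 1

    def test_methylation_positive_or_braf_inferred_count(self, cohort, calls):
        from lynchscreen.records import LossPattern
        from lynchscreen.screening import loss_pattern

        n = sum(1 for c, call in zip(cohort, calls)
                if call.label is Etiology.MLH1_HM
                and loss_pattern(c.ihc) is LossPattern.MLH1_PMS2)
        assert n == 90

    def test_fixture_is_deterministic(self):
        a, va = cohort_to_frames(fixture_cohort())
        b, vb = cohort_to_frames(fixture_cohort())
        assert a.equals(b) and va.equals(vb)


class TestGenerateCohort:
    def test_exact_mode_reproduces_published_counts(self):
        cohort = generate_cohort(CohortConfig(n_cases=1182, exact=True, seed=0))
        truth = {}
        for c in cohort:
            truth[c.true_etiology] = truth.get(c.true_etiology, 0) + 1
        assert truth == {"pMMR": 1044, "LS": 27, "MLH1_hm": 90,
                         "double_somatic": 16, "unexplained": 5}

    def test_round_trip_classification_recovers_mixture(self):
        cohort = generate_cohort(CohortConfig(n_cases=600, exact=True, seed=11))
        merged = {}
        for call in classify_cohort(cohort):
            key = {"LS_sporadic_tumour": "LS",
                   "possibly_double_somatic": "double_somatic"}.get(
                call.label.value, call.label.value)
            merged[key] = merged.get(key, 0) + 1
        truth = {}
        for c in cohort:
            truth[c.true_etiology] = truth.get(c.true_etiology, 0) + 1
        assert merged == truth

    def test_empty_cohort(self):
        assert generate_cohort(CohortConfig(n_cases=0)) == []

    def test_seed_determinism(self):
        a, va = cohort_to_frames(generate_cohort(CohortConfig(n_cases=200, seed=7)))
        b, vb = cohort_to_frames(generate_cohort(CohortConfig(n_cases=200, seed=7)))
        assert a.equals(b) and va.equals(vb)

    def test_invalid_mixture_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(etiology_mix={"pMMR": 0.5, "LS": 0.4})

    def test_ls_cases_carry_exactly_one_qualifying_mutation(self):
        cohort = generate_cohort(CohortConfig(n_cases=1182, exact=True, seed=2))
        for c in cohort:
            if c.true_etiology == "LS":
                assert len(c.germline_variants) == 1
            elif c.true_etiology == "pMMR":
                assert not c.germline_variants


class TestGeneratePopulation:
    CONFIG = dict(
        carrier_freq={"m1": 0.00234},
        cancer_baseline_risk={"crc": {"male": 0.05, "female": 0.04}},
    )

    def test_null_model_equal_carrier_fractions(self):
        cfg = PopulationConfig(n_individuals=120_000, seed=1,
                               true_or={"m1": {"crc": 1.0}}, **self.CONFIG)
        df = generate_population(cfg)
        cases = df[df["affected_crc"] == 1]
        controls = df[df["affected_crc"] == 0]
        f_case = cases["carrier_m1"].mean()
        f_ctrl = controls["carrier_m1"].mean()
        se = np.sqrt(0.00234 / len(cases))
        assert abs(f_case - f_ctrl) < 4 * se

    def test_zero_carrier_frequency(self):
        cfg = PopulationConfig(n_individuals=5000, seed=2,
                               carrier_freq={"m1": 0.0},
                               cancer_baseline_risk={"crc": {"male": 0.05,
                                                             "female": 0.04}},
                               true_or={"m1": {"crc": 3.0}})
        df = generate_population(cfg)
        assert int(df["carrier_m1"].sum()) == 0

    def test_case_carrier_fraction_matches_closed_form(self):
        """Carrier fraction among cases vs the closed-form expectation
        P(carrier|case) = f*p1 / (f*p1 + (1-f)*p0) under the logistic model."""
        f, or_true, k = 0.00234, 3.6, 0.05
        cfg = PopulationConfig(
            n_individuals=240_000, seed=3,
            carrier_freq={"m1": f},
            cancer_baseline_risk={"crc": {"male": k, "female": k}},
            true_or={"m1": {"crc": or_true}},
        )
        df = generate_population(cfg)
        p0 = expit(logit(k))
        p1 = expit(logit(k) + np.log(or_true))
        expected = f * p1 / (f * p1 + (1 - f) * p0)
        cases = df[df["affected_crc"] == 1]
        observed = cases["carrier_m1"].mean()
        se = np.sqrt(expected * (1 - expected) / len(cases))
        assert abs(observed - expected) < 4 * se

    def test_sexless_baseline_structurally_unaffected(self):
        cfg = PopulationConfig(
            n_individuals=2000, seed=4,
            carrier_freq={"m1": 0.5},
            cancer_baseline_risk={"endometrial": {"female": 0.03}},
            true_or={"m1": {"endometrial": 5.0}},
        )
        df = generate_population(cfg)
        males = df[df["sex"] == "male"]
        assert int(males["affected_endometrial"].sum()) == 0


class TestSerialization:
    def test_cohort_round_trip(self, cohort, tmp_path):
        path = tmp_path / "cohort.tsv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == len(cohort)
        a, va = cohort_to_frames(cohort)
        b, vb = cohort_to_frames(back)
        assert a.equals(b)
        assert va.equals(vb)
        # classification is invariant under serialization
        la = [c.label for c in classify_cohort(cohort)]
        lb = [c.label for c in classify_cohort(back)]
        assert la == lb

    def test_schema_version_emitted(self, tmp_path):
        path = tmp_path / "c.tsv"
        write_cohort(fixture_cohort()[:3], path)
        assert path.read_text().startswith("#schema_version=")


def test_imputed_direct_concordance_pair():
    rng_truth = np.random.default_rng(5)
    carrier = (rng_truth.random(2000) < 0.01).astype(float)
    imputed, direct = simulate_imputed_direct(carrier, error_rate=0.01,
                                              missing_rate=0.1, seed=6)
    from lynchscreen.association import imputation_concordance

    conc = imputation_concordance(imputed, direct)
    assert 0.97 <= conc <= 1.0
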