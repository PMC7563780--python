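"""Resistance rules: clause semantics, 2x2 metrics, RR algebra."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from melcohort.models import ClinicalRecord, Cohort, PanelDefinition, VariantRecord
from melcohort.predictor import (
    PredictorPerformance,
    ResistanceRule,
    apply_rule,
    evaluate_rule,
    response_frequencies,
    round_half_up,
    standard_rules,
)

UNION = ResistanceRule(frozenset({"EGFR", "PTEN", "TP53"}), name="union")
COMBO = ResistanceRule(
    frozenset({"EGFR", "PTEN", "TP53", "CDKN2A"}), combination_k=2, name="combo"
)
PRETREAT = ResistanceRule(
    frozenset({"EGFR", "PTEN", "TP53"}), require_pretreatment=True, name="pre"
)


class TestApplyRule:
    def test_single_gene_fires_union(self):
        assert apply_rule(UNION, {"PTEN"}, pretreated=False)

    def test_combination_needs_two_distinct_genes(self):
        assert not apply_rule(COMBO, {"CDKN2A"}, pretreated=False)
        assert apply_rule(COMBO, {"CDKN2A", "PTEN"}, pretreated=False)

    def test_no_alterations_no_pretreatment_never_fires(self):
        for rule in (UNION, COMBO, PRETREAT):
            assert not apply_rule(rule, set(), pretreated=False)

    def test_pretreatment_clause_is_an_or(self):
        assert apply_rule(PRETREAT, set(), pretreated=True)
        assert not apply_rule(UNION, set(), pretreated=True)

    def test_irrelevant_genes_do_not_fire(self):
        assert not apply_rule(UNION, {"BRAF", "MYC"}, pretreated=False)

    def test_invalid_rules_rejected(self):
        with pytest.raises(ValueError):
            ResistanceRule(frozenset(), require_pretreatment=False)
        with pytest.raises(ValueError):
            ResistanceRule(frozenset({"PTEN"}), combination_k=2)


class TestPerformanceMetrics:
    def test_published_full_rule_table(self):
        perf = PredictorPerformance(rule=PRETREAT, a=28, b=6, c=17, d=24)
        assert round_half_up(100 * perf.sensitivity, 1) == 62.2
        assert round_half_up(100 * perf.specificity, 1) == 80.0
        assert round_half_up(perf.relative_risk, 2) == 1.99

    def test_published_combination_table(self):
        perf = PredictorPerformance(rule=COMBO, a=9, b=0, c=36, d=30)
        assert perf.specificity == 1.0
        assert round_half_up(100 * perf.sensitivity, 1) == 20.0
        assert round_half_up(perf.relative_risk, 2) == 1.83
        assert perf.ppv == 1.0

    def test_rule_firing_for_everyone_degenerates(self):
        perf = PredictorPerformance(rule=UNION, a=45, b=30, c=0, d=0)
        assert perf.specificity == 0.0
        assert perf.rr_undefined and perf.relative_risk is None

    def test_rr_undefined_when_no_negative_progressors(self):
        perf = PredictorPerformance(rule=UNION, a=5, b=5, c=0, d=10)
        assert perf.rr_undefined

    @given(
        a=st.integers(1, 30), b=st.integers(1, 30),
        c=st.integers(1, 30), d=st.integers(1, 30),
    )
    def test_rr_algebra(self, a, b, c, d):
        perf = PredictorPerformance(rule=UNION, a=a, b=b, c=c, d=d)
        assert perf.relative_risk * (c / (c + d)) == pytest.approx(a / (a + b))

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    def test_fisher_matches_brute_force(self, a, b, c, d):
        from test_exact import brute_force_fisher

        if a + b == 0 or c + d == 0:
            return
        perf = PredictorPerformance(rule=UNION, a=a, b=b, c=c, d=d)
        one, two = brute_force_fisher(a, b, c, d)
        assert perf.fisher_p == pytest.approx(two, abs=1e-12)
        assert perf.fisher_p_one_sided == pytest.approx(one, abs=1e-12)


def _tiny_ici_cohort():
    """Four ICI patients + one untreated; PTEN deletion in the progressor."""
    panel = PanelDefinition(
        genes=frozenset({"PTEN", "EGFR", "TP53", "CDKN2A"}), target_size_mb=1.0,
        tumor_genes=frozenset({"PTEN", "EGFR", "TP53", "CDKN2A"}),
    )
    from melcohort.models import CNVEvent

    clinical = [
        ClinicalRecord("S1", "cutaneous", "combined", "PD", False),
        ClinicalRecord("S2", "cutaneous", "combined", "PD", True),
        ClinicalRecord("S3", "cutaneous", "anti_pd1", "SD", False),
        ClinicalRecord("S4", "cutaneous", "combined", "PR", False),
        ClinicalRecord("S5", "cutaneous", "none", "not_applicable", False),
    ]
    cnvs = [
        CNVEvent("S1", "PTEN", "deletion", True),
        CNVEvent("S5", "EGFR", "amplification", True),  # untreated: must not count
    ]
    return Cohort(clinical=clinical, variants=[], cnvs=cnvs, panel=panel)


class TestEvaluateRule:
    def test_only_ici_patients_enter_the_table(self):
        perf = evaluate_rule(_tiny_ici_cohort(), UNION)
        assert perf.n == 4
        assert (perf.a, perf.b, perf.c, perf.d) == (1, 0, 1, 2)

    def test_pretreatment_clause_adds_positives(self):
        perf = evaluate_rule(_tiny_ici_cohort(), PRETREAT)
        assert (perf.a, perf.b, perf.c, perf.d) == (2, 0, 0, 2)

    def test_outcome_transposition_identity(self, paper_cohort):
        """Scoring disease control as the positive outcome permutes the table
        to (b, a, d, c)."""
        for rule in standard_rules().values():
            pd_perf = evaluate_rule(paper_cohort, rule, positive_outcome="PD")
            # complementary outcome: SD+PR treated as a single non-PD class
            flipped = PredictorPerformance(
                rule=rule, a=pd_perf.b, b=pd_perf.a, c=pd_perf.d, d=pd_perf.c
            )
            assert flipped.sensitivity == pytest.approx(
                1 - pd_perf.specificity if pd_perf.b + pd_perf.d else float("nan")
            )
            assert flipped.fisher_p == pytest.approx(pd_perf.fisher_p, rel=1e-9)

    def test_no_ici_patients_is_an_error(self):
        cohort = _tiny_ici_cohort()
        cohort.clinical = [c for c in cohort.clinical if not c.ici_treated]
        cohort.variants, cohort.cnvs = [], []
        with pytest.raises(ValueError, match="ICI"):
            evaluate_rule(cohort, UNION)


class TestResponseFrequencies:
    def test_reference_cohort_gene_frequencies(self, paper_cohort):
        df = response_frequencies(paper_cohort, ["EGFR", "TP53", "PTEN"])
        egfr = df.loc["EGFR"]
        assert (egfr.pd_count, egfr.pd_total) == (6, 45)
        assert (egfr.control_count, egfr.control_total) == (0, 30)
        tp53 = df.loc["TP53"]
        assert (tp53.pd_count, tp53.control_count) == (6, 1)
        pten = df.loc["PTEN"]
        assert pten.pd_freq == pytest.approx(11 / 45)
        assert pten.control_freq == pytest.approx(3 / 30)

    def test_absent_gene_reports_zero_over_denominators(self, paper_cohort):
        df = response_frequencies(paper_cohort, ["ALK"])
        row = df.loc["ALK"]
        assert (row.pd_count, row.pd_total) == (0, 45)
        assert (row.control_count, row.control_total) == (0, 30)
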