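"""Stochastic generator: determinism, degenerate configs, parameter recovery."""

import math
from collections import Counter

import numpy as np
import pytest

from melcohort.classify import class_counts
from melcohort.io import alteration_matrix, write_cohort
from melcohort.models import ConfigError
from melcohort.predictor import apply_rule, standard_rules
from melcohort.simulate import SimulationConfig, simulate_cohort
from melcohort.tmb import summarize_burden


def _zeroed_gene_model():
    cfg = SimulationConfig()
    return {
        gene: (kind, direction, (0.0,) * 5)
        for gene, (kind, direction, _p) in cfg.gene_model.items()
    }


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        for sub in ("a", "b"):
            cohort = simulate_cohort(SimulationConfig(n_patients=120, seed=99))
            write_cohort(cohort, tmp_path / sub)
        for name in ("clinical.tsv", "variants.tsv", "cnv.tsv", "panel.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self):
        a = simulate_cohort(SimulationConfig(n_patients=120, seed=1))
        b = simulate_cohort(SimulationConfig(n_patients=120, seed=2))
        assert [c.subtype for c in a.clinical] != [c.subtype for c in b.clinical]


class TestDegenerateConfigs:
    def test_zero_alteration_probabilities_give_all_twt(self):
        cfg = SimulationConfig(n_patients=60, seed=5, gene_model=_zeroed_gene_model())
        cohort = simulate_cohort(cfg)
        counts = class_counts(cohort)
        assert counts == {"BRAF": 0, "RAS": 0, "NF1": 0, "TWT": 60}
        mat = alteration_matrix(cohort)
        rule = standard_rules()["genes_or_pretreated"]
        clin = cohort.clinical_by_id()
        for sid in mat.index:
            genes = set(mat.columns[mat.loc[sid]])
            assert not apply_rule(rule, genes, clin[sid].braf_meki_pretreated)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            simulate_cohort(SimulationConfig(n_patients=10, seed=0, p_ici=1.5))
        with pytest.raises(ConfigError):
            simulate_cohort(
                SimulationConfig(n_patients=10, seed=0, subtype_proportions=(1, 0, 0, 0, 0.5))
            )


def _se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestParameterRecovery:
    """All checks run on one 10,000-patient cohort (session fixture)."""

    def test_subtype_proportions(self, big_cohort):
        counts = Counter(c.subtype for c in big_cohort.clinical)
        n = big_cohort.n_patients
        for subtype, p in zip(
            ("cutaneous", "acral", "mucosal", "uveal", "occult"),
            SimulationConfig().subtype_proportions,
        ):
            assert abs(counts[subtype] / n - p) <= 3 * _se(p, n)

    def test_gene_frequencies_by_subtype(self, big_cohort):
        cfg = SimulationConfig()
        mat = alteration_matrix(big_cohort)
        subtype_of = {c.sample_id: c.subtype for c in big_cohort.clinical}
        order = ("cutaneous", "acral", "mucosal", "uveal", "occult")
        for gene in ("BRAF", "NRAS", "PTEN", "CDKN2A", "MYC"):
            _kind, _dir, probs = cfg.gene_model[gene]
            for s_idx, subtype in enumerate(order):
                ids = [s for s in mat.index if subtype_of[s] == subtype]
                p = probs[s_idx]
                freq = mat.loc[ids, gene].mean()
                assert abs(freq - p) <= max(3 * _se(p, len(ids)), 1e-9), (gene, subtype)

    def test_uveal_gnaq_gna11_exclusive(self, big_cohort):
        mat = alteration_matrix(big_cohort)
        uveal = [c.sample_id for c in big_cohort.clinical if c.subtype == "uveal"]
        assert not (mat.loc[uveal, "GNAQ"] & mat.loc[uveal, "GNA11"]).any()

    def test_cutaneous_tmb_median_recovered(self, big_cohort):
        median = summarize_burden(big_cohort, "tmb").loc["cutaneous", "median"]
        assert median == pytest.approx(9.4, rel=0.05)

    def test_conditional_response_model_recovered(self, big_cohort):
        cfg = SimulationConfig()
        rule = cfg.response_rule
        mat = alteration_matrix(big_cohort)
        clin = big_cohort.clinical_by_id()
        pos = {"pd": 0, "n": 0}
        neg = {"pd": 0, "n": 0}
        for sid in mat.index:
            rec = clin[sid]
            if not rec.ici_treated:
                continue
            fired = apply_rule(rule, set(mat.columns[mat.loc[sid]]), rec.braf_meki_pretreated)
            bucket = pos if fired else neg
            bucket["n"] += 1
            bucket["pd"] += rec.recist_response == "PD"
        p_pos = pos["pd"] / pos["n"]
        p_neg = neg["pd"] / neg["n"]
        assert abs(p_pos - cfg.p_pd_given_positive) <= 3 * _se(cfg.p_pd_given_positive, pos["n"])
        assert abs(p_neg - cfg.p_pd_given_negative) <= 3 * _se(cfg.p_pd_given_negative, neg["n"])

    def test_realised_relative_risk_near_configured_odds(self, big_cohort):
        from melcohort.predictor import evaluate_rule

        perf = evaluate_rule(big_cohort, standard_rules()["genes_or_pretreated"])
        expected_rr = (28 / 34) / (17 / 41)
        assert perf.relative_risk == pytest.approx(expected_rr, abs=0.1)
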