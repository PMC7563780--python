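"""Rule-based predictor of resistance to immune checkpoint inhibition.

A resistance rule is a boolean clause over a patient's driver alterations and
their therapy history: it fires when at least ``combination_k`` distinct
genes of its gene set are altered (k = 1 gives plain union semantics), OR —
if ``require_pretreatment`` is set — when the patient received BRAF/MEK
inhibitor therapy before starting ICI. "Altered" means any driver alteration,
small variant or copy-number event (resistance mechanisms span PTEN
deletions, EGFR amplifications and TP53 point mutations alike).

Rules are evaluated only over ICI-treated patients. The positive outcome is
progressive disease (PD) at the first staging versus disease control
(SD + PR); performance is summarised as a 2x2 table with sensitivity,
specificity, predictive values, the relative risk of PD given a positive
rule, and Fisher's exact p. Rates are computed exactly and rounded
(half-up: RR to 2 decimals, percentages to 1) only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .exact import fisher_one_sided_enrichment, fisher_two_sided
from .io import alteration_matrix
from .models import Cohort

__all__ = [
    "ResistanceRule",
    "PredictorPerformance",
    "standard_rules",
    "apply_rule",
    "evaluate_rule",
    "response_frequencies",
    "round_half_up",
]

#: genes with prior evidence for ICI resistance, used by the standard rules
RESISTANCE_GENES = ("EGFR", "PTEN", "TP53")
EXTENDED_RESISTANCE_GENES = ("EGFR", "PTEN", "TP53", "CDKN2A")


@dataclass(frozen=True)
class ResistanceRule:
    """Boolean alteration rule over a patient row of the alteration matrix."""

    gene_set: frozenset[str]
    combination_k: int = 1
    require_pretreatment: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        if not self.gene_set and not self.require_pretreatment:
            raise ValueError("rule needs a non-empty gene_set or require_pretreatment")
        if self.gene_set and not (1 <= self.combination_k <= len(self.gene_set)):
            raise ValueError("combination_k must be in [1, |gene_set|]")


def standard_rules() -> dict[str, ResistanceRule]:
    """The four predictor variants evaluated on the cohort.

    * ``genes_only`` — alteration in any of EGFR/PTEN/TP53.
    * ``genes_or_pretreated`` — the same union OR BRAF/MEKi pretreatment.
    * ``genes_cdkn2a_or_pretreated`` — union extended by CDKN2A OR pretreatment.
    * ``combination_k2`` — alterations in >= 2 distinct genes of
      EGFR/PTEN/TP53/CDKN2A (the maximally specific variant).
    """
    return {
        "genes_only": ResistanceRule(
            frozenset(RESISTANCE_GENES), name="genes_only"
        ),
        "genes_or_pretreated": ResistanceRule(
            frozenset(RESISTANCE_GENES), require_pretreatment=True, name="genes_or_pretreated"
        ),
        "genes_cdkn2a_or_pretreated": ResistanceRule(
            frozenset(EXTENDED_RESISTANCE_GENES),
            require_pretreatment=True,
            name="genes_cdkn2a_or_pretreated",
        ),
        "combination_k2": ResistanceRule(
            frozenset(EXTENDED_RESISTANCE_GENES), combination_k=2, name="combination_k2"
        ),
    }


def apply_rule(rule: ResistanceRule, altered_genes: set[str] | frozenset[str], pretreated: bool) -> bool:
    """True iff >= combination_k distinct rule genes are altered, or the
    pretreatment clause applies."""
    n_hit = len(rule.gene_set & set(altered_genes))
    if rule.gene_set and n_hit >= rule.combination_k:
        return True
    return rule.require_pretreatment and pretreated


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (presentation rounding for rates and RR)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PredictorPerformance:
    """2x2 evaluation of a rule over the ICI-treated cohort.

    a = rule-positive with PD, b = rule-positive with SD/PR,
    c = rule-negative with PD, d = rule-negative with SD/PR.
    ``relative_risk`` is None (with ``rr_undefined`` set) when either rule
    stratum is empty or no rule-negative patient progressed.
    """

    rule: ResistanceRule
    a: int
    b: int
    c: int
    d: int
    fisher_p: float = field(init=False, default=0.0)
    fisher_p_one_sided: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fisher_p", fisher_two_sided(self.a, self.b, self.c, self.d))
        object.__setattr__(
            self, "fisher_p_one_sided", fisher_one_sided_enrichment(self.a, self.b, self.c, self.d)
        )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def sensitivity(self) -> float:
        return self.a / (self.a + self.c) if self.a + self.c else float("nan")

    @property
    def specificity(self) -> float:
        return self.d / (self.b + self.d) if self.b + self.d else float("nan")

    @property
    def ppv(self) -> float:
        return self.a / (self.a + self.b) if self.a + self.b else float("nan")

    @property
    def npv(self) -> float:
        return self.d / (self.c + self.d) if self.c + self.d else float("nan")

    @property
    def rr_undefined(self) -> bool:
        return self.a + self.b == 0 or self.c + self.d == 0 or self.c == 0

    @property
    def relative_risk(self) -> float | None:
        if self.rr_undefined:
            return None
        return (self.a / (self.a + self.b)) / (self.c / (self.c + self.d))

    def as_dict(self) -> dict:
        """JSON-friendly summary: raw table, exact rates, presentation rounding."""
        rr = self.relative_risk
        return {
            "rule": {
                "name": self.rule.name,
                "gene_set": sorted(self.rule.gene_set),
                "combination_k": self.rule.combination_k,
                "require_pretreatment": self.rule.require_pretreatment,
            },
            "table": {"a": self.a, "b": self.b, "c": self.c, "d": self.d},
            "n": self.n,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "relative_risk": rr,
            "rr_undefined": self.rr_undefined,
            "fisher_p": self.fisher_p,
            "fisher_p_one_sided": self.fisher_p_one_sided,
            "display": {
                "sensitivity_pct": round_half_up(100 * self.sensitivity, 1),
                "specificity_pct": round_half_up(100 * self.specificity, 1),
                "ppv_pct": round_half_up(100 * self.ppv, 1),
                "npv_pct": round_half_up(100 * self.npv, 1),
                "relative_risk": None if rr is None else round_half_up(rr, 2),
            },
        }


def _ici_frame(cohort: Cohort) -> pd.DataFrame:
    """Per-ICI-patient frame: altered gene sets, pretreatment flag, PD flag."""
    ici = [c for c in cohort.clinical if c.ici_treated]
    if not ici:
        raise ValueError("no ICI-treated patients in cohort")
    bad = [c.sample_id for c in ici if c.recist_response not in ("PD", "SD", "PR")]
    if bad:
        raise ValueError(f"ICI-treated patients without RECIST response: {bad}")
    mat = alteration_matrix(cohort, include_cnv=True, drivers_only=True)
    rows = []
    for c in ici:
        genes = frozenset(mat.columns[mat.loc[c.sample_id]])
        rows.append(
            {
                "sample_id": c.sample_id,
                "altered": genes,
                "pretreated": c.braf_meki_pretreated,
                "response": c.recist_response,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def evaluate_rule(
    cohort: Cohort, rule: ResistanceRule, positive_outcome: str = "PD"
) -> PredictorPerformance:
    """Evaluate a rule over exactly the ICI-treated patients of the cohort.

    ``positive_outcome`` may be "PD" (resistance, default) or one of the
    control categories; the complement of the positive outcome forms the
    second column of the table.
    """
    frame = _ici_frame(cohort)
    fired = frame.apply(lambda r: apply_rule(rule, r["altered"], r["pretreated"]), axis=1)
    positive = frame["response"] == positive_outcome
    a = int((fired & positive).sum())
    b = int((fired & ~positive).sum())
    c = int((~fired & positive).sum())
    d = int((~fired & ~positive).sum())
    return PredictorPerformance(rule=rule, a=a, b=b, c=c, d=d)


def response_frequencies(cohort: Cohort, genes: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Per-gene driver-alteration frequency in PD versus SD+PR patients.

    Fractions keep their numerator/denominator; a gene absent from the
    cohort reports 0 / n in both groups.
    """
    frame = _ici_frame(cohort)
    pd_mask = frame["response"] == "PD"
    n_pd = int(pd_mask.sum())
    n_ctrl = len(frame) - n_pd
    rows = []
    for gene in genes:
        has = frame["altered"].apply(lambda s: gene in s)
        k_pd = int((has & pd_mask).sum())
        k_ctrl = int((has & ~pd_mask).sum())
        rows.append(
            {
                "gene": gene,
                "pd_count": k_pd,
                "pd_total": n_pd,
                "pd_freq": k_pd / n_pd if n_pd else float("nan"),
                "control_count": k_ctrl,
                "control_total": n_ctrl,
                "control_freq": k_ctrl / n_ctrl if n_ctrl else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("gene")
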