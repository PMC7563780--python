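"""Subtype-versus-rest gene enrichment and burden comparisons.

For every (gene, histopathological subtype) pair a 2x2 table is formed —
altered/unaltered within the subtype versus the rest of the cohort — and
tested with Fisher's exact test. "Altered" means any driver alteration, small
variant or copy-number event, in that gene. The enrichment tail (one-sided)
drives the reported significance because the analysis asks which genes
characterise a subtype; the two-sided p and a Benjamini-Hochberg column are
emitted alongside, but the significant flag uses the raw one-sided p at the
chosen alpha.

Burden metrics (adjusted TMB, SNV count, CNV count) are compared between each
subtype and a reference subtype with a two-sided Mann-Whitney U test: exact
permutation enumeration for small groups, tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exact import fisher_one_sided_enrichment, fisher_two_sided, mannwhitney_p
from .io import alteration_matrix
from .models import Cohort
from .tmb import _metric_values

__all__ = ["EnrichmentResult", "gene_enrichment", "enrichment_table", "compare_burden"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene-by-subtype exact test on an a/b/c/d table."""

    gene: str
    group: str
    a: int  # altered in group
    b: int  # unaltered in group
    c: int  # altered in rest
    d: int  # unaltered in rest
    p_one_sided: float
    p_two_sided: float
    direction: str  # "enriched" | "depleted"


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    if len(pvals) == 0:
        return pvals
    from statsmodels.stats.multitest import multipletests

    return multipletests(pvals, method="fdr_bh")[1]


def gene_enrichment(
    cohort: Cohort,
    drivers_only: bool = True,
    include_cnv: bool = True,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """One Fisher exact test per (gene, subtype) against the rest of the cohort.

    Results are ordered deterministically by (group, p_one_sided, gene).
    Raises ``ValueError`` when fewer than two subtypes are present (there is
    no "rest" to compare against).
    """
    subtype_of = pd.Series({c.sample_id: c.subtype for c in cohort.clinical})
    groups = sorted(subtype_of.unique())
    if len(groups) < 2:
        raise ValueError("gene enrichment requires at least two subtypes in the cohort")
    mat = alteration_matrix(cohort, include_cnv=include_cnv, drivers_only=drivers_only)
    subtype_of = subtype_of.reindex(mat.index)
    results: list[EnrichmentResult] = []
    for group in groups:
        in_group = (subtype_of == group).to_numpy()
        n_group = int(in_group.sum())
        n_rest = len(mat) - n_group
        altered_group = mat.loc[in_group].sum(axis=0)
        altered_all = mat.sum(axis=0)
        for gene in mat.columns:
            a = int(altered_group[gene])
            c = int(altered_all[gene]) - a
            b, d = n_group - a, n_rest - c
            freq_group = a / n_group if n_group else 0.0
            freq_rest = c / n_rest if n_rest else 0.0
            results.append(
                EnrichmentResult(
                    gene=gene,
                    group=group,
                    a=a,
                    b=b,
                    c=c,
                    d=d,
                    p_one_sided=fisher_one_sided_enrichment(a, b, c, d),
                    p_two_sided=fisher_two_sided(a, b, c, d),
                    direction="enriched" if freq_group >= freq_rest else "depleted",
                )
            )
    results.sort(key=lambda r: (r.group, r.p_one_sided, r.gene))
    return results


def enrichment_table(
    cohort: Cohort,
    drivers_only: bool = True,
    include_cnv: bool = True,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tabular enrichment results with BH column and significance flag.

    A gene altered in no patient is never flagged significant (its only
    possible table has p = 1). The ``significant`` flag uses the raw
    one-sided p (< alpha); ``q_bh`` is informational.
    """
    res = gene_enrichment(
        cohort, drivers_only=drivers_only, include_cnv=include_cnv, alpha=alpha
    )
    df = pd.DataFrame(
        {
            "gene": [r.gene for r in res],
            "group": [r.group for r in res],
            "a": [r.a for r in res],
            "b": [r.b for r in res],
            "c": [r.c for r in res],
            "d": [r.d for r in res],
            "p_one_sided": [r.p_one_sided for r in res],
            "p_two_sided": [r.p_two_sided for r in res],
            "direction": [r.direction for r in res],
        }
    )
    df["q_bh"] = _bh_adjust(df["p_one_sided"].to_numpy())
    df["significant"] = (df["p_one_sided"] < alpha) & (df["a"] + df["c"] > 0)
    return df


def compare_burden(
    cohort: Cohort, metric: str = "tmb", reference_subtype: str = "cutaneous"
) -> pd.DataFrame:
    """Per-subtype two-sided Mann-Whitney comparison against a reference.

    Returns one row per non-reference subtype with the group sizes, medians,
    p-value and the method used ("exact" for both groups <= 12, otherwise
    the tie-corrected normal approximation). Empty comparison groups are
    skipped with a warning; an empty reference group is an error.
    """
    values = _metric_values(cohort, metric)
    subtype_of = pd.Series({c.sample_id: c.subtype for c in cohort.clinical}).reindex(
        values.index
    )
    ref = values[subtype_of == reference_subtype].to_numpy()
    if len(ref) == 0:
        raise ValueError(f"reference subtype {reference_subtype!r} has no patients")
    rows = []
    for group in sorted(subtype_of.unique()):
        if group == reference_subtype:
            continue
        vals = values[subtype_of == group].to_numpy()
        if len(vals) == 0:
            logger.warning("subtype %s empty; burden comparison skipped", group)
            continue
        p, method = mannwhitney_p(vals, ref)
        rows.append(
            {
                "subtype": group,
                "n": len(vals),
                "n_reference": len(ref),
                "median": float(np.median(vals)),
                "median_reference": float(np.median(ref)),
                "p_value": p,
                "method": method,
            }
        )
    return pd.DataFrame(rows).set_index("subtype")
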