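"""Adjusted tumor mutational burden for targeted panels.

A cancer panel deliberately over-samples known tumor suppressors and
oncogenes, so extrapolating *all* of its coding variants per panel megabase
overstates the genome-wide mutation rate. The adjusted burden therefore
splits the somatic coding variants (SNVs and INDELs, synonymous included) of
a sample into two pools:

* variants outside the known-tumor-gene subset, normalised by the panel
  target size (they behave like a random sample of the genome), and
* variants inside the known-tumor-gene subset, normalised by the full genome
  size (they were enriched for by design and must not be extrapolated).

``tmb = (n_somatic - n_tumorgene) / target_size_mb + n_tumorgene / genome_size_mb``

Both addends are kept on the result so the normalisation can be audited or an
alternative reading swapped in one place. Copy-number events never count
toward TMB. Values are rounded only at presentation, never in computation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .models import Cohort, ConfigError, PanelDefinition, VariantRecord

__all__ = ["TMBResult", "compute_tmb", "compute_tmb_cohort", "summarize_burden"]


@dataclass(frozen=True)
class TMBResult:
    """Per-sample adjusted burden with its two normalisation terms."""

    sample_id: str
    n_somatic: int
    n_tumorgene: int
    panel_term: float  # (n_somatic - n_tumorgene) / target_size_mb
    genome_term: float  # n_tumorgene / genome_size_mb

    @property
    def tmb(self) -> float:
        return self.panel_term + self.genome_term


def compute_tmb(
    variants: Iterable[VariantRecord], panel: PanelDefinition, sample_id: str | None = None
) -> TMBResult:
    """Adjusted TMB for one sample's coding SNVs/INDELs (mutations per Mb)."""
    if panel.target_size_mb <= 0:
        raise ConfigError("panel target_size_mb must be positive")
    variants = list(variants)
    if sample_id is None:
        sample_id = variants[0].sample_id if variants else ""
    n_somatic = len(variants)
    n_tumorgene = sum(1 for v in variants if v.gene in panel.tumor_genes)
    return TMBResult(
        sample_id=sample_id,
        n_somatic=n_somatic,
        n_tumorgene=n_tumorgene,
        panel_term=(n_somatic - n_tumorgene) / panel.target_size_mb,
        genome_term=n_tumorgene / panel.genome_size_mb,
    )


def compute_tmb_cohort(cohort: Cohort) -> pd.DataFrame:
    """Adjusted TMB for every patient (vectorised over the variant table).

    Returns a DataFrame indexed by sample_id with columns
    ``n_somatic, n_tumorgene, tmb``; alteration-free patients get zeros.
    """
    samples = sorted(cohort.sample_ids)
    if cohort.variants:
        df = pd.DataFrame(
            {
                "sample_id": [v.sample_id for v in cohort.variants],
                "in_tumorgene": [v.gene in cohort.panel.tumor_genes for v in cohort.variants],
            }
        )
        grouped = df.groupby("sample_id")["in_tumorgene"].agg(["count", "sum"])
        n_somatic = grouped["count"].reindex(samples, fill_value=0).astype(int)
        n_tumorgene = grouped["sum"].reindex(samples, fill_value=0).astype(int)
    else:
        n_somatic = pd.Series(0, index=samples)
        n_tumorgene = pd.Series(0, index=samples)
    out = pd.DataFrame(
        {
            "n_somatic": n_somatic,
            "n_tumorgene": n_tumorgene,
            "tmb": (n_somatic - n_tumorgene) / cohort.panel.target_size_mb
            + n_tumorgene / cohort.panel.genome_size_mb,
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return out


_METRICS = ("tmb", "n_snv", "n_cnv")


def _metric_values(cohort: Cohort, metric: str) -> pd.Series:
    samples = sorted(cohort.sample_ids)
    if metric == "tmb":
        return compute_tmb_cohort(cohort)["tmb"]
    if metric == "n_snv":
        counts = pd.Series([v.sample_id for v in cohort.variants]).value_counts()
        return counts.reindex(samples, fill_value=0).astype(float).rename("n_snv")
    if metric == "n_cnv":
        counts = pd.Series([c.sample_id for c in cohort.cnvs]).value_counts()
        return counts.reindex(samples, fill_value=0).astype(float).rename("n_cnv")
    raise ValueError(f"unknown burden metric {metric!r}; expected one of {_METRICS}")


def summarize_burden(cohort: Cohort, metric: str = "tmb", by: str = "subtype") -> pd.DataFrame:
    """Median, IQR and range of a burden metric per patient group.

    Groups with a single patient report a degenerate IQR/range equal to that
    value. ``by`` may be any :class:`ClinicalRecord` field (default the
    histopathological subtype).
    """
    if cohort.n_patients == 0:
        raise ValueError("cannot summarize an empty cohort")
    values = _metric_values(cohort, metric)
    groups = pd.Series(
        {c.sample_id: getattr(c, by) for c in cohort.clinical}, name=by
    ).reindex(values.index)
    rows = []
    for label, vals in values.groupby(groups, sort=True):
        arr = np.asarray(vals, dtype=float)
        rows.append(
            {
                by: label,
                "n": len(arr),
                "median": float(np.median(arr)),
                "q1": float(np.percentile(arr, 25)),
                "q3": float(np.percentile(arr, 75)),
                "min": float(arr.min()),
                "max": float(arr.max()),
            }
        )
    return pd.DataFrame(rows).set_index(by)
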