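"""Genomic subtype classification: BRAF, RAS, NF1 or triple wild-type.

Melanomas are conventionally partitioned by their driver small variants into
BRAF-mutant, RAS-mutant (NRAS/HRAS/KRAS), NF1-mutant and triple wild-type
(TWT). Only driver SNVs/INDELs count; copy-number events in RAS-pathway genes
never change the class. Patients co-mutated in more than one class gene are
resolved by the fixed precedence BRAF > RAS > NF1, the convention used in the
large-scale melanoma sequencing studies this classification originates from.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .models import Cohort, VariantRecord

__all__ = ["RAS_GENES", "GenomicClass", "classify_genomic_subtype", "classify_cohort", "class_counts"]

RAS_GENES = frozenset({"NRAS", "HRAS", "KRAS"})

#: class labels in precedence order; TWT is the absence of all three
_PRECEDENCE = ("BRAF", "RAS", "NF1")


@dataclass(frozen=True)
class GenomicClass:
    """A patient's genomic subtype label and the variants supporting it."""

    sample_id: str
    label: str  # "BRAF" | "RAS" | "NF1" | "TWT"
    evidence: tuple[tuple[str, str], ...]  # (gene, protein_change) pairs

    def __post_init__(self) -> None:
        if (self.label == "TWT") != (len(self.evidence) == 0):
            raise ValueError("TWT label iff empty evidence")


def _class_of_gene(gene: str) -> str | None:
    if gene == "BRAF":
        return "BRAF"
    if gene in RAS_GENES:
        return "RAS"
    if gene == "NF1":
        return "NF1"
    return None


def classify_genomic_subtype(
    variants: Iterable[VariantRecord], sample_id: str | None = None
) -> GenomicClass:
    """Classify one patient from their driver small variants.

    Non-driver records are ignored (the driver annotation is trusted; no
    attempt is made to re-derive it from protein-change strings). The evidence
    lists every driver variant in the gene(s) matching the winning label.
    """
    drivers = [v for v in variants if v.is_driver]
    if sample_id is None:
        sample_id = drivers[0].sample_id if drivers else ""
    by_class: dict[str, list[VariantRecord]] = {}
    for v in drivers:
        cls = _class_of_gene(v.gene)
        if cls is not None:
            by_class.setdefault(cls, []).append(v)
    for label in _PRECEDENCE:
        if label in by_class:
            evidence = tuple(
                sorted((v.gene, v.protein_change) for v in by_class[label])
            )
            return GenomicClass(sample_id=sample_id, label=label, evidence=evidence)
    return GenomicClass(sample_id=sample_id, label="TWT", evidence=())


def classify_cohort(cohort: Cohort) -> list[GenomicClass]:
    """Classify every patient; one label per clinical record."""
    by_sample: dict[str, list[VariantRecord]] = {s: [] for s in cohort.sample_ids}
    for v in cohort.variants:
        by_sample[v.sample_id].append(v)
    return [
        classify_genomic_subtype(by_sample[s], sample_id=s) for s in sorted(by_sample)
    ]


def class_counts(cohort: Cohort) -> dict[str, int]:
    """Patients per genomic class; counts always sum to the cohort size."""
    counts = Counter(g.label for g in classify_cohort(cohort))
    return {label: counts.get(label, 0) for label in (*_PRECEDENCE, "TWT")}
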