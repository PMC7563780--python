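"""Core data model for a targeted-panel melanoma cohort.

The cohort is gene-level: every somatic alteration is either a small variant
(SNV/INDEL with a protein change) or a whole-gene copy-number event, tied to a
sample and an HGNC-style gene symbol. No genomic coordinates are stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "VARIANT_CLASSES",
    "SUBTYPES",
    "ICI_REGIMENS",
    "RECIST_RESPONSES",
    "VariantRecord",
    "CNVEvent",
    "ClinicalRecord",
    "PanelDefinition",
    "Cohort",
    "CohortError",
    "SchemaError",
    "IntegrityError",
    "UniquenessError",
    "ConfigError",
]

VARIANT_CLASSES = frozenset(
    {"missense", "nonsense", "frameshift", "inframe_indel", "splice", "synonymous"}
)
SUBTYPES = ("cutaneous", "acral", "mucosal", "uveal", "occult")
ICI_REGIMENS = frozenset({"combined", "anti_pd1", "none"})
RECIST_RESPONSES = frozenset({"PD", "SD", "PR", "not_applicable"})

#: GRCh37 total assembly length in megabases; used when no genome size is configured.
DEFAULT_GENOME_SIZE_MB = 3101.79


class CohortError(ValueError):
    """Base class for cohort validation failures."""


class SchemaError(CohortError):
    """An input table is missing a column or contains an invalid value."""


class IntegrityError(CohortError):
    """A record references a sample or gene that does not exist."""


class UniquenessError(CohortError):
    """Duplicate clinical sample identifiers."""


class ConfigError(CohortError):
    """Invalid panel or run configuration."""


@dataclass(frozen=True)
class VariantRecord:
    """One somatic SNV/INDEL assigned to a sample and gene."""

    sample_id: str
    gene: str
    variant_class: str
    protein_change: str
    is_driver: bool
    is_hotspot: bool = False

    def __post_init__(self) -> None:
        if not self.gene:
            raise SchemaError("variant gene symbol must be non-empty")
        if self.variant_class not in VARIANT_CLASSES:
            raise SchemaError(
                f"invalid variant_class {self.variant_class!r} for sample "
                f"{self.sample_id}; expected one of {sorted(VARIANT_CLASSES)}"
            )
        if self.variant_class == "synonymous" and self.is_driver:
            raise SchemaError(
                f"synonymous variant flagged as driver: {self.sample_id} "
                f"{self.gene} {self.protein_change}"
            )


@dataclass(frozen=True)
class CNVEvent:
    """One gene-level somatic amplification or deletion for a sample."""

    sample_id: str
    gene: str
    direction: str  # "amplification" | "deletion"
    is_driver: bool

    def __post_init__(self) -> None:
        if not self.gene:
            raise SchemaError("CNV gene symbol must be non-empty")
        if self.direction not in ("amplification", "deletion"):
            raise SchemaError(
                f"invalid CNV direction {self.direction!r} for sample "
                f"{self.sample_id} gene {self.gene}"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-patient histopathological subtype, ICI therapy and RECIST response.

    ``recist_response`` is ``not_applicable`` exactly for patients who never
    received immune checkpoint inhibition (``ici_regimen == "none"``).
    """

    sample_id: str
    subtype: str
    ici_regimen: str
    recist_response: str
    braf_meki_pretreated: bool

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise SchemaError(
                f"unknown subtype {self.subtype!r} for sample {self.sample_id}; "
                f"expected one of {list(SUBTYPES)}"
            )
        if self.ici_regimen not in ICI_REGIMENS:
            raise SchemaError(
                f"unknown ici_regimen {self.ici_regimen!r} for sample {self.sample_id}"
            )
        if self.recist_response not in RECIST_RESPONSES:
            raise SchemaError(
                f"unknown recist_response {self.recist_response!r} for sample "
                f"{self.sample_id}"
            )
        if (self.recist_response == "not_applicable") != (self.ici_regimen == "none"):
            raise SchemaError(
                f"sample {self.sample_id}: recist_response must be not_applicable "
                "exactly when ici_regimen is none"
            )

    @property
    def ici_treated(self) -> bool:
        return self.ici_regimen != "none"


@dataclass(frozen=True)
class PanelDefinition:
    """The sequencing panel: gene universe, sizes, and the known-tumor-gene subset.

    ``target_size_mb`` is the panel's coding target territory; ``tumor_genes``
    is the curated subset of known tumor suppressors/oncogenes whose variants
    are normalised against the whole genome rather than the panel (panels
    over-sample driver genes, so extrapolating their variants per panel
    megabase would inflate the mutational burden).
    """

    genes: frozenset[str]
    target_size_mb: float
    tumor_genes: frozenset[str]
    genome_size_mb: float = DEFAULT_GENOME_SIZE_MB

    def __post_init__(self) -> None:
        if self.target_size_mb <= 0:
            raise ConfigError("panel target_size_mb must be positive")
        if self.genome_size_mb < self.target_size_mb:
            raise ConfigError("genome_size_mb must be >= target_size_mb")
        if not self.tumor_genes <= self.genes:
            extra = sorted(self.tumor_genes - self.genes)
            raise ConfigError(f"tumor_genes not in panel gene universe: {extra}")


@dataclass
class Cohort:
    """A validated, joinable cohort: clinical records plus all alterations."""

    clinical: list[ClinicalRecord]
    variants: list[VariantRecord]
    cnvs: list[CNVEvent]
    panel: PanelDefinition

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ids = [c.sample_id for c in self.clinical]
        seen: set[str] = set()
        dupes = sorted({s for s in ids if s in seen or seen.add(s)})  # type: ignore[func-returns-value]
        if dupes:
            raise UniquenessError(f"duplicate clinical sample_id values: {dupes}")
        known = set(ids)
        bad_samples = sorted(
            {r.sample_id for r in [*self.variants, *self.cnvs] if r.sample_id not in known}
        )
        if bad_samples:
            raise IntegrityError(
                f"alterations reference unknown sample_ids: {bad_samples}"
            )
        bad_genes = sorted(
            {r.gene for r in [*self.variants, *self.cnvs] if r.gene not in self.panel.genes}
        )
        if bad_genes:
            raise IntegrityError(f"alterations reference genes not on the panel: {bad_genes}")

    @property
    def sample_ids(self) -> list[str]:
        return [c.sample_id for c in self.clinical]

    @property
    def n_patients(self) -> int:
        return len(self.clinical)

    def clinical_by_id(self) -> dict[str, ClinicalRecord]:
        return {c.sample_id: c for c in self.clinical}

    def variants_for(self, sample_id: str) -> list[VariantRecord]:
        return [v for v in self.variants if v.sample_id == sample_id]

    def cnvs_for(self, sample_id: str) -> list[CNVEvent]:
        return [c for c in self.cnvs if c.sample_id == sample_id]

    def ici_subset(self) -> "Cohort":
        """Cohort restricted to ICI-treated patients (predictor denominators)."""
        keep = {c.sample_id for c in self.clinical if c.ici_treated}
        return Cohort(
            clinical=[c for c in self.clinical if c.sample_id in keep],
            variants=[v for v in self.variants if v.sample_id in keep],
            cnvs=[c for c in self.cnvs if c.sample_id in keep],
            panel=self.panel,
        )
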