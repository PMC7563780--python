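"""Reading, validating and writing the tab-delimited cohort tables.

A cohort directory holds four UTF-8, tab-delimited, header-rowed tables plus a
small YAML config carrying the panel sizes:

* ``clinical.tsv``: sample_id, subtype, ici_regimen, recist_response,
  braf_meki_pretreated
* ``variants.tsv``: sample_id, gene, variant_class, protein_change, is_driver,
  is_hotspot
* ``cnv.tsv``: sample_id, gene, direction, is_driver
* ``panel.tsv``: gene, tumor_gene
* ``config.yaml``: target_size_mb, genome_size_mb

Enum-like columns are matched case-insensitively; unknown values are rejected,
never coerced. Row order of any input table never affects downstream results.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from .models import (
    DEFAULT_GENOME_SIZE_MB,
    RECIST_RESPONSES,
    CNVEvent,
    ClinicalRecord,
    Cohort,
    PanelDefinition,
    SchemaError,
    VariantRecord,
)

__all__ = ["read_cohort", "read_cohort_dir", "write_cohort", "alteration_matrix"]

logger = logging.getLogger(__name__)

_CLINICAL_COLS = ["sample_id", "subtype", "ici_regimen", "recist_response", "braf_meki_pretreated"]
_VARIANT_COLS = ["sample_id", "gene", "variant_class", "protein_change", "is_driver", "is_hotspot"]
_CNV_COLS = ["sample_id", "gene", "direction", "is_driver"]
_PANEL_COLS = ["gene", "tumor_gene"]

_TRUE = {"true", "1", "yes"}
_FALSE = {"false", "0", "no"}


def _read_table(path: str | Path, required: list[str], optional: tuple[str, ...] = ()) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns and c not in optional]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in optional:
        if col not in df.columns:
            logger.warning("%s: optional column %r missing, defaulting to false", path.name, col)
            df[col] = "false"
    return df


def _parse_bool(value: str, context: str) -> bool:
    v = value.strip().lower()
    if v in _TRUE:
        return True
    if v in _FALSE:
        return False
    raise SchemaError(f"{context}: cannot parse boolean value {value!r}")


def _norm_enum(value: str) -> str:
    return value.strip().lower()


def _norm_response(value: str) -> str:
    v = value.strip()
    up = v.upper()
    if up in RECIST_RESPONSES:
        return up
    return v.lower()


def read_cohort(
    clinical_path: str | Path,
    variants_path: str | Path,
    cnv_path: str | Path,
    panel_path: str | Path,
    *,
    target_size_mb: float = 1.3,
    genome_size_mb: float = DEFAULT_GENOME_SIZE_MB,
) -> Cohort:
    """Read and validate the three cohort tables plus the panel definition.

    Raises :class:`~melcohort.models.SchemaError` for malformed tables,
    :class:`~melcohort.models.IntegrityError` for dangling sample/gene
    references and :class:`~melcohort.models.UniquenessError` for duplicated
    clinical sample ids.
    """
    clin_df = _read_table(clinical_path, _CLINICAL_COLS)
    var_df = _read_table(variants_path, _VARIANT_COLS, optional=("is_hotspot",))
    cnv_df = _read_table(cnv_path, _CNV_COLS)
    panel_df = _read_table(panel_path, _PANEL_COLS)

    clinical = [
        ClinicalRecord(
            sample_id=row.sample_id.strip(),
            subtype=_norm_enum(row.subtype),
            ici_regimen=_norm_enum(row.ici_regimen),
            recist_response=_norm_response(row.recist_response),
            braf_meki_pretreated=_parse_bool(row.braf_meki_pretreated, f"clinical {row.sample_id}"),
        )
        for row in clin_df.itertuples()
    ]
    variants = [
        VariantRecord(
            sample_id=row.sample_id.strip(),
            gene=row.gene.strip(),
            variant_class=_norm_enum(row.variant_class),
            protein_change=row.protein_change.strip(),
            is_driver=_parse_bool(row.is_driver, f"variant {row.sample_id}/{row.gene}"),
            is_hotspot=_parse_bool(row.is_hotspot, f"variant {row.sample_id}/{row.gene}"),
        )
        for row in var_df.itertuples()
    ]
    cnvs = [
        CNVEvent(
            sample_id=row.sample_id.strip(),
            gene=row.gene.strip(),
            direction=_norm_enum(row.direction),
            is_driver=_parse_bool(row.is_driver, f"cnv {row.sample_id}/{row.gene}"),
        )
        for row in cnv_df.itertuples()
    ]
    genes = frozenset(g.strip() for g in panel_df["gene"])
    tumor_genes = frozenset(
        row.gene.strip()
        for row in panel_df.itertuples()
        if _parse_bool(row.tumor_gene, f"panel {row.gene}")
    )
    panel = PanelDefinition(
        genes=genes,
        target_size_mb=float(target_size_mb),
        tumor_genes=tumor_genes,
        genome_size_mb=float(genome_size_mb),
    )
    return Cohort(clinical=clinical, variants=variants, cnvs=cnvs, panel=panel)


def read_cohort_dir(cohort_dir: str | Path) -> Cohort:
    """Read a cohort directory (four TSVs plus ``config.yaml``)."""
    d = Path(cohort_dir)
    cfg_path = d / "config.yaml"
    target, genome = 1.3, DEFAULT_GENOME_SIZE_MB
    if cfg_path.exists():
        cfg = yaml.safe_load(cfg_path.read_text()) or {}
        target = float(cfg.get("target_size_mb", target))
        genome = float(cfg.get("genome_size_mb", genome))
    return read_cohort(
        d / "clinical.tsv",
        d / "variants.tsv",
        d / "cnv.tsv",
        d / "panel.tsv",
        target_size_mb=target,
        genome_size_mb=genome,
    )


def _fmt_bool(b: bool) -> str:
    return "true" if b else "false"


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a cohort as the four TSVs plus config.yaml (deterministic bytes).

    Rows are sorted so that logically identical cohorts serialize identically
    regardless of in-memory order.
    """
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)

    clin = sorted(cohort.clinical, key=lambda c: c.sample_id)
    with open(d / "clinical.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CLINICAL_COLS) + "\n")
        for c in clin:
            fh.write(
                f"{c.sample_id}\t{c.subtype}\t{c.ici_regimen}\t{c.recist_response}\t"
                f"{_fmt_bool(c.braf_meki_pretreated)}\n"
            )

    variants = sorted(
        cohort.variants, key=lambda v: (v.sample_id, v.gene, v.protein_change, v.variant_class)
    )
    with open(d / "variants.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_VARIANT_COLS) + "\n")
        for v in variants:
            fh.write(
                f"{v.sample_id}\t{v.gene}\t{v.variant_class}\t{v.protein_change}\t"
                f"{_fmt_bool(v.is_driver)}\t{_fmt_bool(v.is_hotspot)}\n"
            )

    cnvs = sorted(cohort.cnvs, key=lambda c: (c.sample_id, c.gene, c.direction))
    with open(d / "cnv.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_CNV_COLS) + "\n")
        for c in cnvs:
            fh.write(f"{c.sample_id}\t{c.gene}\t{c.direction}\t{_fmt_bool(c.is_driver)}\n")

    with open(d / "panel.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(_PANEL_COLS) + "\n")
        for g in sorted(cohort.panel.genes):
            fh.write(f"{g}\t{_fmt_bool(g in cohort.panel.tumor_genes)}\n")

    with open(d / "config.yaml", "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"target_size_mb: {cohort.panel.target_size_mb}\n")
        fh.write(f"genome_size_mb: {cohort.panel.genome_size_mb}\n")


def alteration_matrix(
    cohort: Cohort, include_cnv: bool = True, drivers_only: bool = True
) -> pd.DataFrame:
    """Patient-by-gene boolean presence/absence matrix.

    Cell (p, g) is True iff patient p carries at least one qualifying
    alteration in gene g. A patient with both an SNV and a CNV in the same
    gene counts once. Rows cover every clinical record (alteration-free
    patients keep an all-False row); rows are ordered by sample_id and
    columns by gene symbol, so the matrix is independent of input row order.
    """
    import numpy as np

    samples = sorted(cohort.sample_ids)
    genes = sorted(cohort.panel.genes)
    sidx = {s: i for i, s in enumerate(samples)}
    gidx = {g: j for j, g in enumerate(genes)}
    arr = np.zeros((len(samples), len(genes)), dtype=bool)
    records: list[tuple[str, str]] = [
        (v.sample_id, v.gene) for v in cohort.variants if v.is_driver or not drivers_only
    ]
    if include_cnv:
        records += [
            (c.sample_id, c.gene) for c in cohort.cnvs if c.is_driver or not drivers_only
        ]
    if records:
        rows = [sidx[s] for s, _ in records]
        cols = [gidx[g] for _, g in records]
        arr[rows, cols] = True
    mat = pd.DataFrame(arr, index=samples, columns=genes)
    mat.index.name = "sample_id"
    return mat
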