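"""Deterministic reference cohort reproducing every published count.

The underlying patient-level data of the study cohort were never deposited,
but the publication pins enough marginal and joint counts — subtype sizes,
genomic-class counts, every predictor 2x2 table, the MYC/uveal structure,
the BRAF/MEKi pretreatment ratios — that a concrete 82-patient assignment
satisfying all of them simultaneously can be constructed. This module holds
that assignment, worked out once by hand from the overlap arithmetic (e.g.
among progressors, gene-positive and pretreated patients must overlap in
exactly 7 cases: 19 + 16 - 28) and pinned as literal per-patient tables.
Any change to a count is a breaking change.

The canonical serialized form ships as package data
(``melcohort/data/paper_fixture``); :func:`build_paper_fixture` reconstructs
the same cohort from the pinned tables, and :func:`verify_fixture` asserts
every published constraint.

Patient layout (ids P001..P082, grouped by histopathological subtype):

* cutaneous P001-P042, acral P043-P056, mucosal P057-P065,
  uveal P066-P073, occult P074-P082
* within each subtype: progressive disease first, then stable disease,
  partial response, and finally patients never treated with ICI
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .models import CNVEvent, ClinicalRecord, Cohort, PanelDefinition, VariantRecord

__all__ = [
    "build_paper_fixture",
    "load_paper_fixture",
    "make_paper_fixture",
    "verify_fixture",
    "FixtureConstraintError",
]


class FixtureConstraintError(AssertionError):
    """A pinned published count is violated by the constructed cohort."""


# --------------------------------------------------------------------------
# panel

TUMOR_GENES = (
    "ARID2", "BAP1", "BRAF", "CCND2", "CCND3", "CDK4", "CDKN2A", "CHEK2",
    "CTNNB1", "EGFR", "ERBB2", "ERBB3", "GNA11", "GNAQ", "HRAS", "JAK2",
    "KIT", "KRAS", "MDM2", "MET", "MYC", "NF1", "NRAS", "PDGFRA", "PTEN",
    "PTPRD", "RICTOR", "SF3B1", "SMARCA4", "TP53",
)

#: panel genes outside the curated known-tumor-gene subset; passenger
#: variants land here and are normalised per panel megabase
FILLER_GENES = (
    "ALK", "ARID1B", "FAT1", "FGFR2", "GRIN2A", "KMT2D",
    "LRP1B", "NOTCH2", "PREX2", "RET", "ROS1", "SPEN",
)

TARGET_SIZE_MB = 1.3
GENOME_SIZE_MB = 3101.79


def fixture_panel() -> PanelDefinition:
    return PanelDefinition(
        genes=frozenset(TUMOR_GENES) | frozenset(FILLER_GENES),
        target_size_mb=TARGET_SIZE_MB,
        tumor_genes=frozenset(TUMOR_GENES),
        genome_size_mb=GENOME_SIZE_MB,
    )


# --------------------------------------------------------------------------
# clinical layout

_SUBTYPE_RANGES = {
    "cutaneous": (1, 42),
    "acral": (43, 56),
    "mucosal": (57, 65),
    "uveal": (66, 73),
    "occult": (74, 82),
}

# response blocks within each subtype: (PD, SD, PR, no-ICI) counts
_RESPONSE_BLOCKS = {
    "cutaneous": (20, 7, 11, 4),
    "acral": (9, 2, 2, 1),
    "mucosal": (5, 1, 2, 1),
    "uveal": (6, 1, 1, 0),
    "occult": (5, 1, 2, 1),
}

# BRAF/MEKi pretreatment before ICI: 16 of the 18 BRAF-mutated progressors
# and 2 of the 4 BRAF-mutated SD/PR patients
_PRETREATED = {
    "P001", "P002", "P003", "P004", "P005", "P006", "P007", "P008", "P009",
    "P010", "P011", "P012", "P043", "P057", "P074", "P075",  # PD (16)
    "P021", "P028",  # SD / PR (2)
}


def _pid(n: int) -> str:
    return f"P{n:03d}"


def _clinical_records() -> list[ClinicalRecord]:
    records = []
    for subtype, (lo, _hi) in _SUBTYPE_RANGES.items():
        n_pd, n_sd, n_pr, n_none = _RESPONSE_BLOCKS[subtype]
        responses = ["PD"] * n_pd + ["SD"] * n_sd + ["PR"] * n_pr + ["not_applicable"] * n_none
        for offset, response in enumerate(responses):
            records.append((subtype, _pid(lo + offset), response))
    # regimen: 60 combined / 15 anti-PD-1 among the 75 ICI-treated, assigned
    # in id order (the split is not pinned to individual patients)
    ici_ids = sorted(pid for _s, pid, r in records if r != "not_applicable")
    anti_pd1 = set(ici_ids[60:])
    out = []
    for subtype, pid, response in sorted(records, key=lambda t: t[1]):
        regimen = "none" if response == "not_applicable" else (
            "anti_pd1" if pid in anti_pd1 else "combined"
        )
        out.append(
            ClinicalRecord(
                sample_id=pid,
                subtype=subtype,
                ici_regimen=regimen,
                recist_response=response,
                braf_meki_pretreated=pid in _PRETREATED,
            )
        )
    return out


# --------------------------------------------------------------------------
# driver small variants: (sample, gene, class, protein change, hotspot)

_BRAF_V600 = {
    "P001": "V600E", "P002": "V600E", "P003": "V600E", "P004": "V600K",
    "P005": "V600E", "P006": "V600E", "P007": "V600R", "P008": "V600E",
    "P009": "V600K", "P010": "V600E", "P011": "V600E", "P021": "V600E",
    "P022": "V600K", "P028": "V600E", "P039": "V600E", "P043": "V600E",
    "P057": "V600E", "P074": "V600E", "P075": "V600K", "P076": "V600E",
    "P080": "V600E",
}

_NRAS_Q61 = {
    # the two BRAF+NRAS double-hotspot patients
    "P002": "Q61K", "P003": "Q61R",
    # NRAS-class patients (cutaneous and one acral)
    "P014": "Q61K", "P015": "Q61R", "P016": "Q61L", "P017": "Q61K",
    "P018": "Q61R", "P019": "Q61L", "P020": "Q61K", "P023": "Q61R",
    "P024": "Q61K", "P025": "Q61R", "P026": "Q61L", "P027": "Q61K",
    "P029": "Q61R", "P030": "Q61K", "P031": "Q61L", "P032": "Q61R",
    "P033": "Q61K", "P044": "Q61R",
}

_DRIVER_SNVS: list[tuple[str, str, str, str, bool]] = (
    [(p, "BRAF", "missense", ch, True) for p, ch in sorted(_BRAF_V600.items())]
    + [
        ("P012", "BRAF", "missense", "G466E", False),
        ("P013", "BRAF", "missense", "P367S", False),
        ("P013", "BRAF", "missense", "K601E", False),
    ]
    + [(p, "NRAS", "missense", ch, True) for p, ch in sorted(_NRAS_Q61.items())]
    + [
        ("P077", "HRAS", "missense", "Q61R", True),
        ("P045", "KRAS", "missense", "G12D", True),
        ("P058", "KRAS", "missense", "D119H", False),
        # NF1: two NF1-class patients plus three co-mutated with a BRAF/NRAS hotspot
        ("P004", "NF1", "frameshift", "Q1174fs", False),
        ("P005", "NF1", "nonsense", "R2450*", False),
        ("P014", "NF1", "splice", "X1234_splice", False),
        ("P046", "NF1", "frameshift", "L847fs", False),
        ("P078", "NF1", "nonsense", "R1306*", False),
        # TP53 small variants (the remaining TP53 events are deletions)
        ("P007", "TP53", "missense", "R175H", True),
        ("P008", "TP53", "missense", "R248W", True),
        ("P020", "TP53", "missense", "R273H", True),
        ("P034", "TP53", "missense", "P278S", False),
        ("P061", "TP53", "missense", "G245S", False),
        # uveal: mutually exclusive GNA11/GNAQ, each with SF3B1 or BAP1
        ("P066", "GNA11", "missense", "Q209L", True),
        ("P068", "GNA11", "missense", "Q209L", True),
        ("P070", "GNA11", "missense", "Q209L", True),
        ("P072", "GNA11", "missense", "Q209L", True),
        ("P067", "GNAQ", "missense", "Q209P", True),
        ("P069", "GNAQ", "missense", "Q209P", True),
        ("P071", "GNAQ", "missense", "Q209P", True),
        ("P073", "GNAQ", "missense", "Q209P", True),
        ("P066", "SF3B1", "missense", "R625C", True),
        ("P067", "SF3B1", "missense", "R625C", True),
        ("P070", "SF3B1", "missense", "R625H", True),
        ("P073", "SF3B1", "missense", "R625C", True),
        ("P068", "BAP1", "nonsense", "Q684*", False),
        ("P069", "BAP1", "frameshift", "E31fs", False),
        ("P071", "BAP1", "nonsense", "W196*", False),
        ("P072", "BAP1", "frameshift", "R150fs", False),
        # JAK2: three carriers, two overlapping a PTEN/EGFR alteration
        ("P005", "JAK2", "missense", "R683G", False),
        ("P009", "JAK2", "missense", "R867Q", False),
        ("P078", "JAK2", "missense", "L393V", False),
    ]
)

# --------------------------------------------------------------------------
# driver copy-number events

_DRIVER_CNVS: dict[str, tuple[str, tuple[str, ...]]] = {
    # predictor genes
    "PTEN": ("deletion", (
        "P001", "P004", "P005", "P006", "P018", "P019", "P023", "P029",
        "P047", "P048", "P050", "P052", "P059", "P060",
    )),
    "EGFR": ("amplification", ("P009", "P016", "P017", "P047", "P048", "P049")),
    "TP53": ("deletion", ("P059", "P060")),
    "CDKN2A": ("deletion", (
        "P001", "P007", "P016", "P018", "P020",            # PD, on top of one gene
        "P044", "P045", "P046", "P051", "P058",            # PD, sole predictor gene
        "P024", "P030", "P035", "P063",                    # SD/PR
        "P040", "P082",                                    # never ICI-treated
    )),
    # MYC: every uveal patient plus 12 others (24% of the cohort)
    "MYC": ("amplification", (
        "P066", "P067", "P068", "P069", "P070", "P071", "P072", "P073",
        "P002", "P010", "P026", "P031", "P036", "P040",
        "P046", "P053", "P054", "P061", "P064", "P081",
    )),
    # acral: RTK/cell-cycle amplifications
    "KIT": ("amplification", ("P047", "P049", "P052", "P055")),
    "PDGFRA": ("amplification", ("P047", "P049", "P052", "P055")),
    "CDK4": ("amplification", ("P043", "P048", "P053", "P056")),
    "RICTOR": ("amplification", ("P050", "P054")),
    # mucosal: CCND2 amplification, CHEK2 deletion
    "CCND2": ("amplification", ("P057", "P059", "P062", "P063", "P065")),
    "CHEK2": ("deletion", ("P058", "P060", "P064")),
}

# --------------------------------------------------------------------------
# passenger small variants (drive the per-subtype mutational burden spread)

_PASSENGER_BASE = {"cutaneous": 12, "acral": 2, "mucosal": 4, "uveal": 4, "occult": 10}
_PASSENGER_SPREAD = {"cutaneous": 7, "acral": 3, "mucosal": 3, "uveal": 3, "occult": 7}

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _passenger_variants() -> list[VariantRecord]:
    out: list[VariantRecord] = []
    for subtype, (lo, hi) in _SUBTYPE_RANGES.items():
        base = _PASSENGER_BASE[subtype]
        spread = _PASSENGER_SPREAD[subtype]
        for i, n in enumerate(range(lo, hi + 1)):
            pid = _pid(n)
            count = max(0, base + (i % spread) - spread // 2)
            for j in range(count):
                gene = FILLER_GENES[(i * 3 + j) % len(FILLER_GENES)]
                aa = _AA[(i + j) % len(_AA)]
                if j % 4 == 3:  # every fourth passenger is synonymous
                    out.append(
                        VariantRecord(pid, gene, "synonymous", f"{aa}{200 + j}{aa}", False)
                    )
                else:
                    out.append(
                        VariantRecord(pid, gene, "missense", f"{aa}{100 + j}V", False)
                    )
    return out


# --------------------------------------------------------------------------
# assembly and verification

def build_paper_fixture() -> Cohort:
    """Reconstruct the reference cohort from the pinned per-patient tables."""
    variants = [
        VariantRecord(pid, gene, vclass, change, True, hotspot)
        for pid, gene, vclass, change, hotspot in _DRIVER_SNVS
    ] + _passenger_variants()
    cnvs = [
        CNVEvent(pid, gene, direction, True)
        for gene, (direction, pids) in sorted(_DRIVER_CNVS.items())
        for pid in pids
    ]
    cohort = Cohort(
        clinical=_clinical_records(),
        variants=variants,
        cnvs=cnvs,
        panel=fixture_panel(),
    )
    verify_fixture(cohort)
    return cohort


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise FixtureConstraintError(message)


def verify_fixture(cohort: Cohort) -> None:
    """Assert every pinned published count; raises FixtureConstraintError."""
    from collections import Counter

    from .classify import class_counts
    from .io import alteration_matrix
    from .predictor import evaluate_rule, standard_rules

    _require(cohort.n_patients == 82, "cohort must have 82 patients")
    subtype_counts = Counter(c.subtype for c in cohort.clinical)
    _require(
        subtype_counts
        == {"cutaneous": 42, "acral": 14, "mucosal": 9, "uveal": 8, "occult": 9},
        f"subtype counts wrong: {dict(subtype_counts)}",
    )
    responses = Counter(c.recist_response for c in cohort.clinical if c.ici_treated)
    _require(
        responses == {"PD": 45, "SD": 12, "PR": 18},
        f"ICI response counts wrong: {dict(responses)}",
    )
    _require(
        sum(1 for c in cohort.clinical if not c.ici_treated) == 7,
        "exactly 7 patients never received ICI",
    )

    counts = class_counts(cohort)
    _require(
        counts == {"BRAF": 23, "RAS": 21, "NF1": 2, "TWT": 36},
        f"genomic class counts wrong: {counts}",
    )
    mutated = lambda g: {v.sample_id for v in cohort.variants if v.gene == g and v.is_driver}
    braf, nras = mutated("BRAF"), mutated("NRAS")
    _require(len(braf) == 23 and len(nras) == 20, "BRAF/NRAS mutated patient counts")
    _require(len(braf & nras) == 2, "exactly 2 BRAF+NRAS double-hotspot patients")
    nf1 = mutated("NF1")
    _require(len(nf1) == 5, "5 NF1-mutated patients")
    _require(len(nf1 & (braf | nras)) == 3, "3 NF1 patients co-mutated in BRAF/NRAS")
    _require(len(mutated("HRAS")) == 1 and len(mutated("KRAS")) == 2, "HRAS/KRAS counts")

    mat = alteration_matrix(cohort, include_cnv=True, drivers_only=True)
    myc = mat["MYC"]
    _require(int(myc.sum()) == 20, "MYC altered in 20 of 82 patients")
    uveal_ids = [c.sample_id for c in cohort.clinical if c.subtype == "uveal"]
    _require(bool(myc.loc[uveal_ids].all()), "every uveal patient MYC-amplified")

    expected_tables = {
        "genes_only": (19, 4, 26, 26),
        "genes_or_pretreated": (28, 6, 17, 24),
        "genes_cdkn2a_or_pretreated": (33, 10, 12, 20),
        "combination_k2": (9, 0, 36, 30),
    }
    for name, rule in standard_rules().items():
        perf = evaluate_rule(cohort, rule)
        _require(
            (perf.a, perf.b, perf.c, perf.d) == expected_tables[name],
            f"predictor table for {name}: got {(perf.a, perf.b, perf.c, perf.d)}",
        )

    clin = cohort.clinical_by_id()
    braf_pd = {s for s in braf if clin[s].ici_treated and clin[s].recist_response == "PD"}
    braf_ctrl = {
        s for s in braf if clin[s].ici_treated and clin[s].recist_response in ("SD", "PR")
    }
    pre = {s for s, c in clin.items() if c.braf_meki_pretreated}
    _require(
        len(braf_pd) == 18 and len(braf_pd & pre) == 16,
        "16 of 18 BRAF-mutated progressors pretreated with BRAF/MEKi",
    )
    _require(
        len(braf_ctrl) == 4 and len(braf_ctrl & pre) == 2,
        "2 of 4 BRAF-mutated SD/PR patients pretreated",
    )


_DATA_FILES = ("clinical.tsv", "variants.tsv", "cnv.tsv", "panel.tsv", "config.yaml")


def _data_root():
    return resources.files("melcohort").joinpath("data/paper_fixture")


def make_paper_fixture(out_dir: str | Path) -> Path:
    """Write the canonical fixture TSVs (shipped package data) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = _data_root()
    for name in _DATA_FILES:
        (out / name).write_bytes(root.joinpath(name).read_bytes())
    return out


def load_paper_fixture() -> Cohort:
    """Load the canonical fixture from package data (and re-verify it)."""
    from .io import read_cohort

    with resources.as_file(_data_root()) as d:
        cohort = read_cohort(
            d / "clinical.tsv",
            d / "variants.tsv",
            d / "cnv.tsv",
            d / "panel.tsv",
            target_size_mb=TARGET_SIZE_MB,
            genome_size_mb=GENOME_SIZE_MB,
        )
    verify_fixture(cohort)
    return cohort
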