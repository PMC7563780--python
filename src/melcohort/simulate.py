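"""Stochastic cohort generator with the statistical structure of the study.

The generator emulates the cohort-level statistical features the analysis
relies on, so every pipeline stage can be exercised (and its parameter
recovery checked) at arbitrary sample size without any patient data:

* histopathological subtype drawn from the observed proportions
  (42/14/9/8/9 over 82);
* per-subtype driver-alteration probabilities (Bernoulli per gene, with the
  uveal GNAQ/GNA11 pair drawn mutually exclusively);
* per-subtype adjusted-TMB distribution: log-normal parameterised by its
  median (9.4 / 1.5 / 3.2 / 2.8 / 7.5 mutations per Mb for cutaneous /
  acral / mucosal / uveal / occult), realised as passenger variant counts on
  non-tumor panel genes;
* per-subtype passenger CNV counts: negative binomial with the mean chosen
  numerically so the distribution's median matches the configured one
  (8 / 12.5 / 33 / 8 / 16);
* BRAF/MEKi pretreatment conditional on a BRAF driver;
* RECIST response from a two-point conditional model,
  P(PD | resistance-rule positive) = 28/34 and
  P(PD | rule negative) = 17/41, with non-progressors split SD:PR = 12:18.

Identical seeds give byte-identical serialized cohorts. What the generator
deliberately does not emulate: per-base sequence context, allele
frequencies, FFPE artifacts, or the exact published IQRs/ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fixture import FILLER_GENES, fixture_panel
from .models import CNVEvent, ClinicalRecord, Cohort, ConfigError, VariantRecord
from .predictor import ResistanceRule, apply_rule, standard_rules

__all__ = ["SimulationConfig", "simulate_cohort"]

_SUBTYPES = ("cutaneous", "acral", "mucosal", "uveal", "occult")

# per-subtype driver-alteration probabilities, taken from the reference
# cohort's observed frequencies. Each entry: gene -> (kind, direction, probs
# per subtype in _SUBTYPES order). kind "snv" emits a driver small variant,
# "cnv" a driver copy-number event.
_DEFAULT_GENE_MODEL: dict[str, tuple[str, str, tuple[float, ...]]] = {
    "BRAF": ("snv", "", (17 / 42, 1 / 14, 1 / 9, 0.0, 4 / 9)),
    "NRAS": ("snv", "", (17 / 42, 1 / 14, 0.0, 0.0, 0.0)),
    "KRAS": ("snv", "", (0.0, 1 / 14, 1 / 9, 0.0, 0.0)),
    "HRAS": ("snv", "", (0.0, 0.0, 0.0, 0.0, 1 / 9)),
    "NF1": ("snv", "", (3 / 42, 1 / 14, 0.0, 0.0, 1 / 9)),
    "TP53": ("snv", "", (4 / 42, 0.0, 3 / 9, 0.0, 0.0)),
    "GNA11": ("snv", "", (0.0, 0.0, 0.0, 0.5, 0.0)),
    "GNAQ": ("snv", "", (0.0, 0.0, 0.0, 0.5, 0.0)),
    "SF3B1": ("snv", "", (0.0, 0.0, 0.0, 0.5, 0.0)),
    "BAP1": ("snv", "", (0.0, 0.0, 0.0, 0.5, 0.0)),
    "PTEN": ("cnv", "deletion", (8 / 42, 4 / 14, 2 / 9, 0.0, 0.0)),
    "EGFR": ("cnv", "amplification", (3 / 42, 3 / 14, 0.0, 0.0, 0.0)),
    "CDKN2A": ("cnv", "deletion", (9 / 42, 4 / 14, 2 / 9, 0.0, 1 / 9)),
    "MYC": ("cnv", "amplification", (6 / 42, 3 / 14, 2 / 9, 1.0, 1 / 9)),
    "KIT": ("cnv", "amplification", (0.0, 4 / 14, 0.0, 0.0, 0.0)),
    "PDGFRA": ("cnv", "amplification", (0.0, 4 / 14, 0.0, 0.0, 0.0)),
    "CDK4": ("cnv", "amplification", (0.0, 4 / 14, 0.0, 0.0, 0.0)),
    "RICTOR": ("cnv", "amplification", (0.0, 2 / 14, 0.0, 0.0, 0.0)),
    "CCND2": ("cnv", "amplification", (0.0, 0.0, 5 / 9, 0.0, 0.0)),
    "CHEK2": ("cnv", "deletion", (0.0, 0.0, 3 / 9, 0.0, 0.0)),
}


@dataclass
class SimulationConfig:
    """Tunable study conditions for the stochastic generator."""

    n_patients: int = 82
    seed: int = 0
    subtype_proportions: tuple[float, ...] = (42 / 82, 14 / 82, 9 / 82, 8 / 82, 9 / 82)
    gene_model: dict[str, tuple[str, str, tuple[float, ...]]] = field(
        default_factory=lambda: dict(_DEFAULT_GENE_MODEL)
    )
    #: per-subtype adjusted-TMB medians (mutations/Mb) and log-normal sigma
    tmb_medians: tuple[float, ...] = (9.4, 1.5, 3.2, 2.8, 7.5)
    tmb_sigma: float = 0.8
    #: per-subtype passenger CNV-count medians and negative-binomial dispersion
    cnv_medians: tuple[float, ...] = (8.0, 12.5, 33.0, 8.0, 16.0)
    cnv_dispersion: float = 3.0
    #: probability of ICI treatment, and combined (vs anti-PD-1) regimen
    p_ici: float = 75 / 82
    p_combined: float = 60 / 75
    #: BRAF/MEKi pretreatment probability given a BRAF driver
    p_pretreated_given_braf: float = 18 / 23
    #: two-point conditional response model over the resistance rule
    p_pd_given_positive: float = 28 / 34
    p_pd_given_negative: float = 17 / 41
    #: SD fraction among non-progressors
    p_sd_given_control: float = 12 / 30
    #: rule defining "positive" for the response model
    response_rule: ResistanceRule = field(
        default_factory=lambda: standard_rules()["genes_or_pretreated"]
    )

    def validate(self) -> None:
        probs = [
            self.p_ici, self.p_combined, self.p_pretreated_given_braf,
            self.p_pd_given_positive, self.p_pd_given_negative, self.p_sd_given_control,
            *self.subtype_proportions,
        ]
        for _kind, _direction, ps in self.gene_model.values():
            probs.extend(ps)
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("all simulation probabilities must lie in [0, 1]")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ConfigError("subtype_proportions must sum to 1")
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")


def _nb_params_for_median(median: float, dispersion: float) -> tuple[float, float]:
    """Negative-binomial (n, p) whose median is as close as possible to the
    target (NB medians are integers, so a half-integer target is bracketed)."""
    lo, hi = max(median, 0.5), 3 * median + 5
    for _ in range(60):
        mean = 0.5 * (lo + hi)
        p = dispersion / (dispersion + mean)
        if stats.nbinom.median(dispersion, p) < median:
            lo = mean
        else:
            hi = mean
    mean = 0.5 * (lo + hi)
    return dispersion, dispersion / (dispersion + mean)


_SNV_CLASSES = ("missense", "nonsense", "frameshift", "splice")
_HOTSPOT_CHANGES = {
    "BRAF": "V600E", "NRAS": "Q61K", "KRAS": "G12D", "HRAS": "Q61R",
    "GNA11": "Q209L", "GNAQ": "Q209P", "SF3B1": "R625C",
}


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a synthetic cohort under the configured study conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    panel = fixture_panel()
    n = config.n_patients
    width = max(5, len(str(n)))
    ids = [f"SIM{i:0{width}d}" for i in range(1, n + 1)]
    subtype_idx = rng.choice(len(_SUBTYPES), size=n, p=config.subtype_proportions)

    # exclusive uveal pair: at most one of GNAQ/GNA11 per patient
    exclusive = ("GNA11", "GNAQ")
    variants: list[VariantRecord] = []
    cnvs: list[CNVEvent] = []
    altered: list[set[str]] = [set() for _ in range(n)]

    for gene, (kind, direction, probs) in sorted(config.gene_model.items()):
        p_per_patient = np.array([probs[s] for s in subtype_idx])
        if gene == exclusive[1]:  # GNAQ: drawn jointly with GNA11 below
            continue
        if gene == exclusive[0]:
            p_other = np.array([config.gene_model[exclusive[1]][2][s] for s in subtype_idx])
            total = p_per_patient + p_other
            if np.any(total > 1.0 + 1e-9):
                raise ConfigError("GNA11 + GNAQ probabilities must not exceed 1")
            u = rng.random(n)
            hit_a = u < p_per_patient
            hit_b = (~hit_a) & (u < total)
            for name, mask in ((exclusive[0], hit_a), (exclusive[1], hit_b)):
                for i in np.flatnonzero(mask):
                    altered[i].add(name)
                    variants.append(
                        VariantRecord(
                            ids[i], name, "missense", _HOTSPOT_CHANGES[name], True, True
                        )
                    )
            continue
        hits = rng.random(n) < p_per_patient
        for i in np.flatnonzero(hits):
            altered[i].add(gene)
            if kind == "snv":
                if gene in _HOTSPOT_CHANGES:
                    variants.append(
                        VariantRecord(ids[i], gene, "missense", _HOTSPOT_CHANGES[gene], True, True)
                    )
                else:
                    vclass = _SNV_CLASSES[rng.integers(len(_SNV_CLASSES))]
                    variants.append(
                        VariantRecord(ids[i], gene, vclass, f"E{rng.integers(100, 999)}K", True)
                    )
            else:
                cnvs.append(CNVEvent(ids[i], gene, direction, True))

    # passenger SNVs realising the per-subtype TMB distribution: a log-normal
    # TMB draw converted to a count of non-tumor-gene variants
    medians = np.array([config.tmb_medians[s] for s in subtype_idx])
    tmb_draw = medians * np.exp(config.tmb_sigma * rng.standard_normal(n))
    n_passenger = np.rint(tmb_draw * panel.target_size_mb).astype(int)
    for i in range(n):
        for j in range(n_passenger[i]):
            gene = FILLER_GENES[(i + j) % len(FILLER_GENES)]
            if j % 4 == 3:
                variants.append(
                    VariantRecord(ids[i], gene, "synonymous", f"L{200 + j}L", False)
                )
            else:
                variants.append(
                    VariantRecord(ids[i], gene, "missense", f"A{100 + j}V", False)
                )

    # passenger CNVs (non-driver) on filler genes, topping counts up to a
    # negative-binomial total per patient
    id_index = {pid: i for i, pid in enumerate(ids)}
    driver_cnv_count = np.zeros(n, dtype=int)
    for c in cnvs:
        driver_cnv_count[id_index[c.sample_id]] += 1
    for s_idx, subtype in enumerate(_SUBTYPES):
        mask = subtype_idx == s_idx
        if not mask.any():
            continue
        r, p = _nb_params_for_median(config.cnv_medians[s_idx], config.cnv_dispersion)
        totals = rng.negative_binomial(r, p, size=int(mask.sum()))
        for i, total in zip(np.flatnonzero(mask), totals):
            extra = max(0, int(total) - driver_cnv_count[i])
            for j in range(extra):
                gene = FILLER_GENES[(2 * i + j) % len(FILLER_GENES)]
                direction = "amplification" if j % 2 == 0 else "deletion"
                cnvs.append(CNVEvent(ids[i], gene, direction, False))

    # therapy and response
    pretreated = np.zeros(n, dtype=bool)
    has_braf = np.array(["BRAF" in altered[i] for i in range(n)])
    pretreated[has_braf] = rng.random(int(has_braf.sum())) < config.p_pretreated_given_braf
    ici = rng.random(n) < config.p_ici
    combined = rng.random(n) < config.p_combined

    clinical: list[ClinicalRecord] = []
    for i in range(n):
        if not ici[i]:
            regimen, response = "none", "not_applicable"
        else:
            regimen = "combined" if combined[i] else "anti_pd1"
            positive = apply_rule(config.response_rule, altered[i], bool(pretreated[i]))
            p_pd = config.p_pd_given_positive if positive else config.p_pd_given_negative
            if rng.random() < p_pd:
                response = "PD"
            else:
                response = "SD" if rng.random() < config.p_sd_given_control else "PR"
        clinical.append(
            ClinicalRecord(
                sample_id=ids[i],
                subtype=_SUBTYPES[subtype_idx[i]],
                ici_regimen=regimen,
                recist_response=response,
                braf_meki_pretreated=bool(pretreated[i]),
            )
        )

    return Cohort(clinical=clinical, variants=variants, cnvs=cnvs, panel=panel)
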