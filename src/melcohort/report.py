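"""End-to-end pipeline: burden -> classification -> enrichment -> predictor.

``run_pipeline`` chains every stage over a cohort directory and writes a
deterministic report bundle:

* ``tmb.tsv`` — per-sample adjusted burden (sample_id, n_somatic,
  n_tumorgene, tmb);
* ``classes.tsv`` — genomic subtype per patient with supporting variants;
* ``enrichment.tsv`` — subtype-vs-rest exact tests per gene;
* ``performance.json`` — 2x2 evaluation of every resistance rule;
* ``summary.txt`` — plain-text cohort summary in oncoplot order: per-gene
  driver-alteration percentages (descending) and per-subtype blocks.

Identical inputs and configuration produce byte-identical bundles.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .classify import class_counts, classify_cohort
from .enrichment import compare_burden, enrichment_table
from .io import alteration_matrix, read_cohort_dir
from .models import Cohort
from .predictor import ResistanceRule, evaluate_rule, standard_rules
from .tmb import compute_tmb_cohort

__all__ = ["run_pipeline", "cohort_summary_text"]

logger = logging.getLogger(__name__)


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            logger.info("[%s] running", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorator


def cohort_summary_text(cohort: Cohort) -> str:
    """Plain-text cohort summary: the textual analogue of an oncoplot."""
    lines: list[str] = []
    n = cohort.n_patients
    lines.append(f"melcohort v{__version__} cohort summary")
    lines.append(f"patients: {n}")
    ici = sum(1 for c in cohort.clinical if c.ici_treated)
    lines.append(f"ICI-treated: {ici}")
    counts = class_counts(cohort)
    lines.append(
        "genomic classes: "
        + "  ".join(f"{k}={v}" for k, v in counts.items())
    )
    lines.append("")
    lines.append("driver alteration frequency (all patients)")
    mat = alteration_matrix(cohort, include_cnv=True, drivers_only=True)
    freqs = mat.sum(axis=0)
    freqs = freqs[freqs > 0]
    order = sorted(freqs.index, key=lambda g: (-freqs[g], g))
    for g in order:
        pct = 100 * freqs[g] / n
        lines.append(f"  {g:<10s} {int(freqs[g]):3d}/{n}  {pct:5.1f}%")
    lines.append("")
    subtype_of = {c.sample_id: c.subtype for c in cohort.clinical}
    for subtype in ("cutaneous", "acral", "mucosal", "uveal", "occult"):
        ids = sorted(s for s, sub in subtype_of.items() if sub == subtype)
        if not ids:
            continue
        lines.append(f"[{subtype}] n={len(ids)}")
        sub = mat.loc[ids]
        sub_freqs = sub.sum(axis=0)
        top = sorted(
            (g for g in sub_freqs.index if sub_freqs[g] > 0),
            key=lambda g: (-sub_freqs[g], g),
        )[:8]
        for g in top:
            lines.append(
                f"  {g:<10s} {int(sub_freqs[g]):3d}/{len(ids)}  "
                f"{100 * sub_freqs[g] / len(ids):5.1f}%"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


def run_pipeline(
    cohort_dir: str | Path,
    out_dir: str | Path,
    alpha: float = 0.05,
    rules: dict[str, ResistanceRule] | None = None,
) -> dict:
    """Run every stage over a cohort directory; returns the performance dict."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = _stage("read")(read_cohort_dir)(cohort_dir)

    tmb_df = _stage("tmb")(compute_tmb_cohort)(cohort)
    tmb_df.round(6).to_csv(out / "tmb.tsv", sep="\t")

    classes = _stage("classify")(classify_cohort)(cohort)
    with open(out / "classes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tlabel\tevidence\n")
        for g in classes:
            evidence = ";".join(f"{gene}:{change}" for gene, change in g.evidence)
            fh.write(f"{g.sample_id}\t{g.label}\t{evidence}\n")

    enr = _stage("enrich")(enrichment_table)(cohort, alpha=alpha)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.6g")

    burden = {
        metric: _stage("burden")(compare_burden)(cohort, metric=metric)
        .reset_index()
        .to_dict(orient="records")
        for metric in ("tmb", "n_snv", "n_cnv")
    }

    rules = rules if rules is not None else standard_rules()
    performance = {
        name: _stage("predict")(evaluate_rule)(cohort, rule)
        for name, rule in rules.items()
    }
    payload = {
        "n_ici_patients": sum(1 for c in cohort.clinical if c.ici_treated),
        "rules": {name: perf.as_dict() for name, perf in performance.items()},
        "burden_comparisons": burden,
    }
    with open(out / "performance.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")

    summary = _stage("summary")(cohort_summary_text)(cohort)
    (out / "summary.txt").write_text(summary, encoding="utf-8")
    return payload
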