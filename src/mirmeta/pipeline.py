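"""Config-driven analysis pipeline with a reproducibility manifest.

A YAML config names the study tables and the stages to run; each stage
writes a TSV table plus a JSON sidecar under the output directory, and a
``manifest.json`` records the config hash, input digests and sample
totals so an identical config bit-reproduces every numeric output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import yaml

from . import __version__
from .study_io import (StudySet, StudySummary, attach_counts, load_fixture,
                       read_study_table, write_results)
from .effect_meta import (effects_from_studies, egger_test, leave_one_out,
                          pool, subgroup_pool)
from .dta_meta import pool_accuracy

logger = logging.getLogger("mirmeta")

STAGES = ("pool", "subgroup", "loo", "egger", "dta")


class PipelineError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_studies(cfg: dict, base: Path) -> tuple[StudySet, dict[str, str]]:
    digests: dict[str, str] = {}
    src = cfg.get("studies")
    if src is None:
        raise PipelineError("config must name a 'studies' table or fixture")
    if str(src).startswith("fixture:"):
        studies = load_fixture(str(src).split(":", 1)[1])
        digests[str(src)] = "packaged"
    else:
        p = (base / src).resolve()
        if not p.exists():
            raise PipelineError(f"missing input {p}")
        studies = read_study_table(p, "summary")
        digests[str(p)] = _sha256(p)

    counts_src = cfg.get("counts")
    if counts_src is not None:
        if str(counts_src).startswith("fixture:"):
            counts = load_fixture(str(counts_src).split(":", 1)[1])
            digests[str(counts_src)] = "packaged"
        else:
            p = (base / counts_src).resolve()
            if not p.exists():
                raise PipelineError(f"missing input {p}")
            counts = read_study_table(p, "counts")
            digests[str(p)] = _sha256(p)
    else:
        counts = []

    select = cfg.get("select") or {}
    studies = studies.subset(
        keys=select.get("keys"),
        specimen=select.get("specimen"),
        disease_subset=select.get("disease_subset"))

    for extra in cfg.get("extra_studies", []):
        studies = StudySet(
            studies=[*studies.studies, StudySummary(**extra)],
            counts=studies.counts, provenance=studies.provenance)
    if counts:
        keep = [c for c in counts if c.study_id in {s.key for s in studies}]
        studies = attach_counts(studies, keep)
    return studies, digests


def run_pipeline(config_path, out_dir=None) -> Path:
    """Execute the configured stages; returns the result directory."""
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    base = config_path.parent
    out = Path(out_dir) if out_dir else base / cfg.get("out", "results")
    out.mkdir(parents=True, exist_ok=True)

    stages = cfg.get("stages", [])
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise PipelineError(f"unknown stage(s) {unknown}; valid: {STAGES}")

    studies, digests = _load_studies(cfg, base)
    effect = cfg.get("effect", "hedges")
    model = cfg.get("model", "random_dl")
    correction = effect == "hedges"

    summary: dict = {}
    for stage in stages:
        logger.info("[%s] running on k=%d studies", stage, len(studies))
        try:
            if stage == "pool":
                effects = effects_from_studies(studies, correction=correction)
                res = pool(effects, model=model)
                write_results(res, out / "pool.tsv")
                summary["pool"] = {"pooled": res.pooled, "ci_low": res.ci_low,
                                   "ci_high": res.ci_high, "i2": res.i2}
            elif stage == "subgroup":
                effects = effects_from_studies(studies, correction=correction)
                groups = subgroup_pool(effects, model=model)
                summary["subgroup"] = {}
                for label, res in groups.items():
                    write_results(res, out / f"subgroup_{label}.tsv")
                    summary["subgroup"][label] = {
                        "pooled": res.pooled, "ci_low": res.ci_low,
                        "ci_high": res.ci_high, "k": res.k}
            elif stage == "loo":
                effects = effects_from_studies(studies, correction=correction)
                rows = [
                    {"omitted": sid, "pooled": r.pooled,
                     "ci_low": r.ci_low, "ci_high": r.ci_high}
                    for sid, r in leave_one_out(effects, model=model)]
                (out / "leave_one_out.tsv").write_text(
                    "omitted\tpooled\tci_low\tci_high\n" + "".join(
                        f"{r['omitted']}\t{r['pooled']:.17g}\t"
                        f"{r['ci_low']:.17g}\t{r['ci_high']:.17g}\n"
                        for r in rows))
                summary["loo"] = {
                    "min_pooled": min(r["pooled"] for r in rows),
                    "max_pooled": max(r["pooled"] for r in rows),
                    "all_ci_exclude_zero": all(
                        r["ci_low"] > 0 or r["ci_high"] < 0 for r in rows)}
            elif stage == "egger":
                effects = effects_from_studies(studies, correction=correction)
                bias = egger_test(effects)
                funnel = "effect\tse\n" + "".join(
                    f"{g:.17g}\t{s:.17g}\n" for g, s in bias.funnel_points)
                (out / "funnel.tsv").write_text(funnel)
                summary["egger"] = {"intercept": bias.intercept,
                                    "se": bias.se_intercept,
                                    "p_value": bias.p_value}
            elif stage == "dta":
                dta_cfg = cfg.get("dta", {})
                res = pool_accuracy(
                    studies.counts,
                    model=dta_cfg.get("model", "bivariate"),
                    correction=dta_cfg.get("correction", "zero"),
                    moses_weighting=dta_cfg.get("moses_weighting", "none"))
                write_results(res, out / "dta.tsv")
                res.curve_frame().to_csv(out / "sroc_curve.tsv", sep="\t",
                                         index=False, float_format="%.17g")
                summary["dta"] = {"auc": res.auc, "model": res.model,
                                  "pooled_sens": res.pooled_sens,
                                  "pooled_spec": res.pooled_spec}
        except Exception as err:
            raise PipelineError(f"stage {stage!r} failed: {err}") from err

    manifest = {
        "command": " ".join(sys.argv),
        "artifact_version": __version__,
        "config": str(config_path),
        "config_sha256": _sha256(config_path),
        "input_digests": digests,
        "seed": cfg.get("seed"),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "k_studies": len(studies),
        "n_case_total": sum(s.n_case for s in studies),
        "n_control_total": sum(s.n_control for s in studies),
        "stages": list(stages),
        "summary": summary,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out
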