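"""End-to-end orchestration: simulate -> quantify -> select -> train ->
evaluate -> survival, with one global seed fanned out deterministically to
per-stage seeds and a manifest recording versions, seeds and checksums.

The per-stage seed scheme is ``stage_seed = global_seed * 1000 + offset``
(offsets: simulate 1, folds 2, reads 3), kept below 2**31, so any stage can
be re-run in isolation and reproduce the full run's outputs byte for byte.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import classification_metrics, roc_auc
from .models import (
    CVConfig,
    clinical_design,
    build_nested_models,
    fit_logistic,
    linear_score,
    screen_clinical,
)
from .quantify import ExpressionMatrix
from .selection import CandidateCriteria, LabeledMatrix, candidate_table, select_candidates
from .survival import cox_fit, km_logrank
from .synthetic import (
    CohortConfig,
    clinical_frame,
    counts_frame,
    simulate_cohort,
    truth_frame,
)

_STAGE_OFFSETS = {"simulate": 1, "folds": 2, "reads": 3}


def stage_seed(global_seed: int, stage: str) -> int:
    return (global_seed * 1000 + _STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    outdir: str = "results/pipeline"
    seed: int = 7
    n_pcr: int = 30
    n_nonpcr: int = 69
    max_mm: int = 2
    normalization: str = "assigned"  # or "all"
    detect_fraction: float = 0.8
    median_floor: float = 100.0
    median_scope: str = "both_groups"
    n_folds: int = 5
    train_fraction: float = 0.8
    max_k: int = 3
    alpha_enter: float = 0.1
    cutoff_rule: str = "youden"
    matrix_path: str | None = None  # run on an existing matrix instead of simulating
    clinical_path: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for attr in ("matrix_path", "clinical_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p} does not exist")
        if self.normalization not in ("assigned", "all"):
            raise ValueError("normalization must be 'assigned' or 'all'")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonify) + "\n")


def _jsonify(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and return the run directory.

    Writes clinical.csv, counts.tsv, matrix.tsv, candidates.tsv,
    model_{cf,sr,c}.json, metrics.json, survival.json and manifest.json.
    Deterministic for a fixed config.
    """
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate (or load) -------------------------------------------------
    cohort_cfg = CohortConfig(
        n_pcr=config.n_pcr,
        n_nonpcr=config.n_nonpcr,
        seed=stage_seed(config.seed, "simulate"),
    )
    samples = simulate_cohort(cohort_cfg)
    clin = clinical_frame(samples)
    counts = counts_frame(samples)
    clin.to_csv(out / "clinical.csv")
    counts.to_csv(out / "counts.tsv", sep="\t")
    truth_frame(cohort_cfg).to_csv(out / "truth.csv")

    # --- quantify (normalize) ----------------------------------------------
    matrix = ExpressionMatrix.from_counts(counts)
    matrix.to_tsv(out / "matrix.tsv")
    labels = pd.Series(clin["group"])
    lm = LabeledMatrix(matrix=matrix, labels=labels)

    # --- select -------------------------------------------------------------
    crit = CandidateCriteria(
        detect_fraction=config.detect_fraction,
        median_floor=config.median_floor,
        median_scope=config.median_scope,
    )
    candidates = select_candidates(lm, crit)
    candidate_table(lm, crit).to_csv(out / "candidates.tsv", sep="\t")

    # --- train --------------------------------------------------------------
    records = [s.clinical for s in samples]
    y = np.array([1.0 if s.true_group == "pCR" else 0.0 for s in samples])
    cv = CVConfig(
        n_folds=config.n_folds,
        train_fraction=config.train_fraction,
        seed=stage_seed(config.seed, "folds"),
    )
    screened = screen_clinical(records, alpha_enter=config.alpha_enter)
    clin_design = clinical_design(records, screened) if screened else None

    from .models import rank_features_by_cv_or

    metrics_summary: dict = {"seed": config.seed, "candidates": candidates, "screened_clinical": screened}
    models_out: dict[str, dict] = {}

    if screened:
        cf_fit = fit_logistic(clin_design, y, firth=True)
        models_out["cf"] = {"coefficients": cf_fit.to_dict(), "terms": screened}
    if candidates:
        ranked = rank_features_by_cv_or(lm, candidates, cv)
        metrics_summary["ranked_features"] = ranked
        ranked_names = [f for f, _ in ranked]
        sr = build_nested_models(lm, ranked_names, None, max_k=config.max_k, cv=cv)
        models_out["sr"] = {
            "coefficients": sr.final_coefficients.to_dict(),
            "best_k": sr.best_k,
            "cv_metrics": [e.cv_metrics.to_dict() | {"k": e.k} for e in sr.entries],
        }
        if screened:
            c = build_nested_models(lm, ranked_names, clin_design, max_k=config.max_k, cv=cv)
            models_out["c"] = {
                "coefficients": c.final_coefficients.to_dict(),
                "best_k": c.best_k,
                "cv_metrics": [e.cv_metrics.to_dict() | {"k": e.k} for e in c.entries],
            }
    for name, payload in models_out.items():
        _write_json(out / f"model_{name}.json", payload | {"seed": config.seed})

    # --- evaluate -----------------------------------------------------------
    for name, payload in models_out.items():
        coeffs = payload["coefficients"]
        if coeffs["separation"] and not coeffs["extras"].get("firth"):
            continue
        terms = list(coeffs["coefficients"])
        design = pd.DataFrame(index=range(len(samples)))
        for t in terms:
            if t in matrix.feature_ids:
                design[t] = matrix.values[t].to_numpy()
            else:
                design[t] = clinical_design(records, [t])[t].to_numpy()
        scores = design.to_numpy() @ np.array([coeffs["coefficients"][t] for t in terms]) + coeffs["intercept"]
        roc = roc_auc(scores, y)
        cutoff = roc.youden_cutoff if config.cutoff_rule == "youden" else float(config.cutoff_rule)
        rep = classification_metrics(scores, y, cutoff)
        metrics_summary[f"{name}_pm"] = {
            "auc": roc.auc,
            "cutoff": cutoff,
            "sensitivity": roc.sensitivity,
            "specificity": roc.specificity,
            **rep.to_dict(),
        }
        metrics_summary.setdefault("_scores", {})[name] = scores.tolist()

    # --- survival -----------------------------------------------------------
    times = clin["os_time"].to_numpy()
    events = clin["os_event"].to_numpy().astype(int)
    groups = np.where(y == 1, "pCR", "non-pCR")
    km = km_logrank(times, events, groups)
    surv_out = {
        "os_logrank_stat": km.logrank_stat,
        "os_logrank_p": km.logrank_p,
    }
    cov = pd.DataFrame({"pCR": y})
    if events.sum() >= 10:
        cx = cox_fit(times, events, cov)
        surv_out["os_cox_hr_pcr"] = cx.hazard_ratios["pCR"]
    if "c" in models_out and "_scores" in metrics_summary and "c" in metrics_summary["_scores"]:
        scores = np.array(metrics_summary["_scores"]["c"])
        cutoff = metrics_summary["c_pm"]["cutoff"]
        high = np.where(scores >= cutoff, "C-PM high", "C-PM low")
        km2 = km_logrank(times, events, high)
        surv_out["os_logrank_cpm_p"] = km2.logrank_p
        if events.sum() >= 10:
            cx2 = cox_fit(times, events, pd.DataFrame({"C-PM high": (scores >= cutoff).astype(float)}))
            surv_out["os_cox_hr_cpm_high"] = cx2.hazard_ratios["C-PM high"]
    _write_json(out / "survival.json", surv_out)

    metrics_summary.pop("_scores", None)
    _write_json(out / "metrics.json", metrics_summary)

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in _STAGE_OFFSETS},
        "config": dataclasses.asdict(config),
        "checksums": {
            p.name: _sha256(p)
            for p in sorted(out.glob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    _write_json(out / "manifest.json", manifest)
    return out
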