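"""End-to-end orchestration: exclusions -> volumes -> outcomes -> model
search -> selected model -> prediction, with a run manifest.

Each stage reads and writes plain files (CSV tables, JSON model documents,
YAML config) so the stages are independently scriptable and testable; the
manifest records configuration hash, seed and per-stage record counts so a
run can be audited and reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import AgePrior, posterior
from .errors import ConfigurationError, ConsistencyError
from .model_search import (
    FitResult,
    SexSplitFit,
    enumerate_toothsets,
    fit_sex_model,
    select_model,
    explore,
)
from .outcomes import AVERAGING_MODES, enumerate_outcomes, outcome_series, redundancy_filter
from .segmentation import FDI_TEETH
from .synthetic import GeneratorConfig, generate_cohort, make_exclusion_fixture

__all__ = ["PipelineConfig", "apply_exclusions", "run_all", "fit_to_dict", "fit_from_dict"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Flat configuration of a full analysis run.

    Defaults reproduce the reference analysis settings: thresholds 63/100,
    redundancy cut 0.999, uniform age prior 14.0-23.0 y, majority
    threshold 18 y, ratio-mean averaging, per-observation variance
    weighting selected by AIC.
    """

    cohort_path: str | None = None
    ledger_path: str | None = None
    output_dir: str = "molarage_out"
    hard_max: int = 63
    predentine_max: int = 100
    redundancy_threshold: float = 0.999
    prior_lower: float = 14.0
    prior_upper: float = 23.0
    majority_threshold: float = 18.0
    averaging: str = "ratio_mean"
    filter_teeth: tuple[int, ...] = FDI_TEETH
    n_participants: int = 200
    seed: int = 0
    predict_ratios: tuple[float, ...] = ()
    predict_sex: str = "M"
    ratios_are_ln: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not 0.0 < self.redundancy_threshold <= 1.0:
            raise ConfigurationError(
                f"redundancy_threshold must lie in (0, 1], got {self.redundancy_threshold}"
            )
        if not self.prior_lower < self.prior_upper:
            raise ConfigurationError("prior_lower must be < prior_upper")
        if self.averaging not in AVERAGING_MODES:
            raise ConfigurationError(f"averaging must be one of {AVERAGING_MODES}")
        if not 0 <= self.hard_max < self.predentine_max:
            raise ConfigurationError("require 0 <= hard_max < predentine_max")
        if self.n_participants < 0:
            raise ConfigurationError("n_participants must be >= 0")
        self.filter_teeth = tuple(int(t) for t in self.filter_teeth)
        if any(t not in FDI_TEETH for t in self.filter_teeth):
            raise ConfigurationError(f"filter_teeth must be a subset of {FDI_TEETH}")

    def to_yaml(self, path: str | Path) -> None:
        doc = dataclasses.asdict(self)
        doc["filter_teeth"] = list(self.filter_teeth)
        doc["predict_ratios"] = list(self.predict_ratios)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "filter_teeth" in doc:
            doc["filter_teeth"] = tuple(doc["filter_teeth"])
        if "predict_ratios" in doc:
            doc["predict_ratios"] = tuple(doc["predict_ratios"])
        return cls(**doc)

    def config_hash(self) -> str:
        doc = dataclasses.asdict(self)
        doc["filter_teeth"] = list(self.filter_teeth)
        doc["predict_ratios"] = list(self.predict_ratios)
        return hashlib.sha256(json.dumps(doc, sort_keys=True).encode()).hexdigest()[:16]


def apply_exclusions(
    ledger: pd.DataFrame, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove flagged participants; report per-reason counts.

    Every ledger id must exist in the cohort (``ConsistencyError``
    otherwise); cohort participants absent from the ledger are treated as
    unflagged.  Retained rows keep the input order.
    """
    cohort_ids = set(cohort["participant_id"])
    unknown = set(ledger["participant_id"]) - cohort_ids
    if unknown:
        raise ConsistencyError(
            f"ledger ids not present in cohort: {sorted(unknown)[:5]}"
        )
    reason_by_id = dict(zip(ledger["participant_id"], ledger["exclusion_reason"]))
    reasons = cohort["participant_id"].map(lambda i: reason_by_id.get(i, "none"))
    counts = reasons[reasons != "none"].value_counts().to_dict()
    filtered = cohort[reasons == "none"].copy()
    filtered["excluded_reason"] = "none"
    return filtered.reset_index(drop=True), {str(k): int(v) for k, v in counts.items()}


def fit_to_dict(fit: FitResult | SexSplitFit, extra: dict | None = None) -> dict:
    """Serialize a fitted model (including sex-split fits) to a JSON-safe
    document with coefficient names, covariance, variances and weighting."""
    if isinstance(fit, SexSplitFit):
        return {
            "kind": "sex_split",
            "sex_model": fit.spec.sex_model,
            "weighting": fit.spec.weighting,
            "outcome": fit.spec.outcome_label,
            "teeth": list(fit.spec.teeth or ()),
            "aic": fit.aic,
            "fits": {sex: fit_to_dict(f) for sex, f in fit.fits.items()},
            **(extra or {}),
        }
    return {
        "kind": "wls",
        "sex_model": fit.spec.sex_model,
        "weighting": fit.spec.weighting,
        "outcome": fit.spec.outcome_label,
        "teeth": list(fit.spec.teeth or ()),
        "coef": fit.coef,
        "names": fit.names,
        "cov": np.asarray(fit.cov).tolist(),
        "sigma2": fit.sigma2,
        "sigma2_ml": fit.sigma2_ml,
        "sum_log_w": fit.sum_log_w,
        "n": fit.n,
        "k": fit.k,
        "aic": fit.aic,
        "pvalues": fit.pvalues,
        **(extra or {}),
    }


def fit_from_dict(doc: dict) -> FitResult | SexSplitFit:
    """Rebuild a fitted model from its JSON document."""
    from .model_search import ModelSpec

    spec = ModelSpec(
        doc["sex_model"], doc["weighting"], doc.get("outcome"),
        tuple(doc.get("teeth") or ()) or None,
    )
    if doc["kind"] == "sex_split":
        return SexSplitFit(
            fits={sex: fit_from_dict(sub) for sex, sub in doc["fits"].items()},
            spec=spec,
        )
    return FitResult(
        coef=doc["coef"],
        cov=np.asarray(doc["cov"], dtype=float),
        names=list(doc["names"]),
        sigma2=float(doc["sigma2"]),
        sigma2_ml=float(doc["sigma2_ml"]),
        sum_log_w=float(doc["sum_log_w"]),
        n=int(doc["n"]),
        k=int(doc["k"]),
        aic=float(doc["aic"]),
        pvalues=doc["pvalues"],
        spec=spec,
    )


def _stage(manifest: dict, name: str, t0: float, **counts) -> None:
    elapsed = time.perf_counter() - t0
    manifest["stages"].append({"stage": name, "elapsed_s": round(elapsed, 4), **counts})
    logger.info("stage %-16s %s (%.2fs)", name, counts, elapsed)


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write every artifact plus a manifest.

    Stages, in fixed order: load-or-simulate cohort -> exclusions ->
    outcome enumeration -> redundancy filter -> exploration over the 11
    tooth sets -> selected-model fit -> optional predictions.  Identical
    config + seed yields byte-identical numeric outputs.  Returns the
    manifest (also written to ``manifest.json``).
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": [],
        "warnings": [],
    }

    t0 = time.perf_counter()
    if config.cohort_path:
        cohort = pd.read_csv(config.cohort_path)
    else:
        cohort = generate_cohort(
            GeneratorConfig(n_participants=config.n_participants, seed=config.seed)
        )
        cohort.to_csv(out / "cohort.csv", index=False)
    n_enrolled = len(cohort)
    _stage(manifest, "cohort", t0, enrolled=n_enrolled)

    t0 = time.perf_counter()
    if config.ledger_path:
        ledger = pd.read_csv(config.ledger_path)
        cohort, excl_counts = apply_exclusions(ledger, cohort)
    else:
        excl_counts = {}
    n_analyzed = len(cohort)
    manifest["counts"] = {
        "enrolled": n_enrolled,
        "excluded": excl_counts,
        "analyzed": n_analyzed,
    }
    assert n_analyzed == n_enrolled - sum(excl_counts.values())
    _stage(manifest, "exclusions", t0, analyzed=n_analyzed, excluded=sum(excl_counts.values()))

    t0 = time.perf_counter()
    specs = enumerate_outcomes()
    retained, corr = redundancy_filter(
        cohort, specs, config.filter_teeth, r_threshold=config.redundancy_threshold
    )
    corr.to_csv(out / "outcome_correlations.csv")
    manifest["outcomes"] = {
        "enumerated": len(specs),
        "retained": [s.label for s in retained],
        "dropped": [s.label for s in specs if s not in retained],
    }
    _stage(manifest, "redundancy", t0, enumerated=len(specs), retained=len(retained))

    t0 = time.perf_counter()
    toothsets = enumerate_toothsets()
    report = explore(cohort, retained, toothsets, averaging=config.averaging)
    report.to_csv(out / "exploration.csv", index=False)
    n_skipped = int((report["status"] == "skipped").sum())
    if n_skipped:
        manifest["warnings"].append(f"{n_skipped} exploration candidate(s) skipped")
    manifest["exploration"] = {"rows": len(report), "skipped": n_skipped}
    _stage(manifest, "exploration", t0, rows=len(report), skipped=n_skipped)

    t0 = time.perf_counter()
    best = report[report["status"] == "ok"].iloc[0]
    best_teeth = tuple(int(t) for t in str(best["teeth"]).split("+"))
    best_spec = next(s for s in retained if s.label == best["outcome"])
    series = outcome_series(cohort, best_spec, best_teeth, averaging=config.averaging)
    selected = select_model(series, best_spec.label, best_teeth)
    model_doc = fit_to_dict(
        selected, extra={"seed": config.seed, "config_hash": config.config_hash()}
    )
    (out / "selected_model.json").write_text(json.dumps(model_doc, indent=2, sort_keys=True))
    manifest["selected_model"] = {
        "outcome": best_spec.label,
        "teeth": list(best_teeth),
        "sex_model": selected.spec.sex_model,
        "weighting": selected.spec.weighting,
        "aic": selected.aic,
    }
    _stage(manifest, "fit", t0, n=selected.n)

    if config.predict_ratios:
        t0 = time.perf_counter()
        prior = AgePrior(config.prior_lower, config.prior_upper)
        rows = []
        for ratio in config.predict_ratios:
            y = float(ratio) if config.ratios_are_ln else float(np.log(ratio))
            post = posterior(y, config.predict_sex, selected, prior)
            rows.append(
                {
                    "input": ratio,
                    "sex": config.predict_sex,
                    "y": y,
                    "posterior_mode": post.mode(),
                    "posterior_median": post.median(),
                    "p_over_threshold": post.prob_over(config.majority_threshold),
                }
            )
        pd.DataFrame(rows).to_csv(out / "predictions.csv", index=False)
        _stage(manifest, "predict", t0, predictions=len(rows))

    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
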