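"""End-to-end orchestration: simulate or load cohorts, dichotomize, fit both
Q-matrix specifications, assess fit, validate the Q-matrix, extract item
parameters and mastery probabilities, screen reduced item models, and compare
the two risk models — writing one artifact per stage plus a JSON manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError
from .gdina import (
    attribute_mastery_probabilities,
    classification_accuracy,
    classify,
    fit_gdina,
    item_param_se,
)
from .model_fit import fit_report, lr_test, residual_table
from .prediction import compare_models, define_outcome
from .qmatrix import (
    QMatrix,
    build_bifactor_qmatrix,
    build_nonbifactor_qmatrix,
    default_assignment,
    validate_qmatrix,
)
from .reduced_models import recommendation_table, select_item_models
from .simulate import SimulationConfig, generate_cohorts

log = logging.getLogger("cdmpro")


def dichotomize_likert(likert: np.ndarray, threshold: int = 4) -> np.ndarray:
    """Map 5-point ordinal responses to binary: 1 iff the value reaches the threshold."""
    if threshold not in (2, 3, 4, 5):
        raise InputError("threshold must lie in {2..5}")
    likert = np.asarray(likert)
    if not np.isin(likert, (1, 2, 3, 4, 5)).all():
        raise InputError("Likert values must lie in {1..5}")
    return (likert >= threshold).astype(int)


def cohort_bookkeeping(enrolled, completed) -> pd.DataFrame:
    """Per-cohort completion percentages (one decimal) and the pooled analyzed total."""
    enrolled = np.asarray(enrolled, dtype=int)
    completed = np.asarray(completed, dtype=int)
    if enrolled.shape != completed.shape:
        raise InputError("enrolled and completed must have equal length")
    if (completed > enrolled).any():
        raise InputError("completed cannot exceed enrolled")
    frame = pd.DataFrame(
        {
            "cohort": [chr(ord("A") + i) for i in range(enrolled.size)],
            "enrolled": enrolled,
            "completed": completed,
            "completion_pct": np.round(100.0 * completed / enrolled, 1),
        }
    )
    frame.attrs["pooled_total"] = int(completed.sum())
    return frame


@dataclass
class RunConfig:
    """Full-run configuration with the analysis defaults.

    Exactly one of ``input_paths`` (delimited-text cohort files) or a
    simulation block may be active; the seed is mandatory when simulating.
    """

    output_dir: str = "cdmpro_run"
    input_paths: list[str] | None = None
    simulate: bool = True
    seed: int | None = 0
    n_per_cohort: tuple[int, ...] = (151, 95, 111, 135)
    likert_threshold: int = 4
    structural: str = "higher_order"
    link: str = "identity"
    monotonic: bool = True
    pvaf_cutoff: float = 0.95
    alpha: float = 0.05
    sd_rule_multiplier: float = 0.5
    outcome_grouping: str = "per-cohort"  # or "pooled"
    dca_thresholds: tuple[float, float, float] = (0.01, 0.99, 0.01)
    compute_m2: bool = True
    calibration_bins: int = 10

    def __post_init__(self) -> None:
        if self.simulate and self.input_paths:
            raise ConfigError("choose either simulation or input paths, not both")
        if not self.simulate and not self.input_paths:
            raise ConfigError("either a simulation block or input paths is required")
        if self.simulate and self.seed is None:
            raise ConfigError("seed is mandatory when simulating")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "n_per_cohort" in raw:
            raw["n_per_cohort"] = tuple(raw["n_per_cohort"])
        if "dca_thresholds" in raw:
            raw["dca_thresholds"] = tuple(raw["dca_thresholds"])
        return cls(**raw)


def _load_cohorts(paths: list[str]) -> dict[str, pd.DataFrame]:
    frames = {}
    for idx, path in enumerate(paths):
        name = Path(path).stem
        frames[name or str(idx)] = pd.read_csv(path)
    return frames


def _stage(manifest: dict, name: str, path: Path, t0: float) -> None:
    manifest["stages"][name] = {"artifact": str(path), "seconds": round(time.time() - t0, 3)}
    log.info("stage %s -> %s (%.2fs)", name, path, time.time() - t0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis in order and return the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed, "config": {k: str(v) for k, v in vars(config).items()}}

    # --- stage 1: cohorts -------------------------------------------------
    t0 = time.time()
    if config.simulate:
        sim = SimulationConfig(
            n_per_cohort=config.n_per_cohort,
            sd_rule_multiplier=config.sd_rule_multiplier,
            seed=config.seed,
        )
        cohorts = generate_cohorts(sim)
        frames = {c.name: c.to_frame() for c in cohorts}
        (out / "cohorts").mkdir(exist_ok=True)
        for name, frame in frames.items():
            frame.to_csv(out / "cohorts" / f"cohort_{name}.csv", index=False)
        with open(out / "cohorts" / "generating_parameters.json", "w") as fh:
            json.dump(sim.to_jsonable(), fh, indent=2)
        qmatrix = sim.qmatrix
    else:
        frames = _load_cohorts(config.input_paths)
        qmatrix = build_bifactor_qmatrix(default_assignment())
    _stage(manifest, "cohorts", out / "cohorts", t0)

    item_cols = [c for c in next(iter(frames.values())).columns if c.startswith("item")]
    likert_cols = [c for c in next(iter(frames.values())).columns if c.startswith("likert")]

    # --- stage 2: dichotomization and outcome -----------------------------
    t0 = time.time()
    for name, frame in frames.items():
        if likert_cols:
            binary = dichotomize_likert(frame[likert_cols].to_numpy(), config.likert_threshold)
            frame[item_cols] = binary
            frame["total_score"] = frame[likert_cols].sum(axis=1)
        else:
            frame["total_score"] = frame[item_cols].sum(axis=1)
    pooled = pd.concat(frames.values(), keys=frames.keys(), names=["cohort", "row"]).reset_index(level=0)
    groups = pooled["cohort"].to_numpy() if config.outcome_grouping == "per-cohort" else None
    pooled["outcome"] = define_outcome(
        pooled["factb_t0"].to_numpy(), pooled["factb_t1"].to_numpy(), config.sd_rule_multiplier, groups
    )
    pooled.to_csv(out / "analysis_table.csv", index=False)
    _stage(manifest, "dichotomize", out / "analysis_table.csv", t0)

    # --- stage 3: fit both Q-matrix specifications (pooled) ----------------
    t0 = time.time()
    responses = pooled[item_cols].to_numpy()
    q_bi = qmatrix
    q_non = build_nonbifactor_qmatrix(default_assignment(len(item_cols)))
    fit_bi = fit_gdina(
        responses,
        q_bi,
        link=config.link,
        structural=config.structural,
        monotonic=config.monotonic,
        seed=config.seed or 0,
    )
    fit_non = fit_gdina(
        responses,
        q_non,
        link=config.link,
        structural=config.structural,
        monotonic=config.monotonic,
        seed=config.seed or 0,
    )
    q_bi.to_csv(out / "qmatrix_bifactor.csv")
    q_non.to_csv(out / "qmatrix_nonbifactor.csv")
    _stage(manifest, "gdina_fit", out / "qmatrix_bifactor.csv", t0)

    # --- stage 4: fit statistics ------------------------------------------
    t0 = time.time()
    report_bi = fit_report(fit_bi, compute_m2=config.compute_m2)
    report_non = fit_report(fit_non, compute_m2=config.compute_m2)
    x2, df, p = lr_test(fit_non, fit_bi)
    fit_stats = {
        "bifactor": report_bi,
        "nonbifactor": report_non,
        "lr_test": {"X2": x2, "df": df, "p": p},
        "selected": "bifactor" if report_bi["AIC"] <= report_non["AIC"] else "nonbifactor",
    }
    with open(out / "fit_statistics.json", "w") as fh:
        json.dump(fit_stats, fh, indent=2)
    residual_table(fit_bi).to_csv(out / "residuals_bifactor.csv", index=False)
    _stage(manifest, "fit_statistics", out / "fit_statistics.json", t0)

    fitted = fit_bi if fit_stats["selected"] == "bifactor" else fit_non

    # --- stage 5: Q-matrix validation (PVAF / mesa) ------------------------
    t0 = time.time()
    validation = validate_qmatrix(fitted, config.pvaf_cutoff)
    validation.to_csv(out / "qmatrix_validation.csv", index=False)
    _stage(manifest, "qmatrix_validation", out / "qmatrix_validation.csv", t0)

    # --- stage 6: item parameters, mastery probabilities, classification ---
    t0 = time.time()
    ses = item_param_se(fitted)
    params = fitted.item_params()
    rows = []
    for p_item, se in zip(params, ses):
        rows.append(
            {
                "item": fitted.qmatrix.item_labels[p_item.item],
                "link": p_item.link,
                "delta": list(map(float, p_item.delta)),
                "se_delta": [None if not np.isfinite(v) else float(v) for v in se["se_delta"]],
                "guess": p_item.guess,
                "slip": p_item.slip,
                "se_guess": None if not np.isfinite(se["se_guess"]) else float(se["se_guess"]),
                "se_slip": None if not np.isfinite(se["se_slip"]) else float(se["se_slip"]),
                "class_success_probs": list(map(float, p_item.success_probabilities)),
            }
        )
    with open(out / "item_parameters.json", "w") as fh:
        json.dump(rows, fh, indent=2)
    cdp = attribute_mastery_probabilities(fitted)
    cdp_frame = cdp.to_frame()
    cdp_frame.columns = [f"cdp_A{i + 1}" for i in range(cdp.values.shape[1])]
    cdp_frame.to_csv(out / "cdp.csv", index=False)
    mastery, modal = classify(fitted)
    test_acc, attr_acc = classification_accuracy(fitted)
    class_labels = ["".join(map(str, pat)) for pat in fitted.attr_patterns]
    modal_share = {class_labels[i]: float((modal == i).mean()) for i in range(len(class_labels))}
    summary = {
        "mastery_rates": {
            lab: float(mastery[:, k].mean()) for k, lab in enumerate(fitted.qmatrix.attribute_labels)
        },
        "latent_class_shares": modal_share,
        "accuracy_test_level": test_acc,
        "accuracy_attribute_level": {
            lab: float(attr_acc[k]) for k, lab in enumerate(fitted.qmatrix.attribute_labels)
        },
    }
    with open(out / "classification_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _stage(manifest, "item_parameters", out / "item_parameters.json", t0)

    # --- stage 7: reduced-model Wald screen --------------------------------
    t0 = time.time()
    recs = select_item_models(fitted, config.alpha)
    recommendation_table(recs, fitted.qmatrix.item_labels).to_csv(out / "wald_recommendations.csv", index=False)
    _stage(manifest, "wald", out / "wald_recommendations.csv", t0)

    # --- stage 8: incremental prediction -----------------------------------
    t0 = time.time()
    cdp_cols = list(cdp_frame.columns)
    analysis = pd.concat([pooled.reset_index(drop=True), cdp_frame], axis=1)
    lo, hi, step = config.dca_thresholds
    thresholds = np.arange(lo, hi + step / 2, step)
    comparison = compare_models(
        {name: grp.reset_index(drop=True) for name, grp in analysis.groupby("cohort")},
        cdp_columns=cdp_cols,
        thresholds=thresholds,
        bins=config.calibration_bins,
    )
    comparison.metrics.to_csv(out / "prediction_metrics.csv", index=False)
    with open(out / "prediction_comparison.json", "w") as fh:
        json.dump(comparison.to_jsonable(), fh, indent=2)
    _stage(manifest, "prediction", out / "prediction_comparison.json", t0)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
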