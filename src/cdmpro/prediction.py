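"""Incremental-prediction analysis of attribute-mastery probabilities.

Two logistic risk models for the "decreased quality of life" outcome are
compared per cohort: Model 1 uses TNM stage plus the conventional total
score, Model 2 replaces the total score with the K per-person attribute
mastery probabilities.  Incremental value is quantified by paired AUC
(DeLong), category-free net reclassification improvement (NRI), integrated
discrimination improvement (IDI), Brier score with a calibration table,
decision-curve net benefit, and the clinical impact curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm, rankdata

from .errors import InputError, RuleError, UndefinedMetricError
from .simulate import sd_rule_outcome


def define_outcome(
    factb_t0: np.ndarray,
    factb_t1: np.ndarray,
    multiplier: float = 0.5,
    groups: np.ndarray | None = None,
) -> np.ndarray:
    """Dichotomize quality-of-life change: 1 when the loss from baseline is at
    least ``multiplier`` sample SDs of the change scores.

    With ``groups`` given, the SD is computed within each group (per-cohort
    rule); otherwise pooled.
    """
    t0 = np.asarray(factb_t0, dtype=float)
    t1 = np.asarray(factb_t1, dtype=float)
    if t0.shape != t1.shape:
        raise InputError("baseline and follow-up score vectors differ in length")
    change = t1 - t0
    if groups is None:
        return sd_rule_outcome(change, multiplier)
    groups = np.asarray(groups)
    out = np.empty(change.size, dtype=int)
    for g in np.unique(groups):
        mask = groups == g
        out[mask] = sd_rule_outcome(change[mask], multiplier)
    return out


@dataclass
class RiskModel:
    """Fitted logistic risk model with per-person predicted probabilities."""

    predictors: list[str]
    coefficients: np.ndarray
    predicted: np.ndarray
    converged: bool
    separation: bool


def fit_risk_model(predictors, outcome, add_intercept: bool = True) -> RiskModel:
    """Maximum-likelihood logistic regression (Newton) with separation flagging."""
    x = pd.DataFrame(predictors)
    y = np.asarray(outcome, dtype=float)
    if len(np.unique(y)) < 2:
        raise UndefinedMetricError("outcome must contain both classes")
    if x.shape[0] <= x.shape[1]:
        raise InputError("need more observations than predictors")
    design = sm.add_constant(x, has_constant="add") if add_intercept else x
    separation = False
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, design).fit(disp=0, method="newton", tol=1e-8, maxiter=100)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:  # perfect separation aborts Newton
            separation = True
            res = sm.Logit(y, design).fit(disp=0, method="bfgs", maxiter=500)
    pred = np.asarray(res.predict(design))
    if not separation and (np.abs(res.params) > 25).any():
        separation = True
    eps = 1e-12
    return RiskModel(
        predictors=list(design.columns.astype(str)),
        coefficients=np.asarray(res.params),
        predicted=np.clip(pred, eps, 1 - eps),
        converged=converged,
        separation=separation,
    )


# ---------------------------------------------------------------------------
# Discrimination metrics
# ---------------------------------------------------------------------------

def _split(pred: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    events = pred[outcome == 1]
    nonevents = pred[outcome == 0]
    if events.size == 0 or nonevents.size == 0:
        raise UndefinedMetricError("both outcome classes required")
    return events, nonevents


def auc(pred, outcome) -> float:
    """Mann-Whitney concordance (ties count one half) via the rank formula."""
    events, nonevents = _split(pred, outcome)
    ranks = rankdata(np.concatenate([events, nonevents]))
    r1 = ranks[: events.size].sum()
    return float((r1 - events.size * (events.size + 1) / 2) / (events.size * nonevents.size))


def _placements(pred, outcome):
    """DeLong placement values V10 (per event) and V01 (per nonevent)."""
    events, nonevents = _split(pred, outcome)
    v10 = np.empty(events.size)
    for i, e in enumerate(events):
        v10[i] = ((e > nonevents).sum() + 0.5 * (e == nonevents).sum()) / nonevents.size
    v01 = np.empty(nonevents.size)
    for i, ne in enumerate(nonevents):
        v01[i] = ((events > ne).sum() + 0.5 * (events == ne).sum()) / events.size
    return v10, v01


def delong_compare(pred1, pred2, outcome) -> tuple[float, float, float]:
    """Paired DeLong comparison of two AUCs on the same persons.

    Returns (AUC2 - AUC1, z, two-sided p); z and p are NaN when the paired
    variance degenerates (e.g. identical predictions).
    """
    v10_1, v01_1 = _placements(pred1, outcome)
    v10_2, v01_2 = _placements(pred2, outcome)
    auc1, auc2 = v10_1.mean(), v10_2.mean()
    diff = float(auc2 - auc1)
    m, n = v10_1.size, v01_1.size
    if m < 2 or n < 2:
        return diff, float("nan"), float("nan")
    s10 = np.cov(np.vstack([v10_1, v10_2]))
    s01 = np.cov(np.vstack([v01_1, v01_2]))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    if var <= 1e-16:
        return diff, float("nan"), float("nan") if abs(diff) > 1e-12 else 1.0
    z = diff / np.sqrt(var)
    return diff, float(z), float(2 * norm.sf(abs(z)))


def continuous_nri(p_old, p_new, outcome) -> tuple[float, float, float]:
    """Category-free net reclassification improvement.

    NRI = [P(up|event) - P(down|event)] + [P(down|nonevent) - P(up|nonevent)]
    with "up" meaning the new model raises the predicted risk; asymptotic z
    from the multinomial variance of the two net proportions.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    ev = outcome == 1
    ne = outcome == 0
    if not ev.any() or not ne.any():
        raise UndefinedMetricError("both outcome classes required")
    up_e = float((p_new[ev] > p_old[ev]).mean())
    dn_e = float((p_new[ev] < p_old[ev]).mean())
    up_n = float((p_new[ne] > p_old[ne]).mean())
    dn_n = float((p_new[ne] < p_old[ne]).mean())
    nri = (up_e - dn_e) + (dn_n - up_n)
    var = (up_e + dn_e - (up_e - dn_e) ** 2) / ev.sum() + (up_n + dn_n - (dn_n - up_n) ** 2) / ne.sum()
    if var <= 1e-16:
        return float(nri), float("nan"), 1.0 if abs(nri) < 1e-12 else float("nan")
    z = nri / np.sqrt(var)
    return float(nri), float(z), float(2 * norm.sf(abs(z)))


def idi(p_old, p_new, outcome) -> tuple[float, float, float]:
    """Integrated discrimination improvement: the gain in discrimination slope.

    IDI = (mean new - old risk | events) - (mean new - old risk | nonevents);
    z from the standard error of the two mean differences.
    """
    p_old = np.asarray(p_old, dtype=float)
    p_new = np.asarray(p_new, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    ev = outcome == 1
    ne = outcome == 0
    if not ev.any() or not ne.any():
        raise UndefinedMetricError("both outcome classes required")
    d = p_new - p_old
    idi_val = float(d[ev].mean() - d[ne].mean())
    if ev.sum() < 2 or ne.sum() < 2:
        return idi_val, float("nan"), float("nan")
    var = d[ev].var(ddof=1) / ev.sum() + d[ne].var(ddof=1) / ne.sum()
    if var <= 1e-16:
        return idi_val, float("nan"), 1.0 if abs(idi_val) < 1e-12 else float("nan")
    z = idi_val / np.sqrt(var)
    return idi_val, float(z), float(2 * norm.sf(abs(z)))


def brier(pred, outcome) -> float:
    """Brier score x100: mean squared error of the predicted probabilities."""
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=float)
    return float(100.0 * np.mean((pred - outcome) ** 2))


def calibration_table(pred, outcome, bins: int = 10) -> pd.DataFrame:
    """Equal-frequency calibration bins: mean predicted vs observed event rate."""
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if bins < 2:
        raise InputError("need at least two bins")
    if pred.size < bins:
        raise InputError("fewer observations than bins")
    order = rankdata(pred, method="ordinal") - 1
    bin_id = (order * bins) // pred.size
    rows = []
    for b in range(bins):
        mask = bin_id == b
        if not mask.any():
            continue
        rows.append(
            {
                "bin": b + 1,
                "n": int(mask.sum()),
                "mean_predicted": float(pred[mask].mean()),
                "observed_rate": float(outcome[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision-analytic curves
# ---------------------------------------------------------------------------

def decision_curve(pred, outcome, thresholds=None) -> pd.DataFrame:
    """Net benefit over a threshold grid, with treat-all / treat-none references.

    NB(t) = TP/N - (FP/N) * t/(1-t) for the rule "high risk iff pred >= t".
    """
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    thresholds = np.arange(0.01, 1.0, 0.01) if thresholds is None else np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise InputError("thresholds must lie strictly inside (0, 1)")
    n = pred.size
    prev = outcome.mean()
    rows = []
    for t in thresholds:
        pos = pred >= t
        tp = float((pos & (outcome == 1)).sum()) / n
        fp = float((pos & (outcome == 0)).sum()) / n
        odds = t / (1 - t)
        rows.append(
            {
                "threshold": float(t),
                "net_benefit": tp - fp * odds,
                "treat_all": prev - (1 - prev) * odds,
                "treat_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


def clinical_impact(pred, outcome, thresholds=None, per: int = 1000) -> pd.DataFrame:
    """Clinical impact curve: per ``per`` patients, how many the model flags as
    high risk at each threshold and how many of those are true events."""
    pred = np.asarray(pred, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    thresholds = np.arange(0.01, 1.0, 0.01) if thresholds is None else np.asarray(thresholds, dtype=float)
    rows = []
    for t in thresholds:
        pos = pred >= t
        rows.append(
            {
                "threshold": float(t),
                "high_risk_per": float(per * pos.mean()),
                "events_high_risk_per": float(per * (pos & (outcome == 1)).mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Paired model comparison
# ---------------------------------------------------------------------------

@dataclass
class PredictionComparison:
    """Per-cohort paired evaluation of the two risk models."""

    metrics: pd.DataFrame
    calibration: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    dca: dict[str, dict[str, pd.DataFrame]] = field(default_factory=dict)
    cic: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_jsonable(self) -> dict:
        return {
            "metrics": self.metrics.to_dict(orient="records"),
            "calibration": {
                c: {m: t.to_dict(orient="records") for m, t in d.items()} for c, d in self.calibration.items()
            },
            "dca": {c: {m: t.to_dict(orient="records") for m, t in d.items()} for c, d in self.dca.items()},
            "cic": {c: t.to_dict(orient="records") for c, t in self.cic.items()},
        }


def compare_models(
    cohort_frames: dict[str, pd.DataFrame],
    cdp_columns: list[str],
    total_column: str = "total_score",
    tnm_column: str = "tnm",
    outcome_column: str = "outcome",
    thresholds=None,
    bins: int = 10,
) -> PredictionComparison:
    """Fit Model 1 (TNM + total score) and Model 2 (TNM + mastery
    probabilities) in each cohort and assemble every comparison metric.

    Each value of ``cohort_frames`` must carry aligned per-person columns for
    TNM stage, total score, the K mastery-probability columns, and the binary
    outcome.
    """
    rows = []
    calibration: dict = {}
    dca: dict = {}
    cic: dict = {}
    for name, frame in cohort_frames.items():
        try:
            y = frame[outcome_column].to_numpy()
            m1 = fit_risk_model(frame[[tnm_column, total_column]], y)
            m2 = fit_risk_model(frame[[tnm_column, *cdp_columns]], y)
            dauc, z_auc, p_auc = delong_compare(m1.predicted, m2.predicted, y)
            nri, z_nri, p_nri = continuous_nri(m1.predicted, m2.predicted, y)
            idi_val, z_idi, p_idi = idi(m1.predicted, m2.predicted, y)
        except (UndefinedMetricError, InputError, RuleError) as exc:
            raise type(exc)(f"cohort {name!r}: {exc}") from exc
        rows.append(
            {
                "cohort": name,
                "n": int(len(frame)),
                "prevalence": float(y.mean()),
                "auc_model1": auc(m1.predicted, y),
                "auc_model2": auc(m2.predicted, y),
                "delta_auc": dauc,
                "delong_p": p_auc,
                "nri_pct": 100.0 * nri,
                "nri_p": p_nri,
                "idi_pct": 100.0 * idi_val,
                "idi_p": p_idi,
                "brier_model1": brier(m1.predicted, y),
                "brier_model2": brier(m2.predicted, y),
                "separation_model1": m1.separation,
                "separation_model2": m2.separation,
            }
        )
        calibration[name] = {
            "model1": calibration_table(m1.predicted, y, bins=min(bins, len(frame) // 2)),
            "model2": calibration_table(m2.predicted, y, bins=min(bins, len(frame) // 2)),
        }
        dca[name] = {
            "model1": decision_curve(m1.predicted, y, thresholds),
            "model2": decision_curve(m2.predicted, y, thresholds),
        }
        cic[name] = clinical_impact(m2.predicted, y, thresholds)
    return PredictionComparison(metrics=pd.DataFrame(rows), calibration=calibration, dca=dca, cic=cic)
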