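"""Incremental-prediction metrics: hand examples and oracle equivalences."""

import json

import numpy as np
import pytest

from cdmpro.errors import InputError, RuleError, UndefinedMetricError
from cdmpro.prediction import (
    auc,
    brier,
    calibration_table,
    clinical_impact,
    compare_models,
    continuous_nri,
    decision_curve,
    define_outcome,
    delong_compare,
    fit_risk_model,
    idi,
)


def pair_count_auc(pred, outcome):
    """Brute-force concordance by exhaustive pair counting (ties count 1/2)."""
    events = [p for p, y in zip(pred, outcome) if y == 1]
    nonevents = [p for p, y in zip(pred, outcome) if y == 0]
    total = 0.0
    for e in events:
        for ne in nonevents:
            total += 1.0 if e > ne else (0.5 if e == ne else 0.0)
    return total / (len(events) * len(nonevents))


class TestOutcome:
    def test_hand_example(self):
        t0 = np.array([100.0, 100.0, 100.0, 100.0, 100.0])
        t1 = t0 + np.array([-20.0, -10.0, 0.0, 10.0, 20.0])
        assert define_outcome(t0, t1, 0.5).tolist() == [1, 1, 0, 0, 0]

    def test_all_gains_give_no_events(self):
        t0 = np.zeros(6)
        t1 = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        assert define_outcome(t0, t1).sum() == 0

    def test_zero_multiplier_is_sign_rule(self):
        t0 = np.zeros(4)
        t1 = np.array([-1.0, 0.0, 2.0, -3.0])
        assert define_outcome(t0, t1, 0.0).tolist() == [1, 1, 0, 1]

    def test_per_group_sd(self):
        t0 = np.zeros(8)
        t1 = np.array([-10, 10, -10, 10, -1, 1, -1, 1], dtype=float)
        groups = np.array(["a"] * 4 + ["b"] * 4)
        out = define_outcome(t0, t1, 0.5, groups)
        assert out.tolist() == [1, 0, 1, 0, 1, 0, 1, 0]

    def test_zero_variance_group_rejected(self):
        with pytest.raises(RuleError):
            define_outcome(np.zeros(4), np.ones(4))


class TestRiskModel:
    def test_two_by_two_odds_ratio(self):
        """Counts (20, 10 / 10, 20) give OR 4, slope ln 4."""
        x = np.repeat([0, 0, 1, 1], [20, 10, 10, 20])
        y = np.repeat([0, 1, 0, 1], [20, 10, 10, 20])
        model = fit_risk_model(x[:, None], y)
        assert model.coefficients[1] == pytest.approx(np.log(4.0), abs=1e-6)
        assert not model.separation

    def test_perfect_separation_flagged(self):
        x = np.concatenate([np.zeros(10), np.ones(10)])
        y = x.copy()
        model = fit_risk_model(x[:, None], y)
        assert model.separation

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            fit_risk_model(np.arange(10)[:, None], np.zeros(10))


class TestAUC:
    def test_hand_example(self):
        pred = np.array([0.9, 0.6, 0.7, 0.2])
        outcome = np.array([1, 1, 0, 0])
        assert auc(pred, outcome) == pytest.approx(0.75)

    def test_perfect_and_uninformative(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0
        assert auc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == 0.5

    def test_rank_formula_equals_pair_counting(self):
        """Oracle equivalence on random (tied) inputs."""
        rng = np.random.default_rng(13)
        for _ in range(20):
            pred = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=30)
            outcome = rng.integers(0, 2, size=30)
            if outcome.min() == outcome.max():
                continue
            assert auc(pred, outcome) == pytest.approx(pair_count_auc(pred, outcome), abs=1e-12)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auc([0.1, 0.9], [1, 1])


class TestDeLong:
    def test_identical_predictions(self):
        pred = np.array([0.8, 0.6, 0.4, 0.3, 0.7, 0.2])
        outcome = np.array([1, 1, 0, 0, 1, 0])
        diff, _, p = delong_compare(pred, pred, outcome)
        assert diff == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(21)
        p1 = rng.random(40)
        p2 = rng.random(40)
        outcome = rng.integers(0, 2, size=40)
        outcome[:2] = [0, 1]
        d12, z12, _ = delong_compare(p1, p2, outcome)
        d21, z21, _ = delong_compare(p2, p1, outcome)
        assert d12 == pytest.approx(-d21)
        assert z12 == pytest.approx(-z21)


class TestNRI:
    def test_maximal(self):
        p_old = np.array([0.4, 0.4, 0.6, 0.6])
        p_new = np.array([0.9, 0.9, 0.1, 0.1])
        outcome = np.array([1, 1, 0, 0])
        nri, _, _ = continuous_nri(p_old, p_new, outcome)
        assert nri == pytest.approx(2.0)

    def test_hand_count(self):
        """Events 3 up 1 down, nonevents 3 down 1 up: NRI = 0.5 + 0.5 = 1.0."""
        p_old = np.array([0.5] * 8)
        p_new = np.array([0.6, 0.6, 0.6, 0.4, 0.4, 0.4, 0.4, 0.6])
        outcome = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        nri, z, p = continuous_nri(p_old, p_new, outcome)
        assert nri == pytest.approx(1.0)
        assert z > 0

    def test_no_movement_is_zero(self):
        pred = np.array([0.3, 0.6, 0.2, 0.8])
        outcome = np.array([0, 1, 0, 1])
        nri, _, _ = continuous_nri(pred, pred, outcome)
        assert nri == 0.0


class TestIDI:
    def test_hand_example(self):
        p_old = np.array([0.6, 0.6, 0.3, 0.3])
        p_new = np.array([0.8, 0.8, 0.2, 0.2])
        outcome = np.array([1, 1, 0, 0])
        val, _, _ = idi(p_old, p_new, outcome)
        assert val == pytest.approx(0.3)

    def test_identical_predictions_zero(self):
        pred = np.array([0.2, 0.4, 0.6, 0.8])
        outcome = np.array([0, 0, 1, 1])
        val, _, p = idi(pred, pred, outcome)
        assert val == 0.0 and p == 1.0


class TestBrier:
    def test_perfect_and_constant(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.5] * 4, [1, 0, 1, 0]) == pytest.approx(25.0)

    def test_calibrated_simulation(self):
        """Under outcome ~ Bernoulli(pred), Brier approximates 100 E[p(1-p)]."""
        rng = np.random.default_rng(29)
        pred = rng.uniform(0.05, 0.95, size=20000)
        outcome = (rng.random(20000) < pred).astype(int)
        expected = 100 * np.mean(pred * (1 - pred))
        mc_se = 100 * 3 * np.std((pred - outcome) ** 2) / np.sqrt(20000)
        assert abs(brier(pred, outcome) - expected) < mc_se


class TestCalibrationTable:
    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(33)
        pred = rng.random(137)
        outcome = rng.integers(0, 2, size=137)
        table = calibration_table(pred, outcome, bins=10)
        assert table["n"].sum() == 137

    def test_calibrated_bins(self):
        rng = np.random.default_rng(35)
        pred = rng.uniform(0.1, 0.9, size=20000)
        outcome = (rng.random(20000) < pred).astype(int)
        table = calibration_table(pred, outcome, bins=10)
        for _, row in table.iterrows():
            se = 3 * np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["n"])
            assert abs(row["observed_rate"] - row["mean_predicted"]) < se

    def test_constant_predictor(self):
        pred = np.full(50, 0.4)
        outcome = np.r_[np.ones(20), np.zeros(30)].astype(int)
        table = calibration_table(pred, outcome, bins=5)
        assert (table["mean_predicted"] == 0.4).all()
        pooled = (table["observed_rate"] * table["n"]).sum() / table["n"].sum()
        assert pooled == pytest.approx(0.4)

    def test_too_few_observations(self):
        with pytest.raises(InputError):
            calibration_table([0.5, 0.6], [0, 1], bins=5)


class TestDecisionCurves:
    def test_treat_all_closed_form(self):
        pred = np.full(100, 0.99)
        outcome = np.r_[np.ones(30), np.zeros(70)].astype(int)
        table = decision_curve(pred, outcome, thresholds=[0.2])
        assert table["net_benefit"][0] == pytest.approx(0.3 - 0.7 * 0.25)
        assert table["treat_all"][0] == pytest.approx(0.3 - 0.7 * 0.25)
        assert table["treat_none"][0] == 0.0

    def test_perfect_predictor(self):
        outcome = np.r_[np.ones(30), np.zeros(70)].astype(int)
        pred = outcome.astype(float)
        table = decision_curve(pred, outcome, thresholds=[0.1])
        assert table["net_benefit"][0] == pytest.approx(0.3)

    def test_perfect_predictor_dominates(self):
        rng = np.random.default_rng(43)
        outcome = rng.integers(0, 2, size=200)
        pred = np.clip(outcome + rng.normal(0, 1e-6, 200), 0.001, 0.999)
        table = decision_curve(pred, outcome, thresholds=np.arange(0.05, 0.95, 0.05))
        assert (table["net_benefit"] >= table["treat_all"] - 1e-9).all()
        assert (table["net_benefit"] >= -1e-9).all()

    def test_invalid_thresholds(self):
        with pytest.raises(InputError):
            decision_curve([0.5], [1], thresholds=[0.0, 0.5])

    def test_clinical_impact_boundaries_and_monotonicity(self):
        outcome = np.r_[np.ones(30), np.zeros(70)].astype(int)
        pred = np.linspace(0.2, 0.8, 100)
        table = clinical_impact(pred, outcome, thresholds=[0.1, 0.3, 0.5, 0.7, 0.9])
        assert table["high_risk_per"][0] == 1000.0
        assert table["events_high_risk_per"][0] == pytest.approx(300.0)
        assert table["high_risk_per"].iloc[-1] == 0.0
        assert table["high_risk_per"].is_monotonic_decreasing


class TestCompareModels:
    def _frames(self, with_signal=False):
        import pandas as pd

        rng = np.random.default_rng(47)
        frames = {}
        for name in ("A", "B"):
            n = 120
            tnm = rng.integers(1, 5, size=n)
            total = rng.normal(30, 6, size=n)
            risk = 1 / (1 + np.exp(-(0.3 * (tnm - 2) - 0.1 * (total - 30))))
            outcome = (rng.random(n) < risk).astype(int)
            outcome[:3] = [0, 1, 1]
            frame = pd.DataFrame({"tnm": tnm, "total_score": total, "outcome": outcome})
            for k in range(3):
                frame[f"cdp_A{k+1}"] = total / total.max() if not with_signal else rng.random(n)
            frames[name] = frame
        return frames

    def test_identical_predictors_give_null_increment(self):
        """CDP columns carrying only the total score: no incremental value."""
        import pandas as pd

        rng = np.random.default_rng(53)
        n = 150
        tnm = rng.integers(1, 5, size=n)
        total = rng.normal(30, 6, size=n)
        outcome = (rng.random(n) < 0.3).astype(int)
        outcome[:2] = [0, 1]
        frame = pd.DataFrame({"tnm": tnm, "total_score": total, "outcome": outcome})
        frame["cdp_A1"] = total
        comparison = compare_models({"A": frame}, cdp_columns=["cdp_A1"])
        row = comparison.metrics.iloc[0]
        assert row["delta_auc"] == pytest.approx(0.0, abs=1e-9)
        assert row["nri_pct"] == pytest.approx(0.0, abs=1e-6)
        assert row["idi_pct"] == pytest.approx(0.0, abs=1e-6)

    def test_report_serializes_losslessly(self):
        comparison = compare_models(self._frames(), cdp_columns=["cdp_A1", "cdp_A2", "cdp_A3"])
        payload = comparison.to_jsonable()
        text = json.dumps(payload)
        assert json.loads(text) == payload
        assert {r["cohort"] for r in payload["metrics"]} == {"A", "B"}
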