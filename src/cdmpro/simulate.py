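"""Seeded synthetic cohorts with the statistical structure the analysis assumes.

Emulates a multicenter design of four breast-cancer cohorts administered a
10-item resilience scale: attribute profiles drawn from a higher-order 2PL
latent-trait model, item responses from a G-DINA response function over a
bifactor Q-matrix, an optional 5-point Likert emission layer, TNM stage as an
ordinal covariate, and a quality-of-life outcome dichotomized by the
">= 0.5 SD loss in the 0-144 instrument total" rule.  Everything is
reproducible from a single seed expanded into per-stage substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError, ParameterError, RuleError
from .gdina import delta_to_probs, attribute_patterns
from .qmatrix import QMatrix, build_bifactor_qmatrix, default_assignment

FACTB_RANGE = (0.0, 144.0)
DEFAULT_COHORT_SIZES = (151, 95, 111, 135)
DEFAULT_COHORT_NAMES = ("A", "B", "C", "D")

#: default 5-point emission: a correct (1) binary response surfaces as Likert
#: 4 or 5, an incorrect (0) one as 1-3, so dichotomizing at >= 4 is exact.
DEFAULT_LIKERT_EMISSION = {1: {4: 0.45, 5: 0.55}, 0: {1: 0.25, 2: 0.45, 3: 0.30}}


@dataclass
class SimulationConfig:
    """Generating parameters for the synthetic multicohort study."""

    n_per_cohort: tuple[int, ...] = DEFAULT_COHORT_SIZES
    qmatrix: QMatrix = None
    item_deltas: list[np.ndarray] = None
    link: str = "identity"
    higher_order_slopes: np.ndarray = None
    higher_order_intercepts: np.ndarray = None
    outcome_coefficients: dict = None
    likert_emission: dict | None = None
    sd_rule_multiplier: float = 0.5
    seed: int = 0
    monotonic: bool = True

    def __post_init__(self) -> None:
        if self.qmatrix is None:
            self.qmatrix = build_bifactor_qmatrix(default_assignment())
        if self.item_deltas is None:
            self.item_deltas = default_item_deltas(self.qmatrix)
        if self.higher_order_slopes is None:
            # slopes/intercepts giving mastery prevalences near 68 / 41 / 46%
            self.higher_order_slopes = np.array([1.5, 1.5, 1.5])
            self.higher_order_intercepts = np.array([0.98, -0.47, -0.24])
        self.higher_order_slopes = np.asarray(self.higher_order_slopes, dtype=float)
        self.higher_order_intercepts = np.asarray(self.higher_order_intercepts, dtype=float)
        if self.outcome_coefficients is None:
            self.outcome_coefficients = default_outcome_coefficients()
        if self.likert_emission is None:
            self.likert_emission = DEFAULT_LIKERT_EMISSION
        if len(self.n_per_cohort) == 0 or any(int(n) < 1 for n in self.n_per_cohort):
            raise ConfigError("every cohort size must be a positive integer")
        if self.sd_rule_multiplier < 0:
            raise ConfigError("sd_rule_multiplier must be nonnegative")
        if not (
            np.isfinite(self.higher_order_slopes).all()
            and np.isfinite(self.higher_order_intercepts).all()
        ):
            raise ParameterError("higher-order parameters must be finite")
        if (self.higher_order_slopes < 0).any():
            raise ParameterError("higher-order slopes must be nonnegative")
        for jj, delta in enumerate(self.item_deltas):
            probs = delta_to_probs(np.asarray(delta, dtype=float), self.link)
            kst = int(self.qmatrix.kstar[jj])
            if probs.size != 2**kst:
                raise ParameterError(f"item {jj}: delta length inconsistent with K*={kst}")
            if self.monotonic and _violates_monotonicity(probs, kst):
                raise ParameterError(f"item {jj}: deltas violate monotonicity")

    def to_jsonable(self) -> dict:
        return {
            "n_per_cohort": [int(n) for n in self.n_per_cohort],
            "qmatrix": self.qmatrix.to_frame().to_dict(),
            "item_deltas": [list(map(float, d)) for d in self.item_deltas],
            "link": self.link,
            "higher_order_slopes": self.higher_order_slopes.tolist(),
            "higher_order_intercepts": self.higher_order_intercepts.tolist(),
            "outcome_coefficients": {
                k: (list(map(float, v)) if isinstance(v, (list, tuple, np.ndarray)) else float(v))
                for k, v in self.outcome_coefficients.items()
            },
            "likert_emission": {str(k): {str(c): float(p) for c, p in v.items()} for k, v in self.likert_emission.items()},
            "sd_rule_multiplier": float(self.sd_rule_multiplier),
            "seed": int(self.seed),
        }


def _violates_monotonicity(probs: np.ndarray, kstar: int) -> bool:
    pats = attribute_patterns(kstar)
    for i, a in enumerate(pats):
        for jdx, b in enumerate(pats):
            if (a <= b).all() and probs[jdx] < probs[i] - 1e-12:
                return True
    return False


#: default reduced-class success probabilities (00, 10, 01, 11) per item:
#: guessing floors 0.05-0.12, mastery ceilings 0.92-0.97, and the general
#: factor carrying the larger main effect so the two intermediate classes are
#: well separated (the all-two-attribute bifactor design is only weakly
#: identified when the specific and general effects are similar in size)
DEFAULT_ITEM_CLASS_PROBS = (
    (0.05, 0.30, 0.62, 0.95),
    (0.10, 0.35, 0.65, 0.93),
    (0.08, 0.40, 0.60, 0.96),
    (0.12, 0.32, 0.68, 0.92),
    (0.06, 0.38, 0.63, 0.97),
    (0.07, 0.33, 0.66, 0.94),
    (0.11, 0.36, 0.61, 0.95),
    (0.09, 0.31, 0.69, 0.93),
    (0.05, 0.37, 0.64, 0.96),
    (0.10, 0.34, 0.67, 0.92),
)


def default_item_deltas(qmatrix: QMatrix) -> list[np.ndarray]:
    """Plausible identity-link deltas for well-constructed two-attribute items."""
    from .gdina import probs_to_delta

    deltas = []
    for jj in range(qmatrix.n_items):
        kst = int(qmatrix.kstar[jj])
        probs = np.asarray(DEFAULT_ITEM_CLASS_PROBS[jj % len(DEFAULT_ITEM_CLASS_PROBS)])
        if kst == 2:
            deltas.append(probs_to_delta(probs))
        elif kst == 1:
            deltas.append(np.array([probs[0], probs[-1] - probs[0]]))
        else:
            raise ParameterError("default deltas defined for K* in {1, 2} only")
    return deltas


def default_outcome_coefficients() -> dict:
    """Logistic loss-risk coefficients on (intercept, TNM stage, attribute profile).

    The general resilience factor is strongly protective while the specific
    attributes pull in opposite directions; an equally weighted total score
    cannot express such a profile pattern, which is exactly the situation in
    which per-attribute mastery probabilities add predictive value.
    """
    return {
        "intercept": -0.3,
        "tnm": 0.55,
        "attributes": np.array([0.8, -1.0, -3.0]),
        "change_base": 10.0,
        "change_span": 40.0,
        "change_sd": 5.0,
        "t0_mean": 98.0,
        "t0_sd": 14.0,
    }


@dataclass
class SyntheticCohort:
    """One simulated cohort with all downstream inputs."""

    name: str
    responses: np.ndarray  # N x J binary
    likert: np.ndarray | None  # N x J in {1..5}
    true_profiles: np.ndarray  # N x K binary
    tnm_stage: np.ndarray  # N ordinal 1..4
    factb_t0: np.ndarray
    factb_t1: np.ndarray
    outcome: np.ndarray  # N binary

    @property
    def n(self) -> int:
        return self.responses.shape[0]

    def to_frame(self) -> pd.DataFrame:
        j = self.responses.shape[1]
        k = self.true_profiles.shape[1]
        data = {f"item{i + 1}": self.responses[:, i] for i in range(j)}
        if self.likert is not None:
            data.update({f"likert{i + 1}": self.likert[:, i] for i in range(j)})
        data.update({f"true_A{i + 1}": self.true_profiles[:, i] for i in range(k)})
        data["tnm"] = self.tnm_stage
        data["factb_t0"] = self.factb_t0
        data["factb_t1"] = self.factb_t1
        data["outcome"] = self.outcome
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Sampling stages
# ---------------------------------------------------------------------------

def sample_attribute_profiles(
    n: int,
    slopes: np.ndarray,
    intercepts: np.ndarray,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw N x K mastery profiles from the higher-order 2PL model.

    Each person draws a standard-normal trait theta; attribute k is mastered
    with probability expit(a_k theta + d_k), conditionally independently.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    slopes = np.asarray(slopes, dtype=float)
    intercepts = np.asarray(intercepts, dtype=float)
    if not (np.isfinite(slopes).all() and np.isfinite(intercepts).all()):
        raise ParameterError("non-finite higher-order parameters")
    if (slopes < 0).any():
        raise ParameterError("slopes must be nonnegative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    theta = rng.standard_normal(n)
    p = expit(theta[:, None] * slopes[None, :] + intercepts[None, :])
    return (rng.random((n, slopes.size)) < p).astype(int)


def sample_item_responses(
    profiles: np.ndarray,
    qmatrix: QMatrix,
    item_deltas: list[np.ndarray],
    link: str = "identity",
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bernoulli responses from the G-DINA response function."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    profiles = np.asarray(profiles, dtype=int)
    n = profiles.shape[0]
    j = qmatrix.n_items
    probs = np.empty((n, j))
    for jj in range(j):
        cols = np.flatnonzero(qmatrix.entries[jj])
        red_p = delta_to_probs(np.asarray(item_deltas[jj], dtype=float), link)
        idx = profiles[:, cols] @ (1 << np.arange(len(cols))[::-1])
        probs[:, jj] = red_p[idx]
    if (probs < 0).any() or (probs > 1).any():
        raise ParameterError("implied response probability outside [0, 1]")
    return (rng.random((n, j)) < probs).astype(int)


def emit_likert(
    responses: np.ndarray,
    emission: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Overlay a 5-point ordinal scale on binary responses.

    The emission rule maps 1 to categories {4, 5} and 0 to {1, 2, 3} with
    stated probabilities, so dichotomizing at >= 4 recovers the binary input
    exactly.
    """
    emission = emission or DEFAULT_LIKERT_EMISSION
    for side, allowed in ((1, {4, 5}), (0, {1, 2, 3})):
        rule = emission[side]
        if not set(rule) <= allowed:
            raise ParameterError(f"emission for binary {side} must use categories {sorted(allowed)}")
        if abs(sum(rule.values()) - 1.0) > 1e-9:
            raise ParameterError(f"emission probabilities for binary {side} must sum to 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    responses = np.asarray(responses, dtype=int)
    out = np.empty_like(responses)
    for side in (0, 1):
        cats = np.array(sorted(emission[side]))
        p = np.array([emission[side][c] for c in cats])
        mask = responses == side
        out[mask] = rng.choice(cats, size=int(mask.sum()), p=p)
    return out


def sd_rule_outcome(change: np.ndarray, multiplier: float = 0.5) -> np.ndarray:
    """Dichotomize change scores: 1 when the loss is at least ``multiplier``
    sample SDs (n-1 denominator) of the change distribution."""
    change = np.asarray(change, dtype=float)
    if change.size < 2:
        raise RuleError("need at least two change scores")
    sd = float(np.std(change, ddof=1))
    if sd == 0.0:
        raise RuleError("zero-variance change scores: SD rule undefined")
    return (change <= -multiplier * sd).astype(int)


def sample_outcome(
    profiles: np.ndarray,
    tnm: np.ndarray,
    coefficients: dict | None = None,
    sd_multiplier: float = 0.5,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw FACT-B totals at baseline and follow-up plus the dichotomized outcome.

    The expected QoL loss increases with the logistic risk
    expit(b0 + b_tnm * tnm + b' profile); scores are clipped to the 0-144
    instrument range and the outcome is recomputed from the generated scores
    by the SD rule, never stored independently of it.
    """
    coefficients = coefficients or default_outcome_coefficients()
    b_attr = np.asarray(coefficients["attributes"], dtype=float)
    vals = [coefficients["intercept"], coefficients["tnm"], *b_attr]
    if not np.all(np.isfinite(vals)):
        raise ParameterError("outcome coefficients must be finite")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    profiles = np.asarray(profiles, dtype=float)
    tnm = np.asarray(tnm, dtype=float)
    eta = coefficients["intercept"] + coefficients["tnm"] * (tnm - 2.0) + profiles @ b_attr
    risk = expit(eta)
    n = profiles.shape[0]
    t0 = np.clip(
        rng.normal(coefficients["t0_mean"], coefficients["t0_sd"], size=n), *FACTB_RANGE
    )
    change = (
        coefficients["change_base"]
        - coefficients["change_span"] * risk
        + rng.normal(0.0, coefficients["change_sd"], size=n)
    )
    t1 = np.clip(t0 + change, *FACTB_RANGE)
    outcome = sd_rule_outcome(t1 - t0, sd_multiplier)
    return t0, t1, outcome


def sample_tnm(n: int, rng: np.random.Generator) -> np.ndarray:
    """Ordinal TNM stage codes 1-4 with a unimodal stage distribution."""
    return rng.choice([1, 2, 3, 4], size=n, p=[0.15, 0.40, 0.30, 0.15])


def generate_cohorts(config: SimulationConfig) -> list[SyntheticCohort]:
    """Generate one cohort per entry of ``config.n_per_cohort``.

    A single seed is expanded into independent per-cohort, per-stage
    substreams so any stage can be reproduced in isolation.
    """
    ss = np.random.SeedSequence(config.seed)
    cohort_seeds = ss.spawn(len(config.n_per_cohort))
    cohorts = []
    for idx, (n, cseed) in enumerate(zip(config.n_per_cohort, cohort_seeds)):
        name = DEFAULT_COHORT_NAMES[idx] if idx < len(DEFAULT_COHORT_NAMES) else str(idx)
        try:
            stage_rngs = [np.random.default_rng(s) for s in cseed.spawn(5)]
            profiles = sample_attribute_profiles(
                int(n), config.higher_order_slopes, config.higher_order_intercepts, stage_rngs[0]
            )
            responses = sample_item_responses(
                profiles, config.qmatrix, config.item_deltas, config.link, stage_rngs[1]
            )
            likert = emit_likert(responses, config.likert_emission, stage_rngs[2])
            tnm = sample_tnm(int(n), stage_rngs[3])
            t0, t1, outcome = sample_outcome(
                profiles,
                tnm,
                config.outcome_coefficients,
                config.sd_rule_multiplier,
                stage_rngs[4],
            )
        except Exception as exc:  # annotate failures with the cohort index
            raise type(exc)(f"cohort {idx} ({name!r}): {exc}") from exc
        cohorts.append(
            SyntheticCohort(
                name=name,
                responses=responses,
                likert=likert,
                true_profiles=profiles,
                tnm_stage=tnm,
                factb_t0=t0,
                factb_t1=t1,
                outcome=outcome,
            )
        )
    return cohorts
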