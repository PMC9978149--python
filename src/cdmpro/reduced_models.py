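"""Reduced cognitive diagnosis models as constrained G-DINA items.

DINA, DINO, ACDM, LLM and RRUM are each a linear restriction on the saturated
delta vector under a model-specific link (identity for DINA/DINO/ACDM, logit
for LLM, log for RRUM).  An item-level Wald test of the restriction against
the saturated fit asks whether the simpler model loses significant fit; the
recommendation rule keeps the non-rejected model with the largest p-value and
falls back to the saturated G-DINA otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .errors import ConstructionError, UndefinedMetricError
from .gdina import FittedGDINA, LINKS, PROB_CLIP, delta_design, item_param_se

#: reduced model -> implied link
MODEL_LINKS = {"DINA": "identity", "DINO": "identity", "ACDM": "identity", "LLM": "logit", "RRUM": "log"}

#: ordered simplest-first for reporting
MODEL_ORDER = ("DINA", "DINO", "ACDM", "LLM", "RRUM")


@dataclass
class ItemModelConstraint:
    """Linear restriction R delta = 0 characterizing a reduced model."""

    model: str
    link: str
    restriction: np.ndarray  # df x 2^K*

    @property
    def df(self) -> int:
        return self.restriction.shape[0]


def constraint_for(model: str, kstar: int) -> ItemModelConstraint:
    """Restriction matrix for a reduced model on an item requiring ``kstar`` attributes.

    DINA keeps only the intercept and the top interaction (two success
    levels, all attributes needed); DINO constrains every non-intercept term
    to the alternating-sign multiple of the first main effect (two success
    levels, any attribute suffices); ACDM/LLM/RRUM zero all interaction terms
    under their respective links.
    """
    if model not in MODEL_LINKS:
        raise ConstructionError(f"unknown reduced model {model!r}")
    if kstar < 2:
        raise ConstructionError("reduced models are degenerate for single-attribute items")
    m, subsets = delta_design(kstar)
    p = len(subsets)
    rows = []
    if model == "DINA":
        for idx in range(1, p - 1):  # all but intercept and top interaction
            row = np.zeros(p)
            row[idx] = 1.0
            rows.append(row)
    elif model == "DINO":
        # delta_S = (-1)^(|S|+1) delta_{first main}  for every nonempty S
        for idx in range(2, p):
            size = len(subsets[idx])
            row = np.zeros(p)
            row[idx] = 1.0
            row[1] = -((-1.0) ** (size + 1))
            rows.append(row)
    else:  # additive under the model's link: no interactions
        for idx in range(1, p):
            if len(subsets[idx]) >= 2:
                row = np.zeros(p)
                row[idx] = 1.0
                rows.append(row)
    return ItemModelConstraint(model=model, link=MODEL_LINKS[model], restriction=np.array(rows))


@dataclass
class WaldResult:
    item: int
    model: str
    statistic: float
    df: int
    p: float
    singular: bool = False


def wald_test_item(
    fitted: FittedGDINA,
    item: int,
    model: str,
    se_cache: list[dict] | None = None,
) -> WaldResult:
    """Wald test of a reduced model against the saturated fit for one item.

    The saturated item parameters are transformed into the test's link
    (delta = M^{-1} g(P), an exact reparameterization, so no literal refit is
    needed) and the covariance follows by the delta method from the OPG
    covariance of the reduced-class probabilities.
    """
    kstar = int(fitted.qmatrix.kstar[item])
    cons = constraint_for(model, kstar)
    ses = se_cache if se_cache is not None else item_param_se(fitted)
    sigma_p = ses[item]["sigma_probs"]
    if not ses[item]["defined"] or not np.isfinite(sigma_p).all():
        raise UndefinedMetricError(f"item {item}: covariance undefined (boundary/singular)")
    probs = np.clip(fitted.item_probs[item], PROB_CLIP, 1 - PROB_CLIP)
    g, _, gprime = LINKS[cons.link]
    m, _ = delta_design(kstar)
    delta = np.linalg.solve(m, g(probs))
    jac = np.linalg.solve(m, np.diag(gprime(probs)))
    h = cons.restriction @ delta
    v = cons.restriction @ jac @ sigma_p @ jac.T @ cons.restriction.T
    singular = False
    try:
        w = float(h @ np.linalg.solve(v, h))
        if w < 0 or not np.isfinite(w):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        singular = True
        w = float(h @ np.linalg.pinv(v) @ h)
        w = max(w, 0.0)
    return WaldResult(
        item=item,
        model=model,
        statistic=w,
        df=cons.df,
        p=float(chi2.sf(w, cons.df)),
        singular=singular,
    )


@dataclass
class ItemModelRecommendation:
    item: int
    tests: list[WaldResult]
    recommended: str
    applicable: bool = True


def select_item_models(fitted: FittedGDINA, alpha: float = 0.05) -> list[ItemModelRecommendation]:
    """Per-item model recommendation from the Wald screen.

    For each multi-attribute item every reduced model is tested; the
    recommendation is the model with the largest p-value among those not
    rejected at ``alpha``, and the saturated G-DINA when all are rejected.
    Single-attribute items are marked not applicable (all models coincide).
    """
    if not 0.0 < alpha < 1.0:
        raise ConstructionError("alpha must lie in (0, 1)")
    ses = item_param_se(fitted)
    recs = []
    for item in range(fitted.qmatrix.n_items):
        if int(fitted.qmatrix.kstar[item]) < 2:
            recs.append(
                ItemModelRecommendation(item=item, tests=[], recommended="not applicable", applicable=False)
            )
            continue
        if not ses[item]["defined"]:
            # boundary/singular covariance: keep the saturated model, no tests
            recs.append(ItemModelRecommendation(item=item, tests=[], recommended="GDINA"))
            continue
        tests = [wald_test_item(fitted, item, model, se_cache=ses) for model in MODEL_ORDER]
        accepted = [t for t in tests if t.p >= alpha]
        recommended = max(accepted, key=lambda t: t.p).model if accepted else "GDINA"
        recs.append(ItemModelRecommendation(item=item, tests=tests, recommended=recommended))
    return recs


def recommendation_table(recs: list[ItemModelRecommendation], item_labels: list[str] | None = None) -> pd.DataFrame:
    rows = []
    for rec in recs:
        label = item_labels[rec.item] if item_labels else f"item{rec.item + 1}"
        if not rec.tests:
            rows.append({"item": label, "model": None, "W": None, "df": None, "p": None, "recommended": rec.recommended})
            continue
        for t in rec.tests:
            rows.append(
                {
                    "item": label,
                    "model": t.model,
                    "W": t.statistic,
                    "df": t.df,
                    "p": t.p,
                    "recommended": rec.recommended,
                }
            )
    return pd.DataFrame(rows)
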