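"""Relative and absolute fit assessment for fitted cognitive diagnosis models.

Relative fit: information criteria (AIC/BIC/CAIC/SABIC) and the likelihood
ratio test between nested Q-matrix specifications.  Absolute fit: the
limited-information M2 statistic on univariate and bivariate response margins
with its RMSEA, the standardized root mean squared residual correlation
(SRMSR), and a per-item-pair table of Fisher-z correlation residuals with
Holm-adjusted p-values (the numbers behind a residual heatmap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2, ncx2, norm
from statsmodels.stats.multitest import multipletests

from .errors import NestingError, UndefinedMetricError
from .gdina import FittedGDINA, PROB_CLIP


def relative_fit(loglik: float, n_params: int, n: int) -> dict:
    """Information criteria from a log-likelihood.

    AIC = -2ll + 2p, BIC = -2ll + p ln n, CAIC = -2ll + p (ln n + 1),
    SABIC = -2ll + p ln((n + 2) / 24).
    """
    m2ll = -2.0 * loglik
    return {
        "loglik": float(loglik),
        "n_params": int(n_params),
        "AIC": m2ll + 2 * n_params,
        "BIC": m2ll + n_params * np.log(n),
        "CAIC": m2ll + n_params * (np.log(n) + 1.0),
        "SABIC": m2ll + n_params * np.log((n + 2) / 24.0),
    }


def lr_test(fit_reduced: FittedGDINA, fit_full: FittedGDINA) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested Q-matrix specification.

    Nesting requires entrywise Q-matrix inclusion and the same structural
    kind; degrees of freedom follow the free-parameter counting convention
    (2^K_j* per item plus structural parameters).
    """
    if fit_reduced.structural.kind != fit_full.structural.kind:
        raise NestingError("fits use different structural kinds")
    if not fit_reduced.qmatrix.is_nested_in(fit_full.qmatrix):
        raise NestingError("reduced Q-matrix is not nested in the full one")
    x2 = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if x2 < -1e-6:
        raise NestingError(f"negative LR statistic ({x2:.3g}): check convergence/nesting")
    x2 = max(x2, 0.0)
    df = fit_full.n_params - fit_reduced.n_params
    p = float(chi2.sf(x2, df)) if df > 0 else 1.0
    return float(x2), int(df), p


# ---------------------------------------------------------------------------
# Model-implied moments
# ---------------------------------------------------------------------------

def model_implied_moments(fitted: FittedGDINA) -> tuple[np.ndarray, np.ndarray]:
    """Item means and E[Y_j Y_j'] implied by the fitted latent-class structure."""
    w = fitted.class_weights
    pfull = fitted.full_class_probs()
    means = w @ pfull
    cross = (pfull * w[:, None]).T @ pfull
    np.fill_diagonal(cross, means)
    return means, cross


def _implied_correlations(fitted: FittedGDINA) -> np.ndarray:
    means, cross = model_implied_moments(fitted)
    var = means * (1 - means)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (cross - np.outer(means, means)) / denom
    np.fill_diagonal(corr, 1.0)
    return corr


def _observed_correlations(fitted: FittedGDINA) -> tuple[np.ndarray, np.ndarray]:
    y = fitted.responses.astype(float)
    var = y.var(axis=0)
    keep = var > 0
    if not keep.all():
        warnings.warn("zero-variance items excluded from correlation residuals")
    corr = np.corrcoef(y[:, keep].T)
    return corr, keep


def srmsr(fitted: FittedGDINA) -> float:
    """Root mean squared difference between observed and model-implied item
    correlations over all item pairs."""
    if fitted.qmatrix.n_items < 2:
        raise UndefinedMetricError("SRMSR needs at least two items")
    obs, keep = _observed_correlations(fitted)
    imp = _implied_correlations(fitted)[np.ix_(keep, keep)]
    iu = np.triu_indices_from(obs, k=1)
    return float(np.sqrt(np.mean((obs[iu] - imp[iu]) ** 2)))


def residual_table(fitted: FittedGDINA) -> pd.DataFrame:
    """Fisher-z residuals of observed vs implied item-pair correlations.

    Two-sided asymptotic z-tests with Holm-adjusted p-values; sorted by
    adjusted p for rendering as a heatmap table.
    """
    obs, keep = _observed_correlations(fitted)
    imp = _implied_correlations(fitted)[np.ix_(keep, keep)]
    labels = [lab for lab, k in zip(fitted.qmatrix.item_labels, keep) if k]
    n = fitted.n_obs
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            r_o = np.clip(obs[i, j], -1 + 1e-12, 1 - 1e-12)
            r_i = np.clip(imp[i, j], -1 + 1e-12, 1 - 1e-12)
            z = (np.arctanh(r_o) - np.arctanh(r_i)) * np.sqrt(max(n - 3, 1))
            rows.append(
                {
                    "item_a": labels[i],
                    "item_b": labels[j],
                    "r_observed": float(obs[i, j]),
                    "r_implied": float(imp[i, j]),
                    "residual": float(obs[i, j] - imp[i, j]),
                    "z": float(z),
                    "p": float(2 * norm.sf(abs(z))),
                }
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = multipletests(table["p"].to_numpy(), method="holm")[1]
    return table.sort_values("p_adjusted", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# M2 limited-information statistic
# ---------------------------------------------------------------------------

def _margin_sets(n_items: int) -> list[tuple[int, ...]]:
    sets: list[tuple[int, ...]] = [(j,) for j in range(n_items)]
    for i in range(n_items):
        for j in range(i + 1, n_items):
            sets.append((i, j))
    return sets


def _margins_from_params(theta: np.ndarray, fitted: FittedGDINA, sets) -> np.ndarray:
    """First- and second-order model margins as a function of the free parameters."""
    item_probs = []
    pos = 0
    for probs in fitted.item_probs:
        item_probs.append(theta[pos : pos + probs.size])
        pos += probs.size
    patterns = fitted.attr_patterns
    struct = fitted.structural
    if struct.kind == "saturated":
        w_free = theta[pos : pos + patterns.shape[0] - 1]
        w = np.concatenate([w_free, [1.0 - w_free.sum()]])
    else:
        k = patterns.shape[1]
        slopes = theta[pos : pos + k]
        intercepts = theta[pos + k : pos + 2 * k]
        from scipy.special import expit

        eta = slopes[None, :] * struct.nodes[:, None] + intercepts[None, :]
        pk = expit(eta)
        logp = patterns @ np.log(np.clip(pk, PROB_CLIP, 1.0)).T + (1 - patterns) @ np.log(
            np.clip(1 - pk, PROB_CLIP, 1.0)
        ).T
        w = np.exp(logp) @ struct.node_weights
        w = w / w.sum()
    c = patterns.shape[0]
    pfull = np.empty((c, len(item_probs)))
    for jj in range(len(item_probs)):
        pfull[:, jj] = item_probs[jj][fitted.rmap[jj]]
    out = np.empty(len(sets))
    for idx, s in enumerate(sets):
        prod = np.ones(c)
        for jj in s:
            prod = prod * pfull[:, jj]
        out[idx] = w @ prod
    return out


def _free_param_vector(fitted: FittedGDINA) -> np.ndarray:
    parts = [p.copy() for p in fitted.item_probs]
    struct = fitted.structural
    if struct.kind == "saturated":
        parts.append(struct.class_probs[:-1].copy())
    else:
        parts.append(struct.slopes.copy())
        parts.append(struct.intercepts.copy())
    return np.concatenate(parts)


@dataclass
class M2Result:
    m2: float
    df: int
    p: float
    rmsea2: float
    rmsea2_ci: tuple[float, float]


def m2_rmsea(fitted: FittedGDINA, ci_level: float = 0.90) -> M2Result:
    """Limited-information M2 statistic on first- and second-order margins.

    Follows the quadratic-form construction on the margin residual vector
    e = p_obs - p_model with the model-implied multinomial covariance of the
    margins and the margin Jacobian with respect to the free parameters;
    RMSEA2 = sqrt(max(M2 - df, 0) / (N df)) with a noncentral-chi-square CI.
    """
    sets = _margin_sets(fitted.qmatrix.n_items)
    s = len(sets)
    if s - fitted.n_params <= 0 and s - 1 <= 0:
        raise UndefinedMetricError("M2 degrees of freedom nonpositive")
    y = fitted.responses.astype(float)
    n = y.shape[0]
    obs = np.empty(s)
    for idx, st in enumerate(sets):
        col = np.ones(n)
        for jj in st:
            col = col * y[:, jj]
        obs[idx] = col.mean()
    theta = _free_param_vector(fitted)
    model = _margins_from_params(theta, fitted, sets)
    e = obs - model
    npar = theta.size

    # multinomial covariance of the margins under the model
    w = fitted.class_weights
    pfull = fitted.full_class_probs()
    prods = np.empty((s, len(w)))
    for idx, st in enumerate(sets):
        prod = np.ones(len(w))
        for jj in st:
            prod = prod * pfull[:, jj]
        prods[idx] = prod
    joint = np.empty((s, s))
    for a in range(s):
        for b in range(a, s):
            union = tuple(sorted(set(sets[a]) | set(sets[b])))
            prod = np.ones(len(w))
            for jj in union:
                prod = prod * pfull[:, jj]
            joint[a, b] = joint[b, a] = w @ prod
    xi = joint - np.outer(model, model)

    # margin Jacobian by central differences
    h = 1e-6
    delta_mat = np.empty((s, theta.size))
    for p_idx in range(theta.size):
        up = theta.copy()
        dn = theta.copy()
        up[p_idx] += h
        dn[p_idx] -= h
        delta_mat[:, p_idx] = (_margins_from_params(up, fitted, sets) - _margins_from_params(dn, fitted, sets)) / (
            2 * h
        )

    # the quadratic form must project out only the margin directions the
    # parameters can actually move (range of the Jacobian); a rank-deficient
    # Jacobian (weakly identified designs) raises the degrees of freedom
    u, sv, _ = np.linalg.svd(delta_mat, full_matrices=False)
    rank = int((sv > sv[0] * 1e-8).sum()) if sv.size else 0
    basis = u[:, :rank]
    xi_inv = np.linalg.pinv(xi, rcond=1e-12)
    mid = basis.T @ xi_inv @ basis
    c2 = xi_inv - xi_inv @ basis @ np.linalg.solve(mid, basis.T @ xi_inv)
    m2 = float(n * e @ c2 @ e)
    m2 = max(m2, 0.0)
    df = s - rank
    if df <= 0:
        raise UndefinedMetricError("M2 degrees of freedom nonpositive")
    p = float(chi2.sf(m2, df))
    rmsea2 = float(np.sqrt(max(m2 - df, 0.0) / (n * df)))
    ci = _rmsea_ci(m2, df, n, ci_level)
    return M2Result(m2=m2, df=df, p=p, rmsea2=rmsea2, rmsea2_ci=ci)


def _rmsea_ci(stat: float, df: int, n: int, level: float) -> tuple[float, float]:
    """Noncentrality-inversion confidence interval for the M2 RMSEA."""
    lo_q = (1 + level) / 2
    hi_q = (1 - level) / 2

    def bound(q):
        if ncx2.cdf(stat, df, 0.0) < q:
            return 0.0
        upper = max(stat * 2, df * 2, 10.0)
        while ncx2.cdf(stat, df, upper) > q and upper < 1e7:
            upper *= 2
        try:
            lam = brentq(lambda l: ncx2.cdf(stat, df, l) - q, 0.0, upper)
        except ValueError:
            return 0.0
        return float(np.sqrt(lam / (n * df)))

    return bound(lo_q), bound(hi_q)


def fit_report(fitted: FittedGDINA, compute_m2: bool = True) -> dict:
    """Assemble the full fit report (information criteria, absolute fit,
    residual summary) as a JSON-serializable dictionary."""
    rep = relative_fit(fitted.loglik, fitted.n_params, fitted.n_obs)
    rep["converged"] = bool(fitted.converged)
    rep["n_iter"] = int(fitted.n_iter)
    rep["SRMSR"] = srmsr(fitted)
    if compute_m2:
        try:
            m2 = m2_rmsea(fitted)
            rep.update(
                {
                    "M2": m2.m2,
                    "M2_df": m2.df,
                    "M2_p": m2.p,
                    "RMSEA2": m2.rmsea2,
                    "RMSEA2_CI90": list(m2.rmsea2_ci),
                }
            )
        except UndefinedMetricError:
            rep.update({"M2": None, "M2_df": None, "M2_p": None, "RMSEA2": None, "RMSEA2_CI90": None})
    resid = residual_table(fitted)
    rep["min_residual_p_adjusted"] = float(resid["p_adjusted"].min())
    return rep
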