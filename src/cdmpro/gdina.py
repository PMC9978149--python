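"""Saturated G-DINA estimation by EM marginal maximum likelihood.

The item response function expresses the success probability of item j for a
reduced attribute pattern alpha* (the restriction of the full K-vector to the
item's required attributes) through a full-factorial expansion under a link g:

    g[P_j(alpha*)] = delta_j0 + sum_k delta_jk a_k + sum_{k<k'} delta_jkk' a_k a_k'
                     + ... + delta_j12...K* prod_k a_k

Internally each item is parameterized by its vector of reduced-class success
probabilities P_j (one per 2^(K_j*) reduced pattern); delta coefficients under
any of the identity / logit / log links are recovered exactly as
delta = M^{-1} g(P) with M the saturated design matrix, so the link is a pure
reparameterization of the same fit.

The attribute distribution is either saturated (free class proportions) or a
higher-order model in which each attribute's mastery probability follows a
two-parameter logistic function of a single normal latent trait, integrated
over a fixed quadrature grid.

Monotonicity ("mastering an additional attribute never lowers the success
probability") is imposed in the M-step as the order-constrained binomial MLE,
which coincides with the weighted least-squares isotonic projection of the raw
conditional proportions over the subset-inclusion partial order; imposing the
constraint inside the M-step keeps the EM ascent property.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .errors import InputError, ParameterError
from .qmatrix import QMatrix

PROB_CLIP = 1e-10

LINKS = {
    "identity": (lambda p: p, lambda x: x, lambda p: np.ones_like(p)),
    "logit": (lambda p: np.log(p / (1 - p)), expit, lambda p: 1.0 / (p * (1 - p))),
    "log": (np.log, np.exp, lambda p: 1.0 / p),
}


def attribute_patterns(n_attributes: int) -> np.ndarray:
    """All 2^K binary attribute profiles; row index is the binary number with
    the first attribute as the most significant bit."""
    return np.array(list(product((0, 1), repeat=n_attributes)), dtype=int)


def reduce_profile(alpha: Sequence[int], q_row: Sequence[int]) -> np.ndarray:
    """Restrict a full attribute profile to the attributes an item requires."""
    alpha = np.asarray(alpha, dtype=int)
    q_row = np.asarray(q_row, dtype=int)
    if alpha.shape != q_row.shape:
        raise InputError("profile and q-vector lengths differ")
    if q_row.sum() == 0:
        raise InputError("q-vector requires no attributes")
    return alpha[q_row == 1]


def _reduced_index_map(qmatrix: QMatrix, patterns: np.ndarray) -> np.ndarray:
    """(J, 2^K) map from full latent class to each item's reduced class index."""
    j, k = qmatrix.entries.shape
    rmap = np.zeros((j, patterns.shape[0]), dtype=int)
    for jj in range(j):
        cols = np.flatnonzero(qmatrix.entries[jj])
        weights = 1 << np.arange(len(cols))[::-1]
        rmap[jj] = patterns[:, cols] @ weights
    return rmap


def delta_design(kstar: int) -> tuple[np.ndarray, list[tuple[int, ...]]]:
    """Saturated design matrix mapping delta coefficients to reduced classes.

    Columns are indexed by attribute subsets ordered by size then
    lexicographically: intercept, main effects, two-way interactions, ...,
    the K*-way interaction.  Row r corresponds to reduced pattern r.
    """
    subsets: list[tuple[int, ...]] = [()]
    for size in range(1, kstar + 1):
        subsets.extend(combinations(range(kstar), size))
    patterns = attribute_patterns(kstar)
    m = np.zeros((2**kstar, len(subsets)))
    for r, pat in enumerate(patterns):
        for col, sub in enumerate(subsets):
            m[r, col] = np.prod(pat[list(sub)]) if sub else 1.0
    return m, subsets


def irf_success_probability(delta: Sequence[float], reduced: Sequence[int], link: str = "identity") -> float:
    """Success probability of one reduced attribute pattern under the IRF."""
    delta = np.asarray(delta, dtype=float)
    reduced = np.asarray(reduced, dtype=int)
    kstar = reduced.size
    m, _ = delta_design(kstar)
    if delta.size != m.shape[1]:
        raise ParameterError(f"delta vector must have length {m.shape[1]} for K*={kstar}")
    row = m[int(reduced @ (1 << np.arange(kstar)[::-1]))]
    eta = float(row @ delta)
    p = float(LINKS[link][1](eta))
    if not (0.0 <= p <= 1.0) or not np.isfinite(p):
        raise ParameterError(f"implied success probability {p} outside [0, 1]")
    return p


def delta_to_probs(delta: Sequence[float], link: str = "identity") -> np.ndarray:
    """Success probabilities of all reduced classes implied by a delta vector."""
    delta = np.asarray(delta, dtype=float)
    kstar = int(np.log2(delta.size))
    if 2**kstar != delta.size:
        raise ParameterError("delta length must be a power of two")
    m, _ = delta_design(kstar)
    p = LINKS[link][1](m @ delta)
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise ParameterError("delta vector implies probabilities outside [0, 1]")
    return np.clip(p, 0.0, 1.0)


def probs_to_delta(probs: Sequence[float], link: str = "identity") -> np.ndarray:
    """Invert :func:`delta_to_probs`: delta = M^{-1} g(P)."""
    probs = np.asarray(probs, dtype=float)
    kstar = int(np.log2(probs.size))
    m, _ = delta_design(kstar)
    g = LINKS[link][0](np.clip(probs, PROB_CLIP, 1 - PROB_CLIP))
    return np.linalg.solve(m, g)


def guess_slip(delta: Sequence[float], link: str = "identity") -> tuple[float, float]:
    """Guessing and slip: the success probability floor (no required attribute
    mastered) and one minus the ceiling (all mastered)."""
    probs = delta_to_probs(delta, link)
    return float(probs[0]), float(1.0 - probs[-1])


# ---------------------------------------------------------------------------
# Structural (attribute-distribution) models
# ---------------------------------------------------------------------------

@dataclass
class StructuralParams:
    """Attribute-distribution parameters: saturated class proportions or a
    higher-order 2PL latent-trait model on quadrature."""

    kind: str  # "higher_order" | "saturated"
    class_probs: np.ndarray | None = None
    slopes: np.ndarray | None = None
    intercepts: np.ndarray | None = None
    nodes: np.ndarray | None = None
    node_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("higher_order", "saturated"):
            raise ParameterError(f"unknown structural kind {self.kind!r}")
        if self.kind == "saturated":
            w = np.asarray(self.class_probs, dtype=float)
            if abs(w.sum() - 1.0) > 1e-10 or (w < 0).any():
                raise ParameterError("class probabilities must be a distribution (sum 1)")
            self.class_probs = w

    @property
    def n_free(self) -> int:
        if self.kind == "saturated":
            return self.class_probs.size - 1
        return 2 * self.slopes.size

    def class_node_probs(self, patterns: np.ndarray) -> np.ndarray:
        """(2^K, Q) conditional class probabilities at each quadrature node."""
        eta = self.slopes[None, :] * self.nodes[:, None] + self.intercepts[None, :]  # Q x K
        pk = expit(eta)
        logp = patterns @ np.log(np.clip(pk, PROB_CLIP, 1.0)).T + (1 - patterns) @ np.log(
            np.clip(1 - pk, PROB_CLIP, 1.0)
        ).T
        return np.exp(logp)  # 2^K x Q

    def class_weights(self, patterns: np.ndarray) -> np.ndarray:
        if self.kind == "saturated":
            return self.class_probs
        w = self.class_node_probs(patterns) @ self.node_weights
        return w / w.sum()


def _quadrature(n_nodes: int, bound: float) -> tuple[np.ndarray, np.ndarray]:
    nodes = np.linspace(-bound, bound, n_nodes)
    weights = norm.pdf(nodes)
    return nodes, weights / weights.sum()


# ---------------------------------------------------------------------------
# Item parameters and fitted-model containers
# ---------------------------------------------------------------------------

@dataclass
class ItemParams:
    """Delta coefficients of one item under a link, with optional SEs."""

    item: int
    kstar: int
    delta: np.ndarray
    link: str
    se: np.ndarray | None = None

    @property
    def success_probabilities(self) -> np.ndarray:
        return delta_to_probs(self.delta, self.link)

    @property
    def guess(self) -> float:
        return guess_slip(self.delta, self.link)[0]

    @property
    def slip(self) -> float:
        return guess_slip(self.delta, self.link)[1]


@dataclass
class CDPMatrix:
    """Per-person posterior attribute-mastery probabilities."""

    values: np.ndarray  # N x K in [0, 1]
    attribute_labels: list[str]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.attribute_labels)


@dataclass
class FittedGDINA:
    """A converged (or convergence-flagged) G-DINA fit."""

    qmatrix: QMatrix
    item_probs: list[np.ndarray]
    structural: StructuralParams
    loglik: float
    n_params: int
    n_iter: int
    converged: bool
    posterior: np.ndarray  # N x 2^K
    loglik_trace: np.ndarray
    link: str
    responses: np.ndarray
    responses_digest: str
    attr_patterns: np.ndarray = field(repr=False, default=None)
    rmap: np.ndarray = field(repr=False, default=None)

    @property
    def n_obs(self) -> int:
        return self.responses.shape[0]

    @property
    def class_weights(self) -> np.ndarray:
        return self.structural.class_weights(self.attr_patterns)

    def full_class_probs(self) -> np.ndarray:
        """(2^K, J) success probability of every item in every latent class."""
        c = self.attr_patterns.shape[0]
        j = self.qmatrix.n_items
        out = np.empty((c, j))
        for jj in range(j):
            out[:, jj] = self.item_probs[jj][self.rmap[jj]]
        return out

    def item_params(self, link: str | None = None, with_se: bool = False) -> list[ItemParams]:
        link = link or self.link
        params = []
        ses = item_param_se(self, link) if with_se else [None] * self.qmatrix.n_items
        for jj, probs in enumerate(self.item_probs):
            params.append(
                ItemParams(
                    item=jj,
                    kstar=int(self.qmatrix.kstar[jj]),
                    delta=probs_to_delta(probs, link),
                    link=link,
                    se=None if ses[jj] is None else ses[jj]["se_delta"],
                )
            )
        return params


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _class_loglik(responses: np.ndarray, item_probs: list[np.ndarray], rmap: np.ndarray) -> np.ndarray:
    """(N, 2^K) log-likelihood of each response vector in each latent class."""
    c = rmap.shape[1]
    j = len(item_probs)
    pfull = np.empty((c, j))
    for jj in range(j):
        pfull[:, jj] = item_probs[jj][rmap[jj]]
    pfull = np.clip(pfull, PROB_CLIP, 1 - PROB_CLIP)
    return responses @ np.log(pfull).T + (1 - responses) @ np.log(1 - pfull).T


def marginal_loglik(
    item_probs: list[np.ndarray],
    structural: StructuralParams,
    responses: np.ndarray,
    qmatrix: QMatrix,
) -> float:
    """Marginal log-likelihood by exact enumeration over the 2^K latent classes."""
    patterns = attribute_patterns(qmatrix.n_attributes)
    rmap = _reduced_index_map(qmatrix, patterns)
    w = structural.class_weights(patterns)
    ll = _class_loglik(np.asarray(responses, dtype=float), item_probs, rmap)
    return float(logsumexp(ll + np.log(np.clip(w, PROB_CLIP, 1.0)), axis=1).sum())


# ---------------------------------------------------------------------------
# Monotone M-step
# ---------------------------------------------------------------------------

def _cover_pairs(kstar: int) -> list[tuple[int, int]]:
    """Cover relations (a, b) of the subset partial order: b adds one attribute to a."""
    patterns = attribute_patterns(kstar)
    idx = {tuple(p): i for i, p in enumerate(patterns)}
    pairs = []
    for i, pat in enumerate(patterns):
        for k in range(kstar):
            if pat[k] == 0:
                up = pat.copy()
                up[k] = 1
                pairs.append((i, idx[tuple(up)]))
    return pairs


def _monotone_mle(phat: np.ndarray, weights: np.ndarray, kstar: int) -> np.ndarray:
    """Order-constrained binomial MLE = weighted isotonic projection of phat.

    Only invoked when the unconstrained estimate violates monotonicity.
    """
    pairs = _cover_pairs(kstar)
    if all(phat[b] >= phat[a] - 1e-12 for a, b in pairs):
        return phat
    w = np.maximum(weights, 1e-8)

    def objective(x):
        return float(w @ (x - phat) ** 2), 2 * w * (x - phat)

    constraints = [
        {"type": "ineq", "fun": (lambda x, a=a, b=b: x[b] - x[a]), "jac": _pair_jac(len(phat), a, b)}
        for a, b in pairs
    ]
    res = minimize(
        objective,
        np.full_like(phat, phat.mean()),
        jac=True,
        method="SLSQP",
        bounds=[(PROB_CLIP, 1 - PROB_CLIP)] * len(phat),
        constraints=constraints,
        options={"maxiter": 200, "ftol": 1e-12},
    )
    x = np.clip(res.x, PROB_CLIP, 1 - PROB_CLIP)
    # enforce feasibility exactly by an upward max pass over the partial order
    order = np.argsort(attribute_patterns(kstar).sum(axis=1))
    for i in order:
        for a, b in pairs:
            if b == i and x[b] < x[a]:
                x[b] = x[a]
    return x


def _pair_jac(n: int, a: int, b: int):
    def jac(x):
        g = np.zeros(n)
        g[b] = 1.0
        g[a] = -1.0
        return g

    return jac


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

def fit_gdina(
    responses: np.ndarray,
    qmatrix: QMatrix,
    *,
    link: str = "identity",
    structural: str = "higher_order",
    monotonic: bool = True,
    tol: float = 1e-4,
    max_iter: int = 2000,
    seed: int = 0,
    n_quad: int = 19,
    quad_bound: float = 4.0,
) -> FittedGDINA:
    """Fit the saturated G-DINA model by EM marginal maximum likelihood.

    Parameters
    ----------
    responses
        N x J matrix of 0/1 item scores.
    qmatrix
        Item-by-attribute Q-matrix.
    link
        Reporting link for delta coefficients (estimation is link-free).
    structural
        ``"higher_order"`` for the 2PL latent-trait attribute distribution or
        ``"saturated"`` for free class proportions.
    monotonic
        Impose the monotone (attribute-set inclusion) constraint in the M-step.
    tol, max_iter
        Convergence is declared when the largest absolute parameter change
        falls below ``tol``; otherwise the fit is flagged unconverged.
    seed
        Controls the small jitter applied to the starting values.
    """
    y = np.asarray(responses, dtype=float)
    if y.ndim != 2:
        raise InputError("responses must be a 2-D person x item matrix")
    if not np.isin(y, (0.0, 1.0)).all():
        raise InputError("responses must be binary")
    n, j = y.shape
    if j != qmatrix.n_items:
        raise InputError("responses and Q-matrix disagree on the number of items")
    if n < 2:
        raise InputError("at least two respondents required")
    if link not in LINKS:
        raise ParameterError(f"unknown link {link!r}")

    k = qmatrix.n_attributes
    patterns = attribute_patterns(k)
    c = patterns.shape[0]
    rmap = _reduced_index_map(qmatrix, patterns)
    kstars = qmatrix.kstar
    rng = np.random.default_rng(seed)

    # starting values: item means spread monotonically over reduced classes
    item_probs: list[np.ndarray] = []
    for jj in range(j):
        mean_j = float(np.clip(y[:, jj].mean(), 0.1, 0.9))
        counts = attribute_patterns(int(kstars[jj])).sum(axis=1)
        spread = 0.5 * (counts / max(int(kstars[jj]), 1) - 0.5)
        p0 = np.clip(mean_j + spread + rng.normal(0.0, 0.01, size=2 ** int(kstars[jj])), 0.05, 0.95)
        item_probs.append(np.sort(p0)[np.argsort(np.argsort(counts, kind="stable"), kind="stable")])

    if structural == "saturated":
        struct = StructuralParams(kind="saturated", class_probs=np.full(c, 1.0 / c))
    elif structural == "higher_order":
        nodes, node_w = _quadrature(n_quad, quad_bound)
        struct = StructuralParams(
            kind="higher_order",
            slopes=np.ones(k),
            intercepts=np.zeros(k),
            nodes=nodes,
            node_weights=node_w,
        )
    else:
        raise ParameterError(f"unknown structural kind {structural!r}")

    trace: list[float] = []
    converged = False
    post = np.full((n, c), 1.0 / c)
    it = 0
    for it in range(1, max_iter + 1):
        w = struct.class_weights(patterns)
        ll_class = _class_loglik(y, item_probs, rmap)
        joint = ll_class + np.log(np.clip(w, PROB_CLIP, 1.0))
        ll = float(logsumexp(joint, axis=1).sum())
        trace.append(ll)
        post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))

        old_vec = _param_vector(item_probs, struct)

        # M-step: items (closed form, optionally isotonic)
        class_mass = post.sum(axis=0)  # expected count per class
        succ = post.T @ y  # 2^K x J expected successes
        for jj in range(j):
            kst = int(kstars[jj])
            n_r = np.bincount(rmap[jj], weights=class_mass, minlength=2**kst)
            r_r = np.bincount(rmap[jj], weights=succ[:, jj], minlength=2**kst)
            phat = np.clip(r_r / np.maximum(n_r, 1e-12), PROB_CLIP, 1 - PROB_CLIP)
            if monotonic:
                phat = _monotone_mle(phat, n_r, kst)
            item_probs[jj] = phat

        # M-step: structural
        if struct.kind == "saturated":
            struct.class_probs = np.clip(class_mass / class_mass.sum(), PROB_CLIP, 1.0)
            struct.class_probs /= struct.class_probs.sum()
        else:
            _update_higher_order(struct, patterns, class_mass)

        new_vec = _param_vector(item_probs, struct)
        if np.max(np.abs(new_vec - old_vec)) < tol:
            converged = True
            break

    # final E-step quantities at the last parameter values
    w = struct.class_weights(patterns)
    ll_class = _class_loglik(y, item_probs, rmap)
    joint = ll_class + np.log(np.clip(w, PROB_CLIP, 1.0))
    loglik = float(logsumexp(joint, axis=1).sum())
    trace.append(loglik)
    post = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))

    n_params = int(sum(2 ** int(ks) for ks in kstars)) + struct.n_free
    digest = hashlib.sha256(np.ascontiguousarray(y.astype(np.int8)).tobytes()).hexdigest()
    return FittedGDINA(
        qmatrix=qmatrix,
        item_probs=item_probs,
        structural=struct,
        loglik=loglik,
        n_params=n_params,
        n_iter=it,
        converged=converged,
        posterior=post,
        loglik_trace=np.asarray(trace),
        link=link,
        responses=y.astype(int),
        responses_digest=digest,
        attr_patterns=patterns,
        rmap=rmap,
    )


def _param_vector(item_probs: list[np.ndarray], struct: StructuralParams) -> np.ndarray:
    parts = [p for p in item_probs]
    if struct.kind == "saturated":
        parts.append(struct.class_probs)
    else:
        parts.append(struct.slopes)
        parts.append(struct.intercepts)
    return np.concatenate(parts)


def _update_higher_order(struct: StructuralParams, patterns: np.ndarray, class_mass: np.ndarray) -> None:
    """Marginal-ML update of the 2PL slopes/intercepts given expected class counts.

    Because the responses are independent of the latent trait given the class,
    the node posterior factorizes: p(node | class) does not involve the data,
    so the expected per-node mastery counts reduce to sums over classes.
    """
    pn = struct.class_node_probs(patterns)  # 2^K x Q
    w = pn @ struct.node_weights  # class weights
    # joint expected mass over (class, node)
    joint = (class_mass / np.maximum(w, PROB_CLIP))[:, None] * pn * struct.node_weights[None, :]
    n_q = joint.sum(axis=0)  # expected count per node
    for k in range(patterns.shape[1]):
        r_kq = joint[patterns[:, k] == 1].sum(axis=0)

        def negll(x, r=r_kq, nq=n_q):
            a, d = x
            eta = a * struct.nodes + d
            p = expit(eta)
            val = -(r @ np.log(np.clip(p, PROB_CLIP, 1.0)) + (nq - r) @ np.log(np.clip(1 - p, PROB_CLIP, 1.0)))
            resid = r - nq * p
            return val, np.array([-(resid @ struct.nodes), -resid.sum()])

        res = minimize(
            negll,
            np.array([struct.slopes[k], struct.intercepts[k]]),
            jac=True,
            method="L-BFGS-B",
            bounds=[(0.0, 25.0), (-25.0, 25.0)],
        )
        struct.slopes[k], struct.intercepts[k] = res.x


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def attribute_mastery_probabilities(fitted: FittedGDINA) -> CDPMatrix:
    """Cognitive diagnostic probabilities: posterior mastery of each attribute.

    Entry (i, k) is the posterior mass of person i over latent classes with
    attribute k mastered.
    """
    values = fitted.posterior @ fitted.attr_patterns
    return CDPMatrix(values=values, attribute_labels=list(fitted.qmatrix.attribute_labels))


def classify(fitted: FittedGDINA, rule: str = "EAP", threshold: float = 0.5):
    """Binary mastery classification and modal latent class per person.

    EAP: mastery when the attribute CDP reaches the threshold.  The modal
    (MAP) class is the argmax of the class posterior with ties broken by the
    lowest class index in binary order.
    """
    if rule not in ("EAP", "MAP"):
        raise InputError(f"unknown classification rule {rule!r}")
    if rule == "EAP" and not 0.0 < threshold < 1.0:
        raise InputError("EAP threshold must lie in (0, 1)")
    cdp = attribute_mastery_probabilities(fitted).values
    modal = np.argmax(fitted.posterior, axis=1)  # argmax returns lowest index on ties
    if rule == "EAP":
        mastery = (cdp >= threshold).astype(int)
    else:
        mastery = fitted.attr_patterns[modal]
    return mastery, modal


def classification_accuracy(fitted: FittedGDINA) -> tuple[float, np.ndarray]:
    """Expected classification accuracy at test and attribute level.

    Test level: mean modal-class posterior mass.  Attribute level k: mean of
    max(CDP_ik, 1 - CDP_ik), the posterior probability that the EAP mastery
    call for attribute k is correct.
    """
    test_level = float(fitted.posterior.max(axis=1).mean())
    cdp = attribute_mastery_probabilities(fitted).values
    per_attribute = np.maximum(cdp, 1 - cdp).mean(axis=0)
    return test_level, per_attribute


# ---------------------------------------------------------------------------
# Standard errors (outer product of gradients)
# ---------------------------------------------------------------------------

def _score_matrix(fitted: FittedGDINA) -> tuple[np.ndarray, list[slice]]:
    """Per-person score vectors of the marginal log-likelihood.

    Columns are the item reduced-class probabilities (in item order) followed
    by the structural parameters (free class proportions, or 2PL slopes and
    intercepts).  The score with respect to item j's probability P_r is
    post(i, r) (y_ij - P_r) / (P_r (1 - P_r)) with post(i, r) the posterior
    mass aggregated over latent classes mapping to reduced class r.
    """
    y = fitted.responses.astype(float)
    post = fitted.posterior
    n = y.shape[0]
    blocks: list[np.ndarray] = []
    slices: list[slice] = []
    pos = 0
    for jj, probs in enumerate(fitted.item_probs):
        nred = probs.size
        agg = np.zeros((n, nred))
        for r in range(nred):
            agg[:, r] = post[:, fitted.rmap[jj] == r].sum(axis=1)
        p = np.clip(probs, PROB_CLIP, 1 - PROB_CLIP)
        blocks.append(agg * (y[:, [jj]] - p[None, :]) / (p * (1 - p))[None, :])
        slices.append(slice(pos, pos + nred))
        pos += nred
    struct = fitted.structural
    patterns = fitted.attr_patterns
    w = np.clip(struct.class_weights(patterns), PROB_CLIP, 1.0)
    if struct.kind == "saturated":
        # free parameters w_1..w_{C-1}; w_C absorbs the sum constraint
        ratio = post / w[None, :]
        blocks.append(ratio[:, :-1] - ratio[:, [-1]])
    else:
        pn = struct.class_node_probs(patterns)  # C x Q
        from scipy.special import expit as _expit

        sig = _expit(struct.slopes[None, :] * struct.nodes[:, None] + struct.intercepts[None, :])  # Q x K
        cols = []
        for k in range(patterns.shape[1]):
            resid = patterns[:, [k]] - sig[:, k][None, :]  # C x Q
            dw_da = (pn * resid * struct.nodes[None, :]) @ struct.node_weights
            dw_dd = (pn * resid) @ struct.node_weights
            cols.append((dw_da, dw_dd))
        ratio = post / w[None, :]
        # order: all slopes then all intercepts, matching _param_vector
        slopes_cols = [ratio @ cols[k][0] for k in range(len(cols))]
        inter_cols = [ratio @ cols[k][1] for k in range(len(cols))]
        blocks.append(np.column_stack(slopes_cols + inter_cols))
    return np.hstack(blocks), slices


def _unpack_params(fitted: FittedGDINA, theta: np.ndarray) -> tuple[list[np.ndarray], StructuralParams]:
    item_probs = []
    pos = 0
    for probs in fitted.item_probs:
        item_probs.append(np.clip(theta[pos : pos + probs.size], PROB_CLIP, 1 - PROB_CLIP))
        pos += probs.size
    struct = fitted.structural
    if struct.kind == "saturated":
        w_free = theta[pos : pos + struct.class_probs.size - 1]
        w = np.concatenate([w_free, [1.0 - w_free.sum()]])
        new = StructuralParams(kind="saturated", class_probs=np.clip(w, PROB_CLIP, 1.0) / np.clip(w, PROB_CLIP, 1.0).sum())
    else:
        k = struct.slopes.size
        new = StructuralParams(
            kind="higher_order",
            slopes=theta[pos : pos + k].copy(),
            intercepts=theta[pos + k : pos + 2 * k].copy(),
            nodes=struct.nodes,
            node_weights=struct.node_weights,
        )
    return item_probs, new


def _pack_params(fitted: FittedGDINA) -> np.ndarray:
    parts = [p.copy() for p in fitted.item_probs]
    struct = fitted.structural
    if struct.kind == "saturated":
        parts.append(struct.class_probs[:-1].copy())
    else:
        parts.append(struct.slopes.copy())
        parts.append(struct.intercepts.copy())
    return np.concatenate(parts)


def _total_score(fitted: FittedGDINA, theta: np.ndarray) -> np.ndarray:
    """Analytic gradient of the marginal log-likelihood at arbitrary parameters."""
    item_probs, struct = _unpack_params(fitted, theta)
    shadow = FittedGDINA(
        qmatrix=fitted.qmatrix,
        item_probs=item_probs,
        structural=struct,
        loglik=0.0,
        n_params=fitted.n_params,
        n_iter=0,
        converged=True,
        posterior=None,
        loglik_trace=np.empty(0),
        link=fitted.link,
        responses=fitted.responses,
        responses_digest=fitted.responses_digest,
        attr_patterns=fitted.attr_patterns,
        rmap=fitted.rmap,
    )
    w = np.clip(struct.class_weights(fitted.attr_patterns), PROB_CLIP, 1.0)
    joint = _class_loglik(fitted.responses.astype(float), item_probs, fitted.rmap) + np.log(w)
    shadow.posterior = np.exp(joint - logsumexp(joint, axis=1, keepdims=True))
    scores, _ = _score_matrix(shadow)
    return scores.sum(axis=0)


def observed_information_opg(fitted: FittedGDINA, sandwich: bool = True) -> tuple[np.ndarray, list[slice]]:
    """Covariance of all free parameters from the marginal likelihood.

    The cross-product of per-person scores (OPG, B) is combined with the
    observed information (A, numerical Hessian of the analytic score) into
    the sandwich A^{-1} B A^{-1}; the plain OPG inverse tends to understate
    finite-sample variance for weakly separated latent classes.
    """
    scores, slices = _score_matrix(fitted)
    bmat = scores.T @ scores
    if not sandwich:
        return np.linalg.pinv(bmat, rcond=1e-10, hermitian=True), slices
    theta = _pack_params(fitted)
    npar = theta.size
    h = 1e-5
    amat = np.empty((npar, npar))
    for idx in range(npar):
        up = theta.copy()
        dn = theta.copy()
        up[idx] += h
        dn[idx] -= h
        amat[:, idx] = -(_total_score(fitted, up) - _total_score(fitted, dn)) / (2 * h)
    amat = 0.5 * (amat + amat.T)
    a_inv = np.linalg.pinv(amat, rcond=1e-10, hermitian=True)
    return a_inv @ bmat @ a_inv, slices


def item_param_se(fitted: FittedGDINA, link: str | None = None) -> list[dict]:
    """Per-item SEs from the joint OPG covariance of the marginal likelihood.

    The full information over all item and structural parameters is inverted
    jointly so cross-item and structural covariance is reflected; SEs for
    delta under a link and for guess/slip follow by the delta method.  Items
    with boundary probabilities or an undefined covariance are reported with
    NaN markers rather than raised.
    """
    link = link or fitted.link
    sigma, slices = observed_information_opg(fitted)
    out = []
    for jj, probs in enumerate(fitted.item_probs):
        kst = int(fitted.qmatrix.kstar[jj])
        nred = 2**kst
        sigma_p = sigma[slices[jj], slices[jj]]
        diag = np.diag(sigma_p)
        boundary = bool(np.any(probs < 1e-6) or np.any(probs > 1 - 1e-6))
        if boundary or np.any(diag < -1e-8) or not np.isfinite(sigma_p).all():
            nan = np.full(nred, np.nan)
            out.append(
                {
                    "item": jj,
                    "sigma_probs": np.full((nred, nred), np.nan),
                    "se_probs": nan,
                    "se_delta": nan.copy(),
                    "se_guess": np.nan,
                    "se_slip": np.nan,
                    "defined": False,
                }
            )
            continue
        p = np.clip(probs, PROB_CLIP, 1 - PROB_CLIP)
        m, _ = delta_design(kst)
        jac = np.linalg.solve(m, np.diag(LINKS[link][2](p)))
        sigma_d = jac @ sigma_p @ jac.T
        se_p = np.sqrt(np.maximum(diag, 0.0))
        out.append(
            {
                "item": jj,
                "sigma_probs": sigma_p,
                "se_probs": se_p,
                "se_delta": np.sqrt(np.maximum(np.diag(sigma_d), 0.0)),
                "se_guess": float(se_p[0]),
                "se_slip": float(se_p[-1]),
                "defined": True,
            }
        )
    return out
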