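"""Shared fixtures: small fitted models and brute-force latent-class oracles.

The oracles enumerate latent classes and persons with explicit Python loops,
independent of the vectorized implementation they check.
"""

from itertools import product

import numpy as np
import pytest

from cdmpro.gdina import fit_gdina
from cdmpro.qmatrix import QMatrix, build_bifactor_qmatrix, default_assignment
from cdmpro.simulate import (
    DEFAULT_ITEM_CLASS_PROBS,
    sample_attribute_profiles,
    sample_item_responses,
)
from cdmpro.gdina import probs_to_delta


def brute_force_posterior(responses, qmatrix, item_probs, class_weights):
    """Explicit-loop class posteriors, marginal log-likelihood and CDPs."""
    patterns = list(product((0, 1), repeat=qmatrix.n_attributes))
    n, j = responses.shape
    post = np.zeros((n, len(patterns)))
    loglik = 0.0
    for i in range(n):
        for c, alpha in enumerate(patterns):
            lik = class_weights[c]
            for jj in range(j):
                cols = [k for k in range(qmatrix.n_attributes) if qmatrix.entries[jj, k] == 1]
                reduced = [alpha[k] for k in cols]
                idx = 0
                for bit in reduced:
                    idx = idx * 2 + bit
                p = item_probs[jj][idx]
                lik *= p if responses[i, jj] == 1 else (1.0 - p)
            post[i, c] = lik
        total = post[i].sum()
        loglik += np.log(total)
        post[i] /= total
    cdp = np.zeros((n, qmatrix.n_attributes))
    for i in range(n):
        for c, alpha in enumerate(patterns):
            for k in range(qmatrix.n_attributes):
                if alpha[k] == 1:
                    cdp[i, k] += post[i, c]
    return post, loglik, cdp


@pytest.fixture(scope="session")
def bifactor_q():
    return build_bifactor_qmatrix(default_assignment())


@pytest.fixture(scope="session")
def default_item_probs():
    return [np.asarray(p, dtype=float) for p in DEFAULT_ITEM_CLASS_PROBS]


@pytest.fixture(scope="session")
def study_responses(bifactor_q, default_item_probs):
    """One seeded draw from the study-condition generating model (n=1500)."""
    rng = np.random.default_rng(314159)
    profiles = sample_attribute_profiles(1500, [1.5] * 3, [0.98, -0.47, -0.24], rng)
    deltas = [probs_to_delta(p) for p in default_item_probs]
    responses = sample_item_responses(profiles, bifactor_q, deltas, "identity", rng)
    return responses, profiles


@pytest.fixture(scope="session")
def study_fit(study_responses, bifactor_q):
    """A converged pooled fit reused by read-only tests."""
    responses, _ = study_responses
    return fit_gdina(responses, bifactor_q, structural="higher_order", seed=0)


@pytest.fixture(scope="session")
def small_saturated_fit(bifactor_q, default_item_probs):
    rng = np.random.default_rng(2718)
    patterns = np.array(list(product((0, 1), repeat=3)))
    profiles = patterns[rng.integers(0, 8, size=600)]
    deltas = [probs_to_delta(p) for p in default_item_probs]
    responses = sample_item_responses(profiles, bifactor_q, deltas, "identity", rng)
    return fit_gdina(responses, bifactor_q, structural="saturated", seed=0)
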