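"""Q-matrix construction, I/O and empirical validation.

A Q-matrix declares which latent attributes each scale item measures.  For a
bifactor layout every item loads on one *specific* attribute plus a *general*
attribute shared by all items; the non-bifactor variant drops the general
column.  Validation uses the discrimination-index PVAF (proportion of variance
in latent-class success probabilities accounted for by a candidate q-vector)
with the conventional 0.95 cutoff: for each item, candidate q-vectors are
enumerated from simplest to most complex ("mesa plot" order) and the simplest
candidate reaching the cutoff is suggested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConstructionError, UndefinedMetricError

GENERAL_ATTRIBUTE = "General Factor (A3)"
SPECIFIC_ATTRIBUTES = ("Generic Elements (A1)", "Shift-Persist (A2)")


@dataclass
class QMatrix:
    """Binary item-by-attribute incidence matrix with labels.

    Invariants: every item measures at least one attribute (no all-zero row)
    and every attribute is measured by at least one item (no all-zero column).
    """

    entries: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    attribute_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=int)
        if self.entries.ndim != 2:
            raise ConstructionError("Q-matrix must be two-dimensional")
        if not np.isin(self.entries, (0, 1)).all():
            raise ConstructionError("Q-matrix cells must be 0 or 1")
        j, k = self.entries.shape
        if not self.item_labels:
            self.item_labels = [f"item{i + 1}" for i in range(j)]
        if not self.attribute_labels:
            self.attribute_labels = [f"A{i + 1}" for i in range(k)]
        if len(self.item_labels) != j or len(self.attribute_labels) != k:
            raise ConstructionError("label lengths do not match Q-matrix shape")
        if (self.entries.sum(axis=1) == 0).any():
            raise ConstructionError("every item must measure at least one attribute")
        if (self.entries.sum(axis=0) == 0).any():
            raise ConstructionError("every attribute must be measured by at least one item")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_attributes(self) -> int:
        return self.entries.shape[1]

    @property
    def kstar(self) -> np.ndarray:
        """Number of required attributes per item (row sums)."""
        return self.entries.sum(axis=1)

    def is_nested_in(self, other: "QMatrix") -> bool:
        """True when this Q-matrix is an entrywise subset of ``other``."""
        if self.entries.shape[0] != other.entries.shape[0]:
            return False
        a = self.entries
        b = other.entries
        if a.shape[1] < b.shape[1]:
            # allow comparison of a non-bifactor J x (K-1) matrix with its
            # bifactor J x K extension: pad missing columns with zeros
            common = [i for i, lab in enumerate(other.attribute_labels) if lab in self.attribute_labels]
            if len(common) != a.shape[1]:
                return False
            padded = np.zeros_like(b)
            padded[:, common] = a
            a = padded
        elif a.shape[1] > b.shape[1]:
            return False
        return bool((a <= b).all())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, index=self.item_labels, columns=self.attribute_labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "QMatrix":
        frame = pd.read_csv(path, index_col=0)
        return cls(frame.to_numpy(), list(frame.index.astype(str)), list(frame.columns.astype(str)))


def build_nonbifactor_qmatrix(
    assignment: Mapping[str, str],
    specific_attributes: Sequence[str] = SPECIFIC_ATTRIBUTES,
) -> QMatrix:
    """Simple-structure Q-matrix: each item loads on exactly one specific attribute."""
    if not assignment:
        raise ConstructionError("empty item assignment")
    specific = list(specific_attributes)
    entries = np.zeros((len(assignment), len(specific)), dtype=int)
    items = list(assignment)
    for row, item in enumerate(items):
        attr = assignment[item]
        if attr not in specific:
            raise ConstructionError(f"item {item!r} assigned to unknown attribute {attr!r}")
        entries[row, specific.index(attr)] = 1
    return QMatrix(entries, items, specific)


def build_bifactor_qmatrix(
    assignment: Mapping[str, str],
    specific_attributes: Sequence[str] = SPECIFIC_ATTRIBUTES,
    general_attribute: str = GENERAL_ATTRIBUTE,
) -> QMatrix:
    """Bifactor Q-matrix: each item loads on its specific attribute plus the general one.

    Every row therefore has exactly two ones (K_j* = 2).
    """
    base = build_nonbifactor_qmatrix(assignment, specific_attributes)
    entries = np.hstack([base.entries, np.ones((base.n_items, 1), dtype=int)])
    return QMatrix(entries, base.item_labels, list(specific_attributes) + [general_attribute])


def default_assignment(n_items: int = 10) -> dict[str, str]:
    """Illustrative item-to-specific-factor map: first half A1, second half A2.

    The real instrument's factor assignment is not public; this split is a
    configurable stand-in with the right shape (two five-item specific factors).
    """
    half = n_items // 2
    return {
        f"item{i + 1}": SPECIFIC_ATTRIBUTES[0] if i < half else SPECIFIC_ATTRIBUTES[1]
        for i in range(n_items)
    }


# ---------------------------------------------------------------------------
# PVAF / mesa-plot validation
# ---------------------------------------------------------------------------

@dataclass
class PvafTable:
    """Per-item PVAF of every candidate q-vector, ordered simplest first."""

    item: int
    table: pd.DataFrame  # columns: candidate, n_attributes, pvaf
    suggested: tuple[int, ...]
    cutoff: float


def _class_success_summary(fitted, item: int):
    """Class weights and per-class success probabilities for one item.

    Both are estimated non-iteratively from the fitted posterior: the expected
    count and expected number of successes accumulated over persons in each of
    the 2^K latent classes.
    """
    post = fitted.posterior
    y = fitted.responses[:, item].astype(float)
    n_c = post.sum(axis=0)
    r_c = post.T @ y
    w = n_c / n_c.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_c > 1e-12, r_c / np.maximum(n_c, 1e-12), 0.0)
    return w, p


def _zeta_squared(w: np.ndarray, p: np.ndarray, patterns: np.ndarray, candidate: np.ndarray) -> float:
    """Discrimination index: weighted variance of collapsed class success probabilities."""
    cols = np.flatnonzero(candidate)
    key = patterns[:, cols] @ (1 << np.arange(len(cols))[::-1])
    pbar = float(w @ p)
    zeta = 0.0
    for g in np.unique(key):
        mask = key == g
        wg = w[mask].sum()
        if wg <= 0:
            continue
        pg = float(w[mask] @ p[mask]) / wg
        zeta += wg * (pg - pbar) ** 2
    return zeta


def pvaf(fitted, item: int, candidate: Sequence[int]) -> float:
    """Proportion of variance accounted for by ``candidate`` relative to the full q-vector.

    Raises :class:`UndefinedMetricError` for a flat item (all latent classes
    share the same success probability, so the full-vector variance is zero).
    """
    candidate = np.asarray(candidate, dtype=int)
    if candidate.sum() == 0:
        raise UndefinedMetricError("candidate q-vector must require at least one attribute")
    patterns = fitted.attr_patterns
    w, p = _class_success_summary(fitted, item)
    full = _zeta_squared(w, p, patterns, np.ones(patterns.shape[1], dtype=int))
    if full < 1e-12:
        raise UndefinedMetricError(f"item {item} is flat: PVAF undefined")
    return min(_zeta_squared(w, p, patterns, candidate) / full, 1.0)


def candidate_qvectors(n_attributes: int) -> list[tuple[int, ...]]:
    """All non-zero q-vectors ordered by attribute count, then lexicographically."""
    cands = [c for c in product((0, 1), repeat=n_attributes) if sum(c) > 0]
    cands.sort(key=lambda c: (sum(c), tuple(-x for x in c)))
    return cands


def mesa_table(fitted, item: int, cutoff: float = 0.95) -> PvafTable:
    """PVAF of every candidate q-vector for one item plus the suggested vector.

    The suggestion is the simplest (fewest attributes) candidate whose PVAF
    reaches the cutoff; ties at equal simplicity are broken by larger PVAF,
    then lexicographic order.
    """
    if not 0.0 < cutoff <= 1.0:
        raise UndefinedMetricError("cutoff must lie in (0, 1]")
    rows = []
    for cand in candidate_qvectors(fitted.attr_patterns.shape[1]):
        rows.append({"candidate": cand, "n_attributes": sum(cand), "pvaf": pvaf(fitted, item, cand)})
    table = pd.DataFrame(rows)
    ok = table[table["pvaf"] >= cutoff]
    if len(ok):
        simplest = ok["n_attributes"].min()
        pool = ok[ok["n_attributes"] == simplest]
        suggested = pool.loc[pool["pvaf"].idxmax(), "candidate"]
    else:
        suggested = tuple(np.ones(fitted.attr_patterns.shape[1], dtype=int))
    return PvafTable(item=item, table=table, suggested=tuple(suggested), cutoff=cutoff)


def validate_qmatrix(fitted, cutoff: float = 0.95) -> pd.DataFrame:
    """Run the mesa-plot validation over every item of a fitted model.

    Returns one row per item with the current q-vector, the suggested one,
    and whether a change is indicated.
    """
    q = fitted.qmatrix
    rows = []
    for j in range(q.n_items):
        tab = mesa_table(fitted, j, cutoff)
        current = tuple(q.entries[j])
        rows.append(
            {
                "item": q.item_labels[j],
                "current": current,
                "suggested": tab.suggested,
                "pvaf_current": pvaf(fitted, j, np.asarray(current)),
                "change": tab.suggested != current,
            }
        )
    return pd.DataFrame(rows)
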