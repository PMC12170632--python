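"""Similarity metrics between two synergy decompositions.

EMG-derived and model-derived synergy sets are compared after optimal
one-to-one matching of their components: weight vectors by the
scalar-product (normalized dot product, in [0, 1] for nonnegative
inputs), activation coefficients by Pearson correlation, and each
muscle's weight profile across matched synergies by the scalar product.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .containers import SynergySet
from .errors import DomainError, LabelMismatchError, UndefinedSimilarityError


def scalar_product_similarity(u, v) -> float:
    """Normalized dot product (u.v)/(|u||v|); in [0,1] for nonnegative vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise DomainError("vectors must share length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError("similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def pearson_similarity(x, y) -> float:
    """Standard centered Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise DomainError("sequences must share length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedSimilarityError("correlation undefined for constant sequence")
    return float(pearsonr(x, y)[0])


def match_synergies(a: SynergySet, b: SynergySet) -> list[tuple[int, int]]:
    """Optimal one-to-one pairing of synergy columns by total weight similarity.

    Solved as a linear assignment problem on the pairwise scalar-product
    matrix (exact; equals exhaustive permutation search).  Zero columns
    score 0 against everything.
    """
    if list(a.muscle_labels) != list(b.muscle_labels):
        raise LabelMismatchError("decompositions use different muscle label orders")
    sim = np.zeros((a.k, b.k))
    for i in range(a.k):
        for j in range(b.k):
            try:
                sim[i, j] = scalar_product_similarity(a.w[:, i], b.w[:, j])
            except UndefinedSimilarityError:
                sim[i, j] = 0.0
    rows, cols = linear_sum_assignment(-sim)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    return [(int(i), int(j)) for i, j in pairs][: min(a.k, b.k)]


def match_synergies_bruteforce(a: SynergySet, b: SynergySet) -> list[tuple[int, int]]:
    """Exhaustive-permutation matching (k <= 6); reference for the assignment."""
    if a.k != b.k:
        raise DomainError("brute-force matcher requires equal k")
    if a.k > 6:
        raise DomainError("brute force limited to k <= 6")
    best, best_total = None, -np.inf
    for perm in itertools.permutations(range(b.k)):
        total = 0.0
        for i, j in enumerate(perm):
            try:
                total += scalar_product_similarity(a.w[:, i], b.w[:, j])
            except UndefinedSimilarityError:
                pass
        if total > best_total:
            best_total, best = total, perm
    return [(i, int(j)) for i, j in enumerate(best)]


def per_muscle_similarity(a: SynergySet, b: SynergySet, matching) -> np.ndarray:
    """Scalar-product similarity of each muscle's weight profile across synergies.

    Each muscle contributes a k-vector of weights (its row of W, columns
    ordered by the matching); the two profiles are compared by normalized
    dot product.  All-zero profiles yield NaN.
    """
    ia = [i for i, _ in matching]
    ib = [j for _, j in matching]
    rows_a = a.w[:, ia]
    rows_b = b.w[:, ib]
    out = np.full(a.w.shape[0], np.nan)
    for mi in range(a.w.shape[0]):
        try:
            out[mi] = scalar_product_similarity(rows_a[mi], rows_b[mi])
        except UndefinedSimilarityError:
            pass
    return out


@dataclass
class SimilarityReport:
    """Matched-pair similarities between two decompositions."""

    matching: list[tuple[int, int]]
    w_similarity: np.ndarray
    c_similarity: np.ndarray
    per_muscle: np.ndarray
    muscle_labels: list[str]
    summary: dict = field(default_factory=dict)

    def to_frame(self):
        """Table mirroring the per-muscle + per-component report layout."""
        import pandas as pd

        rows = [
            {"feature": lab, "similarity": val}
            for lab, val in zip(self.muscle_labels, self.per_muscle)
        ]
        for p, (i, j) in enumerate(self.matching, start=1):
            rows.append({"feature": f"W{p}", "similarity": self.w_similarity[p - 1]})
        for p in range(1, len(self.matching) + 1):
            rows.append({"feature": f"C{p}", "similarity": self.c_similarity[p - 1]})
        return pd.DataFrame(rows)


def compare_decompositions(a: SynergySet, b: SynergySet) -> SimilarityReport:
    """Match two synergy sets and report W, C and per-muscle similarities."""
    matching = match_synergies(a, b)
    w_sim = np.array(
        [scalar_product_similarity(a.w[:, i], b.w[:, j]) for i, j in matching]
    )
    c_sim = np.array([pearson_similarity(a.c[i], b.c[j]) for i, j in matching])
    pm = per_muscle_similarity(a, b, matching)
    report = SimilarityReport(
        matching=matching,
        w_similarity=w_sim,
        c_similarity=c_sim,
        per_muscle=pm,
        muscle_labels=list(a.muscle_labels),
        summary={
            "w_mean": float(w_sim.mean()),
            "w_sd": float(w_sim.std(ddof=1)) if w_sim.size > 1 else 0.0,
            "c_mean": float(c_sim.mean()),
            "c_sd": float(c_sim.std(ddof=1)) if c_sim.size > 1 else 0.0,
        },
    )
    return report
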