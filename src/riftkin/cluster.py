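"""Soft clustering of decay profiles and functional enrichment.

Profiles (replicate-mean log2 series, standardized per gene) are
clustered with fuzzy c-means (fuzzifier m = 2 by default), and each
cluster is tested for overrepresentation of functional categories with
the hypergeometric upper tail, Bonferroni-adjusted over all
(cluster, category) tests.  The cluster number is chosen to maximize
the count of significantly enriched (cluster, category) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterConfig",
    "ClusterAssignment",
    "standardize_profiles",
    "fuzzy_cmeans",
    "enrichment_test",
    "select_cluster_number",
    "P_FLOOR",
]

P_FLOOR = 1e-16


@dataclass
class ClusterConfig:
    m: float = 2.0                      # fuzzifier; m -> 1 recovers k-means
    candidates: tuple = tuple(range(4, 21))
    max_iter: int = 300
    tol: float = 1e-6                   # max absolute membership change
    restarts: int = 5
    seed: int = 0
    alpha: float = 0.05                 # on Bonferroni-adjusted p
    support_threshold: float = 0.5      # "well supported" max membership

    def __post_init__(self):
        if not self.m > 1:
            raise ValueError("fuzzifier m must be > 1")
        if any(c < 2 for c in self.candidates):
            raise ValueError("cluster counts must be >= 2")
        if not self.tol > 0:
            raise ValueError("tolerance must be > 0")


@dataclass
class ClusterAssignment:
    """Membership matrix (genes x clusters) with derived hard labels."""

    gene_ids: list
    memberships: np.ndarray
    centers: np.ndarray
    objective: float
    n_iter: int
    support_threshold: float = 0.5

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.memberships, axis=1)

    @property
    def max_membership(self) -> np.ndarray:
        return self.memberships.max(axis=1)

    @property
    def well_supported(self) -> np.ndarray:
        return self.max_membership >= self.support_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "gene_id": self.gene_ids,
            "cluster": self.labels,
            "max_membership": self.max_membership,
            "well_supported": self.well_supported,
        })


def standardize_profiles(mean_log2: pd.DataFrame):
    """Center and scale each gene's log2 profile to mean 0, sd 1.

    Constant profiles (sd = 0) carry no shape information and are
    excluded; returns ``(standardized, excluded_ids)``.
    """
    if mean_log2.shape[1] < 3:
        raise ValueError("need at least 3 timepoints")
    mu = mean_log2.mean(axis=1)
    sd = mean_log2.std(axis=1, ddof=0)
    keep = sd > 0
    z = mean_log2.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z, list(mean_log2.index[~keep])


def _fcm_once(X: np.ndarray, c: int, m: float, max_iter: int, tol: float,
              rng: np.random.Generator):
    n = X.shape[0]
    U = rng.random((n, c))
    U /= U.sum(axis=1, keepdims=True)
    for it in range(1, max_iter + 1):
        Um = U ** m
        centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        inv = d2 ** (-1.0 / (m - 1.0))  # squared distance to the -1/(m-1)
        U_new = inv / inv.sum(axis=1, keepdims=True)
        delta = float(np.abs(U_new - U).max())
        U = U_new
        if delta < tol:
            break
    Um = U ** m
    centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
    d2 = np.maximum(((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), 1e-300)
    obj = float(((U ** m) * d2).sum())
    return U, centers, obj, it


def fuzzy_cmeans(profiles: pd.DataFrame, c: int,
                 config: Optional[ClusterConfig] = None) -> ClusterAssignment:
    """Fuzzy c-means on standardized profiles (Euclidean distance).

    Alternates membership updates (inverse squared distance to the
    power 1/(m-1), normalized per gene) and membership^m-weighted
    center updates until the maximum membership change drops below the
    tolerance.  The best of ``config.restarts`` seeded random starts by
    objective value is kept; the objective is non-increasing across
    iterations.
    """
    config = config or ClusterConfig()
    X = profiles.to_numpy(dtype=float)
    if c >= X.shape[0]:
        raise ValueError("need more profiles than clusters")
    if np.allclose(X, X[0]):
        raise ValueError("degenerate input: all profiles identical")
    best = None
    for r in range(config.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c, r]))
        U, centers, obj, n_iter = _fcm_once(X, c, config.m, config.max_iter,
                                            config.tol, rng)
        if best is None or obj < best[2]:
            best = (U, centers, obj, n_iter)
    U, centers, obj, n_iter = best
    return ClusterAssignment(list(profiles.index), U, centers, obj, n_iter,
                             support_threshold=config.support_threshold)


def enrichment_test(assignment: ClusterAssignment, categories: pd.Series,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric overrepresentation of categories within clusters.

    For a cluster of size n containing k members of a category of size
    K in a universe of N clustered genes, the upper-tail probability
    P(X >= k) is computed (k = 0 gives p = 1), Bonferroni-adjusted over
    all (cluster x category) tests.  Reported p-values are floored at
    1e-16; ``raw_p`` keeps the unfloored value.
    """
    genes = pd.Index(assignment.gene_ids)
    cats = categories.reindex(genes).dropna()
    missing = set(categories.index) - set(genes)
    labels = pd.Series(assignment.labels, index=genes)
    N = len(genes)
    rows = []
    n_clusters = assignment.memberships.shape[1]
    cat_names = sorted(cats.unique())
    n_tests = n_clusters * len(cat_names)
    for cl in range(n_clusters):
        members = genes[labels == cl]
        n = len(members)
        for cat in cat_names:
            K = int((cats == cat).sum())
            if K == 0:
                raise ValueError(f"category {cat!r} absent from universe")
            k = int((cats.reindex(members) == cat).sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            p = min(p, 1.0)
            p_adj = min(p * n_tests, 1.0)
            rows.append({
                "cluster": cl, "category": cat, "k": k, "n": n, "K": K, "N": N,
                "p": max(p, P_FLOOR), "p_adj": max(p_adj, P_FLOOR),
                "raw_p": p, "significant": p_adj < alpha,
            })
    return pd.DataFrame(rows)


def select_cluster_number(profiles: pd.DataFrame, categories: pd.Series,
                          config: Optional[ClusterConfig] = None):
    """Choose the cluster count maximizing functional enrichment.

    The score of a candidate c is the number of (cluster, category)
    pairs whose Bonferroni-adjusted hypergeometric p falls below
    ``config.alpha``.  Ties break to the smallest c.  Returns
    ``(chosen_c, scores_by_c, assignment_at_chosen_c)``.
    """
    config = config or ClusterConfig()
    if not config.candidates:
        raise ValueError("empty candidate range")
    scores: Dict[int, int] = {}
    assignments = {}
    for c in config.candidates:
        asg = fuzzy_cmeans(profiles, c, config)
        enr = enrichment_test(asg, categories, alpha=config.alpha)
        scores[c] = int(enr["significant"].sum())
        assignments[c] = asg
    best_c = max(sorted(scores), key=lambda c: scores[c])
    # max() keeps the first (smallest) c on ties because of the sort
    return best_c, scores, assignments[best_c]
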