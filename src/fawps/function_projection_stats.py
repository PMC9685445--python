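"""Function–projection association statistics.

Neurons are clustered by their two functional indices (R², OSI) with
k-means; the number of clusters is chosen by maximizing the
Calinski–Harabasz index over a scanned range.  Associations between
functional indices and per-region axonal length use Spearman rank
correlation with the dual significance rule p < 0.05 AND |r| > 0.6.
Group comparisons use the Mann–Whitney U test (two motifs) or the
Kruskal–Wallis test with Dunn's post-hoc z-tests (≥ 3 groups).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .projection_quantification import TARGET_THRESHOLD_MM

__all__ = [
    "ClusteringResult",
    "AssociationEntry",
    "kmeans_with_ch",
    "calinski_harabasz",
    "spearman_assoc",
    "mann_whitney",
    "kruskal_dunn",
]

SIGNIFICANCE_P = 0.05
SIGNIFICANCE_ABS_R = 0.6
DEFAULT_K_RANGE = (2, 3, 4, 5, 6)
DEFAULT_N_INIT = 50


@dataclass
class ClusteringResult:
    k: int
    labels: np.ndarray  # values in 1..k
    ch_by_k: dict  # k -> Calinski–Harabasz index
    centroids: np.ndarray  # (k, n_features)


@dataclass
class AssociationEntry:
    feature: str
    region: str
    n: int
    r: float
    p: float
    significant: bool = field(init=False)

    def __post_init__(self):
        self.significant = bool(self.p < SIGNIFICANCE_P and abs(self.r) > SIGNIFICANCE_ABS_R)


# ---------------------------------------------------------------------------
# Clustering


def calinski_harabasz(features: np.ndarray, labels: np.ndarray) -> float:
    """Calinski–Harabasz index: (B/(k−1)) / (W/(n−k)) with B the
    between-cluster and W the within-cluster dispersion.

    Degenerate cases: zero within-cluster dispersion with positive
    between-cluster dispersion → +inf; both zero (all points identical)
    → ValueError.  Requires ≥ 2 non-empty clusters.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    k = len(uniq)
    n = X.shape[0]
    if k < 2:
        raise ValueError("Calinski–Harabasz requires >= 2 clusters")
    grand = X.mean(axis=0)
    between = 0.0
    within = 0.0
    for u in uniq:
        members = X[labels == u]
        if members.shape[0] == 0:
            raise ValueError("empty cluster")
        c = members.mean(axis=0)
        between += members.shape[0] * float(np.sum((c - grand) ** 2))
        within += float(np.sum((members - c) ** 2))
    if within == 0:
        if between == 0:
            raise ValueError("all points identical: CH undefined (0/0)")
        return float("inf")
    return (between / (k - 1)) / (within / (n - k))


def kmeans_with_ch(
    features,
    k_range=DEFAULT_K_RANGE,
    n_init: int = DEFAULT_N_INIT,
    seed: int | None = 0,
) -> ClusteringResult:
    """k-means over a range of k, choosing k by the Calinski–Harabasz index.

    For each k the best of ``n_init`` seeded initializations (by
    within-cluster sum of squares) is kept; the chosen k maximizes CH, ties
    breaking toward the smaller k.  Labels are reported 1-based.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    k_range = sorted(set(int(k) for k in k_range))
    if min(k_range) < 2:
        raise ValueError("k must be >= 2")
    if X.shape[0] < max(k_range) + 1:
        raise ValueError("too few observations for requested k range")
    ch_by_k: dict = {}
    fits: dict = {}
    for k in k_range:
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        fits[k] = km
        try:
            ch_by_k[k] = calinski_harabasz(X, lab)
        except ValueError:
            ch_by_k[k] = float("-inf")
    best_k = max(k_range, key=lambda k: (ch_by_k[k], -k))
    km = fits[best_k]
    return ClusteringResult(
        k=best_k,
        labels=km.labels_ + 1,
        ch_by_k=ch_by_k,
        centroids=km.cluster_centers_,
    )


# ---------------------------------------------------------------------------
# Spearman association


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for Spearman r at small n."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_assoc(
    table: pd.DataFrame,
    feature: str,
    region: str,
    restrict_to_projecting: bool = False,
    threshold_mm: float = TARGET_THRESHOLD_MM,
    min_n: int = 5,
    exact_max_n: int = 8,
) -> AssociationEntry:
    """Spearman correlation between a functional index and a region's
    axonal length, with the dual significance rule (p < 0.05 and |r| > 0.6).

    ``restrict_to_projecting`` keeps only neurons whose length in the region
    meets the target threshold ("projecting neurons").  Ties use average
    ranks; p is the two-sided t-approximation, or an exact permutation
    enumeration for n ≤ ``exact_max_n``.
    """
    sub = table
    if restrict_to_projecting:
        sub = table[table[region] >= threshold_mm]
    if len(sub) < min_n:
        raise ValueError(f"only {len(sub)} rows after restriction (< {min_n})")
    x = sub[feature].to_numpy(dtype=float)
    y = sub[region].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant column: Spearman r undefined")
    r, p = stats.spearmanr(x, y)
    if len(x) <= exact_max_n:
        p = _spearman_exact_p(x, y, r)
    return AssociationEntry(feature=feature, region=region, n=len(sub), r=float(r), p=float(p))


# ---------------------------------------------------------------------------
# Group tests


def mann_whitney(group_a, group_b) -> tuple:
    """Mann–Whitney U with two-sided p (exact for small untied samples,
    normal approximation with tie correction otherwise)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def kruskal_dunn(groups: list, adjust: str | None = None) -> dict:
    """Kruskal–Wallis H (tie-corrected, chi-square p) with Dunn's post-hoc
    pairwise z-tests on mean ranks.

    ``adjust``: None (default), "bonferroni" or "holm" multiplicity
    adjustment of the Dunn p-values.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical")
    h, p = stats.kruskal(*groups)

    # Dunn: z on mean-rank differences with tie correction
    ranks = stats.rankdata(pooled)
    n = pooled.size
    sizes = [g.size for g in groups]
    idx = np.cumsum([0] + sizes)
    mean_ranks = [ranks[idx[i]:idx[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n - 1))
    pairwise = {}
    raw = []
    keys = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = math.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_ij = 2.0 * stats.norm.sf(abs(z))
        keys.append((i, j))
        raw.append(min(p_ij, 1.0))
    m = len(raw)
    if adjust == "bonferroni":
        adj = [min(1.0, q * m) for q in raw]
    elif adjust == "holm":
        order = np.argsort(raw)
        adj = [0.0] * m
        running = 0.0
        for rank, oi in enumerate(order):
            val = min(1.0, raw[oi] * (m - rank))
            running = max(running, val)
            adj[oi] = running
    elif adjust is None:
        adj = raw
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (i, j), q in zip(keys, adj):
        pairwise[(i, j)] = float(q)
    return {"H": float(h), "p": float(p), "dunn_p": pairwise}
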