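"""Expression-profile clustering with silhouette-based model selection.

Counts are variance-stabilized as log2(normalized + 1); the top-variance
genes (default 1000) are clustered on their per-level mean profiles with
Euclidean k-means; candidate k are scored by the mean silhouette width and
local optima of that curve are reported.  Cluster memberships can then be
tested for over-representation of user-supplied gene sets with an
upper-tail hypergeometric test, BH-adjusted across sets; sets with fewer
than three overlapping genes are flagged as excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .design import StudyDesign
from .diffexpr import CountMatrix, bh_adjust

DEFAULT_TOP_N = 1000
DEFAULT_K_RANGE = tuple(range(2, 11))
MIN_SET_OVERLAP = 3


@dataclass
class ExpressionMatrix:
    values: pd.DataFrame  # genes x conditions (or samples)
    provenance: str       # "per-sample" | "level-means"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy())):
            raise ValueError("expression values must be finite")


@dataclass
class ClusterResult:
    assignments: pd.Series  # gene -> cluster in 1..k
    centroids: pd.DataFrame
    k: int
    seed: int
    inertia: float


@dataclass
class SilhouetteScan:
    scores: pd.DataFrame  # columns k, mean_silhouette
    local_optima: list[int]

    @property
    def best_k(self) -> int:
        return int(self.scores.loc[self.scores["mean_silhouette"].idxmax(), "k"])


def vst(counts: CountMatrix, size_factors) -> ExpressionMatrix:
    """log2(count / size_factor + 1): monotone, variance-flattening."""
    sf = np.asarray(size_factors, dtype=float)
    if np.any(sf <= 0):
        raise ValueError("size factors must be positive")
    values = np.log2(counts.values / sf[None, :] + 1.0)
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        provenance="per-sample",
    )


def top_variable_genes(expr: ExpressionMatrix, n: int = DEFAULT_TOP_N) -> list[str]:
    """The n genes of highest variance; ties broken by gene id."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > expr.values.shape[0]:
        raise ValueError(f"n={n} exceeds the gene count {expr.values.shape[0]}")
    var = expr.values.var(axis=1, ddof=1)
    order = sorted(var.index, key=lambda g: (-var[g], g))
    return order[:n]


def condition_means(expr: ExpressionMatrix, design: StudyDesign, level_order=None) -> ExpressionMatrix:
    """Arithmetic mean per gene per condition level."""
    levels = list(level_order) if level_order is not None else design.levels
    cols = {}
    for level in levels:
        samples = design.samples_for_level(level)
        if not samples:
            raise ValueError(f"level {level} has no samples")
        cols[level] = expr.values[samples].mean(axis=1)
    return ExpressionMatrix(pd.DataFrame(cols), provenance="level-means")


def kmeans_profiles(
    level_means: ExpressionMatrix, k: int, seed: int = 0, n_init: int = 50
) -> ClusterResult:
    """Euclidean k-means, best of n_init initializations; deterministic per seed."""
    X = level_means.values.to_numpy()
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the gene count {X.shape[0]}")
    km = KMeans(n_clusters=k, n_init=n_init, max_iter=300, tol=1e-6, random_state=seed)
    labels = km.fit_predict(X)
    return ClusterResult(
        assignments=pd.Series(labels + 1, index=level_means.values.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=level_means.values.columns,
                               index=pd.RangeIndex(1, k + 1, name="cluster")),
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def silhouette_scan(
    level_means: ExpressionMatrix, k_range=DEFAULT_K_RANGE, seed: int = 0, n_init: int = 50
) -> SilhouetteScan:
    """Mean silhouette width per candidate k; strict local optima reported.

    Endpoints of the grid cannot be local optima.
    """
    X = level_means.values.to_numpy()
    if np.allclose(X, X[0]):
        raise ValueError("all profiles are identical; silhouette is undefined")
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 2 or ks[-1] > X.shape[0] - 1:
        raise ValueError("k_range must lie within [2, n_genes - 1]")
    rows = []
    for k in ks:
        res = kmeans_profiles(level_means, k, seed=seed, n_init=n_init)
        rows.append((k, float(silhouette_score(X, res.assignments.to_numpy()))))
    scores = pd.DataFrame(rows, columns=["k", "mean_silhouette"])
    s = scores["mean_silhouette"].to_numpy()
    optima = [
        int(scores["k"].iloc[i])
        for i in range(1, len(ks) - 1)
        if s[i] > s[i - 1] and s[i] > s[i + 1]
    ]
    return SilhouetteScan(scores, optima)


def ora_hypergeometric(cluster_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in one cluster.

    Upper-tail p for drawing at least the observed overlap when sampling
    |cluster| genes from the universe; BH-FDR across sets; sets with
    overlap < 3 flagged ``excluded``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("the universe must be non-empty")
    cluster = set(cluster_genes)
    if not cluster <= universe:
        raise ValueError("cluster genes must be contained in the universe")
    N, n = len(universe), len(cluster)
    rows = []
    for name, members in gene_sets.items():
        members = set(members)
        if not members <= universe:
            raise ValueError(f"gene set {name!r} is not contained in the universe")
        K = len(members)
        k = len(members & cluster)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, p))
    table = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"])
    table["fdr"] = bh_adjust(table["p"].to_numpy())
    table["excluded"] = table["overlap"] < MIN_SET_OVERLAP
    return table.set_index("set")
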