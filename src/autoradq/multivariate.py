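"""Multivariate comparison of fingerprint collections.

The battery mirrors the standard workflow for neurochemical profiles:

* hierarchical clustering of z-scored fingerprints with Euclidean
  distances and Ward linkage, the linkage choice documented by the
  cophenetic correlation coefficient (Ward is reported alongside the
  alternatives so the maximum can be verified on the data at hand);
* the number of "main" clusters chosen by seeded k-means over a k grid,
  scored by mean silhouette;
* nonmetric multidimensional scaling (Kruskal stress-1) to embed the
  receptor space in two dimensions for display;
* an omnibus discriminant test of group separation plus pairwise
  follow-ups.  With many receptors and few replicate brains the pooled
  covariance is singular, so the separation statistic uses a
  Ledoit-Wolf-shrunk within-group covariance and p-values come from label
  permutations, which keeps them exact regardless of dimensionality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.covariance import ledoit_wolf
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score


class MultivariateError(ValueError):
    """Raised for degenerate inputs to the multivariate battery."""


_ALT_LINKAGES = ("single", "complete", "average", "weighted", "centroid", "median")


# --------------------------------------------------------------------------
# Hierarchical clustering
# --------------------------------------------------------------------------

@dataclass
class DendrogramResult:
    linkage: np.ndarray                  # scipy linkage matrix (Ward/Euclidean)
    labels: list[str]
    cophenetic_correlation: float
    alt_cophenetic: dict[str, float] = field(default_factory=dict)

    def cut(self, k: int) -> np.ndarray:
        return hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")

    def to_newick(self) -> str:
        """Serialize with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_dist):
            length = parent_dist - node.dist
            if node.is_leaf():
                name = self.labels[node.id].replace(" ", "_").replace(",", "_")
                return f"{name}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return walk(tree, tree.dist) + ";"


def hcluster(X: np.ndarray | None = None, labels: Sequence[str] | None = None,
             report_alternatives: bool = True,
             D: np.ndarray | None = None) -> DendrogramResult:
    """Ward/Euclidean hierarchical clustering with cophenetic diagnostics.

    Pass either the fingerprint matrix ``X`` (Euclidean distances are
    computed) or a precomputed distance matrix ``D`` (square or condensed).
    Ties between merge candidates are broken by scipy's lowest-index rule,
    which keeps dendrograms reproducible.  Requires >= 3 observations and
    no missing values.
    """
    if (X is None) == (D is None):
        raise MultivariateError("pass exactly one of X (features) or D (distances)")
    if D is None:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or len(X) < 3:
            raise MultivariateError("need a 2-D matrix with >= 3 observations")
        if np.isnan(X).any():
            raise MultivariateError("missing values in fingerprint matrix")
        n = len(X)
        D = pdist(X, metric="euclidean")
    else:
        D = np.asarray(D, dtype=float)
        if D.ndim == 2:
            D = squareform(D, checks=True)
        if np.isnan(D).any():
            raise MultivariateError("missing values in distance matrix")
        n = int(round((1 + np.sqrt(1 + 8 * len(D))) / 2))
        if n < 3:
            raise MultivariateError("need >= 3 observations")
    if labels is None:
        labels = [str(i) for i in range(n)]
    if len(labels) != n:
        raise MultivariateError("labels length does not match matrix")
    Z = hierarchy.linkage(D, method="ward")
    if np.ptp(D) == 0:  # all-equal distances: correlation undefined, tree exact
        coph = 1.0
    else:
        coph = float(hierarchy.cophenet(Z, D)[0])
    alt = {}
    if report_alternatives:
        for method in _ALT_LINKAGES:
            Za = hierarchy.linkage(D, method=method)
            alt[method] = 1.0 if np.ptp(D) == 0 else float(hierarchy.cophenet(Za, D)[0])
    return DendrogramResult(linkage=Z, labels=list(labels),
                            cophenetic_correlation=coph, alt_cophenetic=alt)


# --------------------------------------------------------------------------
# Cluster-number selection
# --------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    k: int
    labels: np.ndarray                    # cluster id per observation
    selection_score: dict[int, float]     # candidate k -> mean silhouette


def choose_k(X: np.ndarray, k_max: int = 12, seed: int = 0,
             n_init: int = 10, min_cluster_frac: float = 0.05) -> ClusterAssignment:
    """Pick the cluster count by seeded k-means + maximal mean silhouette.

    k runs over 2..k_max (k_max must be < n); ties resolve to the smaller
    k.  Candidate partitions whose smallest cluster holds fewer than
    ``ceil(min_cluster_frac * n)`` observations are discarded — the chosen
    count describes the *main* clusters, and raw silhouette otherwise
    rewards splitting off one or two stragglers.  All-identical
    observations have no cluster structure and raise.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    if k_max >= n:
        raise MultivariateError(f"k_max ({k_max}) must be < number of observations ({n})")
    if k_max < 2:
        raise MultivariateError("k_max must be >= 2")
    if np.allclose(X, X[0]):
        raise MultivariateError("zero variance: all observations identical")
    min_size = max(1, int(np.ceil(min_cluster_frac * n)))

    scores: dict[int, float] = {}
    assignments: dict[int, np.ndarray] = {}
    for k in range(2, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(X)
        if len(np.unique(lab)) < 2:
            continue
        if np.bincount(lab).min() < min_size:
            continue
        scores[k] = float(silhouette_score(X, lab))
        assignments[k] = lab
    if not scores:
        raise MultivariateError("no k produced a valid clustering")
    best = min((k for k in scores), key=lambda k: (-scores[k], k))
    return ClusterAssignment(k=best, labels=assignments[best],
                             selection_score=scores)


# --------------------------------------------------------------------------
# Multidimensional scaling
# --------------------------------------------------------------------------

@dataclass
class MDSResult:
    coords: np.ndarray     # (n, 2)
    stress: float          # Kruskal stress-1
    metric: bool = False


def kruskal_stress1(D_target: np.ndarray, coords: np.ndarray) -> float:
    """Stress-1 = sqrt(sum (d_hat - d)^2 / sum d^2) of an embedding."""
    d_emb = pdist(coords)
    d_t = squareform(D_target, checks=False)
    denom = float(np.sum(d_emb ** 2))
    if denom == 0:
        return 0.0
    return float(np.sqrt(np.sum((d_t - d_emb) ** 2) / denom))


def mds_kruskal(X: np.ndarray | None = None, D: np.ndarray | None = None,
                metric: bool = False, n_init: int = 20, seed: int = 0,
                eps: float = 1e-6, max_iter: int = 500) -> MDSResult:
    """2-D embedding of the fingerprint distances.

    ``metric=False`` (default) minimizes rank-based Kruskal stress-1 by
    SMACOF with seeded restarts; ``metric=True`` uses classical
    (Torgerson) scaling, which reproduces plane-embeddable distances
    exactly.  The reported stress is Kruskal stress-1 in both flavours.
    """
    if (X is None) == (D is None):
        raise MultivariateError("pass exactly one of X (features) or D (distances)")
    if D is None:
        X = np.asarray(X, dtype=float)
        if len(X) < 3:
            raise MultivariateError("need >= 3 fingerprints")
        D = squareform(pdist(X, metric="euclidean"))
    D = np.asarray(D, dtype=float)

    if metric:
        n = len(D)
        J = np.eye(n) - np.full((n, n), 1.0 / n)
        B = -0.5 * J @ (D ** 2) @ J
        vals, vecs = np.linalg.eigh(B)
        top = np.argsort(vals)[::-1][:2]
        coords = vecs[:, top] * np.sqrt(np.clip(vals[top], 0.0, None))
        return MDSResult(coords=coords, stress=kruskal_stress1(D, coords),
                         metric=True)

    mds = MDS(n_components=2, metric_mds=False, metric="precomputed",
              n_init=n_init, max_iter=max_iter, eps=eps, init="random",
              random_state=seed, normalized_stress=True)
    coords = mds.fit_transform(D)
    return MDSResult(coords=coords, stress=float(mds.stress_), metric=False)


# --------------------------------------------------------------------------
# Discriminant analysis (group separation)
# --------------------------------------------------------------------------

@dataclass
class DiscriminantResult:
    statistic: float
    p_value: float
    pairwise_p: np.ndarray               # symmetric (g, g), NaN diagonal
    group_names: list[str]
    shrinkage: float
    n_permutations: int


def _separation_statistic(X: np.ndarray, codes: np.ndarray) -> tuple[float, float]:
    """trace(W_shrunk^-1 B): between-group scatter against shrunk within-covariance."""
    n, p = X.shape
    grand = X.mean(axis=0)
    B = np.zeros((p, p))
    within = []
    for g in np.unique(codes):
        Xg = X[codes == g]
        m = Xg.mean(axis=0)
        diff = (m - grand)[:, None]
        B += len(Xg) * diff @ diff.T
        within.append(Xg - m)
    W = np.vstack(within)
    cov, shrink = ledoit_wolf(W, assume_centered=True)
    stat = float(np.trace(np.linalg.solve(cov, B)) / n)
    return stat, float(shrink)


def discriminant_tests(X: np.ndarray, groups: Sequence,
                       n_permutations: int = 999,
                       seed: int = 0) -> DiscriminantResult:
    """Omnibus + pairwise group-separation tests on fingerprint replicates.

    The statistic is Wilks-flavoured (between-scatter weighted by the
    inverse of a Ledoit-Wolf-shrunk pooled within covariance); p-values are
    permutation p-values, so they stay calibrated when replicates are far
    fewer than receptors.  Pairwise p-values are reported uncorrected, as
    post hoc tests following a significant omnibus test.
    """
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    names = list(dict.fromkeys(groups.tolist()))
    codes = np.array([names.index(g) for g in groups])
    if len(names) < 2:
        raise MultivariateError("need >= 2 groups")
    for i, name in enumerate(names):
        if np.sum(codes == i) < 2:
            raise MultivariateError(f"group {name!r} has fewer than 2 replicates")

    rng = np.random.default_rng(seed)
    stat, shrink = _separation_statistic(X, codes)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        s, _ = _separation_statistic(X, perm)
        if s >= stat:
            count += 1
    p = (1 + count) / (1 + n_permutations)

    g = len(names)
    pairwise = np.full((g, g), np.nan)
    for i in range(g):
        for j in range(i + 1, g):
            mask = (codes == i) | (codes == j)
            Xij, cij = X[mask], codes[mask]
            sij, _ = _separation_statistic(Xij, cij)
            cnt = 0
            for _ in range(n_permutations):
                s, _ = _separation_statistic(Xij, rng.permutation(cij))
                if s >= sij:
                    cnt += 1
            pairwise[i, j] = pairwise[j, i] = (1 + cnt) / (1 + n_permutations)
    return DiscriminantResult(statistic=stat, p_value=float(p),
                              pairwise_p=pairwise, group_names=[str(n) for n in names],
                              shrinkage=shrink, n_permutations=n_permutations)
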