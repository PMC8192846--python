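"""Resampling-based consensus k-means clustering, cluster selection and PCA.

The consensus procedure follows the standard resampled-co-clustering recipe:
each of ``reps`` resamples draws ``floor(p_item * n)`` genes without
replacement (features are never subsampled), partitions them with Euclidean
k-means, and tallies (i) how often each gene pair was sampled together and
(ii) how often it co-clustered.  The consensus matrix is the elementwise
ratio; final assignments cut an average-linkage tree built on ``1 - M``.
The number of clusters is advised by the usual consensus-CDF delta-area
statistic but always remains an explicit choice of the caller.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .feature_table import GROUPS


class ClusteringError(ValueError):
    pass


def _seed_int(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2 ** 31))


def kmeans(X, k: int, seed: int = 0, n_restarts: int = 10
           ) -> tuple[np.ndarray, float]:
    """Euclidean k-means; best of ``n_restarts`` seeded Lloyd runs.

    Returns ``(labels, within-cluster sum of squares)``.  Deterministic
    given ``seed``; ``k`` may not exceed the number of rows.  Empty clusters
    are re-seeded from the farthest points (the library's relocation rule).
    """
    X = np.asarray(X, dtype=float)
    if k > X.shape[0]:
        raise ClusteringError(f"k={k} exceeds n={X.shape[0]} rows")
    if k < 1:
        raise ClusteringError("k must be >= 1")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed % (2 ** 31),
                algorithm="lloyd").fit(X)
    return km.labels_.copy(), float(km.inertia_)


@dataclass
class ConsensusRun:
    """Co-clustering and co-sampling tallies from one consensus run."""

    k: int
    reps: int
    p_item: float
    seed: int
    cooccur: np.ndarray    # gene x gene co-cluster counts (symmetric)
    cosample: np.ndarray   # gene x gene co-sample counts (symmetric)

    def consensus_matrix(self) -> np.ndarray:
        """M = cooccur / cosample, 0 where a pair was never co-sampled."""
        with np.errstate(invalid="ignore", divide="ignore"):
            M = np.where(self.cosample > 0, self.cooccur / np.maximum(self.cosample, 1), 0.0)
        return M

    def never_cosampled(self) -> np.ndarray:
        """Boolean mask of pairs with no co-sampling information."""
        return self.cosample == 0


def consensus_cluster(X, k: int, reps: int = 1000, p_item: float = 0.8,
                      seed: int = 0, n_restarts: int = 1) -> ConsensusRun:
    """Resampled consensus k-means (gene subsampling only, pFeature = 1)."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 0.0 < p_item <= 1.0:
        raise ClusteringError(f"p_item must be in (0, 1], got {p_item!r}")
    if k < 2:
        raise ClusteringError("k must be >= 2")
    m = int(np.floor(p_item * n))
    if m < k:
        raise ClusteringError(f"subsample size {m} smaller than k={k}")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    cooccur = np.zeros((n, n), dtype=np.int64)
    cosample = np.zeros((n, n), dtype=np.int64)
    for rep in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        labels, _ = kmeans(X[idx], k, seed=_seed_int(ss.spawn(1)[0]),
                           n_restarts=n_restarts)
        same = labels[:, None] == labels[None, :]
        cosample[np.ix_(idx, idx)] += 1
        cooccur[np.ix_(idx, idx)] += same
    return ConsensusRun(k=k, reps=reps, p_item=p_item, seed=seed,
                        cooccur=cooccur, cosample=cosample)


def final_clusters(M, k: int) -> np.ndarray:
    """Cut an average-linkage tree on dissimilarity ``1 - M`` at k clusters.

    Ties in merge order follow the linkage implementation's deterministic
    smallest-index rule.  Returns integer labels ``1..k``.
    """
    M = np.asarray(M, dtype=float)
    n = M.shape[0]
    if k > n:
        raise ClusteringError(f"k={k} exceeds n={n}")
    D = 1.0 - M
    np.fill_diagonal(D, 0.0)
    D = np.clip((D + D.T) / 2.0, 0.0, None)
    condensed = scipy.spatial.distance.squareform(D, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    return scipy.cluster.hierarchy.fcluster(Z, t=k, criterion="maxclust")


@dataclass
class ChooseKResult:
    runs: dict[int, ConsensusRun]
    areas: dict[int, float]
    deltas: dict[int, float]          # relative delta-area per k
    suggested_k: int
    cdf_grid: np.ndarray = field(default_factory=lambda: np.linspace(0, 1, 101))

    def cdf(self, k: int) -> np.ndarray:
        """Empirical CDF of off-diagonal consensus values, on ``cdf_grid``."""
        M = self.runs[k].consensus_matrix()
        vals = M[np.triu_indices_from(M, k=1)]
        return np.searchsorted(np.sort(vals), self.cdf_grid, side="right") / len(vals)


def _cdf_area(M: np.ndarray) -> float:
    vals = np.sort(M[np.triu_indices_from(M, k=1)])
    n = len(vals)
    if n == 0:
        return 0.0
    # area under the empirical CDF over [0, 1]
    ecdf = np.arange(1, n + 1) / n
    xs = np.concatenate([vals, [1.0]])
    widths = np.diff(np.concatenate([[vals[0]], xs[1:]]))
    return float(vals[0] * 0.0 + np.sum(ecdf * np.maximum(widths, 0.0)))


def choose_k(X, max_k: int = 9, reps: int = 100, p_item: float = 0.8,
             seed: int = 0, delta_floor: float = 0.1,
             n_restarts: int = 1) -> ChooseKResult:
    """Consensus runs for k = 2..max_k with the delta-area advisory.

    The suggestion is the largest k whose relative increase in the area
    under the consensus CDF exceeds ``delta_floor``; it is advisory only —
    the pipeline's k is explicit configuration.
    """
    if max_k < 2:
        raise ClusteringError("max_k must be >= 2")
    ss = np.random.SeedSequence(seed)
    runs: dict[int, ConsensusRun] = {}
    areas: dict[int, float] = {}
    for k in range(2, max_k + 1):
        run = consensus_cluster(X, k, reps=reps, p_item=p_item,
                                seed=_seed_int(ss.spawn(1)[0]),
                                n_restarts=n_restarts)
        runs[k] = run
        areas[k] = _cdf_area(run.consensus_matrix())
    deltas: dict[int, float] = {}
    for k in range(2, max_k + 1):
        if k == 2:
            deltas[k] = areas[k]
        else:
            prev = areas[k - 1]
            deltas[k] = (areas[k] - prev) / prev if prev > 0 else 0.0
    candidates = [k for k, d in deltas.items() if d >= delta_floor]
    suggested = max(candidates) if candidates else 2
    return ChooseKResult(runs=runs, areas=areas, deltas=deltas,
                         suggested_k=suggested)


@dataclass
class PCAResult:
    explained_variance_ratio: np.ndarray  # per-component variance fraction
    scores: np.ndarray                    # n_genes x n_components
    loadings: np.ndarray                  # n_features x n_components


def pca(X) -> PCAResult:
    """Principal components of the column-centered matrix (full SVD)."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ClusteringError("PCA needs at least two rows")
    model = PCA(svd_solver="full")
    scores = model.fit_transform(X)
    return PCAResult(
        explained_variance_ratio=model.explained_variance_ratio_.copy(),
        scores=scores,
        loadings=model.components_.T.copy(),
    )


def cluster_composition(assignment: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Fraction of each group's genes falling into each cluster.

    Rows are groups, columns clusters; every row sums to 1 (groups with no
    genes are omitted).
    """
    df = pd.DataFrame({"cluster": assignment, "group": groups.loc[assignment.index]})
    counts = df.groupby(["group", "cluster"], observed=True).size().unstack(fill_value=0)
    frac = counts.div(counts.sum(axis=1), axis=0)
    order = [g for g in GROUPS if g in frac.index] + [
        g for g in frac.index if g not in GROUPS]
    return frac.loc[order]
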