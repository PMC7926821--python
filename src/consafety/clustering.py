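"""K-means region ranking and the one-way ANOVA cluster-validity test.

Regions are grouped by Lloyd's algorithm on raw (unstandardized) feature
columns — either the absolute factors (accidents, deaths) or the relative
mortality rates.  Cluster labels are then severity-ordered so cluster 1 is
the most critical group.  Validity is checked feature-by-feature with a
one-way ANOVA across the final memberships: a large F statistic means the
clusters separate that feature well beyond its within-cluster spread.

The ANOVA here is descriptive (SPSS quick-cluster style): because the
memberships were *chosen* to separate the features, the nominal p-value is
not a hypothesis test of cluster existence, only a separation index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ClusterResult", "AnovaResult", "kmeans", "anova_validity",
           "rank_clusters", "cluster_panel"]


@dataclass
class ClusterResult:
    """Fitted k-means state.  ``labels`` are 1-based; after fitting they are
    relabelled so that cluster 1 has the largest centroid norm (the most
    critical group on raw severity features)."""

    labels: np.ndarray          # shape (n,), values 1..k
    centroids: np.ndarray       # shape (k, d)
    iterations: int
    within_ss: float
    converged: bool
    wss_history: list[float] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.centroids.shape[0]

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def _wss(X: np.ndarray, labels0: np.ndarray, centroids: np.ndarray) -> float:
    return float(((X - centroids[labels0]) ** 2).sum())


def _init_plusplus(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: first centre uniform, then D^2-weighted draws."""
    n = X.shape[0]
    centres = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(((X[:, None, :] - np.asarray(centres)[None]) ** 2).sum(-1), axis=1)
        total = d2.sum()
        if total == 0:
            centres.append(X[rng.integers(n)])
            continue
        centres.append(X[rng.choice(n, p=d2 / total)])
    return np.asarray(centres, dtype=float)


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int) -> tuple:
    n, k = X.shape[0], centroids.shape[0]
    labels0 = np.full(n, -1)
    history: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(-1)
        new_labels = d2.argmin(axis=1)
        # empty cluster: re-seed its centroid at the point farthest from its
        # current assignment centre, then reassign
        for c in range(k):
            if not (new_labels == c).any():
                far = ((X - centroids[new_labels]) ** 2).sum(-1).argmax()
                centroids[c] = X[far]
                d2 = ((X[:, None, :] - centroids[None]) ** 2).sum(-1)
                new_labels = d2.argmin(axis=1)
        history.append(_wss(X, new_labels, centroids))
        if (new_labels == labels0).all():
            converged = True
            break
        labels0 = new_labels
        centroids = np.array([X[labels0 == c].mean(axis=0) for c in range(k)])
        history.append(_wss(X, labels0, centroids))
    return labels0, centroids, it, history, converged


def kmeans(
    points: np.ndarray | Sequence[Sequence[float]],
    k: int,
    *,
    max_iter: int = 100,
    seed: int | None = None,
    restarts: int = 50,
) -> ClusterResult:
    """Best-of-``restarts`` Lloyd k-means with k-means++ seeding.

    Assignment uses squared Euclidean distance on the raw features;
    centroids are cluster means; a restart stops when assignments are
    stable.  The restart with the smallest within-cluster sum of squares
    wins, and its labels are relabelled in decreasing centroid-norm order.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")

    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(max(restarts, 1)):
        labels0, cents, iters, hist, conv = _lloyd(X, _init_plusplus(X, k, rng), max_iter)
        wss = _wss(X, labels0, cents)
        if best is None or wss < best.within_ss - 1e-12:
            best = ClusterResult(labels0 + 1, cents, iters, wss, conv, hist)
    assert best is not None
    return _relabel(best, order_by=np.linalg.norm(best.centroids, axis=1))


def _relabel(result: ClusterResult, order_by: np.ndarray) -> ClusterResult:
    """Relabel clusters in decreasing ``order_by``; ties go to the larger
    cluster (it receives the smaller, i.e. more critical, label)."""
    sizes = result.sizes()
    order = sorted(range(result.k), key=lambda c: (-order_by[c], -sizes[c]))
    mapping = {old: new + 1 for new, old in enumerate(order)}
    labels = np.array([mapping[l - 1] for l in result.labels])
    centroids = result.centroids[order]
    return ClusterResult(
        labels, centroids, result.iterations, result.within_ss,
        result.converged, result.wss_history,
    )


def rank_clusters(result: ClusterResult, feature: int | None = None) -> ClusterResult:
    """Severity-order the cluster labels.

    Clusters are relabelled in decreasing order of their centroid value on
    ``feature`` (a column index), or of the mean over all centroid
    coordinates when ``feature`` is None; cluster 1 is the most critical.
    Equal centroids tie-break by cluster size, larger first.
    """
    if feature is None:
        key = result.centroids.mean(axis=1)
    else:
        key = result.centroids[:, feature]
    return _relabel(result, order_by=key)


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA of a feature across cluster memberships."""

    between_ss: float
    within_ss: float
    df_between: int
    df_within: int
    f_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def between_ms(self) -> float:
        return self.between_ss / self.df_between

    @property
    def within_ms(self) -> float:
        return self.within_ss / self.df_within

    @property
    def critical_value(self) -> float:
        """Upper critical value of F(df_between, df_within) at ``alpha``."""
        return float(stats.f.ppf(1.0 - self.alpha, self.df_between, self.df_within))


def anova_validity(
    values: Sequence[float] | np.ndarray,
    memberships: Sequence[int] | np.ndarray,
    alpha: float = 0.05,
) -> AnovaResult:
    """Decompose one feature's variance across cluster memberships.

    between SS = sum_k n_k (mean_k - grand mean)^2; within SS = sum of
    squared deviations from cluster means; F = between MS / within MS with
    df (K-1, n-K) and an upper-tail F p-value.  Zero within-variance yields
    an infinite F with p = 0.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(memberships)
    if v.shape != g.shape:
        raise ValueError("values and memberships must have equal length")
    groups = np.unique(g)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty clusters")
    n = len(v)
    grand = v.mean()
    between = sum((g == c).sum() * (v[g == c].mean() - grand) ** 2 for c in groups)
    within = sum(((v[g == c] - v[g == c].mean()) ** 2).sum() for c in groups)
    dfb, dfw = len(groups) - 1, n - len(groups)
    if within == 0.0:
        return AnovaResult(float(between), 0.0, dfb, dfw, float("inf"), 0.0, alpha)
    f = (between / dfb) / (within / dfw)
    p = float(stats.f.sf(f, dfb, dfw))
    return AnovaResult(float(between), float(within), dfb, dfw, float(f), p, alpha)


def cluster_panel(
    panel: pd.DataFrame,
    features: Sequence[str],
    k: int = 3,
    *,
    seed: int | None = 0,
    restarts: int = 50,
) -> tuple[ClusterResult, pd.Series, dict[str, AnovaResult]]:
    """Cluster a province panel on the given feature columns.

    Returns the fit, a label Series indexed by region, and a per-feature
    ANOVA validity table on the final memberships.
    """
    X = panel[list(features)].to_numpy(dtype=float)
    result = kmeans(X, k, seed=seed, restarts=restarts)
    labels = pd.Series(result.labels, index=panel.index, name="cluster")
    anova = {f: anova_validity(panel[f].to_numpy(float), result.labels) for f in features}
    return result, labels, anova
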