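"""Clustering of the ellipse-interior cohort and the comparison battery.

Points inside the prediction ellipse are split into two groups by K-means
with the L1 (cityblock) distance — assignment by minimal L1 distance,
centroid update by the component-wise median (the L1-optimal center), best
of ``n_init`` random restarts. Cluster 1 is always the one with the lower
entropy centroid. The groups are then compared with Box's M test
(homogeneity of covariances), the two-sample Hotelling T-squared test
(bivariate means) and per-variable Mann-Whitney U tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, DomainError
from .population_stats import PredictionEllipse, contains, validate_cohort


def kmeans_l1(points: np.ndarray, k: int = 2,
              seed: int | np.random.Generator | None = None,
              n_init: int = 20, max_iter: int = 300
              ) -> tuple[np.ndarray, np.ndarray]:
    """L1-distance K-means with median centroid updates.

    Runs ``n_init`` restarts from random data points and keeps the partition
    with the lowest total L1 cost. The within-restart cost is non-increasing
    because both steps (assignment to the nearest-L1 centroid, component-wise
    median update) are coordinate-wise optimal. Clusters are relabelled so
    that cluster 0 has the smallest first-coordinate centroid.
    """
    X = np.asarray(points, dtype=float)
    n = len(X)
    if n < k:
        raise DegenerateInputError(f"need at least k={k} points, got {n}")
    rng = np.random.default_rng(seed)
    best_cost, best_labels, best_cent = np.inf, None, None
    for _ in range(n_init):
        cent = X[rng.choice(n, size=k, replace=False)]
        prev_cost = np.inf
        for _ in range(max_iter):
            D = np.abs(X[:, None, :] - cent[None, :, :]).sum(axis=-1)
            labels = D.argmin(axis=1)
            if len(np.unique(labels)) < k:  # empty cluster: reseed restart
                cent = X[rng.choice(n, size=k, replace=False)]
                prev_cost = np.inf
                continue
            cost = D[np.arange(n), labels].sum()
            assert cost <= prev_cost + 1e-9, "L1 cost increased"
            new_cent = np.array([np.median(X[labels == j], axis=0)
                                 for j in range(k)])
            if np.allclose(new_cent, cent):
                break
            cent, prev_cost = new_cent, cost
        D = np.abs(X[:, None, :] - cent[None, :, :]).sum(axis=-1)
        labels = D.argmin(axis=1)
        cost = D[np.arange(n), labels].sum()
        if cost < best_cost:
            best_cost, best_labels, best_cent = cost, labels.copy(), cent.copy()
    order = np.argsort(best_cent[:, 0])
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[best_labels], best_cent[order]


def box_m_test(X1: np.ndarray, X2: np.ndarray) -> tuple[float, float]:
    """Box's M test for equality of two covariance matrices.

    Returns the chi-square approximated statistic and its p-value with
    ``p (p + 1) / 2`` degrees of freedom (two groups).
    """
    X1, X2 = np.asarray(X1, float), np.asarray(X2, float)
    p = X1.shape[1]
    n1, n2 = len(X1), len(X2)
    if n1 <= p or n2 <= p:
        raise DegenerateInputError("each group needs more rows than columns")
    S1, S2 = np.cov(X1.T), np.cov(X2.T)
    if np.linalg.det(S1) <= 0 or np.linalg.det(S2) <= 0:
        raise DegenerateInputError("singular group covariance")
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    M = ((n1 + n2 - 2) * np.log(np.linalg.det(Sp))
         - (n1 - 1) * np.log(np.linalg.det(S1))
         - (n2 - 1) * np.log(np.linalg.det(S2)))
    c1 = ((2 * p ** 2 + 3 * p - 1) / (6.0 * (p + 1))
          * (1.0 / (n1 - 1) + 1.0 / (n2 - 1) - 1.0 / (n1 + n2 - 2)))
    chi = M * (1.0 - c1)
    df = p * (p + 1) / 2.0
    return float(chi), float(stats.chi2.sf(chi, df))


def hotelling_t2(X1: np.ndarray, X2: np.ndarray) -> tuple[float, float]:
    """Two-sample Hotelling T-squared with pooled covariance.

    The p-value comes from the exact F transform
    ``F = (n1 + n2 - p - 1) / (p (n1 + n2 - 2)) * T2`` with
    ``(p, n1 + n2 - p - 1)`` degrees of freedom.
    """
    X1, X2 = np.asarray(X1, float), np.asarray(X2, float)
    p = X1.shape[1]
    n1, n2 = len(X1), len(X2)
    if n1 + n2 - 2 <= p:
        raise DegenerateInputError("not enough observations for T-squared")
    S1 = np.atleast_2d(np.cov(X1.T))
    S2 = np.atleast_2d(np.cov(X2.T))
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    diff = X1.mean(axis=0) - X2.mean(axis=0)
    try:
        t2 = n1 * n2 / (n1 + n2) * diff @ np.linalg.solve(Sp, diff)
    except np.linalg.LinAlgError as exc:
        raise DegenerateInputError("singular pooled covariance") from exc
    fstat = (n1 + n2 - p - 1) / (p * (n1 + n2 - 2.0)) * t2
    pval = stats.f.sf(fstat, p, n1 + n2 - p - 1)
    return float(t2), float(pval)


def mann_whitney_u(x: np.ndarray, y: np.ndarray,
                   use_continuity: bool = True) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (midrank ties, normal approximation).

    Reports the U statistic of the first sample.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateInputError("both samples must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic",
                             use_continuity=use_continuity)
    return float(res.statistic), float(res.pvalue)


@dataclass
class ClusterComparison:
    """Two-cluster split of the ellipse-interior cohort with its test battery."""

    labels: np.ndarray                 # cluster index per interior point
    centroids: np.ndarray              # (2, 2) in the (ENT, DET-scaled) plane
    interior_index: np.ndarray         # row indices of interior points
    box_m: tuple[float, float]
    hotelling: tuple[float, float]
    u_tests: dict[str, tuple[float, float]]
    descriptives: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels.tolist(),
            "centroids": self.centroids.tolist(),
            "interior_index": self.interior_index.tolist(),
            "box_m": {"statistic": self.box_m[0], "p": self.box_m[1]},
            "hotelling": {"t2": self.hotelling[0], "p": self.hotelling[1]},
            "u_tests": {k: {"U": v[0], "p": v[1]}
                        for k, v in self.u_tests.items()},
            "descriptives": {f"{name}_{stat}": col.to_dict()
                             for (name, stat), col in
                             self.descriptives.items()},
        }


def compare_clusters(cohort: pd.DataFrame, ellipse: PredictionEllipse,
                     det_scale: float = 100.0,
                     seed: int | np.random.Generator | None = None,
                     n_init: int = 20) -> ClusterComparison:
    """Cluster the ellipse-interior cohort points and run the test battery.

    Clustering operates on (entropy, det_pct / det_scale) — the same
    coordinates the ellipse is fitted in. Points on the boundary count as
    interior.
    """
    df = validate_cohort(cohort).reset_index(drop=True)
    pts = np.column_stack([df["entropy"], df["det_pct"] / det_scale])
    inside = np.asarray(contains(ellipse, pts))
    if inside.sum() < 2:
        raise DegenerateInputError("fewer than 2 points inside the ellipse")
    interior_index = np.nonzero(inside)[0]
    Q = pts[inside]
    labels, centroids = kmeans_l1(Q, k=2, seed=seed, n_init=n_init)
    X1, X2 = Q[labels == 0], Q[labels == 1]
    sub = df.loc[interior_index]
    u_tests = {
        var: mann_whitney_u(sub[var].to_numpy()[labels == 0],
                            sub[var].to_numpy()[labels == 1])
        for var in ("age", "ess", "pct_change")
    }
    desc_rows = {}
    for j, name in enumerate(("cluster1", "cluster2")):
        grp = sub[labels == j]
        desc_rows[(name, "mean")] = grp.mean()
        desc_rows[(name, "sd")] = grp.std(ddof=1)
        desc_rows[(name, "n")] = pd.Series(
            {c: float((labels == j).sum()) for c in grp.columns})
    descriptives = pd.DataFrame(desc_rows)
    return ClusterComparison(
        labels=labels, centroids=centroids, interior_index=interior_index,
        box_m=box_m_test(X1, X2), hotelling=hotelling_t2(X1, X2),
        u_tests=u_tests, descriptives=descriptives)
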