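"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by a different route than the
implementation under test: average-linkage merges recomputed from the
raw matrix at every step, IRLS written out longhand, the chi-squared
statistic from the direct formula, quantiles by sort-and-interpolate,
and Blomberg's K by naive matrix algebra with an explicit inverse.
"""

from __future__ import annotations

import itertools

import numpy as np


def average_linkage_merges(dist: np.ndarray, labels: list[str]):
    """Brute-force UPGMA: each step recomputes every cluster-pair average
    from the original matrix; ties broken by smallest member label.

    Returns the merge heights (ascending merge order) and the final
    cluster (all labels).
    """
    n = dist.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(clusters, 2):
            avg = np.mean([dist[i, j] for i in a for j in b])
            key = (
                avg,
                *sorted(
                    (
                        min(labels[i] for i in a),
                        min(labels[j] for j in b),
                    )
                ),
            )
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, *_), a, b = best
        heights.append(avg)
        clusters = [c for c in clusters if c not in (a, b)] + [a | b]
    return heights, clusters[0]


def irls_glm(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    trials: np.ndarray | None = None,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> np.ndarray:
    """Iteratively reweighted least squares, written from the textbook
    updates (canonical links).  For binomial, ``y`` is the success count
    and ``trials`` the trial count per row."""
    n, p = X.shape
    beta = np.zeros(p)
    if family == "gaussian":
        return np.linalg.lstsq(X, y, rcond=None)[0]
    for _ in range(max_iter):
        eta = X @ beta
        if family == "binomial":
            mu = trials / (1.0 + np.exp(-eta))
            var = mu * (1.0 - mu / trials)
            dmu = var  # logit canonical: dmu/deta = m p (1-p)
        elif family == "poisson":
            mu = np.exp(eta)
            var = mu
            dmu = mu
        else:
            raise ValueError(family)
        var = np.clip(var, 1e-12, None)
        z = eta + (y - mu) / dmu
        w = dmu**2 / var
        WX = X * w[:, None]
        beta_new = np.linalg.solve(X.T @ WX, X.T @ (w * z))
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            break
        beta = beta_new
    return beta


def chi_sq_pearson(table: np.ndarray) -> float:
    """Sum of (O-E)^2/E, no continuity correction."""
    t = np.asarray(table, float)
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    e = row @ col / t.sum()
    return float(((t - e) ** 2 / e).sum())


def quantile_sorted(values, q: float) -> float:
    """Linear-interpolation quantile by hand: h = (n-1)q on the sorted
    sample, interpolate between floor(h) and ceil(h)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    h = (n - 1) * q
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def blomberg_k_naive(V: np.ndarray, x: np.ndarray) -> float:
    """Blomberg's K from the defining algebra with an explicit inverse."""
    n = len(x)
    Vinv = np.linalg.inv(V)
    ones = np.ones(n)
    a = (ones @ Vinv @ x) / (ones @ Vinv @ ones)
    dev = x - a
    ratio = (dev @ dev) / (dev @ Vinv @ dev)
    expected = (np.trace(V) - n / (ones @ Vinv @ ones)) / (n - 1)
    return float(ratio / expected)
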