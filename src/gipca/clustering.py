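"""Gaussian mixture clustering of pooled bootstrapped-mean clouds.

A two-component full-covariance Gaussian mixture is fitted by
expectation-maximization to the pooled clouds of the two groups, without
using the labels; points are then assigned to the component with maximal
posterior responsibility, and the unlabelled clusters are matched to the
true groups by optimal assignment before tabulating the confusion matrix.
Because the bootstrapped-mean clouds are genuinely near-Gaussian (means of
resampled participants), the mixture model is well specified for this data.

EM details: k-means++-style seeding of the component means, uniform initial
weights, pooled covariance as the initial covariance of every component; a
small eigenvalue floor regularizes the covariances (the clouds are tight
and can be near-degenerate); best of ``n_init`` seeded restarts by final
log-likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.optimize import linear_sum_assignment
from scipy.special import logsumexp


class ComponentCollapseError(RuntimeError):
    """A mixture component repeatedly collapsed onto too few points."""


@dataclass
class GMMModel:
    """Fitted Gaussian mixture: weights, means, covariances and the EM trace."""

    weights: np.ndarray          # (K,), sums to 1
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # (K, d, d)
    loglik_trace: np.ndarray     # per-iteration total log-likelihood
    converged: bool
    n_iter: int

    @property
    def K(self) -> int:
        return self.weights.shape[0]

    @property
    def d(self) -> int:
        return self.means.shape[1]

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at the rows of X, via Cholesky."""
    d = mean.shape[0]
    L = np.linalg.cholesky(cov)
    dev = solve_triangular(L, (X - mean).T, lower=True)
    maha = np.sum(dev ** 2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _floor_cov(cov: np.ndarray, floor: float) -> np.ndarray:
    """Clip covariance eigenvalues from below at ``floor``."""
    w, V = np.linalg.eigh(cov)
    if w[0] >= floor:
        return cov
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def _kmeanspp_means(X: np.ndarray, K: int, rng: np.random.Generator
                    ) -> np.ndarray:
    """k-means++ seeding: spread initial means over the data."""
    n = X.shape[0]
    means = [X[rng.integers(n)]]
    for _ in range(1, K):
        d2 = np.min(
            [np.sum((X - m) ** 2, axis=1) for m in means], axis=0)
        total = d2.sum()
        if total <= 0:
            means.append(X[rng.integers(n)])
            continue
        means.append(X[rng.choice(n, p=d2 / total)])
    return np.array(means)


def _em_once(
    X: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
    reg_floor: float,
    max_collapses: int = 5,
) -> GMMModel:
    n, d = X.shape
    means = _kmeanspp_means(X, K, rng)
    pooled = _floor_cov(np.atleast_2d(np.cov(X, rowvar=False)), reg_floor)
    covs = np.repeat(pooled[None], K, axis=0)
    weights = np.full(K, 1.0 / K)
    trace: list[float] = []
    collapses = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step
        log_r = np.stack(
            [np.log(weights[k]) + _log_gauss(X, means[k], covs[k])
             for k in range(K)], axis=1)
        log_norm = logsumexp(log_r, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_r - log_norm[:, None])
        # M-step
        nk = resp.sum(axis=0)
        bad = np.flatnonzero(nk < max(1e-10 * n, 1e-300))
        if bad.size:
            collapses += bad.size
            if collapses > max_collapses:
                raise ComponentCollapseError(
                    f"component(s) {bad.tolist()} collapsed {collapses} "
                    "times; data cannot support K components")
            warnings.warn(
                f"re-initializing collapsed component(s) {bad.tolist()}",
                RuntimeWarning, stacklevel=3)
            for k in bad:
                means[k] = X[rng.integers(n)]
                covs[k] = pooled
                weights = np.full(K, 1.0 / K)
            continue
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        new_covs = np.empty_like(covs)
        for k in range(K):
            dev = X - means[k]
            c = (resp[:, k, None] * dev).T @ dev / nk[k]
            new_covs[k] = _floor_cov(c, reg_floor)
        covs = new_covs
        if trace and ll - trace[-1] < tol * max(1.0, abs(ll)):
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
    return GMMModel(
        weights=weights, means=means, covariances=covs,
        loglik_trace=np.array(trace), converged=converged, n_iter=it)


def fit_gmm(
    points: np.ndarray,
    K: int = 2,
    seed: int | np.random.Generator = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_init: int = 10,
    reg_floor: float = 1e-8,
) -> GMMModel:
    """Fit a K-component full-covariance Gaussian mixture by EM.

    Keeps the best of ``n_init`` seeded initializations by final
    log-likelihood.  The log-likelihood trace of the returned model is
    non-decreasing (EM guarantee, up to the covariance floor).
    """
    X = np.atleast_2d(np.asarray(points, float))
    n, d = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if n <= K * d:
        raise ValueError(f"need more than K*d = {K * d} points, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    best: GMMModel | None = None
    for _ in range(n_init):
        model = _em_once(X, K, rng, tol, max_iter, reg_floor)
        if best is None or model.loglik > best.loglik:
            best = model
    assert best is not None
    return best


def classify(model: GMMModel, points: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and posterior responsibilities for an (m, d) array.

    Each point goes to the component with the largest posterior;
    responsibilities are the normalized weighted densities and sum to one
    per point.
    """
    X = np.atleast_2d(np.asarray(points, float))
    if X.shape[1] != model.d:
        raise ValueError(
            f"points have dimension {X.shape[1]}, model expects {model.d}")
    log_r = np.stack(
        [np.log(model.weights[k])
         + _log_gauss(X, model.means[k], model.covariances[k])
         for k in range(model.K)], axis=1)
    resp = np.exp(log_r - logsumexp(log_r, axis=1)[:, None])
    return np.argmax(resp, axis=1), resp


@dataclass
class ConfusionMatrix:
    """Row-normalized confusion table (percentages per true group).

    ``mapping`` records which raw cluster was matched to each group;
    ``percent[i, j]`` is the percentage of true group ``i`` predicted as
    group ``j`` after that alignment.
    """

    groups: tuple[str, ...]
    counts: np.ndarray
    percent: np.ndarray = field(init=False)
    mapping: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        totals = self.counts.sum(axis=1, keepdims=True)
        if (totals == 0).any():
            raise ValueError("every true group needs at least one point")
        self.percent = 100.0 * self.counts / totals

    @property
    def per_group_accuracy(self) -> dict[str, float]:
        return {g: float(self.percent[i, i])
                for i, g in enumerate(self.groups)}

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.percent,
            index=[f"true_{g}" for g in self.groups],
            columns=[f"pred_{g}" for g in self.groups],
        )


def align_and_confuse(true_groups: np.ndarray | list,
                      cluster_labels: np.ndarray | list) -> ConfusionMatrix:
    """Match unlabelled clusters to true groups and tabulate the confusion.

    The cluster -> group mapping maximizes total agreement (optimal
    assignment over permutations), so a global swap of cluster indices
    leaves the matrix unchanged.  Requires no more clusters than groups.
    """
    true_groups = np.asarray(true_groups)
    cluster_labels = np.asarray(cluster_labels)
    if true_groups.shape != cluster_labels.shape:
        raise ValueError("label vectors must have the same length")
    groups = tuple(sorted(map(str, np.unique(true_groups))))
    clusters = np.unique(cluster_labels)
    if clusters.size > len(groups):
        raise ValueError(
            f"{clusters.size} clusters for {len(groups)} groups; "
            "over-clustering is out of scope")
    # contingency: rows true groups, cols raw clusters
    cont = np.zeros((len(groups), clusters.size))
    for i, g in enumerate(groups):
        for j, c in enumerate(clusters):
            cont[i, j] = np.sum((true_groups.astype(str) == g)
                                & (cluster_labels == c))
    rows, cols = linear_sum_assignment(cont, maximize=True)
    counts = np.zeros((len(groups), len(groups)))
    mapping = {int(clusters[j]): groups[i] for i, j in zip(rows, cols)}
    for i, g in enumerate(groups):
        mask = true_groups.astype(str) == g
        for c, target in mapping.items():
            j = groups.index(target)
            counts[i, j] = np.sum(mask & (cluster_labels == c))
    return ConfusionMatrix(groups=groups, counts=counts, mapping=mapping)
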