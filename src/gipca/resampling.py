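"""Bootstrap of group-mean PC scores, confidence ellipses and the Jaccard
overlap of two bootstrapped-mean clouds.

With only ~10 participants per group, the sampling distribution of a group's
mean score vector is estimated by the nonparametric bootstrap: resample the
participants with replacement, recompute the mean, repeat B times.  The
cloud of resampled means concentrates around the sample mean at rate
``1/sqrt(n)``, so its 95% confidence ellipse is much smaller than the
ellipse of the raw scores — this shrinkage is what separates the two group
clouds and enables unsupervised classification downstream.

The Jaccard coefficient quantifies cloud overlap.  It is defined for finite
sets, so the point clouds are discretised through ellipse membership: a
point of either cloud belongs to set A when it lies inside cloud A's
95% ellipse, and ``J = |in both| / |in at least one|``.  A Monte-Carlo
ellipse-*area* variant is available as an alternative rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2


@dataclass
class ConfidenceEllipse:
    """Gaussian confidence region: ``(x-c)' S^{-1} (x-c) <= chi2_df(level)``.

    ``shape`` is the covariance matrix of the cloud; the boundary is the
    corresponding Mahalanobis contour at the ``level`` quantile of the
    chi-square distribution with ``df = dim`` degrees of freedom.
    """

    center: np.ndarray
    shape: np.ndarray
    level: float = 0.95

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, float)
        self.shape = np.asarray(self.shape, float)
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        d = self.center.shape[0]
        if self.shape.shape != (d, d):
            raise ValueError("shape matrix does not match center dimension")
        rank = np.linalg.matrix_rank(self.shape)
        if rank < d:
            raise ValueError(
                f"singular cloud covariance (rank {rank} < {d}); "
                "the ellipse is degenerate")
        self._chi2 = float(chi2.ppf(self.level, df=d))
        self._inv = np.linalg.inv(self.shape)

    @property
    def radius2(self) -> float:
        """Squared Mahalanobis radius of the boundary."""
        return self._chi2

    def mahalanobis2(self, points: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(points, float)) - self.center
        return np.einsum("ij,jk,ik->i", x, self._inv, x)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for an (m, d) array (or a single point)."""
        return self.mahalanobis2(points) <= self._chi2

    @property
    def area(self) -> float:
        """Area (d=2) / volume of the ellipse."""
        import math

        d = self.center.shape[0]
        unit = math.pi ** (d / 2) / math.gamma(d / 2 + 1)  # unit-ball volume
        return float(unit * self._chi2 ** (d / 2)
                     * np.sqrt(np.linalg.det(self.shape)))


@dataclass
class BootstrapCloud:
    """B resampled mean score vectors for one group.

    ``sample_mean`` is the plain mean of the original scores (the statistic
    being bootstrapped); ``means`` holds the B resampled means and ``cov``
    their covariance.
    """

    group: str
    B: int
    means: np.ndarray
    sample_mean: np.ndarray
    cov: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, float)
        if self.B < 1 or self.means.shape[0] != self.B:
            raise ValueError("means must have B rows with B >= 1")
        self.cov = np.atleast_2d(np.cov(self.means, rowvar=False, ddof=1)) \
            if self.B > 1 else np.zeros((self.means.shape[1],) * 2)

    def ellipse(self, dims: tuple[int, int] = (0, 1),
                level: float = 0.95) -> ConfidenceEllipse:
        """Confidence ellipse of the cloud in a 2-D score subspace."""
        idx = list(dims)
        return ConfidenceEllipse(
            center=self.means[:, idx].mean(axis=0),
            shape=np.cov(self.means[:, idx], rowvar=False, ddof=1),
            level=level,
        )


def bootstrap_means(
    scores: np.ndarray,
    B: int = 10_000,
    seed: int | np.random.Generator = 0,
    group: str = "",
) -> BootstrapCloud:
    """Bootstrap the mean of an (n, k) score matrix.

    Each replicate draws n rows with replacement and stores their column
    mean; the resampling unit is the participant.  Deterministic given the
    seed (or caller-provided Generator).
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    if scores.ndim != 2:
        raise ValueError("scores must be a 2-D (n, k) array")
    n = scores.shape[0]
    if n < 2:
        raise ValueError(f"cannot bootstrap n={n} rows (singleton resampling "
                         "is degenerate)")
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = scores[idx].mean(axis=1)
    return BootstrapCloud(group=group, B=B, means=means,
                          sample_mean=scores.mean(axis=0))


def confidence_ellipse(points: np.ndarray,
                       level: float = 0.95) -> ConfidenceEllipse:
    """95% (by default) ellipse of an (m, d) point cloud: centred on the
    cloud mean with the cloud covariance as shape matrix."""
    points = np.asarray(points, float)
    if points.ndim != 2 or points.shape[0] < 3:
        raise ValueError("need an (m, d) cloud with m >= 3")
    return ConfidenceEllipse(
        center=points.mean(axis=0),
        shape=np.cov(points, rowvar=False, ddof=1),
        level=level,
    )


def jaccard_overlap(
    cloud_a: np.ndarray,
    cloud_b: np.ndarray,
    level: float = 0.95,
    method: str = "membership",
    n_mc: int = 200_000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Jaccard similarity of two point clouds via their ``level`` ellipses.

    ``membership`` (default): every point of the union counts as an element;
    it is "in A" when inside cloud A's ellipse, and
    ``J = |in both| / |in either|``.  ``area_mc`` instead estimates the
    ratio of the intersection to the union *areas* of the two ellipses by
    Monte-Carlo over their joint bounding box.
    """
    a = np.asarray(cloud_a, float)
    b = np.asarray(cloud_b, float)
    ell_a = confidence_ellipse(a, level)
    ell_b = confidence_ellipse(b, level)
    if method == "membership":
        pts = np.vstack([a, b])
        in_a = ell_a.contains(pts)
        in_b = ell_b.contains(pts)
        union = int(np.sum(in_a | in_b))
        if union == 0:
            warnings.warn("no points inside either ellipse; J defined as 0",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        return float(np.sum(in_a & in_b) / union)
    if method == "area_mc":
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        # bounding box covering both ellipses
        half_a = np.sqrt(np.diag(ell_a.shape) * ell_a.radius2)
        half_b = np.sqrt(np.diag(ell_b.shape) * ell_b.radius2)
        lo = np.minimum(ell_a.center - half_a, ell_b.center - half_b)
        hi = np.maximum(ell_a.center + half_a, ell_b.center + half_b)
        pts = rng.uniform(lo, hi, size=(n_mc, lo.size))
        in_a = ell_a.contains(pts)
        in_b = ell_b.contains(pts)
        union = int(np.sum(in_a | in_b))
        if union == 0:
            warnings.warn("no Monte-Carlo points inside either ellipse",
                          RuntimeWarning, stacklevel=2)
            return 0.0
        return float(np.sum(in_a & in_b) / union)
    raise ValueError(f"unknown Jaccard method {method!r}")
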