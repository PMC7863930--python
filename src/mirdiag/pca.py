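"""PCA views of the cohort with group confidence ellipses.

Principal components are fitted on the training cohort over a chosen
feature subset (all miRNAs, or the differentially expressed set) and
held-out validation samples are projected onto the trained axes — the
training centers, scales and loadings are frozen, never refit.  Group
scatter in the leading two components is summarized by confidence
ellipses based on the multivariate t distribution: the ellipse is the set
of points whose Mahalanobis distance from the group mean (in the sample
covariance metric) is below the radial quantile of a bivariate t law.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["PCAModel", "EllipseSpec", "fit_pca", "project", "confidence_ellipse"]


@dataclass
class PCAModel:
    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray            # components x features, orthonormal rows
    explained_variance_ratio: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def fit_pca(
    expression: pd.DataFrame,
    feature_subset: list[str] | None = None,
    scale_features: bool = True,
    n_components: int | None = None,
) -> PCAModel:
    """Fit principal components on the given samples.

    ``expression`` is features x samples; components are fitted over
    samples (columns).  Features are centered and, by default, scaled to
    unit variance (serum intensities span very different ranges).
    Zero-variance features are dropped with a warning when scaling.
    Loadings have a fixed sign: the largest-magnitude entry of each
    component is positive.
    """
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples to fit a PCA")
    ids = list(feature_subset) if feature_subset is not None else list(expression.index)
    if not ids:
        raise ValueError("feature subset is empty")
    X = expression.loc[ids].to_numpy().T  # samples x features
    center = X.mean(axis=0)
    if scale_features:
        scale = X.std(axis=0)
        dead = scale < 1e-12
        if dead.any():
            warnings.warn(f"dropping {int(dead.sum())} zero-variance features from the PCA")
            keep = ~dead
            ids = [f for f, k in zip(ids, keep) if k]
            X, center, scale = X[:, keep], center[keep], scale[keep]
    else:
        scale = np.ones(X.shape[1])
    Z = (X - center) / scale
    # thin SVD; components ordered by singular value
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    var = s**2 / (Z.shape[0] - 1)
    ratio = var / max(var.sum(), 1e-300)
    if n_components is not None:
        Vt, ratio = Vt[:n_components], ratio[:n_components]
    # sign convention: largest |loading| entry positive
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] = -Vt[i]
    return PCAModel(
        feature_ids=ids,
        center=center,
        scale=scale,
        loadings=Vt,
        explained_variance_ratio=ratio,
    )


def project(model: PCAModel, expression: pd.DataFrame, n_components: int = 2) -> pd.DataFrame:
    """Project samples onto trained components (no refitting).

    Missing model features are an error.  Returns a samples x components
    DataFrame with columns ``pc1, pc2, ...``.
    """
    missing = [f for f in model.feature_ids if f not in expression.index]
    if missing:
        raise ValueError(f"features missing from expression matrix: {missing[:5]}")
    X = expression.loc[model.feature_ids].to_numpy().T
    Z = (X - model.center) / model.scale
    k = min(n_components, model.n_components)
    scores = Z @ model.loadings[:k].T
    return pd.DataFrame(
        scores, index=expression.columns, columns=[f"pc{i+1}" for i in range(k)]
    )


@dataclass
class EllipseSpec:
    """A bivariate confidence ellipse: x on it satisfies
    (x - center)' shape^{-1} (x - center) = 1."""

    group: str
    center: np.ndarray
    shape: np.ndarray   # 2x2 symmetric positive definite (includes the radius)
    level: float
    df: int

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        if self.level <= 0:
            return np.all(pts == 0, axis=1)
        sol = np.linalg.solve(self.shape, pts.T)
        return np.einsum("ij,ji->i", pts, sol) <= 1.0

    def boundary(self, n_points: int = 200) -> np.ndarray:
        """Polyline on the ellipse boundary (for plotting)."""
        theta = np.linspace(0, 2 * np.pi, n_points)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        L = np.linalg.cholesky(self.shape + 1e-300 * np.eye(2))
        return (self.center[:, None] + L @ circle).T


def confidence_ellipse(
    points: np.ndarray,
    level: float = 0.95,
    group: str = "",
    df: int | None = None,
) -> EllipseSpec:
    """Confidence ellipse of one group's 2-D scores.

    Center is the sample mean and the shape matrix is the sample
    covariance scaled by the radial quantile of a bivariate t law with
    ``df`` degrees of freedom (default ``n - 1``): for the bivariate t,
    the squared Mahalanobis radius over 2 is F(2, df)-distributed, so the
    boundary uses ``r^2 = 2 * F^{-1}(level; 2, df)``.  ``level = 0``
    degenerates to the center point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    n = pts.shape[0]
    if n < 4:
        raise ValueError("need at least 4 points for a confidence ellipse")
    if not (0.0 <= level < 1.0):
        raise ValueError("level must lie in [0, 1)")
    nu = int(df) if df is not None else n - 1
    center = pts.mean(axis=0)
    cov = np.cov(pts.T)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("singular covariance: ellipse undefined")
    r2 = 2.0 * stats.f.ppf(level, 2, nu) if level > 0 else 0.0
    return EllipseSpec(group=group, center=center, shape=cov * r2, level=level, df=nu)
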