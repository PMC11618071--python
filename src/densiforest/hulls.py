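"""Interpolation vs extrapolation screening in PCA space.

Whether a prediction pixel lies inside the environmental envelope of the
training data is decided in principal-component space: the training
covariate matrix is standardized and decomposed, the top k components
(smallest k explaining more than ``var_threshold`` of the variance) are
retained, and a 2-D convex hull is built for each of the C(k, 2) bivariate
component pairs.  A pixel is projected with the training centering,
scaling and eigenvectors and scored by the fraction of hulls that contain
it (boundary counts as inside); pixels inside at least 95% of the hulls
are flagged as interpolation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = ["HullModel", "fit_hull_model", "classify_grid", "points_in_hull"]

_BOUNDARY_TOL = 1e-9


@dataclass
class HullModel:
    center: np.ndarray
    scale: np.ndarray
    eigenvectors: np.ndarray  # columns = components
    eigenvalues: np.ndarray
    k: int
    feature_names: list[str] = field(default_factory=list)
    # (i, j) -> (A, b) half-plane form: inside iff A @ p + b <= tol, plus vertices
    hulls: dict = field(default_factory=dict)

    @property
    def n_hulls(self) -> int:
        return len(self.hulls)

    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def project(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.center) / self.scale
        return Z @ self.eigenvectors[:, : self.k]


def fit_hull_model(
    X: np.ndarray,
    var_threshold: float = 0.90,
    feature_names: list[str] | None = None,
) -> HullModel:
    """PCA of the standardized training matrix plus bivariate convex hulls.

    Constant columns are dropped with a warning; k is the smallest number
    of leading components whose cumulative explained variance exceeds the
    threshold; one hull is built per component pair (k(k-1)/2 in total; a
    single retained component degenerates to its 1-D interval, stored as a
    flat 2-gon).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with at least 3 rows")
    if np.isnan(X).any():
        raise ValueError("training matrix contains missing values")
    names = list(feature_names) if feature_names else [f"f{i}" for i in range(X.shape[1])]
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = [n for n, k_ in zip(names, keep) if not k_]
        logger.warning("fit_hull_model: dropping constant columns %s", dropped)
        X = X[:, keep]
        names = [n for n, k_ in zip(names, keep) if k_]
        sd = sd[keep]
    center = X.mean(axis=0)
    Z = (X - center) / sd
    # eigendecomposition of the correlation structure via SVD
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigvals = s**2 / (X.shape[0] - 1)
    eigvecs = Vt.T
    ratio = eigvals / eigvals.sum()
    k = int(np.searchsorted(np.cumsum(ratio), 0.0 + var_threshold) + 1)
    k = min(k, len(eigvals))
    scores = Z @ eigvecs[:, :k]

    hulls: dict = {}
    if k == 1:
        lo, hi = scores[:, 0].min(), scores[:, 0].max()
        A = np.array([[1.0], [-1.0]])
        b = np.array([-hi, lo])
        hulls[(0, 0)] = (A, b, np.array([[lo], [hi]]))
    else:
        for i, j in itertools.combinations(range(k), 2):
            pts = scores[:, (i, j)]
            hull = ConvexHull(pts)
            # scipy equations: A @ p + b <= 0 inside
            A = hull.equations[:, :2]
            b = hull.equations[:, 2]
            hulls[(i, j)] = (A, b, pts[hull.vertices])
    return HullModel(
        center=center,
        scale=sd,
        eigenvectors=eigvecs,
        eigenvalues=eigvals,
        k=k,
        feature_names=names,
        hulls=hulls,
    )


def points_in_hull(A: np.ndarray, b: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Half-plane membership test; boundary points count as inside."""
    return (pts @ A.T + b <= _BOUNDARY_TOL).all(axis=1)


def classify_grid(
    model: HullModel,
    stack: RasterGrid,
    interp_threshold: float = 0.95,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Per-pixel hull-coverage fraction, interpolation mask and summary.

    Each non-masked pixel is projected with the training centering/scaling/
    eigenvectors and tested against every bivariate hull; the fraction of
    containing hulls is returned, the interpolation mask flags fractions at
    or above ``interp_threshold``, and the summary reports the share of
    non-masked pixels flagged as interpolation.
    """
    missing = [f for f in model.feature_names if f not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing features: {missing}")
    free = ~stack.mask
    X = np.column_stack([stack[f][free] for f in model.feature_names])
    scores = model.project(X)
    counts = np.zeros(len(X), dtype=int)
    for (i, j), (A, b, _) in model.hulls.items():
        pts = scores[:, (i,)] if i == j else scores[:, (i, j)]
        counts += points_in_hull(A, b, pts)
    frac = counts / model.n_hulls
    frac_map = np.full(stack.shape, np.nan)
    frac_map[free] = frac
    interp = frac_map >= interp_threshold
    summary = {
        "n_pixels": int(free.sum()),
        "interpolation_share": float(np.mean(frac >= interp_threshold)),
        "n_hulls": model.n_hulls,
        "k": model.k,
    }
    return frac_map, interp, summary
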