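"""Drivers of community wood density: screening, importance, partitioning.

Three stages: (1) predictor screening — hierarchical clustering removes
near-duplicate covariates (|r| > 0.95), then variables are dropped
iteratively until every variance inflation factor is below 5; (2)
spatially blocked bootstrap importance — each of 100 subsamples keeps one
observation per 0.25-degree grid cell, fits a random forest (held-out
permutation importance, the "decrease in accuracy" reading) and an OLS on
z-scored variables (standardized partial regression coefficients); (3)
model-based recursive partitioning of the response-on-disturbance
regression: nodes split on the covariate/threshold that most reduces the
two-child SSE, accepted only when a Bonferroni-adjusted F-test clears the
significance level and both children hold the minimum node size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

logger = logging.getLogger(__name__)

__all__ = [
    "vif_screen",
    "bootstrap_grid_subsample",
    "importance_bootstrap",
    "partition_disturbance",
    "PartitionNode",
    "render_partition_tree",
]


# ---------------------------------------------------------------------------
# variable screening
# ---------------------------------------------------------------------------

def _vif(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R^2_j) of predictor j regressed on the others."""
    n, p = X.shape
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    out = np.empty(p)
    for j in range(p):
        others = np.delete(Z, j, axis=1)
        A = np.column_stack([np.ones(n), others])
        coef, *_ = np.linalg.lstsq(A, Z[:, j], rcond=None)
        resid = Z[:, j] - A @ coef
        sst = float(np.sum(Z[:, j] ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst
        out[j] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return out


def vif_screen(
    predictors: pd.DataFrame,
    threshold: float = 5.0,
    cluster_r: float = 0.95,
) -> tuple[list[str], pd.Series]:
    """Two-stage multicollinearity screen.

    Complete-linkage hierarchical clustering on 1 - |r| first merges
    near-duplicate predictors (|r| > ``cluster_r``), keeping the first
    column of each cluster; then the highest-VIF predictor is dropped
    iteratively until all remaining VIFs are below ``threshold``.
    Returns the retained names and their final VIFs.
    """
    names = list(predictors.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 predictors")
    X = predictors.to_numpy(dtype=float)
    if len(X) <= len(names):
        raise ValueError("need more rows than predictors")

    # drop exactly constant columns up front (zero variance breaks correlations)
    sd = X.std(axis=0, ddof=1)
    for n_, s_ in zip(list(names), sd):
        if s_ == 0:
            logger.warning("vif_screen: dropping constant column %r", n_)
    names = [n_ for n_, s_ in zip(names, sd) if s_ > 0]
    X = predictors[names].to_numpy(dtype=float)

    corr = np.corrcoef(X, rowvar=False)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    clusters = fcluster(
        linkage(squareform(dist, checks=False), method="complete"),
        t=1.0 - cluster_r,
        criterion="distance",
    )
    kept: list[str] = []
    seen: set[int] = set()
    for n_, c in zip(names, clusters):
        if c in seen:
            logger.info("vif_screen: %r merged away at the clustering step", n_)
            continue
        seen.add(c)
        kept.append(n_)

    while len(kept) >= 2:
        vifs = _vif(predictors[kept].to_numpy(dtype=float))
        worst = int(np.argmax(vifs))
        if vifs[worst] < threshold:
            break
        logger.info("vif_screen: dropping %r (VIF %.2f)", kept[worst], vifs[worst])
        kept.pop(worst)
    vifs = _vif(predictors[kept].to_numpy(dtype=float)) if len(kept) >= 2 else np.array([1.0])
    return kept, pd.Series(vifs, index=kept, name="vif")


# ---------------------------------------------------------------------------
# spatially blocked bootstrap
# ---------------------------------------------------------------------------

def grid_cell_ids(lat: np.ndarray, lon: np.ndarray, cell_deg: float = 0.25) -> np.ndarray:
    """Integer id of the 0.25-degree cell containing each point."""
    row = np.floor((90.0 - np.asarray(lat)) / cell_deg).astype(np.int64)
    col = np.floor((np.asarray(lon) + 180.0) / cell_deg).astype(np.int64)
    return row * int(np.ceil(360.0 / cell_deg)) + col


def bootstrap_grid_subsample(
    cell_ids: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One uniformly chosen row index per occupied grid cell."""
    order = rng.permutation(len(cell_ids))
    chosen: dict[int, int] = {}
    for i in order:
        c = int(cell_ids[i])
        if c not in chosen:
            chosen[c] = int(i)
    return np.sort(np.fromiter(chosen.values(), dtype=int))


def importance_bootstrap(
    data: pd.DataFrame,
    predictors: list[str],
    response: str = "cwd",
    cell_col: str = "cell_id",
    n_boot: int = 100,
    seed: int = 0,
    rf_params: dict | None = None,
    holdout_fraction: float = 0.3,
    n_repeats: int = 3,
) -> dict[str, pd.DataFrame]:
    """Bootstrapped permutation importance and standardized coefficients.

    Per bootstrap: one row per occupied grid cell; a random forest is fit
    on a train split and scored by permutation importance (decrease in
    held-out R^2); an OLS on z-scored response and predictors yields
    standardized partial regression coefficients.  Means and sds over
    bootstraps are returned along with the top-1 count per predictor.
    Bootstraps with fewer than 10 rows per predictor are skipped.
    """
    rf_params = rf_params or {"n_estimators": 100, "min_samples_leaf": 3, "n_jobs": 1}
    cells = data[cell_col].to_numpy()
    imps, coefs = [], []
    n_skipped = 0
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(b,)))
        idx = bootstrap_grid_subsample(cells, rng)
        sub = data.iloc[idx]
        if len(sub) < 10 * len(predictors):
            n_skipped += 1
            continue
        X = sub[predictors].to_numpy(dtype=float)
        y = sub[response].to_numpy(dtype=float)
        n = len(y)
        cut = int(n * (1.0 - holdout_fraction))
        perm = rng.permutation(n)
        tr, te = perm[:cut], perm[cut:]
        rf = RandomForestRegressor(random_state=int(rng.integers(2**31)), **rf_params)
        rf.fit(X[tr], y[tr])
        pi = permutation_importance(
            rf, X[te], y[te], n_repeats=n_repeats,
            random_state=int(rng.integers(2**31)),
        )
        imps.append(pi.importances_mean)
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        A = np.column_stack([np.ones(n), Z])
        beta, *_ = np.linalg.lstsq(A, zy, rcond=None)
        coefs.append(beta[1:])
    if n_skipped:
        logger.info("importance_bootstrap: skipped %d undersized bootstraps", n_skipped)
    if not imps:
        raise ValueError("all bootstraps skipped: too few rows per predictor")
    imps_arr = np.asarray(imps)
    coefs_arr = np.asarray(coefs)
    top1 = np.bincount(np.argmax(imps_arr, axis=1), minlength=len(predictors))
    importance = pd.DataFrame(
        {
            "mean_importance": imps_arr.mean(axis=0),
            "sd_importance": imps_arr.std(axis=0, ddof=1),
            "top1_count": top1,
        },
        index=predictors,
    ).sort_values("mean_importance", ascending=False)
    coefficients = pd.DataFrame(
        {
            "mean_coef": coefs_arr.mean(axis=0),
            "sd_coef": coefs_arr.std(axis=0, ddof=1),
        },
        index=predictors,
    )
    return {"importance": importance, "coefficients": coefficients,
            "n_bootstraps": len(imps)}


# ---------------------------------------------------------------------------
# model-based recursive partitioning
# ---------------------------------------------------------------------------

@dataclass
class PartitionNode:
    """Node of the disturbance-slope partition tree."""

    n: int
    intercept: float
    slope: float | None
    depth: int = 0
    split_var: str | None = None
    split_threshold: float | None = None
    p_value: float | None = None  # Bonferroni-adjusted
    left: "PartitionNode | None" = None
    right: "PartitionNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def leaves(self) -> list["PartitionNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "intercept": self.intercept,
            "slope": self.slope,
        }
        if not self.is_leaf:
            d.update(
                split_var=self.split_var,
                split_threshold=self.split_threshold,
                p_value=self.p_value,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


def _fit_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float | None, float]:
    """(intercept, slope, SSE) of y ~ x; slope None when x is constant."""
    if np.ptp(x) == 0:
        mu = float(y.mean())
        return mu, None, float(np.sum((y - mu) ** 2))
    A = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(np.sum(resid**2))


def partition_disturbance(
    data: pd.DataFrame,
    disturbance_var: str,
    candidate_splits: list[str],
    response: str = "cwd",
    min_node: int | None = None,
    alpha: float = 0.01,
    n_thresholds: int = 9,
    max_depth: int = 4,
) -> PartitionNode:
    """Recursive partitioning of the response-on-disturbance regression.

    At each node the univariate model ``response ~ disturbance`` is fit;
    for every candidate covariate, split thresholds on an interior decile
    grid are scanned, children get separate regressions, and the best
    (covariate, threshold) pair minimizes the two-child SSE.  The split is
    accepted iff the F-test p-value, Bonferroni-multiplied by the number
    of candidates, is at most ``alpha`` and both children hold at least
    ``min_node`` rows (default max(500, 3% of n)).
    """
    if disturbance_var in candidate_splits:
        raise ValueError("disturbance variable cannot be a split candidate")
    df = data.dropna(subset=[response, disturbance_var] + candidate_splits)
    n_total = len(df)
    if min_node is None:
        min_node = max(500, int(0.03 * n_total))

    def build(sub: pd.DataFrame, depth: int) -> PartitionNode:
        y = sub[response].to_numpy(dtype=float)
        d = sub[disturbance_var].to_numpy(dtype=float)
        intercept, slope, sse_pooled = _fit_line(d, y)
        node = PartitionNode(n=len(sub), intercept=intercept, slope=slope, depth=depth)
        if slope is None:
            logger.warning("constant disturbance in a node of %d rows", len(sub))
            return node
        if len(sub) < 2 * min_node or depth >= max_depth:
            return node

        best = None  # (sse_split, var, threshold, mask)
        for var in candidate_splits:
            x = sub[var].to_numpy(dtype=float)
            qs = np.quantile(x, np.linspace(0.1, 0.9, n_thresholds))
            for t in np.unique(qs):
                mask = x <= t
                nl, nr = int(mask.sum()), int((~mask).sum())
                if nl < min_node or nr < min_node:
                    continue
                _, _, sse_l = _fit_line(d[mask], y[mask])
                _, _, sse_r = _fit_line(d[~mask], y[~mask])
                sse = sse_l + sse_r
                if best is None or sse < best[0]:
                    best = (sse, var, float(t), mask)
        if best is None:
            return node
        sse_split, var, threshold, mask = best
        n = len(sub)
        if sse_split <= 0:
            p_adj = 0.0
        else:
            F = ((sse_pooled - sse_split) / 2.0) / (sse_split / (n - 4))
            p_adj = min(1.0, float(stats.f.sf(F, 2, n - 4)) * len(candidate_splits))
        if p_adj > alpha:
            return node
        node.split_var = var
        node.split_threshold = threshold
        node.p_value = p_adj
        node.left = build(sub[mask], depth + 1)
        node.right = build(sub[~mask], depth + 1)
        return node

    return build(df, 0)


def render_partition_tree(node: PartitionNode, indent: str = "") -> str:
    """Plain-text rendering of the partition tree."""
    if node.is_leaf:
        slope = "undefined" if node.slope is None else f"{node.slope:+.4f}"
        return (
            f"{indent}leaf n={node.n}: intercept={node.intercept:.4f} "
            f"slope={slope}\n"
        )
    out = (
        f"{indent}split {node.split_var} <= {node.split_threshold:.3f} "
        f"(adj p={node.p_value:.2e}, n={node.n})\n"
    )
    out += render_partition_tree(node.left, indent + "  ")
    out += render_partition_tree(node.right, indent + "  ")
    return out
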