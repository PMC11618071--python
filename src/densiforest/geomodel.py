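"""Spatial-bootstrap random-forest ensemble mapping.

The mapping stage diagnoses residual spatial autocorrelation (Moran's I of
smooth-baseline residuals over distance bins), then trains an ensemble of
tree regressors, each on an independent buffer-thinned bootstrap subsample
in which every pair of training plots is more than ``min_dist_km`` apart.
Each member's hyperparameters are tuned by random search over a discrete
grid with k-fold cross-validated R^2.  The ensemble prediction per pixel
is the unweighted member mean, and its uncertainty the pixel-wise
coefficient of variation (population sd / mean).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator
from sklearn.ensemble import RandomForestRegressor

from ._seeds import split_rng, split_seed
from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "EARTH_RADIUS_KM",
    "haversine_km",
    "residual_correlogram",
    "buffer_subsample",
    "default_param_grid",
    "grid_search_member",
    "train_ensemble",
    "predict_ensemble",
    "EnsembleModel",
]

EARTH_RADIUS_KM = 6371.0


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance on a sphere of radius 6,371 km (vectorized)."""
    lat1, lon1, lat2, lon2 = map(np.radians, (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


# ---------------------------------------------------------------------------
# Moran's I correlogram of smooth-baseline residuals
# ---------------------------------------------------------------------------

def smooth_baseline_residuals(
    lat: np.ndarray,
    lon: np.ndarray,
    values: np.ndarray,
    covariates: np.ndarray | None = None,
    smoothing: float = 1.0,
) -> np.ndarray:
    """Residuals from a thin-plate-spline smoother on coordinates (+covariates).

    Stands in for any smooth additive baseline fit; inputs are standardized
    before fitting so the smoothing penalty acts isotropically.
    """
    X = np.column_stack([lat, lon] if covariates is None else [lat, lon, covariates])
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    fit = RBFInterpolator(X, values, kernel="thin_plate_spline", smoothing=smoothing)
    return values - fit(X)


def residual_correlogram(
    lat: np.ndarray,
    lon: np.ndarray,
    residuals: np.ndarray,
    bin_edges_km: np.ndarray | None = None,
) -> pd.DataFrame:
    """Binned Moran's I of residuals over great-circle distance classes.

    Per bin, I = (n / sum W) * (sum_ij w_ij z_i z_j) / (sum_i z_i^2) with
    w_ij = 1 iff the pair distance falls in the bin; the null expectation
    -1/(n-1) is reported alongside.  Bins without pairs come back as NaN.
    """
    z = np.asarray(residuals, dtype=float)
    n = z.size
    if n < 30:
        raise ValueError("need at least 30 points")
    if z.std() == 0:
        raise ValueError("zero-variance residuals")
    if bin_edges_km is None:
        bin_edges_km = np.linspace(0.0, 1000.0, 21)
    bin_edges_km = np.asarray(bin_edges_km, dtype=float)
    if not np.all(np.diff(bin_edges_km) > 0):
        raise ValueError("bin edges must increase")
    z = z - z.mean()
    denom = float(np.sum(z**2))
    D = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
    iu = np.triu_indices(n, k=1)
    d_pairs = D[iu]
    cross = (z[:, None] * z[None, :])[iu]
    rows = []
    for lo, hi in zip(bin_edges_km[:-1], bin_edges_km[1:]):
        sel = (d_pairs >= lo) & (d_pairs < hi)
        n_pairs = int(sel.sum())
        if n_pairs == 0:
            I = np.nan
        else:
            sum_w = 2.0 * n_pairs  # symmetric weights
            I = (n / sum_w) * (2.0 * float(cross[sel].sum())) / denom
        rows.append((lo, hi, n_pairs, I, -1.0 / (n - 1)))
    return pd.DataFrame(
        rows, columns=["bin_lo_km", "bin_hi_km", "n_pairs", "morans_i", "expected"]
    )


# ---------------------------------------------------------------------------
# buffer-zone bootstrap thinning
# ---------------------------------------------------------------------------

def buffer_subsample(
    lat: np.ndarray,
    lon: np.ndarray,
    min_dist_km: float = 50.0,
    target_n: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random-order greedy thinning to a minimum pairwise distance.

    Points are visited in random order; a point is accepted iff it is more
    than ``min_dist_km`` from every previously accepted point.  Stops at
    ``target_n`` accepted points or exhaustion (a short set is returned
    with a notice, not an error).
    """
    if min_dist_km <= 0:
        raise ValueError("min_dist_km must be positive")
    n = len(lat)
    order = np.arange(n) if rng is None else rng.permutation(n)
    acc_lat: list[float] = []
    acc_lon: list[float] = []
    accepted: list[int] = []
    for i in order:
        if accepted:
            d = haversine_km(
                np.asarray(acc_lat), np.asarray(acc_lon), lat[i], lon[i]
            )
            if np.min(d) <= min_dist_km:
                continue
        accepted.append(int(i))
        acc_lat.append(float(lat[i]))
        acc_lon.append(float(lon[i]))
        if target_n is not None and len(accepted) >= target_n:
            break
    if target_n is not None and len(accepted) < target_n:
        logger.info(
            "buffer_subsample: only %d of the requested %d points at >%g km",
            len(accepted), target_n, min_dist_km,
        )
    return np.asarray(accepted, dtype=int)


# ---------------------------------------------------------------------------
# per-member grid search
# ---------------------------------------------------------------------------

def default_param_grid() -> list[dict]:
    """240 discrete random-forest parameter combinations (5 x 4 x 4 x 3)."""
    grid = []
    for n_est, mf, md, ml in itertools.product(
        (40, 80, 120, 160, 200),
        (0.33, 0.5, 0.75, 1.0),
        (6, 10, 14, None),
        (1, 3, 5),
    ):
        grid.append(
            {
                "n_estimators": n_est,
                "max_features": mf,
                "max_depth": md,
                "min_samples_leaf": ml,
            }
        )
    return grid


def _cv_r2(
    X: np.ndarray,
    y: np.ndarray,
    params: dict,
    cv_folds: int,
    rng: np.random.Generator,
) -> float:
    """Mean out-of-fold R^2 = 1 - SSE/SST over random row folds."""
    n = len(y)
    idx = rng.permutation(n)
    folds = np.array_split(idx, cv_folds)
    scores = []
    for k in range(cv_folds):
        test = folds[k]
        train = np.concatenate([folds[j] for j in range(cv_folds) if j != k])
        model = RandomForestRegressor(
            random_state=int(rng.integers(2**31)), n_jobs=1, **params
        )
        model.fit(X[train], y[train])
        pred = model.predict(X[test])
        sst = float(np.sum((y[test] - y[test].mean()) ** 2))
        if sst == 0:
            continue
        scores.append(1.0 - float(np.sum((y[test] - pred) ** 2)) / sst)
    return float(np.mean(scores)) if scores else -np.inf


def grid_search_member(
    X: np.ndarray,
    y: np.ndarray,
    param_grid: list[dict] | None = None,
    n_draws: int = 48,
    cv_folds: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[RandomForestRegressor, dict, float]:
    """Random grid search: best of ``n_draws`` parameter sets by CV R^2.

    Draws without replacement from the discrete grid (all combinations if
    ``n_draws`` exceeds the grid size), scores each by ``cv_folds``-fold
    cross-validated R^2, refits the winner on the full subset.
    """
    if np.std(y) == 0:
        raise ValueError("degenerate response: zero variance")
    rng = rng or np.random.default_rng()
    grid = param_grid or default_param_grid()
    n_draws = min(n_draws, len(grid))
    chosen = [grid[i] for i in rng.choice(len(grid), size=n_draws, replace=False)]
    best, best_score = None, -np.inf
    for params in chosen:
        score = _cv_r2(X, y, params, cv_folds, rng)
        if score > best_score:
            best, best_score = params, score
    model = RandomForestRegressor(random_state=int(rng.integers(2**31)), n_jobs=1, **best)
    model.fit(X, y)
    return model, best, float(best_score)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------

@dataclass
class EnsembleModel:
    """Bag of independently trained members plus their subsample metadata."""

    members: list = field(default_factory=list)           # fitted regressors
    hyperparams: list = field(default_factory=list)
    subsample_indices: list = field(default_factory=list) # row indices per member
    cv_r2: list = field(default_factory=list)
    feature_names: list = field(default_factory=list)
    min_dist_km: float = 50.0
    seed: int | None = None

    @property
    def n_members(self) -> int:
        return len(self.members)

    def mean_cv_r2(self) -> float:
        return float(np.mean(self.cv_r2))


def train_ensemble(
    table: pd.DataFrame,
    feature_names: list[str],
    response: str = "cwd",
    n_members: int = 200,
    min_dist_km: float = 50.0,
    subsample_target: int = 2000,
    n_draws: int = 48,
    cv_folds: int = 10,
    param_grid: list[dict] | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Buffer-zone bootstrap ensemble of tuned random-forest members.

    Rows with any missing feature or response are dropped (logged).  Each
    member is trained on an independent random-order buffer subsample and
    tuned by its own random grid search; everything is reproducible from
    ``seed``.
    """
    cols = feature_names + [response, "lat", "lon"]
    df = table[cols].dropna()
    n_dropped = len(table) - len(df)
    if n_dropped:
        logger.info("train_ensemble: dropped %d rows with missing values", n_dropped)
    lat = df["lat"].to_numpy()
    lon = df["lon"].to_numpy()
    X = df[feature_names].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)

    model = EnsembleModel(
        feature_names=list(feature_names), min_dist_km=min_dist_km, seed=seed
    )
    for m in range(n_members):
        rng = split_rng(seed, "ensemble", m)
        idx = buffer_subsample(lat, lon, min_dist_km, subsample_target, rng)
        if len(idx) < 10 * cv_folds:
            raise ValueError(
                f"member {m}: only {len(idx)} points after thinning; "
                "not enough for cross-validation"
            )
        reg, params, score = grid_search_member(
            X[idx], y[idx], param_grid, n_draws, cv_folds, rng
        )
        model.members.append(reg)
        model.hyperparams.append(params)
        model.subsample_indices.append(df.index.to_numpy()[idx])
        model.cv_r2.append(score)
    return model


def predict_ensemble(
    model: EnsembleModel, stack: RasterGrid
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel-wise ensemble mean and coefficient of variation (sd/mean).

    Uses the population (n) standard deviation for determinism at small
    member counts; pixels with non-positive mean have undefined CV and are
    returned as NaN (counted in the log).  Masked pixels propagate NaN.
    """
    missing = [f for f in model.feature_names if f not in stack.layers]
    if missing:
        raise ValueError(f"stack is missing features: {missing}")
    free = ~stack.mask
    Xpix = np.column_stack([stack[f][free] for f in model.feature_names])
    preds = np.stack([m.predict(Xpix) for m in model.members])
    mean = preds.mean(axis=0)
    sd = preds.std(axis=0)  # population sd
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / mean, np.nan)
    n_undef = int(np.sum(~(mean > 0)))
    if n_undef:
        logger.info("predict_ensemble: CV undefined at %d pixels (mean <= 0)", n_undef)
    mean_map = np.full(stack.shape, np.nan)
    cv_map = np.full(stack.shape, np.nan)
    mean_map[free] = mean
    cv_map[free] = cv
    return mean_map, cv_map
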