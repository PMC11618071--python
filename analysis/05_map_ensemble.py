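#!/usr/bin/env python
"""Spatial autocorrelation diagnosis and buffer-bootstrap ensemble mapping.

First diagnoses residual spatial autocorrelation (Moran's I of smooth-
baseline residuals over 0-1,000 km bins), then trains a 20-member
random-forest ensemble, each member on an independent >50 km buffer
subsample with its own random grid search, and writes the ensemble mean
and coefficient-of-variation maps.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from densiforest import geomodel
from densiforest.pipeline import FEATURES, _join_covariates
from densiforest.raster import RasterGrid, write_ascii_grid

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    landscape = RasterGrid.read_dir(OUT / "world" / "landscape")
    pixels = pd.read_csv(OUT / "pixels.tsv", sep="\t", float_precision="round_trip")
    joined = _join_covariates(pixels, landscape).dropna()

    lat = joined["lat"].to_numpy()
    lon = joined["lon"].to_numpy()
    resid = geomodel.smooth_baseline_residuals(
        lat, lon, joined["cwd"].to_numpy(),
        covariates=joined[FEATURES].to_numpy(),
    )
    corr = geomodel.residual_correlogram(
        lat, lon, resid, np.linspace(0.0, 1000.0, 11)
    )
    corr.to_csv(OUT / "residual_correlogram.tsv", sep="\t", index=False)
    first = corr.dropna().iloc[0]
    print(f"Moran's I in the {first['bin_lo_km']:.0f}-{first['bin_hi_km']:.0f} km "
          f"bin: {first['morans_i']:.3f} (null {first['expected']:.4f}; the "
          "synthetic world carries no residual autocorrelation beyond its "
          "covariates, so I stays near the null — the buffer bootstrap is "
          "exercised regardless)")

    model = geomodel.train_ensemble(
        joined, FEATURES, n_members=20, subsample_target=2000,
        n_draws=8, cv_folds=5, seed=SEED,
    )
    print(f"20-member ensemble, mean cross-validated R^2 = "
          f"{model.mean_cv_r2():.2f}")

    mean_map, cv_map = geomodel.predict_ensemble(model, landscape)
    grid = RasterGrid(
        west=landscape.west, north=landscape.north, cellsize=landscape.cellsize,
        layers={"cwd_mean": np.nan_to_num(mean_map, nan=0.0),
                "cwd_cv": np.nan_to_num(cv_map, nan=0.0)},
        mask=~np.isfinite(mean_map),
    )
    write_ascii_grid(OUT / "cwd_mean.asc", grid, "cwd_mean")
    write_ascii_grid(OUT / "cwd_cv.asc", grid, "cwd_cv")
    cv = cv_map[np.isfinite(cv_map)]
    print(f"pixel CV below 5% on {np.mean(cv < 0.05):.1%} of mapped pixels")


if __name__ == "__main__":
    main()
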