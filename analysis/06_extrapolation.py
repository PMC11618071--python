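#!/usr/bin/env python
"""Interpolation vs extrapolation screening of the mapped landscape.

Fits the PCA bivariate convex-hull model on the training pixels (top
components explaining >90% of covariate variance) and classifies every
landscape pixel by the fraction of hulls containing it.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from densiforest.hulls import classify_grid, fit_hull_model
from densiforest.pipeline import FEATURES, _join_covariates
from densiforest.raster import RasterGrid, write_ascii_grid

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    landscape = RasterGrid.read_dir(OUT / "world" / "landscape")
    pixels = pd.read_csv(OUT / "pixels.tsv", sep="\t", float_precision="round_trip")
    joined = _join_covariates(pixels, landscape).dropna()

    model = fit_hull_model(joined[FEATURES].to_numpy(), 0.90, FEATURES)
    frac_map, interp, summary = classify_grid(model, landscape)
    print(f"{model.k} components retained -> {model.n_hulls} bivariate hulls")
    print(f"{summary['interpolation_share']:.1%} of landscape pixels fall "
          "inside >= 95% of the training hulls (interpolation)")

    grid = RasterGrid(
        west=landscape.west, north=landscape.north, cellsize=landscape.cellsize,
        layers={"hull_fraction": np.nan_to_num(frac_map, nan=0.0)},
        mask=~np.isfinite(frac_map),
    )
    write_ascii_grid(OUT / "hull_fraction.asc", grid, "hull_fraction")
    (OUT / "hull_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
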