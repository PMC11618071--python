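"""Plot- and pixel-level community wood density metrics.

The central quantity is the community-weighted wood density (CWD) of a
forest inventory plot: the mean wood density of its trees weighted by
basal area,

    CWD = sum(WD_tree * B_tree) / sum(B_tree),    B_tree = pi * (DBH/2)^2.

Plots pass through the standard inventory filters before CWD is computed:
only the latest census per plot is kept, each tree is matched to a species
(or, failing that, genus) mean density, and plots where fewer than 75% of
individuals can be matched are excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .traitdb import TraitTable
from .raster import RasterGrid

logger = logging.getLogger(__name__)

__all__ = [
    "PlotCensus",
    "CommunityRecord",
    "filter_latest_census",
    "assign_wood_density",
    "coverage_filter",
    "compute_cwd",
    "richness_scaled",
    "community_table",
    "aggregate_to_pixels",
    "biome_summary",
    "temporal_variance_decomposition",
    "read_plots_tsv",
    "write_plots_tsv",
]

MIN_DBH_CM = 5.0


@dataclass
class PlotCensus:
    """One census of one inventory plot: location, area, year and trees."""

    plot_id: str
    lat: float
    lon: float
    area_m2: float
    year: int
    trees: list[tuple[str, float]]  # (species binomial or genus token, dbh cm)

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat <= 90.0):
            raise ValueError(f"latitude out of range: {self.lat}")
        if self.area_m2 <= 0:
            raise ValueError("plot area must be positive")
        bad = [t for t in self.trees if t[1] <= MIN_DBH_CM]
        if bad:
            raise ValueError(
                f"plot {self.plot_id}: {len(bad)} trees at or below the "
                f"{MIN_DBH_CM} cm DBH threshold"
            )

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class CommunityRecord:
    """Plot-level summary produced by :func:`compute_cwd`."""

    plot_id: str
    lat: float
    lon: float
    year: int
    cwd: float
    angiosperm_ratio: float
    richness_scaled: float
    mean_dbh: float
    coverage_fraction: float
    n_trees: int


# ---------------------------------------------------------------------------
# census filters
# ---------------------------------------------------------------------------

def filter_latest_census(censuses: Iterable[PlotCensus]) -> list[PlotCensus]:
    """Keep one census per plot: the latest year, ties to the larger count."""
    best: dict[str, PlotCensus] = {}
    for c in censuses:
        cur = best.get(c.plot_id)
        if cur is None or (c.year, c.n_trees) > (cur.year, cur.n_trees):
            if cur is not None and c.year == cur.year:
                logger.info(
                    "plot %s: tied census year %s, keeping the %d-tree census",
                    c.plot_id, c.year, c.n_trees,
                )
            best[c.plot_id] = c
    return list(best.values())


def assign_wood_density(
    tree: tuple[str, float], trait_table: TraitTable
) -> tuple[float | None, str]:
    """Wood density for one tree: species match first, then genus mean.

    Returns ``(density, level)`` with level in {"species", "genus", "none"};
    an unmatched tree is data (level "none"), not an error.
    """
    name = tree[0]
    if name in trait_table.species_mean:
        return trait_table.species_mean[name], "species"
    genus = name.split()[0]
    if genus in trait_table.genus_mean:
        return trait_table.genus_mean[genus], "genus"
    return None, "none"


def coverage_filter(
    census: PlotCensus, trait_table: TraitTable, threshold: float = 0.75
) -> tuple[bool, float]:
    """(keep, coverage): drop iff strictly fewer than 75% of trees match."""
    if census.n_trees == 0:
        logger.info("plot %s: empty census dropped", census.plot_id)
        return False, 0.0
    matched = sum(
        1 for t in census.trees if assign_wood_density(t, trait_table)[0] is not None
    )
    coverage = matched / census.n_trees
    return coverage >= threshold, coverage


# ---------------------------------------------------------------------------
# CWD and plot metrics
# ---------------------------------------------------------------------------

def compute_cwd(
    census: PlotCensus,
    trait_table: TraitTable,
    reference_area_m2: float = 25.0,
    z: float = 0.25,
) -> CommunityRecord:
    """Basal-area-weighted community wood density over matched trees.

    Weights are renormalized over the matched trees only; the >= 75%
    coverage guarantee bounds the induced error.  The angiosperm ratio is
    the proportion of matched individuals whose taxon is an angiosperm.
    """
    densities, weights, clades, dbhs = [], [], [], []
    matched = 0
    for name, dbh in census.trees:
        wd, level = assign_wood_density((name, dbh), trait_table)
        if wd is None:
            continue
        matched += 1
        ba = math.pi * (dbh / 2.0) ** 2
        densities.append(wd)
        weights.append(ba)
        dbhs.append(dbh)
        key = name if level == "species" else name.split()[0]
        clades.append(trait_table.clade.get(key, "unknown"))
    total_ba = float(np.sum(weights))
    if total_ba <= 0:
        raise ValueError(f"plot {census.plot_id}: zero total basal area")
    cwd = float(np.dot(densities, weights) / total_ba)
    n_angio = sum(1 for c in clades if c == "angiosperm")
    species = {name for name, _ in census.trees}
    return CommunityRecord(
        plot_id=census.plot_id,
        lat=census.lat,
        lon=census.lon,
        year=census.year,
        cwd=cwd,
        angiosperm_ratio=n_angio / matched,
        richness_scaled=richness_scaled(
            len(species), census.area_m2, reference_area_m2, z
        ),
        mean_dbh=float(np.mean(dbhs)),
        coverage_fraction=matched / census.n_trees,
        n_trees=census.n_trees,
    )


def richness_scaled(
    s_obs: int, area_m2: float, reference_area_m2: float = 25.0, z: float = 0.25
) -> float:
    """Observed richness rescaled to a reference plot area.

    Arrhenius species-area scaling S_ref = S_obs * (A_ref / A)^z; z = 0
    returns the raw count.
    """
    if area_m2 <= 0:
        raise ValueError("plot area must be positive")
    return float(s_obs) * (reference_area_m2 / area_m2) ** z


def community_table(
    censuses: Iterable[PlotCensus],
    trait_table: TraitTable,
    threshold: float = 0.75,
    latest_only: bool = True,
) -> pd.DataFrame:
    """End-to-end: filters + CWD for a batch of censuses, as a DataFrame."""
    cs = filter_latest_census(censuses) if latest_only else list(censuses)
    rows = []
    n_dropped = 0
    for c in cs:
        keep, cov = coverage_filter(c, trait_table, threshold)
        if not keep:
            n_dropped += 1
            continue
        rows.append(compute_cwd(c, trait_table).__dict__)
    if n_dropped:
        logger.info("coverage filter dropped %d of %d plots", n_dropped, len(cs))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pixel aggregation and biome summaries
# ---------------------------------------------------------------------------

def aggregate_to_pixels(
    records: pd.DataFrame, resolution_deg: float = 30.0 / 3600.0
) -> pd.DataFrame:
    """Mean of plot values within each half-open lon/lat pixel.

    Pixel index: col = floor((lon + 180)/res), row = floor((90 - lat)/res),
    north-up with the origin at the top-left; a point on a cell edge belongs
    to the cell whose half-open interval [edge, edge + res) contains it.
    """
    df = records.copy()
    df["pix_col"] = np.floor((df["lon"] + 180.0) / resolution_deg).astype(int)
    df["pix_row"] = np.floor((90.0 - df["lat"]) / resolution_deg).astype(int)
    value_cols = [
        c
        for c in ("cwd", "angiosperm_ratio", "richness_scaled", "mean_dbh")
        if c in df.columns
    ]
    agg = {c: "mean" for c in value_cols}
    agg["plot_id"] = "count"
    agg["lat"] = "mean"
    agg["lon"] = "mean"
    out = (
        df.groupby(["pix_row", "pix_col"], as_index=False)
        .agg(agg)
        .rename(columns={"plot_id": "n_plots"})
    )
    return out


def biome_summary(
    pixel_records: pd.DataFrame,
    biome: RasterGrid,
    grouping: Mapping[int, str] | None = None,
    biome_layer: str = "biome",
) -> pd.DataFrame:
    """Per-biome and per-forest-type mean +/- sd of pixel CWD.

    ``grouping`` maps biome codes to broad forest types (tropical,
    temperate, boreal, dryland); unclassified pixels are excluded and
    counted.
    """
    codes = biome.sample(
        biome_layer, pixel_records["lat"].to_numpy(), pixel_records["lon"].to_numpy()
    )
    ok = np.isfinite(codes)
    n_excluded = int((~ok).sum())
    if n_excluded:
        logger.info("biome_summary: %d records on unclassified pixels excluded", n_excluded)
    df = pixel_records.loc[ok].copy()
    df["biome_code"] = codes[ok].astype(int)
    if grouping is None:
        grouping = DEFAULT_FOREST_TYPE_GROUPING
    df["forest_type"] = df["biome_code"].map(dict(grouping))

    def _summary(g: pd.DataFrame) -> pd.Series:
        return pd.Series(
            {
                "mean_cwd": g["cwd"].mean(),
                "sd_cwd": g["cwd"].std(ddof=1),
                "n": len(g),
            }
        )

    by_biome = df.groupby("biome_code").apply(_summary, include_groups=False).reset_index()
    by_biome["level"] = "biome"
    by_biome = by_biome.rename(columns={"biome_code": "group"})
    by_type = df.groupby("forest_type").apply(_summary, include_groups=False).reset_index()
    by_type["level"] = "forest_type"
    by_type = by_type.rename(columns={"forest_type": "group"})
    out = pd.concat([by_biome, by_type], ignore_index=True)
    out.attrs["n_excluded"] = n_excluded
    return out


# WWF-style 14-biome codes grouped into the four broad forest categories
# (6 tropical, 4 temperate, 2 boreal, 2 dryland).
DEFAULT_FOREST_TYPE_GROUPING: dict[int, str] = {
    1: "tropical",   # tropical/subtropical moist broadleaf
    2: "tropical",   # tropical/subtropical dry broadleaf
    3: "tropical",   # tropical/subtropical coniferous
    7: "tropical",   # tropical/subtropical grassland, savanna, shrubland
    9: "tropical",   # flooded grassland and savanna
    14: "tropical",  # mangroves
    4: "temperate",  # temperate broadleaf and mixed
    5: "temperate",  # temperate conifer
    8: "temperate",  # temperate grassland, savanna, shrubland
    10: "temperate", # montane grassland and shrubland
    6: "boreal",     # boreal forest / taiga
    11: "boreal",    # tundra
    12: "dryland",   # Mediterranean forest, woodland, scrub
    13: "dryland",   # desert and xeric shrubland
}


# ---------------------------------------------------------------------------
# temporal variance decomposition
# ---------------------------------------------------------------------------

def temporal_variance_decomposition(records: pd.DataFrame) -> dict[str, float]:
    """Crossed plot x year variance components of CWD, as fractions.

    Two-way random-effects ANOVA (method of moments on mean squares, one
    observation per plot-year cell, negative estimates truncated to 0):
    y_ij = mu + plot_i + year_j + e_ij.  Requires columns ``plot_id``,
    ``year``, ``cwd``.
    """
    df = records[["plot_id", "year", "cwd"]].dropna()
    plots = df["plot_id"].unique()
    years = df["year"].unique()
    if len(plots) < 2:
        logger.warning("temporal decomposition with a single plot: plot component 0")
    if len(years) < 2:
        return {"plot": 1.0 if len(plots) > 1 else 0.0, "year": 0.0, "residual": 0.0}

    y = df["cwd"].to_numpy(dtype=float)
    grand = y.mean()
    n = len(df)
    a, b = len(plots), len(years)
    plot_means = df.groupby("plot_id")["cwd"].mean()
    year_means = df.groupby("year")["cwd"].mean()
    n_per_plot = df.groupby("plot_id").size()
    n_per_year = df.groupby("year").size()

    ss_plot = float((n_per_plot * (plot_means - grand) ** 2).sum())
    ss_year = float((n_per_year * (year_means - grand) ** 2).sum())
    ss_tot = float(((y - grand) ** 2).sum())
    ss_res = max(0.0, ss_tot - ss_plot - ss_year)
    df_plot, df_year = a - 1, b - 1
    df_res = max(1, n - a - b + 1)
    ms_plot = ss_plot / max(1, df_plot)
    ms_year = ss_year / max(1, df_year)
    ms_res = ss_res / df_res
    # average replication per level (balanced: b and a respectively)
    k_plot = (n - (n_per_plot**2).sum() / n) / max(1, df_plot)
    k_year = (n - (n_per_year**2).sum() / n) / max(1, df_year)
    var_plot = max(0.0, (ms_plot - ms_res) / k_plot) if a > 1 else 0.0
    var_year = max(0.0, (ms_year - ms_res) / k_year) if b > 1 else 0.0
    var_res = max(0.0, ms_res)
    total = var_plot + var_year + var_res
    if total == 0:
        return {"plot": 0.0, "year": 0.0, "residual": 0.0}
    return {
        "plot": var_plot / total,
        "year": var_year / total,
        "residual": var_res / total,
    }


# ---------------------------------------------------------------------------
# TSV I/O (long format: one row per tree)
# ---------------------------------------------------------------------------

PLOT_COLUMNS = ["plot_id", "lat", "lon", "area_m2", "year", "species", "dbh_cm"]


def write_plots_tsv(censuses: Sequence[PlotCensus], path: str | Path) -> None:
    rows = []
    for c in censuses:
        for sp, dbh in c.trees:
            rows.append((c.plot_id, c.lat, c.lon, c.area_m2, c.year, sp, dbh))
    pd.DataFrame(rows, columns=PLOT_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_plots_tsv(path: str | Path) -> list[PlotCensus]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    out = []
    for (pid, year), g in df.groupby(["plot_id", "year"], sort=False):
        first = g.iloc[0]
        out.append(
            PlotCensus(
                plot_id=str(pid),
                lat=float(first["lat"]),
                lon=float(first["lon"]),
                area_m2=float(first["area_m2"]),
                year=int(year),
                trees=list(zip(g["species"], g["dbh_cm"].astype(float))),
            )
        )
    return out
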