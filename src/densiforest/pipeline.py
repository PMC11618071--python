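"""End-to-end pipeline: simulate -> traits -> community -> map -> hulls
-> drivers -> biomass.

Each stage reads the artifacts of its predecessors from the output
directory and writes its own as plain text (TSV, Newick, ASCII-grid
rasters, JSON/YAML), so any stage is resumable: a stage whose outputs
already exist is skipped unless ``force``.  A manifest records every file
with its checksum, stage and wall time.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import biomass as biomass_mod
from . import community as community_mod
from . import drivers as drivers_mod
from . import geomodel, hulls, synthetic, traitdb
from .raster import RasterGrid, read_ascii_grid, write_ascii_grid

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "traits", "community", "map", "hulls", "drivers", "biomass")

FEATURES = [
    "temperature", "soil_moisture", "disturbance", "fire",
    "cn_ratio", "lai", "forest_age",
]

DRIVER_PREDICTORS = FEATURES + ["richness_scaled", "mean_dbh", "angiosperm_ratio"]


@dataclass
class PipelineConfig:
    """All stage parameters with their documented defaults; unknown keys rejected."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    world: synthetic.WorldParams = field(default_factory=synthetic.WorldParams)
    n_members: int = 10
    min_dist_km: float = 50.0
    subsample_target: int = 2000
    n_draws: int = 48
    cv_folds: int = 10
    var_threshold: float = 0.90
    interp_threshold: float = 0.95
    n_boot: int = 100
    partition_alpha: float = 0.01
    biomass: biomass_mod.BiomassConfig = field(default_factory=biomass_mod.BiomassConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "world" in kwargs:
            wp = dict(kwargs["world"])
            if "landscape" in wp:
                wp["landscape"] = synthetic.LandscapeParams(**wp["landscape"])
            if "plots" in wp:
                wp["plots"] = synthetic.PlotParams(**wp["plots"])
            kwargs["world"] = synthetic.WorldParams(**wp)
        if "biomass" in kwargs:
            b = dict(kwargs["biomass"])
            if "bef" in b:
                b["bef"] = {int(k): float(v) for k, v in b["bef"].items()}
            kwargs["biomass"] = biomass_mod.BiomassConfig(**b)
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, force: bool = False) -> list[dict]:
    """Execute all stages, skipping those whose outputs already exist.

    Returns the manifest: one entry per output file with stage, checksum
    and stage wall time.  A stage whose upstream artifact is missing fails
    with an error naming the stage to rerun.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    dirty = bool(force)  # once a stage reruns, everything downstream reruns

    def record(stage: str, paths: list[Path], elapsed: float) -> None:
        for p in paths:
            manifest.append(
                {
                    "stage": stage,
                    "file": str(p.relative_to(out)),
                    "sha256": _sha256(p),
                    "wall_time_s": round(elapsed, 3),
                }
            )

    def need(stage: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists():
                raise FileNotFoundError(
                    f"stage {stage!r} needs {p.name}; rerun the producing stage"
                )

    # -- simulate -----------------------------------------------------
    world_dir = out / "world"
    world_done = (world_dir / "plots.tsv").exists()
    t0 = time.perf_counter()
    if dirty or not world_done:
        dirty = True
        world = synthetic.generate_world(config.world, config.seed)
        world.write(world_dir)
    record(
        "simulate",
        sorted(p for p in world_dir.rglob("*") if p.is_file()),
        time.perf_counter() - t0,
    )

    # -- traits -------------------------------------------------------
    t0 = time.perf_counter()
    table_path = out / "trait_table.tsv"
    records_path = out / "trait_records.tsv"
    if dirty or not table_path.exists():
        dirty = True
        need("traits", world_dir / "trait_truth.tsv", world_dir / "taxonomy.tsv")
        truth = pd.read_csv(world_dir / "trait_truth.tsv", sep="\t")
        taxonomy = pd.read_csv(world_dir / "taxonomy.tsv", sep="\t")
        records = synthetic.generate_trait_records(
            dict(zip(truth["tip"], truth["wood_density"])), taxonomy,
            seed=config.seed,
        )
        pd.DataFrame(
            [
                (r.raw_name, r.wood_density, r.source_id, r.family, r.order, r.clade)
                for r in records
            ],
            columns=traitdb.RECORD_COLUMNS,
        ).to_csv(records_path, sep="\t", index=False)
        table = traitdb.build_trait_table(records)
        traitdb.write_trait_table_tsv(table, table_path)
    record("traits", [table_path, records_path], time.perf_counter() - t0)

    # -- community ----------------------------------------------------
    t0 = time.perf_counter()
    pixels_path = out / "pixels.tsv"
    if dirty or not pixels_path.exists():
        dirty = True
        need("community", world_dir / "plots.tsv", table_path)
        censuses = community_mod.read_plots_tsv(world_dir / "plots.tsv")
        table = _read_trait_table(table_path)
        comm = community_mod.community_table(censuses, table)
        landscape = RasterGrid.read_dir(world_dir / "landscape")
        pixels = community_mod.aggregate_to_pixels(
            comm, resolution_deg=landscape.cellsize
        )
        pixels.to_csv(pixels_path, sep="\t", index=False)
    record("community", [pixels_path], time.perf_counter() - t0)

    # -- map ----------------------------------------------------------
    t0 = time.perf_counter()
    mean_path = out / "cwd_mean.asc"
    cv_path = out / "cwd_cv.asc"
    model_meta = out / "ensemble_meta.json"
    if dirty or not mean_path.exists():
        dirty = True
        need("map", pixels_path, world_dir / "landscape" / "temperature.asc")
        landscape = RasterGrid.read_dir(world_dir / "landscape")
        pixels = pd.read_csv(pixels_path, sep="\t", float_precision="round_trip")
        joined = _join_covariates(pixels, landscape)
        model = geomodel.train_ensemble(
            joined,
            FEATURES,
            n_members=config.n_members,
            min_dist_km=config.min_dist_km,
            subsample_target=config.subsample_target,
            n_draws=config.n_draws,
            cv_folds=config.cv_folds,
            seed=config.seed,
        )
        mean_map, cv_map = geomodel.predict_ensemble(model, landscape)
        pred = RasterGrid(
            west=landscape.west,
            north=landscape.north,
            cellsize=landscape.cellsize,
            layers={"cwd_mean": np.nan_to_num(mean_map, nan=0.0),
                    "cwd_cv": np.nan_to_num(cv_map, nan=0.0)},
            mask=~np.isfinite(mean_map),
        )
        write_ascii_grid(mean_path, pred, "cwd_mean")
        write_ascii_grid(cv_path, pred, "cwd_cv")
        model_meta.write_text(
            json.dumps(
                {
                    "n_members": model.n_members,
                    "cv_r2": model.cv_r2,
                    "hyperparams": model.hyperparams,
                    "min_dist_km": model.min_dist_km,
                    "feature_names": model.feature_names,
                    "seed": config.seed,
                },
                indent=2,
            )
        )
    record("map", [mean_path, cv_path, model_meta], time.perf_counter() - t0)

    # -- hulls --------------------------------------------------------
    t0 = time.perf_counter()
    hull_path = out / "hull_summary.json"
    frac_path = out / "hull_fraction.asc"
    if dirty or not hull_path.exists():
        dirty = True
        need("hulls", pixels_path)
        landscape = RasterGrid.read_dir(world_dir / "landscape")
        pixels = pd.read_csv(pixels_path, sep="\t", float_precision="round_trip")
        joined = _join_covariates(pixels, landscape).dropna()
        model = hulls.fit_hull_model(
            joined[FEATURES].to_numpy(), config.var_threshold, FEATURES
        )
        frac_map, interp, summary = hulls.classify_grid(
            model, landscape, config.interp_threshold
        )
        grid = RasterGrid(
            west=landscape.west, north=landscape.north, cellsize=landscape.cellsize,
            layers={"hull_fraction": np.nan_to_num(frac_map, nan=0.0)},
            mask=~np.isfinite(frac_map),
        )
        write_ascii_grid(frac_path, grid, "hull_fraction")
        hull_path.write_text(json.dumps(summary, indent=2))
    record("hulls", [hull_path, frac_path], time.perf_counter() - t0)

    # -- drivers ------------------------------------------------------
    t0 = time.perf_counter()
    imp_path = out / "importance.tsv"
    coef_path = out / "coefficients.tsv"
    tree_path = out / "partition_tree.json"
    if dirty or not imp_path.exists():
        dirty = True
        need("drivers", pixels_path)
        landscape = RasterGrid.read_dir(world_dir / "landscape")
        pixels = pd.read_csv(pixels_path, sep="\t", float_precision="round_trip")
        joined = _join_covariates(pixels, landscape).dropna()
        joined["cell_id"] = drivers_mod.grid_cell_ids(
            joined["lat"].to_numpy(), joined["lon"].to_numpy()
        )
        kept, _ = drivers_mod.vif_screen(joined[DRIVER_PREDICTORS])
        res = drivers_mod.importance_bootstrap(
            joined, kept, n_boot=config.n_boot, seed=config.seed
        )
        res["importance"].to_csv(imp_path, sep="\t")
        res["coefficients"].to_csv(coef_path, sep="\t")
        top4 = [
            v for v in res["importance"].index if v != "disturbance"
        ][:4]
        tree = drivers_mod.partition_disturbance(
            joined, "disturbance", top4,
            min_node=max(50, int(0.03 * len(joined))),
            alpha=config.partition_alpha,
        )
        tree_path.write_text(json.dumps(tree.to_dict(), indent=2))
    record("drivers", [imp_path, coef_path, tree_path], time.perf_counter() - t0)

    # -- biomass ------------------------------------------------------
    t0 = time.perf_counter()
    biomass_path = out / "biomass_summary.json"
    pct_path = out / "pct_difference.asc"
    if dirty or not biomass_path.exists():
        dirty = True
        need("biomass", mean_path)
        landscape = RasterGrid.read_dir(world_dir / "landscape")
        pred = read_ascii_grid(mean_path)
        cwd = pred.masked("cwd_mean")
        layers = biomass_mod.tgb_map(
            cwd, landscape.masked("gsv"), landscape["biome"],
            landscape.masked("rmf"), config.biomass,
        )
        area = landscape.pixel_area_ha()
        total_gtc = biomass_mod.global_total(
            layers["total"], area, config.biomass.carbon_fraction
        )
        pct, summary = biomass_mod.constant_density_comparison(
            cwd, landscape.masked("gsv"), landscape["biome"],
            landscape.masked("rmf"), config.biomass,
        )
        const = biomass_mod.tgb_map(
            np.full_like(cwd, config.biomass.constant_wd),
            landscape.masked("gsv"), landscape["biome"],
            landscape.masked("rmf"), config.biomass,
        )
        const_gtc = biomass_mod.global_total(
            const["total"], area, config.biomass.carbon_fraction
        )
        grid = RasterGrid(
            west=landscape.west, north=landscape.north, cellsize=landscape.cellsize,
            layers={"pct_difference": np.nan_to_num(pct, nan=0.0)},
            mask=~np.isfinite(pct),
        )
        write_ascii_grid(pct_path, grid, "pct_difference")
        biomass_path.write_text(
            json.dumps(
                {
                    "total_gtc": total_gtc,
                    "constant_density_gtc": const_gtc,
                    "overall_pct_difference": 100.0 * (const_gtc - total_gtc) / total_gtc,
                    "per_biome": summary.to_dict(orient="records"),
                },
                indent=2,
            )
        )
    record("biomass", [biomass_path, pct_path], time.perf_counter() - t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _read_trait_table(path: Path) -> traitdb.TraitTable:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    sp = df[df["level"] == "species"]
    ge = df[df["level"] == "genus"]
    return traitdb.TraitTable(
        species_mean=dict(zip(sp["taxon"], sp["wood_density"])),
        genus_mean=dict(zip(ge["taxon"], ge["wood_density"])),
        n_records=dict(zip(df["taxon"], df["n_records"])),
        clade=dict(zip(df["taxon"], df["clade"])),
    )


def _join_covariates(pixels: pd.DataFrame, landscape: RasterGrid) -> pd.DataFrame:
    out = pixels.copy()
    lat = out["lat"].to_numpy()
    lon = out["lon"].to_numpy()
    for f in FEATURES:
        out[f] = landscape.sample(f, lat, lon)
    return out
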