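"""Synthetic-world generator with known ground truth.

Builds a self-contained study system for exercising every downstream
stage: a two-clade ultrametric phylogeny (angiosperms vs gymnosperms as
the two children of the root), wood density evolved under a
lambda-transformed Brownian model with distinct clade means, a smooth
temperature/moisture landscape with disturbance, volume (GSV) and
root-mass-fraction layers, and inventory plots whose community composition
tracks a prescribed community wood density vs temperature slope.

Every generator parameter is recorded in ``truth_params``; identical seeds
reproduce identical worlds byte-for-byte.  Community assembly is inverse-
distance trait filtering around a temperature-dependent target density —
deliberately phenomenological: the contract is only the induced
CWD-environment relationship that the mapping, driver and biomass stages
are tested against.

Default study conditions: clade mean densities 0.59 (angiosperm) and 0.47
(gymnosperm) g cm^-3, strong phylogenetic signal (lambda = 0.9), a +0.5%
per degree C community density slope, lognormal DBH with median ~20 cm
(95% range roughly 7-57 cm) and a 5 cm minimum calliper, and a median
plot size of 25 m^2.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from ._seeds import split_rng
from .community import PlotCensus, write_plots_tsv
from .phylo import brownian_covariance, write_newick
from .raster import RasterGrid
from .traitdb import TraitRecord

logger = logging.getLogger(__name__)

__all__ = [
    "LandscapeParams",
    "PlotParams",
    "WorldParams",
    "SyntheticWorld",
    "generate_phylogeny",
    "simulate_traits",
    "generate_landscape",
    "generate_plots",
    "generate_trait_records",
    "generate_world",
    "clade_of_tips",
]

CLADE_NAMES = ("angiosperm", "gymnosperm")


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

def _yule_subtree(
    taxon_namespace: dendropy.TaxonNamespace,
    labels: list[str],
    depth: float,
    rng: np.random.Generator,
) -> dendropy.Node:
    """Pure-birth (Yule) ultrametric subtree over the given tip labels."""
    m = len(labels)
    if m == 1:
        tip = dendropy.Node()
        tip.taxon = taxon_namespace.require_taxon(label=labels[0])
        tip.edge.length = depth
        return tip
    root = dendropy.Node()
    # forward simulation: split a random active lineage at each event
    birth: dict[int, float] = {id(root): 0.0}
    children: dict[int, list] = {}
    active = [root]
    t = 0.0
    while len(active) < m:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(rng.integers(len(active)))
        kids = [dendropy.Node(), dendropy.Node()]
        for k in kids:
            birth[id(k)] = t
        children[id(node)] = kids
        active.extend(kids)
    t_end = t + rng.exponential(1.0 / m)
    scale = depth / t_end

    order = rng.permutation(m)
    tips = list(active)
    for i, node in enumerate(tips):
        node.taxon = taxon_namespace.require_taxon(label=labels[order[i]])

    def attach(node: dendropy.Node) -> None:
        for child in children.get(id(node), []):
            end = birth[id(children[id(child)][0])] if id(child) in children else t_end
            child.edge.length = (end - birth[id(child)]) * scale
            node.add_child(child)
            attach(child)

    attach(root)
    # the waiting time before the first split belongs to the subtree's stem
    t_first = birth[id(children[id(root)][0])]
    root.edge.length = t_first * scale
    return root


def _make_taxonomy(
    labels: list[str], clade: str, genus_size: int, family_size: int, order_size: int
) -> pd.DataFrame:
    """Hierarchical synthetic taxonomy over contiguous tip groups."""
    rows = []
    for i, lab in enumerate(labels):
        g = i // genus_size
        f = g // family_size
        o = f // order_size
        rows.append(
            {
                "tip": lab,
                "genus": lab.split("_")[0],
                "family": f"{clade[:1].upper()}faceae{f:03d}",
                "order": f"{clade[:1].upper()}ales{o:02d}",
                "clade": clade,
            }
        )
    return pd.DataFrame(rows)


def generate_phylogeny(
    n_tips: int,
    seed: int,
    angiosperm_fraction: float = 0.75,
    depth: float = 100.0,
    stem_fraction: float = 0.3,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Rooted bifurcating ultrametric Yule tree with two labelled clades.

    The two children of the root are the angiosperm and gymnosperm clades
    (node labels set accordingly); tip labels are synthetic binomials
    ``<Genus>NNN_spNNNN`` annotated with genus/family/order in the returned
    taxonomy frame.  ``depth`` is the root-to-tip distance (arbitrary time
    units, default 100 ~ Myr-like).
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = split_rng(seed, "phylogeny")
    n_angio = max(1, min(n_tips - 1, int(round(n_tips * angiosperm_fraction))))
    n_gymno = n_tips - n_angio

    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    clade_depth = depth * (1.0 - stem_fraction)
    taxonomies = []
    # genus sizes differ between clades so genus tokens stay distinct
    for clade, n_c, prefix in (
        ("angiosperm", n_angio, "Angio"),
        ("gymnosperm", n_gymno, "Gymno"),
    ):
        genus_size = 3
        labels = [
            f"{prefix}gen{i // genus_size:03d}_sp{i:04d}" for i in range(n_c)
        ]
        sub = _yule_subtree(tns, labels, clade_depth, rng)
        sub.label = clade
        sub.edge.length = (depth - clade_depth) + (sub.edge.length or 0.0)
        tree.seed_node.add_child(sub)
        taxonomies.append(_make_taxonomy(labels, clade, genus_size, 4, 3))
    taxonomy = pd.concat(taxonomies, ignore_index=True)
    tree.is_rooted = True
    return tree, taxonomy


def clade_of_tips(tree: dendropy.Tree) -> dict[str, str]:
    """Map tip label -> clade from the labelled children of the root."""
    out: dict[str, str] = {}
    for child in tree.seed_node.child_nodes():
        if child.label not in CLADE_NAMES:
            raise ValueError("root children must be labelled angiosperm/gymnosperm")
        for lf in child.leaf_iter():
            out[lf.taxon.label] = child.label
    return out


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(
    tree: dendropy.Tree,
    lambda_true: float,
    clade_means: Mapping[str, float],
    sigma2: float,
    seed: int,
    clip: tuple[float, float] = (0.05, 1.5),
) -> dict[str, float]:
    """Evolve wood density on the tree under a lambda-Brownian model.

    Traits are one multivariate-normal draw with per-tip mean equal to the
    tip's clade mean and covariance ``sigma2 * C(lambda)`` (off-diagonal
    Brownian covariance scaled by ``lambda_true``, diagonal unchanged, tree
    depth normalized to 1 so ``sigma2`` is the tip variance).  Values are
    clipped to the span of real wood, [0.05, 1.5] g cm^-3; clipping is
    logged because it perturbs normality slightly.
    """
    if not (0.0 <= lambda_true <= 1.0):
        raise ValueError("lambda_true must lie in [0, 1]")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    for clade, m in clade_means.items():
        if not (0.0 < m <= 1.5):
            raise ValueError(f"clade mean for {clade} outside (0, 1.5]: {m}")
    rng = split_rng(seed, "traits")
    labels, C = brownian_covariance(tree)
    C = C / np.diag(C).max()  # unit depth
    V = lambda_true * C
    np.fill_diagonal(V, np.diag(C))
    clades = clade_of_tips(tree)
    mu = np.array([clade_means[clades[l]] for l in labels])
    L = np.linalg.cholesky(sigma2 * V + 1e-12 * np.eye(len(labels)))
    vals = mu + L @ rng.standard_normal(len(labels))
    n_clip = int(np.sum((vals < clip[0]) | (vals > clip[1])))
    if n_clip:
        logger.info("simulate_traits: clipped %d of %d tip values", n_clip, len(vals))
    vals = np.clip(vals, clip[0], clip[1])
    return {l: float(v) for l, v in zip(labels, vals)}


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

@dataclass
class LandscapeParams:
    west: float = -20.0
    north: float = 52.0
    cellsize_deg: float = 0.5
    t_north: float = -2.0          # deg C at the northern edge
    t_south: float = 26.0          # deg C at the southern edge
    temp_noise_sd: float = 1.0     # deg C, smooth field
    moisture_range: tuple[float, float] = (0.05, 0.95)
    smooth_sigma_px: float = 4.0   # Gaussian correlation length of noise fields
    gsv_base: float = 60.0         # m^3 ha^-1
    gsv_per_degC: float = 6.0
    gsv_per_moisture: float = 180.0
    gsv_noise_sd: float = 20.0
    rmf_mean: float = 0.25
    rmf_sd: float = 0.05
    mask_fraction: float = 0.04    # share of pixels masked as water/no-forest
    # biome thresholds (deg C, moisture fraction)
    boreal_below: float = 8.0
    tropical_above: float = 18.0
    dry_moisture_below: float = 0.35


def _smooth_field(
    shape: tuple[int, int], sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance smooth Gaussian random field (filtered white noise)."""
    z = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(z, sigma=sigma, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_landscape(
    n_rows: int, n_cols: int, params: LandscapeParams | None = None, seed: int = 0
) -> RasterGrid:
    """Smooth synthetic covariate stack on a shared lon/lat lattice.

    Temperature is a monotone north-south gradient plus smooth noise;
    moisture, disturbance (human modification), fire, soil C:N, LAI and
    forest age are smooth fields in plausible ranges; GSV rises with
    temperature and moisture; biome codes are thresholded from
    temperature/moisture (1 boreal, 2 temperate, 3 tropical, 4 dryland).
    """
    if n_rows < 8 or n_cols < 8:
        raise ValueError("landscape must be at least 8x8")
    p = params or LandscapeParams()
    rng = split_rng(seed, "landscape")
    shape = (n_rows, n_cols)

    row_frac = np.repeat(
        (np.arange(n_rows) / max(1, n_rows - 1))[:, None], n_cols, axis=1
    )
    temperature = p.t_north + (p.t_south - p.t_north) * row_frac
    if p.temp_noise_sd > 0:
        temperature = temperature + p.temp_noise_sd * _smooth_field(
            shape, p.smooth_sigma_px, rng
        )

    lo, hi = p.moisture_range
    col_frac = np.repeat(
        (np.arange(n_cols) / max(1, n_cols - 1))[None, :], n_rows, axis=0
    )
    moist_raw = 0.8 * (col_frac - 0.5) + 0.6 * _smooth_field(shape, p.smooth_sigma_px, rng)
    moisture = lo + (hi - lo) / (1.0 + np.exp(-2.0 * moist_raw))

    disturbance = np.clip(
        0.35 + 0.25 * _smooth_field(shape, p.smooth_sigma_px, rng), 0.0, 1.0
    )
    fire = np.clip(0.15 + 0.15 * _smooth_field(shape, p.smooth_sigma_px, rng), 0.0, 1.0)
    cn_ratio = np.clip(18.0 + 4.0 * _smooth_field(shape, p.smooth_sigma_px, rng), 6.0, 40.0)
    lai = np.clip(
        1.0 + 4.0 * moisture + 0.8 * _smooth_field(shape, p.smooth_sigma_px, rng),
        0.2,
        8.0,
    )
    forest_age = np.clip(
        100.0 + 50.0 * _smooth_field(shape, p.smooth_sigma_px, rng), 10.0, 300.0
    )
    gsv = np.clip(
        p.gsv_base
        + p.gsv_per_degC * np.clip(temperature, 0.0, None)
        + p.gsv_per_moisture * moisture
        + p.gsv_noise_sd * _smooth_field(shape, p.smooth_sigma_px, rng),
        0.0,
        None,
    )
    rmf = np.clip(
        p.rmf_mean + p.rmf_sd * _smooth_field(shape, p.smooth_sigma_px, rng), 0.02, 0.59
    )

    biome = np.full(shape, 2, dtype=float)  # temperate default
    biome[temperature < p.boreal_below] = 1
    warm = temperature >= p.tropical_above
    biome[warm & (moisture >= p.dry_moisture_below)] = 3
    biome[warm & (moisture < p.dry_moisture_below)] = 4

    mask = np.zeros(shape, dtype=bool)
    if p.mask_fraction > 0:
        water = _smooth_field(shape, p.smooth_sigma_px, rng)
        thresh = np.quantile(water, p.mask_fraction)
        mask = water < thresh

    return RasterGrid(
        west=p.west,
        north=p.north,
        cellsize=p.cellsize_deg,
        layers={
            "temperature": temperature,
            "soil_moisture": moisture,
            "disturbance": disturbance,
            "fire": fire,
            "cn_ratio": cn_ratio,
            "lai": lai,
            "forest_age": forest_age,
            "gsv": gsv,
            "rmf": rmf,
            "biome": biome,
        },
        mask=mask,
    )


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

@dataclass
class PlotParams:
    base_density: float = 0.50          # g cm^-3 target at 0 deg C
    filter_tau: float = 0.02            # softness of the trait filter (g cm^-3)
    gymno_decay_per_degC: float = 0.18  # gymnosperm weight ~ exp(-k T)
    trees_min: int = 8
    trees_poisson_mean: float = 18.0
    dbh_median_cm: float = 20.0
    dbh_sigma_log: float = 0.53         # 95% range ~ 7-57 cm, mean ~ 22.9
    area_median_m2: float = 25.0
    area_sigma_log: float = 0.6
    year_base: int = 2003
    year_spread: int = 8
    # optional planted disturbance interaction: CWD slope on the disturbance
    # layer flips sign at t_threshold (cold: slope_cold, warm: slope_warm)
    disturbance_interaction: dict | None = None


def generate_plots(
    landscape: RasterGrid,
    trait_truth: Mapping[str, float],
    clades: Mapping[str, str],
    n_plots: int,
    slope_pct_per_degC: float = 0.5,
    seed: int = 0,
    params: PlotParams | None = None,
    n_censuses: int = 1,
) -> list[PlotCensus]:
    """Sample inventory plots whose CWD tracks temperature at a known slope.

    At a plot with temperature T the target community density is
    ``base * (1 + slope * T / 100)``; species are drawn with weights
    ``clade_weight(T) / (|wd - target| + tau)^2`` (inverse-distance trait
    filtering), where the gymnosperm clade weight decays exponentially with
    temperature.  DBH is lognormal (median ~20 cm) left-truncated at the
    5 cm calliper; plot areas are lognormal with median 25 m^2.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    p = params or PlotParams()
    rng = split_rng(seed, "plots")

    species = sorted(trait_truth)
    wd = np.array([trait_truth[s] for s in species])
    is_gymno = np.array([clades[s] == "gymnosperm" for s in species])

    free = ~landscape.mask
    rows, cols = np.nonzero(free)
    pick = rng.integers(len(rows), size=n_plots)
    lat_c = landscape.lat_centers()[rows[pick]]
    lon_c = landscape.lon_centers()[cols[pick]]
    # jitter within the cell so plots do not sit exactly on centers
    half = landscape.cellsize / 2.0
    lat = lat_c + rng.uniform(-half, half, n_plots) * 0.98
    lon = lon_c + rng.uniform(-half, half, n_plots) * 0.98

    temp = landscape["temperature"][rows[pick], cols[pick]]
    dist = landscape["disturbance"][rows[pick], cols[pick]]

    censuses: list[PlotCensus] = []
    interaction = p.disturbance_interaction
    for i in range(n_plots):
        target = p.base_density * (1.0 + slope_pct_per_degC * temp[i] / 100.0)
        if interaction:
            slope = (
                interaction["slope_cold"]
                if temp[i] < interaction["t_threshold"]
                else interaction["slope_warm"]
            )
            target = target + slope * dist[i]
        w = 1.0 / (np.abs(wd - target) + p.filter_tau) ** 2
        gym_mult = np.exp(-p.gymno_decay_per_degC * max(0.0, temp[i]))
        w = w * np.where(is_gymno, gym_mult, 1.0)
        w = w / w.sum()
        n_trees = p.trees_min + rng.poisson(p.trees_poisson_mean)
        idx = rng.choice(len(species), size=n_trees, p=w)
        dbh = _truncated_lognormal(
            rng, n_trees, np.log(p.dbh_median_cm), p.dbh_sigma_log, lower=5.0
        )
        area = float(np.exp(rng.normal(np.log(p.area_median_m2), p.area_sigma_log)))
        year = int(p.year_base + rng.integers(-p.year_spread, p.year_spread + 1))
        trees = [(species[j].replace("_", " "), float(d)) for j, d in zip(idx, dbh)]
        censuses.append(
            PlotCensus(
                plot_id=f"plot{i:05d}",
                lat=float(lat[i]),
                lon=float(lon[i]),
                area_m2=area,
                year=year,
                trees=trees,
            )
        )
        for c in range(1, n_censuses):
            # earlier census: mostly the same community, smaller stems
            keep = rng.random(n_trees) < 0.85
            idx2 = np.where(keep, idx, rng.choice(len(species), size=n_trees, p=w))
            dbh2 = np.maximum(5.01, dbh - rng.uniform(1.0, 4.0, n_trees))
            censuses.append(
                PlotCensus(
                    plot_id=f"plot{i:05d}",
                    lat=float(lat[i]),
                    lon=float(lon[i]),
                    area_m2=area,
                    year=year - 10 * c,
                    trees=[
                        (species[j].replace("_", " "), float(d))
                        for j, d in zip(idx2, dbh2)
                    ],
                )
            )
    return censuses


def _truncated_lognormal(
    rng: np.random.Generator, n: int, mu: float, sigma: float, lower: float
) -> np.ndarray:
    out = np.exp(rng.normal(mu, sigma, n))
    bad = out <= lower
    while bad.any():
        out[bad] = np.exp(rng.normal(mu, sigma, int(bad.sum())))
        bad = out <= lower
    return out


# ---------------------------------------------------------------------------
# raw trait records (for the trait_db stage)
# ---------------------------------------------------------------------------

def generate_trait_records(
    trait_truth: Mapping[str, float],
    taxonomy: pd.DataFrame,
    n_sources: int = 4,
    coverage: float = 0.7,
    noise_sd: float = 0.03,
    records_per_species: tuple[int, int] = (1, 4),
    seed: int = 0,
) -> list[TraitRecord]:
    """Noisy multi-source measurement records around the true species values."""
    rng = split_rng(seed, "records")
    tax = taxonomy.set_index("tip")
    out: list[TraitRecord] = []
    species = sorted(trait_truth)
    for src in range(n_sources):
        covered = rng.random(len(species)) < coverage
        for keep, sp in zip(covered, species):
            if not keep:
                continue
            info = tax.loc[sp]
            binomial = sp.replace("_", " ")
            n_rec = int(rng.integers(records_per_species[0], records_per_species[1] + 1))
            for _ in range(n_rec):
                val = float(
                    np.clip(trait_truth[sp] + rng.normal(0.0, noise_sd), 0.05, 1.95)
                )
                out.append(
                    TraitRecord(
                        raw_name=binomial,
                        wood_density=val,
                        source_id=f"source{src:02d}",
                        canonical_species=binomial,
                        genus=binomial.split()[0],
                        family=str(info["family"]),
                        order=str(info["order"]),
                        clade=str(info["clade"]),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# whole world
# ---------------------------------------------------------------------------

@dataclass
class WorldParams:
    n_tips: int = 300
    angiosperm_fraction: float = 0.75
    lambda_true: float = 0.9
    clade_means: dict = field(
        default_factory=lambda: {"angiosperm": 0.59, "gymnosperm": 0.47}
    )
    sigma2: float = 0.012  # tip trait variance (sd ~0.11 g cm^-3 within clade)
    n_rows: int = 64
    n_cols: int = 64
    n_plots: int = 2000
    slope_pct_per_degC: float = 0.5
    n_censuses: int = 1
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    plots: PlotParams = field(default_factory=PlotParams)


@dataclass
class SyntheticWorld:
    phylogeny: dendropy.Tree
    taxonomy: pd.DataFrame
    trait_truth: dict[str, float]
    landscape: RasterGrid
    plots: list[PlotCensus]
    truth_params: dict

    def clades(self) -> dict[str, str]:
        return dict(zip(self.taxonomy["tip"], self.taxonomy["clade"]))

    def write(self, directory: str | Path) -> dict[str, str]:
        """Serialize the world: Newick, TSVs, ASCII-grid rasters, config."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_newick(self.phylogeny, directory / "phylogeny.nwk")
        self.taxonomy.to_csv(directory / "taxonomy.tsv", sep="\t", index=False)
        pd.DataFrame(
            sorted(self.trait_truth.items()), columns=["tip", "wood_density"]
        ).to_csv(directory / "trait_truth.tsv", sep="\t", index=False)
        write_plots_tsv(self.plots, directory / "plots.tsv")
        self.landscape.write_dir(directory / "landscape")
        (directory / "truth_params.yaml").write_text(
            yaml.safe_dump(self.truth_params, sort_keys=True)
        )
        return {"dir": str(directory)}


def generate_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate the full synthetic study system from one seed."""
    p = params or WorldParams()
    tree, taxonomy = generate_phylogeny(
        p.n_tips, seed, angiosperm_fraction=p.angiosperm_fraction
    )
    traits = simulate_traits(tree, p.lambda_true, p.clade_means, p.sigma2, seed)
    landscape = generate_landscape(p.n_rows, p.n_cols, p.landscape, seed)
    clades = dict(zip(taxonomy["tip"], taxonomy["clade"]))
    plots = generate_plots(
        landscape,
        traits,
        clades,
        p.n_plots,
        p.slope_pct_per_degC,
        seed,
        p.plots,
        n_censuses=p.n_censuses,
    )
    truth = asdict(p)
    truth["seed"] = int(seed)
    # tuples are not YAML-stable; normalize
    truth["landscape"]["moisture_range"] = list(p.landscape.moisture_range)
    truth["plots"]["dbh_sigma_log"] = float(p.plots.dbh_sigma_log)
    return SyntheticWorld(
        phylogeny=tree,
        taxonomy=taxonomy,
        trait_truth=traits,
        landscape=landscape,
        plots=plots,
        truth_params=truth,
    )
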