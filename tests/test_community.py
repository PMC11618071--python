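"""Inventory filters, CWD arithmetic, pixel aggregation, biome summaries
and the temporal variance decomposition."""

import numpy as np
import pandas as pd
import pytest

from densiforest.community import (
    PlotCensus,
    aggregate_to_pixels,
    assign_wood_density,
    biome_summary,
    community_table,
    compute_cwd,
    coverage_filter,
    filter_latest_census,
    read_plots_tsv,
    richness_scaled,
    temporal_variance_decomposition,
    write_plots_tsv,
)
from densiforest.traitdb import TraitTable

TABLE = TraitTable(
    species_mean={"Quercus robur": 0.55, "Fagus sylvatica": 0.6, "Pinus nigra": 0.45},
    genus_mean={"Quercus": 0.58, "Fagus": 0.6, "Pinus": 0.43},
    clade={
        "Quercus robur": "angiosperm", "Fagus sylvatica": "angiosperm",
        "Pinus nigra": "gymnosperm", "Quercus": "angiosperm",
        "Fagus": "angiosperm", "Pinus": "gymnosperm",
    },
)


def census(trees, plot_id="p1", year=2000, lat=45.0, lon=5.0, area=25.0):
    return PlotCensus(plot_id=plot_id, lat=lat, lon=lon, area_m2=area, year=year,
                      trees=trees)


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

class TestLatestCensus:
    def test_latest_year_kept(self):
        old = census([("Quercus robur", 10.0)], year=1998)
        new = census([("Quercus robur", 12.0)], year=2010)
        assert filter_latest_census([old, new]) == [new]

    def test_single_census_unchanged(self):
        c = census([("Quercus robur", 10.0)])
        assert filter_latest_census([c]) == [c]

    def test_tie_broken_by_tree_count(self):
        small = census([("Quercus robur", 10.0)] * 12, year=2000)
        big = census([("Quercus robur", 10.0)] * 30, year=2000)
        assert filter_latest_census([small, big]) == [big]


class TestAssignDensity:
    def test_species_match_preferred(self):
        wd, level = assign_wood_density(("Quercus robur", 20.0), TABLE)
        assert (wd, level) == (0.55, "species")

    def test_genus_fallback(self):
        wd, level = assign_wood_density(("Quercus ilex", 20.0), TABLE)
        assert (wd, level) == (0.58, "genus")

    def test_unknown_genus_is_none(self):
        wd, level = assign_wood_density(("Ailanthus altissima", 20.0), TABLE)
        assert (wd, level) == (None, "none")


class TestCoverage:
    def make(self, n_matched, n_total):
        trees = [("Quercus robur", 10.0)] * n_matched + [
            ("Unknownus plantus", 10.0)
        ] * (n_total - n_matched)
        return census(trees)

    @pytest.mark.parametrize(
        "matched,total,kept", [(7, 10, False), (8, 10, True), (9, 12, True)]
    )
    def test_threshold(self, matched, total, kept):
        keep, cov = coverage_filter(self.make(matched, total), TABLE)
        assert keep is kept
        assert cov == pytest.approx(matched / total)

    def test_exact_boundary_is_kept(self):
        """The exclusion rule is strict '< 75%': exactly 0.75 stays."""
        keep, cov = coverage_filter(self.make(9, 12), TABLE)
        assert cov == pytest.approx(0.75)
        assert keep


# ---------------------------------------------------------------------------
# CWD
# ---------------------------------------------------------------------------

class TestComputeCwd:
    def test_single_tree(self):
        rec = compute_cwd(census([("Quercus robur", 20.0)]), TABLE)
        assert rec.cwd == pytest.approx(0.55)

    def test_equal_dbh_is_plain_mean(self):
        rec = compute_cwd(
            census([("Pinus nigra", 20.0), ("Fagus sylvatica", 20.0)]), TABLE
        )
        assert rec.cwd == pytest.approx((0.45 + 0.6) / 2)

    def test_weighted_mean_arithmetic(self):
        """dbh {10,20,30}, wd {0.4,0.5,0.6}: basal areas ~ {100,400,900}."""
        table = TraitTable(
            species_mean={"A a": 0.4, "B b": 0.5, "C c": 0.6},
            genus_mean={}, clade={},
        )
        rec = compute_cwd(
            census([("A a", 10.0), ("B b", 20.0), ("C c", 30.0)]), table
        )
        assert rec.cwd == pytest.approx(780.0 / 1400.0)

    def test_dbh_unit_invariance(self):
        """CWD is unchanged when DBH is expressed in different units."""
        trees_cm = [("Pinus nigra", 12.0), ("Fagus sylvatica", 40.0)]
        trees_mm = [(s, d * 10.0) for s, d in trees_cm]
        assert compute_cwd(census(trees_cm), TABLE).cwd == pytest.approx(
            compute_cwd(census(trees_mm), TABLE).cwd
        )

    def test_bounded_by_member_densities(self, rng):
        species = list(TABLE.species_mean)
        trees = [
            (species[i], float(d))
            for i, d in zip(rng.integers(0, 3, 50), rng.uniform(6, 80, 50))
        ]
        rec = compute_cwd(census(trees), TABLE)
        vals = [TABLE.species_mean[s] for s, _ in trees]
        assert min(vals) <= rec.cwd <= max(vals)

    def test_angiosperm_ratio(self):
        rec = compute_cwd(
            census([("Pinus nigra", 20.0), ("Fagus sylvatica", 20.0),
                    ("Quercus robur", 20.0)]),
            TABLE,
        )
        assert rec.angiosperm_ratio == pytest.approx(2.0 / 3.0)

    def test_dbh_below_calliper_rejected(self):
        with pytest.raises(ValueError, match="DBH"):
            census([("Quercus robur", 4.0)])


class TestRichnessScaled:
    def test_reference_area_identity(self):
        assert richness_scaled(7, 25.0) == pytest.approx(7.0)

    def test_arrhenius_scaling(self):
        assert richness_scaled(16, 16 * 25.0) == pytest.approx(8.0)

    def test_z_zero_gives_raw_count(self):
        assert richness_scaled(9, 1000.0, z=0.0) == pytest.approx(9.0)


# ---------------------------------------------------------------------------
# pixel aggregation
# ---------------------------------------------------------------------------

class TestAggregateToPixels:
    def frame(self, rows):
        return pd.DataFrame(rows, columns=["plot_id", "lat", "lon", "cwd"])

    def test_same_pixel_mean(self):
        df = self.frame([("a", 45.001, 5.001, 0.4), ("b", 45.002, 5.002, 0.6)])
        out = aggregate_to_pixels(df, resolution_deg=0.5)
        assert len(out) == 1
        assert out["cwd"].iloc[0] == pytest.approx(0.5)
        assert out["n_plots"].iloc[0] == 2

    def test_edge_point_belongs_to_half_open_cell(self):
        res = 0.5
        df = self.frame([("a", 45.0, 5.0, 0.5)])  # exactly on both edges
        out = aggregate_to_pixels(df, resolution_deg=res)
        assert out["pix_col"].iloc[0] == int((5.0 + 180.0) / res)
        assert out["pix_row"].iloc[0] == int((90.0 - 45.0) / res)

    def test_distinct_pixels_kept_separate(self):
        df = self.frame([("a", 45.1, 5.1, 0.4), ("b", 46.1, 6.1, 0.6)])
        assert len(aggregate_to_pixels(df, resolution_deg=0.5)) == 2

    def test_pixel_then_global_mean_differs_under_uneven_counts(self):
        """Plot-level and pixel-level global means agree only for equal
        per-pixel plot counts."""
        df = self.frame(
            [("a", 45.1, 5.1, 0.4), ("b", 45.1, 5.1, 0.4), ("c", 46.1, 6.1, 0.7)]
        )
        out = aggregate_to_pixels(df, resolution_deg=0.5)
        assert out["cwd"].mean() == pytest.approx(0.55)
        assert df["cwd"].mean() == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# biome summaries
# ---------------------------------------------------------------------------

def test_biome_summary_recovers_generator_contrast(small_world, small_community):
    """Warm biomes assemble denser wood than boreal ones by construction."""
    pixels = aggregate_to_pixels(
        small_community, resolution_deg=small_world.landscape.cellsize
    )
    grouping = {1: "boreal", 2: "temperate", 3: "tropical", 4: "dryland"}
    out = biome_summary(pixels, small_world.landscape, grouping)
    ft = out[out["level"] == "forest_type"].set_index("group")
    assert ft.loc["tropical", "mean_cwd"] > ft.loc["boreal", "mean_cwd"]
    # single-biome subsets: overall mean equals member mean by construction
    b = out[out["level"] == "biome"]
    assert set(b["group"]).issubset({1, 2, 3, 4})


def test_empty_biome_absent(small_world, small_community):
    pixels = aggregate_to_pixels(
        small_community, resolution_deg=small_world.landscape.cellsize
    )
    out = biome_summary(pixels, small_world.landscape, {1: "boreal"})
    # groups not present in the grouping map fall out of forest-type rows
    assert set(out[out["level"] == "forest_type"]["group"]) <= {"boreal"}


# ---------------------------------------------------------------------------
# temporal variance decomposition
# ---------------------------------------------------------------------------

class TestTemporalDecomposition:
    def test_pure_plot_variation(self):
        df = pd.DataFrame(
            {
                "plot_id": ["a", "a", "b", "b"],
                "year": [2000, 2010, 2000, 2010],
                "cwd": [0.4, 0.4, 0.6, 0.6],
            }
        )
        frac = temporal_variance_decomposition(df)
        assert frac["plot"] == pytest.approx(1.0)
        assert frac["year"] == pytest.approx(0.0)

    def test_component_recovery(self, rng):
        """sigma2 plot=9, year=1, residual=0 -> fractions ~ {0.9, 0.1, 0}."""
        plots = rng.normal(0, 3, 120)
        years = rng.normal(0, 1, 2)
        rows = []
        for i, a in enumerate(plots):
            for j, b in enumerate(years):
                rows.append((f"p{i}", 2000 + 10 * j, 0.5 + a + b))
        frac = temporal_variance_decomposition(
            pd.DataFrame(rows, columns=["plot_id", "year", "cwd"])
        )
        assert frac["plot"] == pytest.approx(0.9, abs=0.05)
        assert frac["year"] == pytest.approx(0.1, abs=0.05)
        assert frac["residual"] == pytest.approx(0.0, abs=0.02)

    def test_single_plot_zero_plot_fraction(self):
        df = pd.DataFrame(
            {"plot_id": ["a"] * 3, "year": [2000, 2005, 2010],
             "cwd": [0.4, 0.5, 0.6]}
        )
        frac = temporal_variance_decomposition(df)
        assert frac["plot"] == 0.0


# ---------------------------------------------------------------------------
# round trips and the batch path
# ---------------------------------------------------------------------------

def test_plots_tsv_roundtrip(tmp_path, small_world):
    path = tmp_path / "plots.tsv"
    write_plots_tsv(small_world.plots[:20], path)
    back = read_plots_tsv(path)
    assert len(back) == 20
    a, b = small_world.plots[0], back[0]
    assert (a.plot_id, a.year, a.n_trees) == (b.plot_id, b.year, b.n_trees)
    assert a.trees == b.trees


def test_community_table_applies_filters(small_world, small_trait_table):
    out = community_table(small_world.plots, small_trait_table)
    assert (out["coverage_fraction"] >= 0.75).all()
    assert out["cwd"].between(0.05, 1.5).all()
    assert out["angiosperm_ratio"].between(0, 1).all()
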