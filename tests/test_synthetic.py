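"""Generator contracts: phylogeny shape, trait model limits, landscape
structure, plot assembly and whole-world determinism."""

import numpy as np
import pytest

from densiforest.phylo import brownian_covariance
from densiforest.synthetic import (
    LandscapeParams,
    PlotParams,
    WorldParams,
    clade_of_tips,
    generate_landscape,
    generate_phylogeny,
    generate_plots,
    generate_world,
    simulate_traits,
)

CLADE_MEANS = {"angiosperm": 0.59, "gymnosperm": 0.47}


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------

class TestGeneratePhylogeny:
    def test_smallest_bifurcating_case(self):
        tree, tax = generate_phylogeny(3, seed=0)
        tips = [l for l in tree.leaf_node_iter()]
        assert len(tips) == 3
        n_edges = sum(1 for e in tree.preorder_edge_iter() if e.head_node.parent_node)
        assert n_edges == 4
        _, C = brownian_covariance(tree)
        assert np.allclose(np.diag(C), np.diag(C)[0])  # ultrametric

    def test_determinism_newick_identical(self):
        a = generate_phylogeny(40, seed=7)[0].as_string(schema="newick")
        b = generate_phylogeny(40, seed=7)[0].as_string(schema="newick")
        assert a == b

    def test_root_clades_partition_tips(self):
        tree, tax = generate_phylogeny(200, seed=3)
        clades = clade_of_tips(tree)
        sizes = {c: sum(1 for v in clades.values() if v == c) for c in set(clades.values())}
        assert sizes["angiosperm"] + sizes["gymnosperm"] == 200
        assert set(tax["clade"]) == {"angiosperm", "gymnosperm"}

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            generate_phylogeny(2, seed=0)

    def test_taxonomy_annotations_cover_all_tips(self):
        tree, tax = generate_phylogeny(60, seed=5)
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        assert set(tax["tip"]) == labels
        assert tax[["genus", "family", "order"]].notna().all().all()


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def tree200():
    return generate_phylogeny(200, seed=21)[0]


class TestSimulateTraits:
    def test_clade_means_recovered(self, tree200):
        """Sample clade means land within 3 SE of the configured targets."""
        traits = simulate_traits(tree200, 0.9, CLADE_MEANS, 0.012, seed=2)
        clades = clade_of_tips(tree200)
        for clade, target in CLADE_MEANS.items():
            vals = np.array([v for k, v in traits.items() if clades[k] == clade])
            # phylogenetic correlation inflates the SE of the clade mean; a
            # conservative bound is the full trait sd
            assert abs(vals.mean() - target) <= 3 * np.sqrt(0.012)

    def test_degenerate_variance_collapses_to_clade_means(self, tree200):
        traits = simulate_traits(tree200, 0.5, CLADE_MEANS, 1e-12, seed=3)
        clades = clade_of_tips(tree200)
        for k, v in traits.items():
            assert v == pytest.approx(CLADE_MEANS[clades[k]], abs=1e-4)

    def test_lambda_zero_gives_iid_within_clade(self, tree200):
        """With lambda=0 trait covariances vanish: neighbouring tips are no
        more similar than random pairs."""
        traits = simulate_traits(tree200, 0.0, CLADE_MEANS, 0.012, seed=4)
        labels, C = brownian_covariance(tree200)
        y = np.array([traits[l] for l in labels])
        clades = clade_of_tips(tree200)
        angio = [i for i, l in enumerate(labels) if clades[l] == "angiosperm"]
        ya = y[angio]
        Ca = C[np.ix_(angio, angio)]
        iu = np.triu_indices(len(angio), k=1)
        sib = Ca[iu] > np.median(Ca[iu])  # closely related pairs
        prod = (ya - ya.mean())[:, None] * (ya - ya.mean())[None, :]
        # mean cross-product of close pairs ~ 0 under independence
        close_cov = prod[iu][sib].mean()
        assert abs(close_cov) < 0.004

    def test_invalid_clade_mean_rejected(self, tree200):
        with pytest.raises(ValueError):
            simulate_traits(tree200, 0.5, {"angiosperm": 2.0, "gymnosperm": 0.4}, 0.01, 1)

    def test_values_clipped_to_wood_range(self, tree200):
        traits = simulate_traits(tree200, 1.0, CLADE_MEANS, 0.2, seed=5)
        vals = np.array(list(traits.values()))
        assert vals.min() >= 0.05 and vals.max() <= 1.5


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------

class TestGenerateLandscape:
    def test_zero_noise_temperature_monotone_in_rows(self):
        p = LandscapeParams(temp_noise_sd=0.0)
        g = generate_landscape(16, 16, p, seed=0)
        t = g["temperature"]
        assert np.all(np.diff(t, axis=0) > 0)

    def test_biome_codes_partition_unmasked_pixels(self):
        g = generate_landscape(32, 32, seed=9)
        codes = g["biome"][~g.mask]
        assert set(np.unique(codes)).issubset({1.0, 2.0, 3.0, 4.0})
        assert np.isfinite(codes).all()

    def test_determinism_bit_identical(self):
        a = generate_landscape(16, 16, seed=4)
        b = generate_landscape(16, 16, seed=4)
        for name in a.layers:
            np.testing.assert_array_equal(a[name], b[name])
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_ranges(self):
        g = generate_landscape(32, 32, seed=2)
        assert g["gsv"].min() >= 0
        assert 0 < g["rmf"].min() and g["rmf"].max() < 0.6
        for name in ("disturbance", "fire"):
            assert 0 <= g[name].min() and g[name].max() <= 1

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            generate_landscape(4, 64, seed=0)


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

class TestGeneratePlots:
    def test_every_species_exists_in_trait_truth(self, small_world):
        known = {k.replace("_", " ") for k in small_world.trait_truth}
        for census in small_world.plots:
            for sp, _ in census.trees:
                assert sp in known

    def test_n_plots_validated(self, small_world):
        with pytest.raises(ValueError):
            generate_plots(
                small_world.landscape, small_world.trait_truth,
                small_world.clades(), n_plots=0,
            )

    def test_null_slope_gives_flat_cwd_temperature_relation(self, small_world):
        """slope=0 plus no clade-temperature effect: fitted slope ~ 0."""
        params = PlotParams(gymno_decay_per_degC=0.0)
        plots = generate_plots(
            small_world.landscape, small_world.trait_truth, small_world.clades(),
            n_plots=600, slope_pct_per_degC=0.0, seed=17, params=params,
        )
        truth = {k.replace("_", " "): v for k, v in small_world.trait_truth.items()}
        cwd, temp = [], []
        for c in plots:
            ba = np.array([np.pi * (d / 2) ** 2 for _, d in c.trees])
            wd = np.array([truth[s] for s, _ in c.trees])
            cwd.append(float((wd * ba).sum() / ba.sum()))
            temp.append(
                small_world.landscape.sample(
                    "temperature", np.array([c.lat]), np.array([c.lon])
                )[0]
            )
        ok = np.isfinite(temp)
        X = np.column_stack([np.ones(ok.sum()), np.asarray(temp)[ok]])
        y = np.asarray(cwd)[ok]
        beta, res_ss, *_ = np.linalg.lstsq(X, y, rcond=None)
        sigma2 = res_ss[0] / (ok.sum() - 2)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert abs(beta[1]) <= 2 * se

    def test_positive_slope_recovered(self, small_world):
        """The default 0.5 %/degC condition leaves a positive CWD~T slope."""
        truth = {k.replace("_", " "): v for k, v in small_world.trait_truth.items()}
        cwd, temp = [], []
        for c in small_world.plots:
            ba = np.array([np.pi * (d / 2) ** 2 for _, d in c.trees])
            wd = np.array([truth[s] for s, _ in c.trees])
            cwd.append(float((wd * ba).sum() / ba.sum()))
            temp.append(
                small_world.landscape.sample(
                    "temperature", np.array([c.lat]), np.array([c.lon])
                )[0]
            )
        ok = np.isfinite(temp)
        slope = np.polyfit(np.asarray(temp)[ok], np.asarray(cwd)[ok], 1)[0]
        assert slope > 0

    def test_two_censuses_have_distinct_years(self, small_world):
        plots = generate_plots(
            small_world.landscape, small_world.trait_truth, small_world.clades(),
            n_plots=20, seed=3, n_censuses=2,
        )
        years = {}
        for c in plots:
            years.setdefault(c.plot_id, set()).add(c.year)
        assert all(len(v) == 2 for v in years.values())

    def test_median_dbh_near_20cm(self, small_world):
        dbhs = [d for c in small_world.plots for _, d in c.trees]
        assert 17.0 < np.median(dbhs) < 23.0
        assert min(dbhs) > 5.0


# ---------------------------------------------------------------------------
# whole world
# ---------------------------------------------------------------------------

def test_world_serialization_deterministic(tmp_path):
    """Identical seeds give byte-identical serialized worlds."""
    params = WorldParams(n_tips=30, n_rows=12, n_cols=12, n_plots=25)
    digests = []
    for run in ("a", "b"):
        d = tmp_path / run
        generate_world(params, seed=99).write(d)
        import hashlib

        h = hashlib.sha256()
        for p in sorted(d.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
        digests.append(h.hexdigest())
    assert digests[0] == digests[1]


def test_truth_params_record_inputs():
    w = generate_world(WorldParams(n_tips=20, n_rows=10, n_cols=10, n_plots=10), seed=5)
    assert w.truth_params["seed"] == 5
    assert w.truth_params["lambda_true"] == 0.9
    assert w.truth_params["slope_pct_per_degC"] == 0.5
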