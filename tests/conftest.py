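"""Shared fixtures: small synthetic worlds generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from densiforest.community import community_table
from densiforest.synthetic import (
    WorldParams,
    generate_trait_records,
    generate_world,
)
from densiforest.traitdb import build_trait_table


@pytest.fixture(scope="session")
def small_world():
    """32x32 landscape, 120 species, 400 plots — fast, shared, read-only."""
    params = WorldParams(n_tips=120, n_rows=32, n_cols=32, n_plots=400)
    return generate_world(params, seed=11)


@pytest.fixture(scope="session")
def small_trait_table(small_world):
    records = generate_trait_records(
        small_world.trait_truth, small_world.taxonomy, seed=11
    )
    return build_trait_table(records)


@pytest.fixture(scope="session")
def small_community(small_world, small_trait_table):
    return community_table(small_world.plots, small_trait_table)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
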