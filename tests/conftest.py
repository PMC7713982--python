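"""Shared fixtures: all data is generated at test time, nothing is bundled."""

from __future__ import annotations

import numpy as np
import pytest

from sagehab.grid import GridLayer
from sagehab.pipeline import default_centroids
from sagehab.synthetic import (
    LandscapeConfig,
    build_predictor_sets,
    generate_landscape,
)


@pytest.fixture(scope="session")
def tiny_config() -> LandscapeConfig:
    """A small, fast landscape: 8x8 km at 100-m fine grain, 1-km grain."""
    return LandscapeConfig(extent=(0.0, 0.0, 8000.0, 8000.0), fine_cell=100.0,
                           coarse_cell=1000.0)


@pytest.fixture(scope="session")
def tiny_stack(tiny_config):
    return generate_landscape(tiny_config, seed=7)


@pytest.fixture(scope="session")
def tiny_psets(tiny_stack):
    return build_predictor_sets(tiny_stack, years=(2011, 2012), radius=2000.0)


@pytest.fixture(scope="session")
def tiny_centroids(tiny_stack):
    return default_centroids(tiny_stack.extent, 4)


@pytest.fixture(scope="session")
def study_stack():
    """Study-condition landscape (36x36 km) at a 60-m fine grain for speed."""
    cfg = LandscapeConfig(fine_cell=60.0)
    return generate_landscape(cfg, seed=1)


@pytest.fixture(scope="session")
def study_breeding_psets(study_stack):
    return build_predictor_sets(study_stack, seasons=("breeding",),
                                years=(2011, 2012))


def make_grid(values, cell=1.0, origin=(0.0, 0.0)) -> GridLayer:
    return GridLayer(np.asarray(values, dtype=float), cell, origin)
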