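"""Generator determinism, built-in covariate correlation, and known selection."""

import numpy as np
import pytest
from scipy.stats import chisquare

from sagehab.covariates import PredictorSet, ENV_PREDICTORS
from sagehab.grid import GridLayer
from sagehab.synthetic import (
    ConfigurationError,
    LandscapeConfig,
    SelectionTruth,
    cell_site_assignment,
    generate_landscape,
    locations_to_frame,
    read_stack,
    simulate_locations,
    truth_rss,
    write_stack,
)


def small_config(**kw):
    base = dict(extent=(0.0, 0.0, 6000.0, 6000.0), fine_cell=100.0,
                coarse_cell=500.0)
    base.update(kw)
    return LandscapeConfig(**base)


def test_identical_seed_and_config_reproduce_stack_exactly():
    cfg = small_config()
    a = generate_landscape(cfg, seed=1)
    b = generate_landscape(cfg, seed=1)
    for name in a.layers:
        np.testing.assert_array_equal(a.layers[name].values,
                                      b.layers[name].values)
    assert [g.wkt for g in a.towers] == [g.wkt for g in b.towers]
    assert [(y, g.wkt) for y, g in a.fires] == [(y, g.wkt) for y, g in b.fires]
    c = generate_landscape(cfg, seed=2)
    assert not np.array_equal(a.layers["elevation"].values,
                              c.layers["elevation"].values)


def test_zero_amplitude_gives_constant_elevation():
    cfg = small_config(elev_mean=1500.0, elev_amplitude=0.0)
    stack = generate_landscape(cfg, seed=3)
    np.testing.assert_array_equal(stack.layers["elevation"].values, 1500.0)


def test_temperature_declines_with_elevation_by_construction():
    stack = generate_landscape(small_config(), seed=4)
    rng = np.random.default_rng(0)
    elev = stack.layers["elevation"].values.ravel()
    tmax = stack.layers["tmax_m07"].values.ravel()
    idx = rng.choice(elev.size, size=min(10_000, elev.size), replace=False)
    assert np.corrcoef(elev[idx], tmax[idx])[0, 1] < 0


def test_invalid_config_rejected():
    with pytest.raises(ConfigurationError):
        small_config(extent=(0.0, 0.0, -10.0, 100.0))
    with pytest.raises(ConfigurationError):
        small_config(fine_cell=0.0)


def test_cover_shares_match_declared_proportions():
    cfg = small_config()
    stack = generate_landscape(cfg, seed=5)
    cover = stack.layers["cover_2012"].values
    n = cover.size
    for code, share in cfg.cover_proportions.items():
        got = (cover == code).mean()
        assert got == pytest.approx(share, abs=1.5 / np.sqrt(n) + 0.01)


# ------------------------------------------------------------- simulation
def test_record_counts_follow_design(tiny_stack, tiny_psets, tiny_centroids):
    truth = SelectionTruth.uniform_over_seasons(
        {"sagebrush": 1.0}, tiny_centroids, n_per_site_season_year=50)
    recs = simulate_locations(tiny_stack, truth, seed=2, years=(2011, 2012),
                              predictor_sets=tiny_psets)
    df = locations_to_frame(recs)
    vhf = df[df.source == "vhf"]
    assert len(vhf) == 50 * 4 * 3 * 2  # n x sites x seasons x years
    leks = df[df.source == "lek"]
    assert len(leks) == 4 * 2          # one lek per site, one record per year


def test_zero_selection_is_uniform_over_territory(tiny_stack, tiny_psets,
                                                  tiny_centroids):
    """With all coefficients zero the cell counts pass a chi-square GOF."""
    truth = SelectionTruth.uniform_over_seasons(
        {"sagebrush": 0.0}, tiny_centroids, n_per_site_season_year=2500)
    recs = simulate_locations(tiny_stack, truth, seasons=("summer",),
                              seed=3, years=(2011,), predictor_sets=tiny_psets)
    df = locations_to_frame(recs)
    grid = tiny_psets[("summer", 2011)].grid
    site_of_cell = cell_site_assignment(grid, tiny_centroids)
    sub = df[df.site == "site1"]
    rows, cols = grid.cell_index(sub.x.to_numpy(), sub.y.to_numpy())
    flat = rows * grid.ncols + cols
    cells = np.flatnonzero((site_of_cell == 0).ravel())
    counts = np.array([(flat == c).sum() for c in cells])
    assert counts.sum() == len(sub)
    p = chisquare(counts).pvalue
    assert p > 0.01


def test_positive_coefficient_shifts_used_mean_up(tiny_stack, tiny_psets,
                                                  tiny_centroids):
    """Monte-Carlo check of the selection-consistency invariant."""
    truth = SelectionTruth.uniform_over_seasons(
        {"sagebrush": 2.0}, tiny_centroids, n_per_site_season_year=500)
    recs = simulate_locations(tiny_stack, truth, seasons=("breeding",),
                              seed=4, years=(2011,), predictor_sets=tiny_psets)
    df = locations_to_frame(recs)
    pset = tiny_psets[("breeding", 2011)]
    layer = pset.layers["sagebrush"]
    used_mean = layer.sample(df.x.to_numpy(), df.y.to_numpy()).mean()
    territory_mean = layer.values[pset.valid_mask()].mean()
    assert used_mean > territory_mean


def test_centroid_outside_extent_rejected(tiny_stack):
    truth = SelectionTruth.uniform_over_seasons({"sagebrush": 1.0},
                                                [(1e6, 1e6)], 10)
    with pytest.raises(ConfigurationError, match="outside extent"):
        simulate_locations(tiny_stack, truth, seed=1)


# --------------------------------------------------------------- truth RSS
def constant_pset(layers: dict, season="breeding", year=2011, cell=1000.0):
    filled = {}
    shape = next(iter(layers.values())).shape if layers else (2, 2)
    for name in ENV_PREDICTORS:
        vals = layers.get(name, np.zeros(shape))
        filled[name] = GridLayer(np.asarray(vals, dtype=float), cell)
    return PredictorSet(season=season, year=year, layers=filled)


def test_truth_rss_is_one_under_zero_coefficients():
    pset = constant_pset({"sagebrush": np.full((3, 3), 0.4)})
    truth = SelectionTruth({"breeding": {"sagebrush": 0.0}}, [(1.0, 1.0)])
    surface = truth_rss(None, truth, "breeding", predictor_set=pset)
    np.testing.assert_allclose(surface.values, 1.0)


def test_truth_rss_closed_form_binary_covariate():
    """beta = ln 2 on a half-and-half 0/1 covariate gives {2^-0.5, 2^0.5}."""
    vals = np.array([[0.0, 1.0], [1.0, 0.0]])
    pset = constant_pset({"sagebrush": vals})
    truth = SelectionTruth({"breeding": {"sagebrush": np.log(2.0)}}, [(1.0, 1.0)])
    surface = truth_rss(None, truth, "breeding", predictor_set=pset)
    want = np.where(vals == 1.0, 2.0**0.5, 2.0**-0.5)
    np.testing.assert_allclose(surface.values, want, rtol=1e-12)


def test_truth_rss_is_one_at_mean_composition():
    vals = np.array([[0.2, 0.4], [0.6, 0.4]])  # mean 0.4 at two cells
    pset = constant_pset({"sagebrush": vals})
    truth = SelectionTruth({"breeding": {"sagebrush": 3.0}}, [(1.0, 1.0)])
    surface = truth_rss(None, truth, "breeding", predictor_set=pset)
    assert surface.values[0, 1] == pytest.approx(1.0)
    assert surface.values[1, 1] == pytest.approx(1.0)


# ---------------------------------------------------------------------- I/O
def test_stack_roundtrip_through_disk(tmp_path):
    cfg = small_config()
    stack = generate_landscape(cfg, seed=6)
    write_stack(stack, tmp_path / "land")
    back = read_stack(tmp_path / "land")
    assert set(back.layers) == set(stack.layers)
    np.testing.assert_allclose(back.layers["elevation"].values,
                               stack.layers["elevation"].values, rtol=1e-9)
    np.testing.assert_array_equal(back.layers["cover_2012"].values,
                                  stack.layers["cover_2012"].values)
    assert len(back.fires) == len(stack.fires)
    assert {k: len(v) for k, v in back.lines.items()} \
        == {k: len(v) for k, v in stack.lines.items()}
    assert back.config.extent == cfg.extent
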