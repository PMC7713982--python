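"""Geometric covariate operations against brute-force and closed-form oracles."""

import numpy as np
import pytest
from shapely.geometry import LineString, Point

from sagehab.covariates import (
    CoverCodeTable,
    burned_fraction,
    feature_density,
    focal_proportion,
    resample_to_grain,
    seasonal_climate,
    vector_ruggedness,
)
from sagehab.grid import GridLayer

from conftest import make_grid


# --------------------------------------------------------------- focal props
def brute_force_focal_proportion(values, codes, radius, cell):
    """Exhaustive per-cell double loop; cell-center-in-radius, inclusive."""
    nr, nc = values.shape
    out = np.zeros((nr, nc))
    for r in range(nr):
        for c in range(nc):
            n_in = n_valid = 0
            for rr in range(nr):
                for cc in range(nc):
                    d2 = ((rr - r) * cell) ** 2 + ((cc - c) * cell) ** 2
                    if d2 <= radius**2:
                        n_valid += 1
                        if values[rr, cc] in codes:
                            n_in += 1
            out[r, c] = n_in / n_valid
    return out


def test_focal_proportion_trivial_extremes():
    grid = GridLayer(np.full((9, 9), 3, dtype=int), cell=1.0)
    ones = focal_proportion(grid, {3}, radius=2.5)
    np.testing.assert_allclose(ones.values, 1.0, atol=1e-9)
    zeros = focal_proportion(grid, {4}, radius=2.5)
    np.testing.assert_allclose(zeros.values, 0.0, atol=1e-9)


def test_focal_proportion_matches_brute_force_oracle():
    rng = np.random.default_rng(11)
    values = rng.integers(0, 4, size=(21, 21))
    grid = GridLayer(values, cell=1.0)
    got = focal_proportion(grid, {1, 2}, radius=5.0)
    want = brute_force_focal_proportion(values, {1, 2}, 5.0, 1.0)
    np.testing.assert_allclose(got.values, want, atol=1e-7)


def test_focal_proportion_partition_closure():
    """Proportions over groups that partition all codes sum to 1 everywhere."""
    rng = np.random.default_rng(5)
    table = CoverCodeTable.default()
    values = rng.choice(list(table.codes), size=(15, 15))
    grid = GridLayer(values, cell=1.0)
    total = np.zeros((15, 15))
    for group in table.groups.values():
        total += focal_proportion(grid, group, radius=4.0).values
    np.testing.assert_allclose(total, 1.0, atol=1e-9)


def test_focal_proportion_rejects_empty_kernel():
    grid = GridLayer(np.zeros((5, 5)), cell=10.0)
    with pytest.raises(ValueError, match="kernel"):
        focal_proportion(grid, {1}, radius=3.0)


# ---------------------------------------------------------------- resampling
def test_resample_identity_and_constant():
    rng = np.random.default_rng(2)
    fine = GridLayer(rng.random((6, 6)), cell=10.0)
    same = resample_to_grain(fine, 10.0)
    np.testing.assert_array_equal(same.values, fine.values)
    const = GridLayer(np.full((6, 6), 4.2), cell=10.0)
    np.testing.assert_allclose(resample_to_grain(const, 30.0).values, 4.2)


def test_resample_4x4_to_2x2_hand_computed_tie_rule():
    # fine centers at 0.5,1.5,2.5,3.5; coarse centers at 1.0,3.0 -> exact
    # halfway ties resolve toward the lower index (north/west neighbor)
    fine = GridLayer(np.arange(16, dtype=float).reshape(4, 4), cell=1.0)
    coarse = resample_to_grain(fine, 2.0)
    np.testing.assert_array_equal(coarse.values, [[0.0, 2.0], [8.0, 10.0]])


# ------------------------------------------------------------------ density
def test_feature_density_trivial_and_closed_form():
    target = GridLayer(np.zeros((11, 11)), cell=1000.0)
    empty = feature_density([], radius=5000.0, target=target)
    np.testing.assert_array_equal(empty.values, 0.0)
    # horizontal line through the center cell's center: chord = diameter,
    # density = 2r / (pi r^2)
    line = LineString([(-50_000, 5500.0), (60_000, 5500.0)])
    dens = feature_density([line], radius=5000.0, target=target)
    want = (2 * 5000.0) / (np.pi * 5000.0**2)
    assert dens.values[5, 5] == pytest.approx(want, rel=1e-4)


def test_feature_density_linear_in_duplicated_features():
    rng = np.random.default_rng(9)
    target = GridLayer(np.zeros((5, 5)), cell=1000.0)
    lines = [LineString(rng.random((2, 2)) * 5000.0) for _ in range(4)]
    one = feature_density(lines, radius=2000.0, target=target)
    two = feature_density(lines + lines, radius=2000.0, target=target)
    np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-9)


def test_feature_density_matches_rasterized_length_oracle():
    """Clipped-length densities agree with dense point-sampling of the lines."""
    rng = np.random.default_rng(21)
    target = GridLayer(np.zeros((4, 4)), cell=1000.0)
    lines = [LineString(rng.random((3, 2)) * 4000.0) for _ in range(5)]
    radius = 1500.0
    got = feature_density(lines, radius, target)
    step = 0.5
    for (r, c) in [(0, 0), (1, 2), (3, 3)]:
        cx, cy = target.x_centers[c], target.y_centers[r]
        total = 0.0
        for line in lines:
            n = max(2, int(np.ceil(line.length / step)))
            ts = np.linspace(0.0, line.length, n)
            pts = np.array([line.interpolate(t).coords[0] for t in ts])
            inside = ((pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2) <= radius**2
            total += inside.mean() * line.length
        want = total / (np.pi * radius**2)
        assert got.values[r, c] == pytest.approx(want, rel=0.01, abs=1e-8)


def test_point_density_counts_within_radius():
    target = GridLayer(np.zeros((3, 3)), cell=1000.0)
    pts = [Point(1500.0, 1500.0), Point(1600.0, 1500.0), Point(10_000.0, 10_000.0)]
    dens = feature_density(pts, radius=500.0, target=target, kind="point")
    assert dens.values[1, 1] == pytest.approx(2 / (np.pi * 500.0**2))


# ---------------------------------------------------------------------- VRM
def brute_force_vrm(elevation: GridLayer, window: int) -> np.ndarray:
    """Independent vector-sum VRM: explicit Horn normals + window loops."""
    z = elevation.values
    cell = elevation.cell
    nr, nc = z.shape
    pad = np.pad(z, 1, mode="edge")
    nx = np.zeros_like(z)
    ny = np.zeros_like(z)
    nz = np.zeros_like(z)
    for r in range(nr):
        for c in range(nc):
            w = pad[r:r + 3, c:c + 3]
            dzdx = ((w[0, 2] + 2 * w[1, 2] + w[2, 2])
                    - (w[0, 0] + 2 * w[1, 0] + w[2, 0])) / (8 * cell)
            dzdy = ((w[0, 0] + 2 * w[0, 1] + w[0, 2])
                    - (w[2, 0] + 2 * w[2, 1] + w[2, 2])) / (8 * cell)
            slope = np.arctan(np.hypot(dzdx, dzdy))
            aspect = np.arctan2(dzdx, dzdy)
            nx[r, c] = np.sin(slope) * np.sin(aspect)
            ny[r, c] = np.sin(slope) * np.cos(aspect)
            nz[r, c] = np.cos(slope)
    half = window // 2
    out = np.zeros_like(z)
    for r in range(nr):
        for c in range(nc):
            r0, r1 = max(0, r - half), min(nr, r + half + 1)
            c0, c1 = max(0, c - half), min(nc, c + half + 1)
            n = (r1 - r0) * (c1 - c0)
            res = np.sqrt(nx[r0:r1, c0:c1].sum() ** 2
                          + ny[r0:r1, c0:c1].sum() ** 2
                          + nz[r0:r1, c0:c1].sum() ** 2)
            out[r, c] = 1.0 - res / n
    return out


@pytest.mark.parametrize("surface", ["flat", "inclined"])
def test_vrm_zero_on_planes(surface):
    x, y = np.meshgrid(np.arange(9.0), np.arange(9.0))
    z = np.zeros((9, 9)) if surface == "flat" else 3.0 * x + 1.5 * y
    vrm = vector_ruggedness(GridLayer(z, cell=1.0), window=3)
    # interior excludes two rings: one for the edge-padded gradient, one for
    # the 3x3 window that touches it
    np.testing.assert_allclose(vrm.values[2:-2, 2:-2], 0.0, atol=1e-12)


def test_vrm_matches_brute_force_on_bumpy_surface():
    rng = np.random.default_rng(4)
    z = rng.random((9, 9)) * 10.0
    layer = GridLayer(z, cell=1.0)
    got = vector_ruggedness(layer, window=3)
    want = brute_force_vrm(layer, 3)
    np.testing.assert_allclose(got.values, want, atol=1e-9)
    assert np.all(got.values >= 0.0) and np.all(got.values <= 1.0)


def test_vrm_monotone_under_added_roughness():
    rng = np.random.default_rng(8)
    base = rng.random((12, 12))
    rough = base + rng.random((12, 12)) * 5.0
    v_base = vector_ruggedness(GridLayer(base, cell=1.0)).values.mean()
    v_rough = vector_ruggedness(GridLayer(rough, cell=1.0)).values.mean()
    assert v_rough > v_base


def test_vrm_rejects_bad_window():
    layer = GridLayer(np.zeros((5, 5)), cell=1.0)
    for bad in (2, 4, 1):
        with pytest.raises(ValueError):
            vector_ruggedness(layer, window=bad)


# --------------------------------------------------------------- burned area
def test_burned_fraction_window_and_lag():
    target = GridLayer(np.zeros((3, 3)), cell=1000.0)
    fire = (2010, Point(1500.0, 1500.0).buffer(800.0))
    # same-year query excluded by the one-year lag
    same = burned_fraction([fire], query_year=2010, radius=1000.0, target=target)
    np.testing.assert_array_equal(same.values, 0.0)
    after = burned_fraction([fire], query_year=2011, radius=1000.0, target=target)
    assert after.values[1, 1] > 0.0
    # 20-year window: a fire 21 years back no longer counts
    old = burned_fraction([fire], query_year=2031, radius=1000.0, target=target)
    np.testing.assert_array_equal(old.values, 0.0)
    edge = burned_fraction([fire], query_year=2030, radius=1000.0, target=target)
    assert edge.values[1, 1] > 0.0


def test_burned_fraction_half_circle_geometry():
    # a huge burned half-plane east of the center cell covers half the circle
    target = GridLayer(np.zeros((3, 3)), cell=1000.0)
    from shapely.geometry import box

    half_plane = box(1500.0, -1e6, 1e6, 1e6)
    frac = burned_fraction([(2000, half_plane)], query_year=2001,
                           radius=1000.0, target=target)
    assert frac.values[1, 1] == pytest.approx(0.5, abs=0.005)


# ------------------------------------------------------------------- climate
def month_grids(values_by_month, shape=(2, 2), cell=1000.0):
    return {m: make_grid(np.full(shape, v), cell) for m, v in values_by_month.items()}


def test_seasonal_climate_means_and_month_lists():
    monthly = {"precipitation": month_grids({m: float(m) for m in range(1, 13)})}
    breeding = seasonal_climate(monthly, "breeding")["precipitation"]
    np.testing.assert_allclose(breeding.values, 4.5)  # (4+5)/2
    summer = seasonal_climate(monthly, "summer")["precipitation"]
    np.testing.assert_allclose(summer.values, 7.0)
    winter = seasonal_climate(monthly, "winter")["precipitation"]
    np.testing.assert_allclose(winter.values, (11 + 12 + 1 + 2 + 3) / 5)


def test_winter_sensitive_to_november_not_october():
    base = {m: 1.0 for m in range(1, 13)}
    ref = seasonal_climate({"tmin": month_grids(base)}, "winter")["tmin"].values
    oct_bump = {**base, 10: 100.0}
    nov_bump = {**base, 11: 100.0}
    same = seasonal_climate({"tmin": month_grids(oct_bump)}, "winter")["tmin"].values
    diff = seasonal_climate({"tmin": month_grids(nov_bump)}, "winter")["tmin"].values
    np.testing.assert_array_equal(same, ref)
    assert np.all(diff != ref)


def test_seasonal_climate_names_missing_month():
    grids = month_grids({m: 1.0 for m in range(1, 13) if m != 5})
    with pytest.raises(ValueError, match="5"):
        seasonal_climate({"tmax": grids}, "breeding")
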