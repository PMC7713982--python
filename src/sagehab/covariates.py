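"""Environmental predictor surfaces at the modeling grain.

Second-order habitat selection is analyzed at a 1-km grain, but selection is
assumed to respond to the landscape *context* around each cell, so land-cover
proportions, burned area, and infrastructure densities are summarized inside a
5-km-radius circular neighborhood before being resampled to the coarse grid.

The 24 environmental predictors:

* land cover proportions (5-km focal): sagebrush (pooled over the four
  sagebrush community types), agriculture, conifer, developed, grassland,
  riparian;
* topography: elevation, slope, vector ruggedness (VRM);
* soils: clay, silt, sand, available water capacity, salinity, soil depth;
* climate (seasonal means of monthly 30-year normals): precipitation,
  minimum temperature, maximum temperature;
* disturbance: fraction burned in the previous 20 years (one-year lag);
  line densities for secondary roads, highways, powerlines, pipelines, and
  point density for communication towers (all 5-km radius).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from shapely.geometry import Point
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .grid import GridLayer, assert_aligned

#: calendar months averaged for each season's climate normals
SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "breeding": (4, 5),
    "summer": (6, 7, 8),
    "winter": (11, 12, 1, 2, 3),
}

SEASONS = ("breeding", "summer", "winter")

#: canonical order of the 24 environmental predictors
ENV_PREDICTORS: tuple[str, ...] = (
    "sagebrush", "agriculture", "conifer", "developed", "grassland", "riparian",
    "elevation", "slope", "ruggedness",
    "clay", "silt", "sand", "awc", "salinity", "soil_depth",
    "precipitation", "tmin", "tmax",
    "burned",
    "road_secondary", "highway", "powerline", "pipeline", "tower",
)

COVER_CLASSES = ("sagebrush", "agriculture", "conifer", "developed",
                 "grassland", "riparian")

LINE_FEATURES = ("road_secondary", "highway", "powerline", "pipeline")


@dataclass
class CoverCodeTable:
    """Categorical land-cover code registry with named class groups.

    ``groups`` maps a class-group name (e.g. ``"sagebrush"``) to the set of
    raster codes pooled into it — the sagebrush group is the union of the four
    sagebrush community types.
    """

    codes: dict[int, str]
    groups: dict[str, frozenset[int]]

    def __post_init__(self) -> None:
        for name, members in self.groups.items():
            unknown = set(members) - set(self.codes)
            if unknown:
                raise ValueError(f"group {name!r} references unknown codes {unknown}")

    @classmethod
    def default(cls) -> "CoverCodeTable":
        """Code table mirroring the pooled land-cover classes used for modeling."""
        codes = {
            0: "other",
            1: "big_sagebrush_shrubland",
            2: "big_sagebrush_steppe",
            3: "low_sagebrush",
            4: "mountain_sagebrush",
            5: "agriculture",
            6: "conifer",
            7: "developed",
            8: "grassland",
            9: "riparian",
        }
        groups = {
            "sagebrush": frozenset({1, 2, 3, 4}),
            "agriculture": frozenset({5}),
            "conifer": frozenset({6}),
            "developed": frozenset({7}),
            "grassland": frozenset({8}),
            "riparian": frozenset({9}),
            "other": frozenset({0}),
        }
        return cls(codes, groups)


@dataclass
class PredictorSet:
    """The 24 aligned environmental predictor layers for one season.

    ``layers`` maps each name in :data:`ENV_PREDICTORS` to a coarse-grain
    :class:`GridLayer`.  Cover and burned-area layers correspond to ``year``
    (epoch lookup / 20-year burn window); climate layers are the season's
    means.
    """

    season: str
    year: int
    layers: dict[str, GridLayer]

    def __post_init__(self) -> None:
        missing = set(ENV_PREDICTORS) - set(self.layers)
        if missing:
            raise ValueError(f"missing predictor layers: {sorted(missing)}")
        assert_aligned(self.layers)

    @property
    def grid(self) -> GridLayer:
        return self.layers[ENV_PREDICTORS[0]]

    def valid_mask(self) -> np.ndarray:
        mask = np.ones(self.grid.values.shape, dtype=bool)
        for layer in self.layers.values():
            mask &= layer.valid_mask()
        return mask

    def matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(n_cells, 24) matrix of predictor values over ``mask`` cells."""
        if mask is None:
            mask = self.valid_mask()
        return np.column_stack(
            [self.layers[name].values[mask] for name in ENV_PREDICTORS]
        )

    def means(self) -> dict[str, float]:
        mask = self.valid_mask()
        return {
            name: float(np.mean(self.layers[name].values[mask]))
            for name in ENV_PREDICTORS
        }


# --------------------------------------------------------------------------- #
# focal / kernel operations
# --------------------------------------------------------------------------- #

def _circular_kernel(radius: float, cell: float) -> np.ndarray:
    """Binary kernel of cell offsets whose centers lie within ``radius`` (<=)."""
    if radius < cell / 2:
        raise ValueError("radius smaller than half a cell: empty kernel")
    r_cells = int(np.floor(radius / cell))
    offs = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return ((dy * cell) ** 2 + (dx * cell) ** 2 <= radius**2).astype(float)


def _focal_sum(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    out = signal.fftconvolve(values, kernel, mode="same")
    # convolution of counts: clean tiny FFT noise
    return np.where(np.abs(out) < 1e-9, 0.0, out)


def focal_proportion(
    class_grid: GridLayer, codes: frozenset[int] | set[int], radius: float
) -> GridLayer:
    """Fraction of valid cells within ``radius`` whose code is in ``codes``.

    Neighborhood membership is cell-center-in-circle (inclusive).  Nodata
    cells are excluded from numerator and denominator; kernels truncate at
    the grid edge (valid-cell denominator).
    """
    kernel = _circular_kernel(radius, class_grid.cell)
    valid = class_grid.valid_mask()
    inset = np.isin(class_grid.values, list(codes)) & valid
    num = _focal_sum(inset.astype(float), kernel)
    den = _focal_sum(valid.astype(float), kernel)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.clip(num / den, 0.0, 1.0)
    frac[den == 0] = np.nan
    return GridLayer(frac, class_grid.cell, class_grid.origin)


def resample_to_grain(fine: GridLayer, coarse_cell: float) -> GridLayer:
    """Nearest-neighbor resample: each coarse cell takes the fine value whose
    center is nearest the coarse cell center (ties toward the lower index)."""
    if coarse_cell <= 0:
        raise ValueError("coarse_cell must be positive")
    xmin, ymin, xmax, ymax = fine.extent
    ncols = max(1, int(np.ceil((xmax - xmin) / coarse_cell - 1e-9)))
    nrows = max(1, int(np.ceil((ymax - ymin) / coarse_cell - 1e-9)))
    cx = xmin + (np.arange(ncols) + 0.5) * coarse_cell
    cy_top = ymax - (np.arange(nrows) + 0.5) * coarse_cell  # row 0 = north
    # nearest fine center along each axis; exact halfway ties -> lower index
    tx = (cx - xmin) / fine.cell - 0.5
    ty = (ymax - cy_top) / fine.cell - 0.5
    j = np.clip(np.ceil(tx - 0.5).astype(int), 0, fine.ncols - 1)
    i = np.clip(np.ceil(ty - 0.5).astype(int), 0, fine.nrows - 1)
    values = fine.values[np.ix_(i, j)]
    return GridLayer(values.copy(), coarse_cell, (xmin, ymax - nrows * coarse_cell),
                     fine.nodata)


def feature_density(
    features, radius: float, target: GridLayer, kind: str = "line"
) -> GridLayer:
    """Magnitude-per-unit-area of vector features around each cell center.

    For ``kind="line"``: total length of line features clipped to the circle
    of ``radius`` around the cell center, divided by the circle area (m/m^2).
    For ``kind="point"``: count of points within the circle per unit area.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    geoms = list(features)
    area = np.pi * radius**2
    out = np.zeros(target.values.shape, dtype=float)
    if not geoms:
        return target.like(out)
    tree = STRtree(geoms)
    xg, yg = target.center_meshgrid()
    for (r, c) in np.ndindex(out.shape):
        center = Point(xg[r, c], yg[r, c])
        if kind == "point":
            idx = tree.query(center.buffer(radius))
            n = sum(1 for k in idx if geoms[k].distance(center) <= radius)
            out[r, c] = n / area
        else:
            circle = center.buffer(radius, quad_segs=64)
            idx = tree.query(circle)
            total = sum(geoms[k].intersection(circle).length for k in idx)
            out[r, c] = total / area
    return target.like(out)


def slope_from_elevation(elevation: GridLayer) -> GridLayer:
    """Slope in degrees from a DEM by Horn's 3x3 finite-difference method."""
    z = elevation.values.astype(float)
    c = elevation.cell
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8 * c)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float) / (8 * c)
    dzdx = ndimage.convolve(z, kx[:, ::-1], mode="nearest")
    dzdy = ndimage.convolve(z, ky[::-1, :], mode="nearest")
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return elevation.like(slope)


def _surface_normals(elevation: GridLayer) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    z = elevation.values.astype(float)
    c = elevation.cell
    kx = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float) / (8 * c)
    ky = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float) / (8 * c)
    dzdx = ndimage.convolve(z, kx[:, ::-1], mode="nearest")
    dzdy = ndimage.convolve(z, ky[::-1, :], mode="nearest")
    slope = np.arctan(np.hypot(dzdx, dzdy))
    aspect = np.arctan2(dzdx, dzdy)
    nx = np.sin(slope) * np.sin(aspect)
    ny = np.sin(slope) * np.cos(aspect)
    nz = np.cos(slope)
    return nx, ny, nz


def vector_ruggedness(elevation: GridLayer, window: int = 3) -> GridLayer:
    """Vector ruggedness measure (VRM) in [0, 1] over a square moving window.

    Each cell's unit surface normal is decomposed into (x, y, z); the VRM of a
    window of n cells is ``1 - ||sum of normals|| / n``: 0 on any plane
    (parallel normals), approaching 1 as orientations disperse.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    nx, ny, nz = _surface_normals(elevation)
    size = (window, window)

    def wsum(a: np.ndarray) -> np.ndarray:
        return ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0) * window**2

    count = wsum(np.ones_like(nx))
    resultant = np.sqrt(wsum(nx) ** 2 + wsum(ny) ** 2 + wsum(nz) ** 2)
    vrm = np.clip(1.0 - resultant / count, 0.0, 1.0)
    return elevation.like(vrm)


def burned_fraction(
    fires: list[tuple[int, object]],
    query_year: int,
    radius: float,
    target: GridLayer,
    window_years: int = 20,
) -> GridLayer:
    """Fraction of the circular neighborhood burned in the window
    ``[query_year - window_years, query_year - 1]``.

    The one-year lag excludes the query year itself (fires mostly occur in
    late summer, after that year's locations).  ``fires`` is a list of
    ``(year, polygon)`` pairs; overlapping perimeters are unioned so area is
    not double-counted.
    """
    in_window = [geom for (year, geom) in fires
                 if query_year - window_years <= year <= query_year - 1]
    out = np.zeros(target.values.shape, dtype=float)
    if not in_window:
        return target.like(out)
    burned = unary_union(in_window)
    circle_area = np.pi * radius**2
    xg, yg = target.center_meshgrid()
    for (r, c) in np.ndindex(out.shape):
        circle = Point(xg[r, c], yg[r, c]).buffer(radius, quad_segs=64)
        out[r, c] = circle.intersection(burned).area / circle_area
    return target.like(np.clip(out, 0.0, 1.0))


def seasonal_climate(
    monthly: dict[str, dict[int, GridLayer]], season: str
) -> dict[str, GridLayer]:
    """Cellwise seasonal means of monthly climate normals.

    ``monthly`` maps variable name (``precipitation``/``tmin``/``tmax``) to a
    {month: GridLayer} mapping with all 12 months present.
    """
    months = SEASON_MONTHS.get(season)
    if months is None:
        raise ValueError(f"unknown season {season!r}")
    out = {}
    for var, grids in monthly.items():
        missing = [m for m in months if m not in grids]
        if missing:
            raise ValueError(f"{var}: missing month(s) {missing} for {season}")
        stack = np.stack([grids[m].values for m in months])
        ref = grids[months[0]]
        out[var] = ref.like(stack.mean(axis=0))
    return out


def write_predictor_sets(psets: dict[tuple[str, int], PredictorSet], out_dir) -> None:
    """One .asc per predictor layer under ``<season>_<year>/`` plus a manifest
    JSON mapping layer name to file."""
    import json
    import os

    manifest: dict[str, dict[str, str]] = {}
    for (season, year), pset in psets.items():
        key = f"{season}_{year}"
        sub = os.path.join(out_dir, key)
        os.makedirs(sub, exist_ok=True)
        manifest[key] = {}
        for name, layer in pset.layers.items():
            rel = os.path.join(key, f"{name}.asc")
            layer.write_ascii(os.path.join(out_dir, rel))
            manifest[key][name] = rel
    with open(os.path.join(out_dir, "predictors_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def read_predictor_sets(in_dir) -> dict[tuple[str, int], PredictorSet]:
    import json
    import os

    with open(os.path.join(in_dir, "predictors_manifest.json")) as fh:
        manifest = json.load(fh)
    out = {}
    for key, files in manifest.items():
        season, year = key.rsplit("_", 1)
        layers = {name: GridLayer.read_ascii(os.path.join(in_dir, rel))
                  for name, rel in files.items()}
        out[(season, int(year))] = PredictorSet(season=season, year=int(year),
                                                layers=layers)
    return out


def epoch_for_year(year: int, epochs: list[int]) -> int:
    """Most recent cover epoch <= year; years before the first use the first."""
    if not epochs:
        raise ValueError("no epochs declared")
    eligible = [e for e in sorted(epochs) if e <= year]
    return eligible[-1] if eligible else min(epochs)
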