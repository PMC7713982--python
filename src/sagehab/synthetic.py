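"""Synthetic landscapes and location data with known selection structure.

The study system this package targets — multi-year VHF telemetry and lek
surveys of greater sage-grouse over a heterogeneous sagebrush landscape — is
built from legally protected location data, so the pipeline ships with a
generator that emulates its essential structure: a raster stack of correlated
environmental fields (elevation-driven climate, categorical land cover per
epoch, soils, infrastructure lines, fire perimeters with years), K discrete
population sites, and used points drawn with *known* log-linear selection
(weight ``exp(sum beta_p * x_p)`` over each site's territory).  Because the
selection coefficients are known, downstream estimates (variable importance,
response curves, RSS surfaces) can be checked against analytic truth.

Territories are the Voronoi cells of the site centroids clipped to the
landscape extent — the same site definition the analysis side uses, so the
simulated site labels coincide with recovered ones.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, Point, mapping, shape

from .grid import GridLayer
from .covariates import (
    COVER_CLASSES,
    ENV_PREDICTORS,
    LINE_FEATURES,
    SEASONS,
    CoverCodeTable,
    PredictorSet,
    burned_fraction,
    epoch_for_year,
    feature_density,
    focal_proportion,
    resample_to_grain,
    seasonal_climate,
    slope_from_elevation,
    vector_ruggedness,
)

CLIMATE_VARS = ("precipitation", "tmin", "tmax")


class ConfigurationError(ValueError):
    """Invalid landscape or simulation configuration."""


class SimulationError(RuntimeError):
    """Location simulation failed (e.g. a site with no valid territory)."""


@dataclass
class LandscapeConfig:
    """Knobs of the synthetic landscape generator.

    Defaults emulate a discontinuous high-elevation sagebrush landscape:
    30-m fine grain (land-cover / DEM resolution), 1-km modeling grain,
    ~2-km autocorrelation length for the random fields, temperature
    decreasing and precipitation increasing with elevation.
    """

    extent: tuple[float, float, float, float] = (0.0, 0.0, 36_000.0, 36_000.0)
    fine_cell: float = 30.0
    coarse_cell: float = 1000.0
    smoothness_m: float = 2000.0          # autocorrelation length of random fields
    elev_mean: float = 2000.0             # m
    elev_amplitude: float = 600.0         # m; 0 => flat landscape
    lapse_rate: float = 6.5               # degC per km of elevation
    orographic_mm_per_km: float = 25.0    # monthly precip gain per km elevation
    cover_epochs: tuple[int, ...] = (2001, 2008, 2010, 2012)
    #: target landscape share per cover code (see CoverCodeTable.default)
    cover_proportions: dict[int, float] = field(default_factory=lambda: {
        0: 0.30,  # other
        1: 0.12, 2: 0.10, 3: 0.07, 4: 0.06,  # sagebrush types (0.35 pooled)
        5: 0.06,  # agriculture
        6: 0.12,  # conifer
        7: 0.03,  # developed
        8: 0.10,  # grassland
        9: 0.04,  # riparian
    })
    n_lines: dict[str, int] = field(default_factory=lambda: {
        "road_secondary": 8, "highway": 2, "powerline": 3, "pipeline": 2,
    })
    n_towers: int = 12
    n_fires: int = 6
    fire_year_range: tuple[int, int] = (1992, 2011)
    fire_radius_m: tuple[float, float] = (800.0, 2500.0)

    def __post_init__(self) -> None:
        xmin, ymin, xmax, ymax = self.extent
        if xmax <= xmin or ymax <= ymin:
            raise ConfigurationError("extent must have positive width and height")
        if self.fine_cell <= 0 or self.coarse_cell <= 0:
            raise ConfigurationError("cell sizes must be positive")
        total = sum(self.cover_proportions.values())
        if not np.isclose(total, 1.0):
            raise ConfigurationError(f"cover proportions sum to {total}, expected 1")


@dataclass
class LandscapeStack:
    """Aligned raster layers plus vector features for one synthetic landscape.

    ``layers`` holds fine-grain grids: ``elevation``, ``slope``,
    ``cover_<epoch>`` (categorical codes), six soil properties, and 36 monthly
    climate normals named ``<var>_m<month>``.  ``lines``/``towers`` are
    shapely geometries; ``fires`` is a list of ``(year, polygon)``.
    """

    config: LandscapeConfig
    seed: int
    layers: dict[str, GridLayer]
    lines: dict[str, list[LineString]]
    towers: list[Point]
    fires: list[tuple[int, object]]
    cover_table: CoverCodeTable = field(default_factory=CoverCodeTable.default)

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return self.config.extent

    def monthly_climate(self) -> dict[str, dict[int, GridLayer]]:
        return {
            var: {m: self.layers[f"{var}_m{m:02d}"] for m in range(1, 13)}
            for var in CLIMATE_VARS
        }


SOIL_FIELDS = {
    # name: (mean, amplitude, low clip, high clip)
    "clay": (22.0, 8.0, 2.0, 55.0),        # percent
    "silt": (32.0, 9.0, 5.0, 65.0),        # percent
    "sand": (42.0, 12.0, 5.0, 85.0),       # percent
    "awc": (0.12, 0.04, 0.02, 0.25),       # cm water / cm soil
    "salinity": (1.0, 1.0, 0.0, 8.0),      # dS/m
    "soil_depth": (90.0, 35.0, 10.0, 200.0),  # cm
}

def _smooth_unit_field(rng: np.random.Generator, shape, sigma_cells: float) -> np.ndarray:
    """Kernel-smoothed white noise rescaled to zero mean, unit variance."""
    noise = rng.standard_normal(shape)
    if sigma_cells <= 0:
        f = noise
    else:
        f = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = f.std()
    if sd == 0:
        return np.zeros(shape)
    return (f - f.mean()) / sd


def _classify_cover(fields: dict[int, np.ndarray],
                    proportions: dict[int, float],
                    background: int = 0) -> np.ndarray:
    """Assign cover codes from per-class smooth fields at exact target shares.

    Classes are claimed sequentially: each class takes the still-unassigned
    cells where its own field is highest, up to its target count; the
    background class receives the remainder.  Each class's patches follow an
    independent field, so pairwise correlations between cover types arise
    only through mutual exclusion — not from a shared gradient.
    """
    codes = [c for c in sorted(proportions) if c != background
             and proportions.get(c, 0) > 0]
    shape = next(iter(fields.values())).shape
    n_total = int(np.prod(shape))
    out = np.full(n_total, background, dtype=np.int16)
    unassigned = np.ones(n_total, dtype=bool)
    for c in codes:
        want = int(round(proportions[c] * n_total))
        if want <= 0:
            continue
        cand = np.flatnonzero(unassigned)
        vals = fields[c].ravel()[cand]
        take = cand[np.argsort(-vals, kind="stable")[:want]]
        out[take] = c
        unassigned[take] = False
    return out.reshape(shape)


def generate_landscape(config: LandscapeConfig, seed: int) -> LandscapeStack:
    """Build a reproducible synthetic landscape stack.

    Elevation is a smooth Gaussian random field; monthly temperature declines
    with elevation (lapse rate) and precipitation rises with it (orographic
    effect), each plus smooth noise, so the realistic covariate correlation
    structure of mountain landscapes is present.  Cover classes are quantile
    regions of an independent smooth field, re-perturbed per epoch; lines,
    towers, and fire perimeters are random vector features.  Identical
    ``(config, seed)`` give identical output.
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = config.extent
    ncols = int(round((xmax - xmin) / config.fine_cell))
    nrows = int(round((ymax - ymin) / config.fine_cell))
    shape = (nrows, ncols)
    sigma = config.smoothness_m / config.fine_cell
    origin = (xmin, ymin)

    def make(values: np.ndarray) -> GridLayer:
        return GridLayer(values, config.fine_cell, origin)

    layers: dict[str, GridLayer] = {}

    elev = config.elev_mean + config.elev_amplitude * _smooth_unit_field(rng, shape, sigma)
    layers["elevation"] = make(elev)
    layers["slope"] = slope_from_elevation(layers["elevation"])

    # land cover: one base field per class, small epoch-specific perturbation
    class_codes = [c for c in sorted(config.cover_proportions) if c != 0]
    base_fields = {c: _smooth_unit_field(rng, shape, sigma) for c in class_codes}
    for epoch in config.cover_epochs:
        fields = {c: base_fields[c] + 0.15 * _smooth_unit_field(rng, shape, sigma)
                  for c in class_codes}
        codes = _classify_cover(fields, config.cover_proportions)
        layers[f"cover_{epoch}"] = make(codes)

    for name, (mean, amp, lo, hi) in SOIL_FIELDS.items():
        vals = np.clip(mean + amp * _smooth_unit_field(rng, shape, sigma), lo, hi)
        layers[name] = make(vals)

    # monthly climate normals driven by elevation + smooth noise
    elev_km = (elev - config.elev_mean) / 1000.0
    for m in range(1, 13):
        cyc = np.cos(2 * np.pi * (m - 7) / 12.0)  # +1 in July, -1 in January
        tmax = 13.0 + 14.0 * cyc - config.lapse_rate * elev_km \
            + 0.8 * _smooth_unit_field(rng, shape, sigma)
        tmin = tmax - 14.0 + 1.5 * cyc + 0.8 * _smooth_unit_field(rng, shape, sigma)
        precip = (28.0 - 8.0 * cyc + config.orographic_mm_per_km * elev_km
                  + 3.0 * _smooth_unit_field(rng, shape, sigma))
        layers[f"tmax_m{m:02d}"] = make(tmax)
        layers[f"tmin_m{m:02d}"] = make(tmin)
        layers[f"precipitation_m{m:02d}"] = make(np.clip(precip, 0.0, None))

    # linear infrastructure: jittered straight transects
    lines: dict[str, list[LineString]] = {}
    width, height = xmax - xmin, ymax - ymin
    for feature in LINE_FEATURES:
        geoms = []
        for _ in range(config.n_lines.get(feature, 0)):
            x0 = xmin + width * rng.random()
            y0 = ymin + height * rng.random()
            angle = rng.random() * np.pi
            length = 0.6 * max(width, height) * (0.5 + rng.random())
            n_seg = 4
            ts = np.linspace(-0.5, 0.5, n_seg + 1)
            xs = x0 + length * ts * np.cos(angle) + 300 * rng.standard_normal(n_seg + 1)
            ys = y0 + length * ts * np.sin(angle) + 300 * rng.standard_normal(n_seg + 1)
            geoms.append(LineString(np.column_stack([xs, ys])))
        lines[feature] = geoms

    towers = [Point(xmin + width * rng.random(), ymin + height * rng.random())
              for _ in range(config.n_towers)]

    fires: list[tuple[int, object]] = []
    y_lo, y_hi = config.fire_year_range
    r_lo, r_hi = config.fire_radius_m
    for _ in range(config.n_fires):
        year = int(rng.integers(y_lo, y_hi + 1))
        cx = xmin + width * rng.random()
        cy = ymin + height * rng.random()
        radius = r_lo + (r_hi - r_lo) * rng.random()
        fires.append((year, Point(cx, cy).buffer(radius, quad_segs=32)))

    return LandscapeStack(config=config, seed=seed, layers=layers,
                          lines=lines, towers=towers, fires=fires)


# --------------------------------------------------------------------------- #
# predictor construction at the modeling grain
# --------------------------------------------------------------------------- #

def build_predictor_sets(
    stack: LandscapeStack,
    seasons=SEASONS,
    years=(2011, 2012),
    radius: float = 5000.0,
    vrm_window: int = 3,
    fire_window_years: int = 20,
) -> dict[tuple[str, int], PredictorSet]:
    """Compute the 24 environmental predictor layers for every (season, year).

    Shared surfaces (topography, soils, densities, per-epoch cover
    proportions) are computed once and reused across combinations.
    """
    cfg = stack.config
    coarse = cfg.coarse_cell

    def to_coarse(layer: GridLayer) -> GridLayer:
        return resample_to_grain(layer, coarse)

    static: dict[str, GridLayer] = {}
    static["elevation"] = to_coarse(stack.layers["elevation"])
    static["slope"] = to_coarse(stack.layers["slope"])
    static["ruggedness"] = to_coarse(vector_ruggedness(stack.layers["elevation"],
                                                       vrm_window))
    for soil in ("clay", "silt", "sand", "awc", "salinity", "soil_depth"):
        static[soil] = to_coarse(stack.layers[soil])

    target = static["elevation"]
    for feature in LINE_FEATURES:
        static[feature] = feature_density(stack.lines[feature], radius, target,
                                          kind="line")
    static["tower"] = feature_density(stack.towers, radius, target, kind="point")

    # focal cover proportions per epoch actually needed
    needed_epochs = sorted({epoch_for_year(y, list(cfg.cover_epochs)) for y in years})
    cover_by_epoch: dict[int, dict[str, GridLayer]] = {}
    for epoch in needed_epochs:
        grid = stack.layers[f"cover_{epoch}"]
        cover_by_epoch[epoch] = {
            cls: to_coarse(focal_proportion(grid, stack.cover_table.groups[cls],
                                            radius))
            for cls in COVER_CLASSES
        }

    monthly = stack.monthly_climate()
    climate_by_season = {
        s: {var: to_coarse(g) for var, g in seasonal_climate(monthly, s).items()}
        for s in seasons
    }

    burned_by_year = {
        y: burned_fraction(stack.fires, y, radius, target,
                           window_years=fire_window_years)
        for y in years
    }

    out: dict[tuple[str, int], PredictorSet] = {}
    for season in seasons:
        for year in years:
            epoch = epoch_for_year(year, list(cfg.cover_epochs))
            layers = dict(static)
            layers.update(cover_by_epoch[epoch])
            layers.update(climate_by_season[season])
            layers["burned"] = burned_by_year[year]
            out[(season, year)] = PredictorSet(season=season, year=year,
                                               layers=layers)
    return out


# --------------------------------------------------------------------------- #
# selection truth and location simulation
# --------------------------------------------------------------------------- #

@dataclass
class SelectionTruth:
    """Known log-linear selection weights and the sampling frame.

    ``coefficients`` maps season -> {predictor: beta}; used points within a
    site's territory are drawn with probability proportional to
    ``exp(sum beta_p * x_p)`` over candidate cells (raw predictor scale, so
    coefficients must match predictor units).
    """

    coefficients: dict[str, dict[str, float]]
    site_centroids: list[tuple[float, float]]
    n_per_site_season_year: int = 50

    def __post_init__(self) -> None:
        nonzero = any(abs(b) > 0 for season in self.coefficients.values()
                      for b in season.values())
        if not nonzero and self.coefficients:
            # all-zero truth is legal (null model) but flagged via attribute
            pass
        for season, coefs in self.coefficients.items():
            unknown = set(coefs) - set(ENV_PREDICTORS)
            if unknown:
                raise ConfigurationError(
                    f"{season}: unknown predictors {sorted(unknown)}")
        if not self.site_centroids:
            raise ConfigurationError("at least one site centroid required")

    @classmethod
    def uniform_over_seasons(cls, coefs: dict[str, float],
                             site_centroids, n_per_site_season_year=50
                             ) -> "SelectionTruth":
        return cls({s: dict(coefs) for s in SEASONS}, list(site_centroids),
                   n_per_site_season_year)

    def validate_against(self, config: LandscapeConfig) -> None:
        xmin, ymin, xmax, ymax = config.extent
        for (x, y) in self.site_centroids:
            if not (xmin <= x <= xmax and ymin <= y <= ymax):
                raise ConfigurationError(f"centroid ({x}, {y}) outside extent")


@dataclass
class LocationRecord:
    """One used point: telemetry fix or lek record."""

    id: int
    x: float
    y: float
    date: dt.date
    source: str          # "vhf" | "lek"
    site: str


SEASON_WINDOW_DAYS = {
    # (start month, start day), (end month, end day); winter spans new year
    "breeding": ((4, 1), (5, 31)),
    "summer": ((6, 1), (8, 31)),
    "winter": ((11, 15), (3, 15)),
}


def season_date_range(season: str, year: int) -> tuple[dt.date, dt.date]:
    """Inclusive date window of ``season`` in the year labeled ``year``.

    Winter is labeled by the calendar year of its start (Nov 15 of ``year``
    through Mar 15 of ``year + 1``).
    """
    (m0, d0), (m1, d1) = SEASON_WINDOW_DAYS[season]
    start = dt.date(year, m0, d0)
    end = dt.date(year + 1 if season == "winter" else year, m1, d1)
    return start, end


def site_labels(n: int) -> list[str]:
    return [f"site{i + 1}" for i in range(n)]


def cell_site_assignment(grid: GridLayer, centroids) -> np.ndarray:
    """Index of the nearest centroid per cell (Voronoi territories); ties to
    the lowest centroid index."""
    xg, yg = grid.center_meshgrid()
    cent = np.asarray(centroids, dtype=float)
    d2 = (xg[..., None] - cent[:, 0]) ** 2 + (yg[..., None] - cent[:, 1]) ** 2
    return np.argmin(d2, axis=-1)


def simulate_locations(
    stack: LandscapeStack,
    truth: SelectionTruth,
    seasons=SEASONS,
    seed: int = 0,
    years=(2011, 2012),
    predictor_sets: dict[tuple[str, int], PredictorSet] | None = None,
    leks_per_site: int = 1,
    lek_records_per_year: int = 1,
) -> list[LocationRecord]:
    """Draw used points with the known selection structure.

    Within each site's Voronoi territory, cells are sampled with probability
    proportional to ``exp(sum beta * x)`` for that season and year, and the
    point is placed uniformly inside the chosen 1-km cell.  Dates are uniform
    within the season window.  Lek points sit at each site's top-1% breeding
    selection cells (``leks_per_site`` of them) and are recorded
    ``lek_records_per_year`` times per year with breeding-window dates.
    """
    truth.validate_against(stack.config)
    if predictor_sets is None:
        predictor_sets = build_predictor_sets(stack, seasons=seasons, years=years)
    rng = np.random.default_rng(seed)
    grid = next(iter(predictor_sets.values())).grid
    sites = site_labels(len(truth.site_centroids))
    site_of_cell = cell_site_assignment(grid, truth.site_centroids)

    records: list[LocationRecord] = []
    next_id = 0

    def weights_for(pset: PredictorSet, season: str) -> np.ndarray:
        coefs = truth.coefficients.get(season, {})
        lin = np.zeros(grid.values.shape)
        for name, beta in coefs.items():
            if beta:
                lin = lin + beta * pset.layers[name].values
        lin = lin - np.nanmax(lin)  # overflow guard; cancels in normalization
        w = np.exp(lin)
        w[~pset.valid_mask()] = 0.0
        return w

    for season in seasons:
        for year in years:
            pset = predictor_sets[(season, year)]
            w = weights_for(pset, season)
            start, end = season_date_range(season, year)
            n_days = (end - start).days + 1
            for si, site in enumerate(sites):
                mask = (site_of_cell == si) & (w > 0)
                idx = np.flatnonzero(mask.ravel())
                if idx.size == 0:
                    raise SimulationError(
                        f"site {site!r}: empty territory for {season} {year}")
                p = w.ravel()[idx]
                p = p / p.sum()
                n = truth.n_per_site_season_year
                chosen = rng.choice(idx, size=n, replace=True, p=p)
                rows, cols = np.unravel_index(chosen, grid.values.shape)
                xs = grid.x_centers[cols] + (rng.random(n) - 0.5) * grid.cell
                ys = grid.y_centers[rows] + (rng.random(n) - 0.5) * grid.cell
                days = rng.integers(0, n_days, size=n)
                for k in range(n):
                    records.append(LocationRecord(
                        id=next_id, x=float(xs[k]), y=float(ys[k]),
                        date=start + dt.timedelta(days=int(days[k])),
                        source="vhf", site=site))
                    next_id += 1

    # leks: breeding-season fixtures at each site's highest-selection cells
    if "breeding" in seasons and leks_per_site > 0:
        year0 = years[0]
        pset = predictor_sets[("breeding", year0)]
        w = weights_for(pset, "breeding")
        for si, site in enumerate(sites):
            mask = (site_of_cell == si) & (w > 0)
            idx = np.flatnonzero(mask.ravel())
            if idx.size == 0:
                raise SimulationError(f"site {site!r}: empty breeding territory")
            wv = w.ravel()[idx]
            cutoff = np.quantile(wv, 0.99)
            top = idx[wv >= cutoff]
            order = np.argsort(-w.ravel()[top], kind="stable")
            lek_cells = top[order][:leks_per_site]
            for cell in lek_cells:
                r, c = np.unravel_index(cell, grid.values.shape)
                lx, ly = float(grid.x_centers[c]), float(grid.y_centers[r])
                for year in years:
                    start, end = season_date_range("breeding", year)
                    n_days = (end - start).days + 1
                    for _ in range(lek_records_per_year):
                        records.append(LocationRecord(
                            id=next_id, x=lx, y=ly,
                            date=start + dt.timedelta(days=int(rng.integers(0, n_days))),
                            source="lek", site=site))
                        next_id += 1
    return records


def truth_rss(
    stack: LandscapeStack,
    truth: SelectionTruth,
    season: str,
    predictor_set: PredictorSet | None = None,
    year: int = 2012,
) -> GridLayer:
    """Analytic relative-selection surface: ``exp(beta . (x - xbar))`` per cell.

    The reference composition is the mean of each predictor over valid cells,
    so a cell at exactly mean conditions has value 1; with all coefficients
    zero the surface is identically 1.
    """
    if predictor_set is None:
        predictor_set = build_predictor_sets(stack, seasons=(season,),
                                             years=(year,))[(season, year)]
    coefs = truth.coefficients.get(season, {})
    grid = predictor_set.grid
    mask = predictor_set.valid_mask()
    lin = np.zeros(grid.values.shape)
    for name, beta in coefs.items():
        if beta:
            x = predictor_set.layers[name].values
            lin = lin + beta * (x - np.mean(x[mask]))
    out = np.exp(lin)
    out[~mask] = np.nan
    return grid.like(out)


# --------------------------------------------------------------------------- #
# plain-text I/O
# --------------------------------------------------------------------------- #

def write_stack(stack: LandscapeStack, out_dir) -> None:
    """Write every raster as .asc, vectors as GeoJSON, and a metadata JSON."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for name, layer in stack.layers.items():
        layer.write_ascii(os.path.join(out_dir, f"{name}.asc"))
    for feature, geoms in stack.lines.items():
        _write_geojson(os.path.join(out_dir, f"{feature}.geojson"), geoms)
    _write_geojson(os.path.join(out_dir, "towers.geojson"), stack.towers)
    _write_geojson(os.path.join(out_dir, "fires.geojson"),
                   [g for (_, g) in stack.fires],
                   props=[{"year": y} for (y, _) in stack.fires])
    meta = {"seed": stack.seed, "config": _config_to_jsonable(stack.config),
            "cover_codes": {str(k): v for k, v in stack.cover_table.codes.items()}}
    with open(os.path.join(out_dir, "landscape_meta.json"), "w") as fh:
        json.dump(meta, fh, indent=2)


def _config_to_jsonable(config: LandscapeConfig) -> dict:
    d = asdict(config)
    d["cover_proportions"] = {str(k): v for k, v in d["cover_proportions"].items()}
    return d


def _write_geojson(path, geoms, props=None) -> None:
    features = []
    for i, g in enumerate(geoms):
        feat = {"type": "Feature", "geometry": mapping(g),
                "properties": (props[i] if props else {})}
        features.append(feat)
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_stack(in_dir) -> LandscapeStack:
    """Re-load a landscape written by :func:`write_stack`."""
    import os

    with open(os.path.join(in_dir, "landscape_meta.json")) as fh:
        meta = json.load(fh)
    cfg_dict = dict(meta["config"])
    cfg_dict["extent"] = tuple(cfg_dict["extent"])
    cfg_dict["cover_epochs"] = tuple(cfg_dict["cover_epochs"])
    cfg_dict["fire_year_range"] = tuple(cfg_dict["fire_year_range"])
    cfg_dict["fire_radius_m"] = tuple(cfg_dict["fire_radius_m"])
    cfg_dict["cover_proportions"] = {int(k): v for k, v in
                                     cfg_dict["cover_proportions"].items()}
    config = LandscapeConfig(**cfg_dict)
    layers = {}
    for fname in sorted(os.listdir(in_dir)):
        if fname.endswith(".asc"):
            name = fname[:-4]
            layer = GridLayer.read_ascii(os.path.join(in_dir, fname))
            if name.startswith("cover_"):
                vals = layer.values.copy()
                vals[np.isnan(vals)] = layer.nodata
                layer = layer.like(vals.astype(np.int16))
            layers[name] = layer
    lines = {}
    for feature in LINE_FEATURES:
        geoms, _ = read_geojson(os.path.join(in_dir, f"{feature}.geojson"))
        lines[feature] = geoms
    towers, _ = read_geojson(os.path.join(in_dir, "towers.geojson"))
    fire_geoms, fire_props = read_geojson(os.path.join(in_dir, "fires.geojson"))
    fires = [(int(p["year"]), g) for g, p in zip(fire_geoms, fire_props)]
    return LandscapeStack(config=config, seed=int(meta["seed"]), layers=layers,
                          lines=lines, towers=towers, fires=fires)


def read_geojson(path) -> tuple[list, list[dict]]:
    with open(path) as fh:
        collection = json.load(fh)
    geoms = [shape(f["geometry"]) for f in collection["features"]]
    props = [f.get("properties", {}) for f in collection["features"]]
    return geoms, props


def locations_to_frame(records: list[LocationRecord]):
    """Location records as a DataFrame (columns id, x, y, date, source, site)."""
    import pandas as pd

    return pd.DataFrame({
        "id": [r.id for r in records],
        "x": [r.x for r in records],
        "y": [r.y for r in records],
        "date": [r.date.isoformat() for r in records],
        "source": [r.source for r in records],
        "site": [r.site for r in records],
    })
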