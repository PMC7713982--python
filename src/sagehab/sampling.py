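"""Use-availability sampling design: seasons, sites, stratified availability.

Used points (telemetry fixes and lek records) are assigned to biological
seasons by date — breeding Apr 1–May 31 (plus every lek record regardless of
date), summer Jun 1–Aug 31, winter Nov 15–Mar 15 — and to population sites by
nearest site centroid, which is exactly Voronoi-polygon membership.  Available
points are then drawn uniformly within each site's Voronoi polygon clipped to
the study region, one per used point in each (site, year, season) stratum, so
the design is 1:1 overall and within every stratum.  Year and site then enter
the classifier as covariates, absorbing spatio-temporal structure.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import voronoi_diagram

log = logging.getLogger(__name__)

SEASONS = ("breeding", "summer", "winter")


class SamplingError(RuntimeError):
    """Availability sampling failed for a stratum."""


# --------------------------------------------------------------------------- #
# season assignment
# --------------------------------------------------------------------------- #

def assign_season(date: dt.date | str, source: str = "vhf") -> str:
    """Season label for one record: ``breeding``/``summer``/``winter``/``none``.

    Lek records are breeding-season used points regardless of survey date.
    VHF windows are inclusive at both endpoints; dates in the gaps
    (Mar 16–31, Sep 1–Nov 14) map to ``none``.
    """
    if source == "lek":
        return "breeding"
    if isinstance(date, str):
        try:
            date = dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValueError(f"unparseable date {date!r}") from exc
    m, d = date.month, date.day
    if (m, d) >= (4, 1) and (m, d) <= (5, 31):
        return "breeding"
    if (m, d) >= (6, 1) and (m, d) <= (8, 31):
        return "summer"
    if (m, d) >= (11, 15) or (m, d) <= (3, 15):
        return "winter"
    return "none"


def stratum_year(date: dt.date | str, season: str) -> int:
    """Year label of the stratum containing ``date``.

    A winter stratum is labeled by the calendar year of the window's start, so
    a 5 January location belongs to the winter that began the preceding
    November — one winter stays contiguous in one stratum.
    """
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    if season == "winter" and (date.month, date.day) <= (3, 15):
        return date.year - 1
    return date.year


# --------------------------------------------------------------------------- #
# site assignment (Voronoi duality)
# --------------------------------------------------------------------------- #

def assign_site(points: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Index of the nearest centroid for each point (ties: lowest index).

    Nearest-centroid labeling is identical to membership in the centroid's
    Voronoi polygon.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    cent = np.atleast_2d(np.asarray(centroids, dtype=float))
    if cent.shape[0] < 1:
        raise ValueError("at least one centroid required")
    d2 = ((pts[:, None, :] - cent[None, :, :]) ** 2).sum(axis=-1)
    return np.argmin(d2, axis=1)  # argmin returns first (lowest) index on ties


def voronoi_polygons(centroids, extent) -> list:
    """Voronoi polygon of each centroid, clipped to the extent box, in
    centroid order."""
    cent = [Point(x, y) for (x, y) in centroids]
    clip = box(*(extent[0], extent[1], extent[2], extent[3]))
    if len(cent) == 1:
        return [clip]
    cells = voronoi_diagram(MultiPoint(cent), envelope=clip)
    out = [None] * len(cent)
    for poly in cells.geoms:
        for i, c in enumerate(cent):
            if poly.covers(c):
                out[i] = poly.intersection(clip)
                break
    if any(p is None for p in out):
        raise SamplingError("could not match a Voronoi cell to every centroid")
    return out


# --------------------------------------------------------------------------- #
# table preparation and availability draws
# --------------------------------------------------------------------------- #

def prepare_used_table(locations: pd.DataFrame, centroids, extent=None) -> pd.DataFrame:
    """Attach season, site, and stratum year to raw used locations.

    Rows whose dates fall in no season window are dropped (their count is
    logged).  Input columns: x, y, date (ISO), source; any pre-existing site
    column is replaced by the nearest-centroid assignment.
    """
    df = locations.copy()
    df["season"] = [assign_season(d, s) for d, s in zip(df["date"], df["source"])]
    n_gap = int((df["season"] == "none").sum())
    if n_gap:
        log.info("dropping %d used locations outside all season windows", n_gap)
    df = df[df["season"] != "none"].copy()
    site_idx = assign_site(df[["x", "y"]].to_numpy(), np.asarray(centroids))
    df["site"] = [f"site{i + 1}" for i in site_idx]
    df["year"] = [stratum_year(d, s) for d, s in zip(df["date"], df["season"])]
    df["label"] = "used"
    return df.reset_index(drop=True)


def draw_available(
    used: pd.DataFrame,
    centroids,
    extent,
    seed: int,
    max_batches: int = 1000,
) -> pd.DataFrame:
    """Stratified uniform availability sample, 1:1 with used points.

    For every (site, year, season) stratum with ``n`` used points, draws
    exactly ``n`` points uniformly within that site's Voronoi polygon
    intersected with the study region (the landscape extent), carrying the
    stratum's site/year/season labels.  Uniformity within the polygon is
    achieved by rejection sampling from the extent box against the
    nearest-centroid rule.
    """
    rng = np.random.default_rng(seed)
    cent = np.asarray(centroids, dtype=float)
    polys = voronoi_polygons(centroids, extent)
    xmin, ymin, xmax, ymax = extent
    strata = used.groupby(["site", "year", "season"], sort=True).size()

    rows = []
    for (site, year, season), n in strata.items():
        si = int(site.removeprefix("site")) - 1
        if polys[si].area <= 0:
            raise SamplingError(
                f"stratum (site={site}, year={year}, season={season}): "
                "degenerate Voronoi polygon")
        need = int(n)
        got_x: list[float] = []
        got_y: list[float] = []
        for _ in range(max_batches):
            if len(got_x) >= need:
                break
            m = max(4 * (need - len(got_x)), 64)
            xs = xmin + (xmax - xmin) * rng.random(m)
            ys = ymin + (ymax - ymin) * rng.random(m)
            keep = assign_site(np.column_stack([xs, ys]), cent) == si
            got_x.extend(xs[keep])
            got_y.extend(ys[keep])
        if len(got_x) < need:
            raise SamplingError(
                f"stratum (site={site}, year={year}, season={season}): "
                "rejection sampling failed to fill the quota")
        rows.append(pd.DataFrame({
            "x": got_x[:need], "y": got_y[:need],
            "date": "", "source": "available",
            "season": season, "site": site, "year": year,
            "label": "available",
        }))
    if not rows:
        return used.iloc[0:0].copy()
    avail = pd.concat(rows, ignore_index=True)
    avail.insert(0, "id", -1 - np.arange(len(avail)))
    return avail


def build_use_avail_table(locations: pd.DataFrame, centroids, extent,
                          seed: int) -> pd.DataFrame:
    """Used rows with design labels plus the matched availability sample."""
    used = prepare_used_table(locations, centroids, extent)
    avail = draw_available(used, centroids, extent, seed)
    table = pd.concat([used, avail], ignore_index=True)
    return table
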