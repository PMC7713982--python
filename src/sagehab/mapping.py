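"""Relative selection strength (RSS) surfaces, seasonal maps, and responses.

A presence-background classifier predicts use probability only up to a
model-specific constant, so seasonal models are put on a common scale by
dividing each cell's predicted probability by that of a hypothetical
reference pixel whose predictors all sit at their mean value over the mapped
region (seasonal means for climate).  RSS > 1 means selection over average
conditions, RSS < 1 avoidance.  Seasonal maps average RSS across the
cross-validation folds; the year-round synthesis marks a cell habitat when
its fold-mean RSS exceeds 1 in at least one season.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .covariates import ENV_PREDICTORS, PredictorSet
from .grid import GridLayer
from .model import FittedForest
from .sampling import assign_site


class MappingError(RuntimeError):
    """RSS mapping cannot proceed on the given inputs."""


@dataclass
class RSSLayer:
    """A ratio surface for one season: predicted p / reference p."""

    season: str
    rss: GridLayer
    reference_probability: float
    fold: str = "mean"


@dataclass
class ResponseCurve:
    """Single-predictor RSS profile with all other predictors at their means."""

    predictor: str
    values: np.ndarray
    rss: np.ndarray
    reference_value: float


def _reference_env_row(pset: PredictorSet) -> np.ndarray:
    means = pset.means()
    return np.array([[means[name] for name in ENV_PREDICTORS]])


def _categorical_reference(model: FittedForest) -> tuple[int, str]:
    year = model.modal_year if model.modal_year is not None \
        else (model.year_categories[0] if model.year_categories else 0)
    site = model.modal_site if model.modal_site is not None \
        else (model.site_categories[0] if model.site_categories else "")
    return year, site


def reference_probability(model: FittedForest, pset: PredictorSet) -> float:
    """Predicted use probability of the mean-conditions reference pixel.

    Continuous predictors sit at their mean over valid cells of the mapped
    region (the season's climate layers make these seasonal means); year and
    site sit at the modal training category.  The result is clamped away
    from 0/1 so it can serve as a ratio denominator.
    """
    env = _reference_env_row(pset)
    year, site = _categorical_reference(model)
    p = model.predict_prob(env, [year], [site], clamp=True)
    return float(p[0])


def rss_surface(
    model: FittedForest,
    pset: PredictorSet,
    centroids=None,
    fold: str = "mean",
) -> RSSLayer:
    """Per-cell RSS: clamped predicted probability over the reference pixel.

    Cells take their geographic site label (nearest centroid) when
    ``centroids`` is given, otherwise the modal training site; the year is
    the predictor set's map year if registered with the model, else the modal
    training year.  Divide-by-reference preserves the ordering of predicted
    probabilities across cells.
    """
    mask = pset.valid_mask()
    env = pset.matrix(mask)
    n = env.shape[0]
    ref_year, ref_site = _categorical_reference(model)
    year = pset.year if pset.year in model.year_categories else ref_year
    years = np.full(n, year)
    if centroids is not None:
        xg, yg = pset.grid.center_meshgrid()
        pts = np.column_stack([xg[mask], yg[mask]])
        sites = np.array([f"site{i + 1}" for i in assign_site(pts, centroids)])
    else:
        sites = np.full(n, ref_site, dtype=object)
    p = model.predict_prob(env, years, sites, clamp=True)
    p_ref = reference_probability(model, pset)
    out = np.full(pset.grid.values.shape, np.nan)
    out[mask] = p / p_ref
    return RSSLayer(season=pset.season, rss=pset.grid.like(out),
                    reference_probability=p_ref, fold=fold)


def mean_across_folds(layers: list[RSSLayer]) -> RSSLayer:
    """Cellwise arithmetic mean of aligned per-fold RSS surfaces."""
    if not layers:
        raise MappingError("no fold layers to average")
    first = layers[0]
    for lay in layers[1:]:
        if lay.season != first.season or not lay.rss.aligned_with(first.rss):
            raise MappingError("fold RSS layers misaligned or mixed seasons")
    stack = np.stack([lay.rss.values for lay in layers])
    mean = stack.mean(axis=0)
    return RSSLayer(season=first.season, rss=first.rss.like(mean),
                    reference_probability=float(np.mean(
                        [lay.reference_probability for lay in layers])),
                    fold="mean")


def annual_habitat(seasonal: dict[str, RSSLayer]) -> GridLayer:
    """Year-round habitat mask from the three seasonal fold-mean RSS maps.

    A cell is habitat (1) iff its RSS exceeds 1 in at least one season —
    equivalently, the union of the per-season exceedance masks; a cell at or
    below 1 in every season is nonhabitat (0).
    """
    missing = {"breeding", "summer", "winter"} - set(seasonal)
    if missing:
        raise MappingError(f"missing season(s) for annual map: {sorted(missing)}")
    ref = seasonal["breeding"].rss
    stack = np.stack([seasonal[s].rss.values
                      for s in ("breeding", "summer", "winter")])
    with np.errstate(invalid="ignore"):
        habitat = (np.nanmax(stack, axis=0) > 1.0).astype(np.uint8)
    habitat_f = habitat.astype(float)
    habitat_f[np.isnan(stack).all(axis=0)] = np.nan
    return ref.like(habitat_f)


def response_curve(
    model: FittedForest,
    pset: PredictorSet,
    predictor: str,
    n_points: int = 50,
) -> ResponseCurve:
    """RSS across one predictor's observed range, all else held at the mean.

    The evaluation grid spans the predictor's range over valid cells; every
    other continuous predictor is pinned at its mean (seasonal means for
    climate) and year/site at the modal category.  The curve passes through
    (mean value, 1.0) by self-normalization.
    """
    if predictor not in ENV_PREDICTORS:
        raise MappingError(f"unknown continuous predictor {predictor!r}")
    mask = pset.valid_mask()
    vals = pset.layers[predictor].values[mask]
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise MappingError(f"predictor {predictor!r} is constant: no range")
    grid_vals = np.linspace(lo, hi, n_points)
    ref_env = _reference_env_row(pset)
    col = ENV_PREDICTORS.index(predictor)
    env = np.repeat(ref_env, n_points, axis=0)
    env[:, col] = grid_vals
    year, site = _categorical_reference(model)
    p = model.predict_prob(env, np.full(n_points, year),
                           np.full(n_points, site, dtype=object), clamp=True)
    p_ref = reference_probability(model, pset)
    return ResponseCurve(predictor=predictor, values=grid_vals,
                         rss=p / p_ref, reference_value=float(ref_env[0, col]))


def response_frame(curve: ResponseCurve) -> pd.DataFrame:
    return pd.DataFrame({"predictor": curve.predictor, "value": curve.values,
                         "rss": curve.rss})
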