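"""Use-vs-availability random-forest model with fixed hyperparameters.

The classifier contrasts used with available points over 26 predictors: the
24 environmental surfaces plus year and site as categorical covariates.
Hyperparameters follow the second-order selection protocol: 1,000 trees,
minimum node size 1, and mtry = 5 variables tried per split (optionally tuned
by out-of-bag error).  Probability of use is the fraction of trees voting
"used"; variable importance is the mean decrease in node impurity (Gini),
with the indicator columns of a categorical predictor summed back into one
score.

Year and site are one-hot encoded against an explicit category registry from
the training data.  A category unseen in training (the held-out site under
spatial cross-validation) encodes as an all-zero indicator vector — the
spatial-transfer semantics: the model falls back on environmental predictors
alone for sites it has never seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .covariates import ENV_PREDICTORS, PredictorSet

log = logging.getLogger(__name__)

CATEGORICAL_PREDICTORS = ("year", "site")
ALL_PREDICTORS = tuple(ENV_PREDICTORS) + CATEGORICAL_PREDICTORS  # 26


class ModelingError(RuntimeError):
    """Model fitting is impossible on the given table."""


@dataclass
class ModelConfig:
    """Random-forest hyperparameters and the predictor registry."""

    n_trees: int = 1000
    min_node_size: int = 1
    m_try: int = 5
    seed: int = 0
    predictors: tuple[str, ...] = ALL_PREDICTORS

    def __post_init__(self) -> None:
        if len(self.predictors) != 26:
            raise ValueError(f"expected 26 predictors, got {len(self.predictors)}")
        if not (1 <= self.m_try <= len(self.predictors) + 64):
            raise ValueError("m_try out of range")


def build_design_matrix(
    table: pd.DataFrame,
    predictor_sets: dict[tuple[str, int], PredictorSet],
) -> pd.DataFrame:
    """Sample the 24 environmental layers at every location (1-km grain).

    Each labeled row is intersected with the predictor stack matching its
    (season, year): land cover by the epoch lookup for the row's year, climate
    by the row's season, burned area by the row's year.  Two locations in the
    same coarse cell with the same season/year receive identical predictor
    rows.  Rows landing on nodata are dropped with a logged count.
    """
    parts = []
    for (season, year), grp in table.groupby(["season", "year"], sort=True):
        key = (season, int(year))
        if key not in predictor_sets:
            raise KeyError(f"no predictor set for season={season}, year={year}")
        pset = predictor_sets[key]
        out = grp.copy()
        for name in ENV_PREDICTORS:
            out[name] = pset.layers[name].sample(grp["x"].to_numpy(),
                                                 grp["y"].to_numpy())
        parts.append(out)
    df = pd.concat(parts, ignore_index=True)
    env = df[list(ENV_PREDICTORS)].to_numpy(dtype=float)
    bad = np.isnan(env).any(axis=1)
    if bad.any():
        log.info("dropping %d rows on nodata cells", int(bad.sum()))
        df = df[~bad].reset_index(drop=True)
    return df


@dataclass
class FittedForest:
    """A fitted seasonal classifier with its category registry and OOB record."""

    clf: RandomForestClassifier
    config: ModelConfig
    year_categories: tuple[int, ...]
    site_categories: tuple[str, ...]
    feature_names: tuple[str, ...]
    oob_prob: np.ndarray              # per training row, P(used); NaN if never OOB
    oob_confusion: dict[str, int]
    modal_year: int | None = None     # most frequent training categories; used
    modal_site: str | None = None     # as the categorical reference (mapping)

    @property
    def prob_floor(self) -> float:
        return 1.0 / (2.0 * self.config.n_trees)

    def clamp(self, p: np.ndarray) -> np.ndarray:
        """Clamp probabilities away from 0/1 before ratio operations."""
        lo = self.prob_floor
        return np.clip(p, lo, 1.0 - lo)

    def encode(self, env: np.ndarray, years, sites) -> np.ndarray:
        """Design matrix: 24 numeric columns + one-hot year + one-hot site.

        Unregistered year/site values encode as all-zero indicators.
        """
        n = env.shape[0]
        years = np.asarray(years)
        sites = np.asarray(sites)
        ycols = np.column_stack([(years == y).astype(float)
                                 for y in self.year_categories]) \
            if self.year_categories else np.empty((n, 0))
        scols = np.column_stack([(sites == s).astype(float)
                                 for s in self.site_categories]) \
            if self.site_categories else np.empty((n, 0))
        return np.column_stack([env, ycols, scols])

    def predict_prob(self, env: np.ndarray, years, sites,
                     clamp: bool = False) -> np.ndarray:
        X = self.encode(env, years, sites)
        used_col = int(np.flatnonzero(self.clf.classes_ == 1)[0])
        p = self.clf.predict_proba(X)[:, used_col]
        return self.clamp(p) if clamp else p

    def predict_table(self, table: pd.DataFrame, clamp: bool = False) -> np.ndarray:
        env = table[list(ENV_PREDICTORS)].to_numpy(dtype=float)
        return self.predict_prob(env, table["year"].to_numpy(),
                                 table["site"].to_numpy(), clamp=clamp)


def _confusion_from(y: np.ndarray, p: np.ndarray) -> dict[str, int]:
    """Confusion counts at the 0.5 vote threshold; NaN predictions skipped."""
    ok = ~np.isnan(p)
    y, p = y[ok], p[ok]
    pred = (p > 0.5).astype(int)
    return {
        "used_correct": int(((y == 1) & (pred == 1)).sum()),
        "used_wrong": int(((y == 1) & (pred == 0)).sum()),
        "avail_correct": int(((y == 0) & (pred == 0)).sum()),
        "avail_wrong": int(((y == 0) & (pred == 1)).sum()),
    }


def fit_forest(table: pd.DataFrame, config: ModelConfig,
               require_balance: bool = True) -> FittedForest:
    """Fit the classifier and record per-row out-of-bag predictions.

    The 1:1 design guarantees balanced classes, asserted here; the seed makes
    the fit, votes, and OOB record reproducible.
    """
    y = (table["label"].to_numpy() == "used").astype(int)
    n_used, n_avail = int((y == 1).sum()), int((y == 0).sum())
    if n_used == 0 or n_avail == 0:
        raise ModelingError("both classes must be present")
    if require_balance and n_used != n_avail:
        raise ModelingError(
            f"design not balanced: {n_used} used vs {n_avail} available")

    year_cats = tuple(sorted(pd.unique(table["year"]).tolist()))
    site_cats = tuple(sorted(pd.unique(table["site"]).tolist()))
    feature_names = tuple(ENV_PREDICTORS) \
        + tuple(f"year_{y_}" for y_ in year_cats) \
        + tuple(f"site_{s}" for s in site_cats)

    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        min_samples_leaf=config.min_node_size,
        max_features=config.m_try,
        criterion="gini",
        oob_score=True,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    env = table[list(ENV_PREDICTORS)].to_numpy(dtype=float)
    dummy = FittedForest(clf, config, year_cats, site_cats, feature_names,
                         oob_prob=np.empty(0), oob_confusion={})
    X = dummy.encode(env, table["year"].to_numpy(), table["site"].to_numpy())
    clf.fit(X, y)

    used_col = int(np.flatnonzero(clf.classes_ == 1)[0])
    oob = clf.oob_decision_function_[:, used_col]
    n_missing = int(np.isnan(oob).sum())
    if n_missing:
        log.info("%d rows had no out-of-bag trees", n_missing)
    return FittedForest(clf, config, year_cats, site_cats, feature_names,
                        oob_prob=oob, oob_confusion=_confusion_from(y, oob),
                        modal_year=int(table["year"].mode().iloc[0]),
                        modal_site=str(table["site"].mode().iloc[0]))


PERSIST_FORMAT_VERSION = 1


def save_model(model: FittedForest, path) -> None:
    """Persist a fitted model with its config and category registry embedded."""
    import pickle

    payload = {
        "format_version": PERSIST_FORMAT_VERSION,
        "config": model.config,
        "model": model,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh)


def load_model(path) -> FittedForest:
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("format_version") != PERSIST_FORMAT_VERSION:
        raise ModelingError(f"unsupported model artifact version in {path}")
    return payload["model"]


def oob_error(model: FittedForest) -> float:
    """Overall out-of-bag misclassification rate at the 0.5 threshold."""
    c = model.oob_confusion
    total = sum(c.values())
    return (c["used_wrong"] + c["avail_wrong"]) / total


def tune_mtry(table: pd.DataFrame, candidates, config: ModelConfig
              ) -> tuple[int, dict[int, float]]:
    """Choose the mtry candidate minimizing overall OOB error.

    Returns ``(chosen, errors)`` with the full error vector for plotting;
    ties resolve to the smallest candidate.
    """
    candidates = sorted(set(int(c) for c in candidates))
    if not candidates:
        raise ValueError("no mtry candidates")
    errors: dict[int, float] = {}
    for cand in candidates:
        model = fit_forest(table, replace(config, m_try=cand))
        errors[cand] = oob_error(model)
    chosen = min(candidates, key=lambda c: (errors[c], c))
    return chosen, errors


def _grouped_importance(model: FittedForest) -> pd.Series:
    """MDI per predictor with one-hot indicator columns summed per factor."""
    imp = pd.Series(model.clf.feature_importances_, index=list(model.feature_names))
    out = {name: imp[name] for name in ENV_PREDICTORS}
    out["year"] = float(imp[[f"year_{y}" for y in model.year_categories]].sum()) \
        if model.year_categories else 0.0
    out["site"] = float(imp[[f"site_{s}" for s in model.site_categories]].sum()) \
        if model.site_categories else 0.0
    return pd.Series(out, dtype=float)


def importance_mdi(fold_models: list[FittedForest]) -> pd.DataFrame:
    """Mean-decrease-in-impurity importance averaged across fold models.

    Returns a table indexed by the 26 predictors with columns ``mean`` and
    ``sd`` across folds and a descending-mean ``rank`` (1 = most important).
    """
    if not fold_models:
        raise ValueError("at least one fold model required")
    per_fold = pd.concat([_grouped_importance(m) for m in fold_models], axis=1)
    mean = per_fold.mean(axis=1)
    sd = per_fold.std(axis=1, ddof=0)
    order = mean.sort_values(ascending=False, kind="stable").index
    rank = pd.Series(np.arange(1, len(order) + 1), index=order).reindex(mean.index)
    return pd.DataFrame({"mean": mean, "sd": sd, "rank": rank.astype(int)})
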