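"""Leave-one-site-out cross-validation, pooled confusion, and calibration.

Model transferability is judged spatially: each fold withholds one site
entirely, fits the forest to the remaining sites, and scores the withheld
rows.  Confusion matrices are summed across folds, both for out-of-bag
predictions (within-fold training data) and for the held-out rows.
Classification error is reported for the used class only — availability
points have unknown status under a presence-background design, so an
"error" on them is not meaningful (and AUC is rejected for the same reason).

Calibration follows the use-availability convention: held-out rows are
binned by quantiles of predicted probability; the expected number of used
points per bin (sum of predicted probabilities) is compared with the
observed count, summarized by Spearman's rank correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .model import FittedForest, ModelConfig, _confusion_from, fit_forest


class ValidationError(RuntimeError):
    """Cross-validation cannot proceed on the given table."""


@dataclass
class ConfusionCounts:
    """2x2 confusion counts at the 0.5 vote threshold; additive under pooling."""

    used_correct: int = 0
    used_wrong: int = 0
    avail_correct: int = 0
    avail_wrong: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.used_correct + other.used_correct,
            self.used_wrong + other.used_wrong,
            self.avail_correct + other.avail_correct,
            self.avail_wrong + other.avail_wrong,
        )

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ConfusionCounts":
        return cls(d["used_correct"], d["used_wrong"],
                   d["avail_correct"], d["avail_wrong"])

    @property
    def total(self) -> int:
        return (self.used_correct + self.used_wrong
                + self.avail_correct + self.avail_wrong)

    def as_dict(self) -> dict[str, int]:
        return {"used_correct": self.used_correct, "used_wrong": self.used_wrong,
                "avail_correct": self.avail_correct, "avail_wrong": self.avail_wrong}


def used_class_error(counts: ConfusionCounts) -> float:
    """Misclassification rate of the used class: wrong / (correct + wrong)."""
    n = counts.used_correct + counts.used_wrong
    if n == 0:
        raise ValidationError("no used rows: used-class error undefined")
    return counts.used_wrong / n


def make_folds(table: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-site-out folds: (held-out site, train index, test index).

    Sites are iterated in sorted order so fold construction is independent of
    row order; every site is withheld exactly once.
    """
    sites = sorted(pd.unique(table["site"]).tolist())
    if len(sites) < 2:
        raise ValidationError("leave-one-site-out needs at least 2 sites")
    folds = []
    site_col = table["site"].to_numpy()
    for site in sites:
        test = np.flatnonzero(site_col == site)
        train = np.flatnonzero(site_col != site)
        folds.append((site, train, test))
    return folds


@dataclass
class CalibrationCurve:
    """Quantile-binned expected vs observed used counts and their Spearman rho."""

    bins: pd.DataFrame      # columns: bin, expected_used, observed_used
    rho: float


def calibration(probs: np.ndarray, labels: np.ndarray,
                n_bins: int = 10) -> CalibrationCurve:
    """Use-availability calibration curve over quantile bins of probability.

    Rows are ordered by predicted probability (stable sort, so heavy ties
    still yield ``n_bins`` near-equal bins rather than merged ones) and split
    into quantile bins.  Expected used count per bin is the sum of predicted
    probabilities; observed is the count of used rows.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    if probs.size == 0:
        raise ValidationError("empty test set")
    if np.ptp(probs) == 0:
        raise ValidationError(
            "all predicted probabilities identical: quantile bins are "
            "degenerate; check the model and the test data")
    used = (labels == "used") if labels.dtype.kind in "OU" else labels == 1
    order = np.argsort(probs, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins)):
        rows.append({
            "bin": b,
            "expected_used": float(probs[idx].sum()),
            "observed_used": int(used[idx].sum()),
        })
    bins = pd.DataFrame(rows)
    rho = float(spearmanr(bins["expected_used"], bins["observed_used"]).statistic)
    return CalibrationCurve(bins=bins, rho=rho)


@dataclass
class FoldResult:
    """Everything retained per held-out site."""

    site: str
    model: FittedForest
    oob_confusion: ConfusionCounts
    val_confusion: ConfusionCounts
    test_probs: np.ndarray
    test_labels: np.ndarray
    calibration: CalibrationCurve | None = None


def run_cross_validation(table: pd.DataFrame, config: ModelConfig,
                         n_bins: int = 10) -> list[FoldResult]:
    """Fit one forest per leave-one-site-out fold and score the held-out site."""
    folds = make_folds(table)
    results = []
    for (site, train_idx, test_idx) in folds:
        train = table.iloc[train_idx]
        test = table.iloc[test_idx]
        model = fit_forest(train, config, require_balance=False)
        probs = model.predict_table(test)
        y_test = (test["label"].to_numpy() == "used").astype(int)
        try:
            cal = calibration(probs, y_test, n_bins=n_bins)
        except ValidationError:
            cal = None
        results.append(FoldResult(
            site=site,
            model=model,
            oob_confusion=ConfusionCounts.from_dict(model.oob_confusion),
            val_confusion=ConfusionCounts.from_dict(_confusion_from(y_test, probs)),
            test_probs=probs,
            test_labels=test["label"].to_numpy(),
            calibration=cal,
        ))
    return results


def pooled_confusion(folds: list[FoldResult]
                     ) -> tuple[ConfusionCounts, ConfusionCounts]:
    """Sum confusion matrices across folds: (pooled OOB, pooled validation).

    With K sites, every row appears in K-1 training sets, so the pooled OOB
    matrix totals (K-1) x n rows; each row is held out exactly once, so the
    pooled validation matrix totals n rows.
    """
    oob = ConfusionCounts()
    val = ConfusionCounts()
    for fr in folds:
        oob = oob + fr.oob_confusion
        val = val + fr.val_confusion
    return oob, val
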