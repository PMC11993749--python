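"""Scoring of site-level stoichiometry predictions against a ground truth.

The metric suite pairs a truth file and a prediction file over one reference
of N evaluable positions and reports:

* error metrics over all N positions, with Y = 0 at unmodified positions and
  Yhat = 0 where no site was predicted — RMSE, MAE, median absolute error;
* the deviation range (max and min absolute error) restricted to the modified
  positions;
* classification metrics under a tolerant matching rule: a predicted site is
  a true positive if it lies within ``pos_window`` bases (default 1) of a
  truth site AND its frequency falls inside the truth frequency Y +- 0.6*Y.
  An unmodified position counts as a true negative when no site (or a
  frequency-0 site) is predicted there.  Accuracy = (TP+TN)/N and
  F1 = 2TP/(2TP+FP+FN).

Matching is one-to-one and TP-maximizing (ties broken by smallest total
positional offset), so one prediction can never satisfy two truth sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .bedrmod import SiteRecord

__all__ = [
    "ToleranceRule",
    "PairedVectors",
    "ConfusionCounts",
    "EvalReport",
    "acceptance_interval",
    "match_predictions",
    "confusion_counts",
    "rmse",
    "mae",
    "median_ae",
    "max_deviation",
    "min_deviation",
    "accuracy",
    "f1",
    "evaluate",
]

_INFEASIBLE = 1.0e9  # assignment cost for pairs outside the tolerance rule


@dataclass(frozen=True)
class ToleranceRule:
    """Frequency and position tolerance for true-positive matching."""

    freq_tol_factor: float = 0.6
    pos_window: int = 1

    def __post_init__(self) -> None:
        if self.freq_tol_factor < 0:
            raise ValueError("freq_tol_factor must be >= 0")
        if self.pos_window < 0 or int(self.pos_window) != self.pos_window:
            raise ValueError("pos_window must be a non-negative integer")


@dataclass
class PairedVectors:
    """Observed and predicted frequencies over all N evaluable positions."""

    y: np.ndarray
    yhat: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.yhat = np.asarray(self.yhat, dtype=float)
        if self.y.shape != self.yhat.shape:
            raise ValueError("observed and predicted vectors differ in length")
        for name, v in (("Y", self.y), ("Yhat", self.yhat)):
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} values outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def modified(self) -> np.ndarray:
        """Mask of modified positions (target frequency > 0)."""
        return self.y > 0


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion counts")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def acceptance_interval(y: float, rule: ToleranceRule = ToleranceRule()) -> tuple[float, float]:
    """Frequency interval [max(0, Y*(1-f)), min(1, Y*(1+f))] accepted as correct.

    Only defined for modified positions (Y > 0); zero-target positions are
    governed by the exact-zero true-negative rule instead.
    """
    if not 0.0 < y <= 1.0:
        raise ValueError(f"target frequency must be in (0, 1], got {y}")
    lo = max(0.0, y * (1.0 - rule.freq_tol_factor))
    hi = min(1.0, y * (1.0 + rule.freq_tol_factor))
    return lo, hi


def _feasible(truth: SiteRecord, pred: SiteRecord, rule: ToleranceRule) -> bool:
    if abs(pred.start - truth.start) > rule.pos_window:
        return False
    lo, hi = acceptance_interval(truth.frequency, rule)
    return lo <= pred.frequency <= hi


def _check_sorted(sites: list[SiteRecord], label: str) -> None:
    if any(sites[i].start > sites[i + 1].start for i in range(len(sites) - 1)):
        raise ValueError(f"{label} sites are not sorted by position")


def match_predictions(
    truth: list[SiteRecord],
    predictions: list[SiteRecord],
    rule: ToleranceRule = ToleranceRule(),
) -> list[tuple[int, int]]:
    """One-to-one TP-maximizing matching of truth to prediction sites.

    Returns index pairs (truth_idx, pred_idx).  Among matchings of maximal
    cardinality, the one with the smallest total positional offset is chosen.
    Truth sites with frequency 0 are rejected (they are not modified sites).
    """
    _check_sorted(truth, "truth")
    _check_sorted(predictions, "prediction")
    if not truth or not predictions:
        return []
    cost = np.full((len(truth), len(predictions)), _INFEASIBLE)
    for i, t in enumerate(truth):
        for j, p in enumerate(predictions):
            if _feasible(t, p, rule):
                cost[i, j] = abs(p.start - t.start)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols) if cost[i, j] < _INFEASIBLE]


def confusion_counts(
    matching: list[tuple[int, int]],
    truth: list[SiteRecord],
    predictions: list[SiteRecord],
    n_positions: int,
) -> ConfusionCounts:
    """Classify all N positions given a matching.

    TP = matched truth sites; FN = unmatched truth sites; FP = unmatched
    predictions with frequency > 0 at positions without a truth site; TN =
    the remaining zero-target positions.
    """
    if n_positions < len(truth):
        raise ValueError(f"N = {n_positions} smaller than number of truth sites {len(truth)}")
    tp = len(matching)
    fn = len(truth) - tp
    truth_positions = {t.start for t in truth}
    matched_preds = {j for _, j in matching}
    fp = sum(
        1
        for j, p in enumerate(predictions)
        if j not in matched_preds and p.frequency > 0 and p.start not in truth_positions
    )
    tn = n_positions - len(truth) - fp
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def rmse(pair: PairedVectors) -> float:
    """Root mean squared error over all N positions."""
    if pair.n == 0:
        raise ValueError("no evaluable positions")
    return float(np.sqrt(np.mean((pair.y - pair.yhat) ** 2)))


def mae(pair: PairedVectors) -> float:
    """Mean absolute error over all N positions."""
    if pair.n == 0:
        raise ValueError("no evaluable positions")
    return float(np.mean(np.abs(pair.y - pair.yhat)))


def median_ae(pair: PairedVectors) -> float:
    """Median absolute error (lower median for even N)."""
    if pair.n == 0:
        raise ValueError("no evaluable positions")
    errors = np.sort(np.abs(pair.y - pair.yhat))
    return float(errors[(pair.n - 1) // 2])


def max_deviation(pair: PairedVectors) -> float:
    """Largest absolute error over the modified positions."""
    mask = pair.modified
    if not mask.any():
        raise ValueError("no modified positions: deviation range undefined")
    return float(np.max(np.abs(pair.y[mask] - pair.yhat[mask])))


def min_deviation(pair: PairedVectors) -> float:
    """Smallest absolute error over the modified positions."""
    mask = pair.modified
    if not mask.any():
        raise ValueError("no modified positions: deviation range undefined")
    return float(np.min(np.abs(pair.y[mask] - pair.yhat[mask])))


def accuracy(counts: ConfusionCounts, n_positions: int) -> float:
    """(TP + TN) / N."""
    if n_positions <= 0:
        raise ValueError("N must be positive")
    if counts.n != n_positions:
        raise ValueError(f"confusion counts sum to {counts.n}, expected N = {n_positions}")
    return (counts.tp + counts.tn) / n_positions


def f1(counts: ConfusionCounts) -> float:
    """2*TP / (2*TP + FP + FN); 1 by convention when all three are zero."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 1.0
    return 2 * counts.tp / denom


@dataclass
class EvalReport:
    """All seven metrics plus confusion counts for one truth/prediction pair."""

    rmse: float
    mae: float
    median_ae: float
    max_deviation: float
    min_deviation: float
    accuracy: float
    f1: float
    confusion: ConfusionCounts
    n_positions: int
    rule: ToleranceRule
    matches: list[tuple[int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "metrics": {
                "rmse": self.rmse,
                "mae": self.mae,
                "median_ae": self.median_ae,
                "max_deviation": self.max_deviation,
                "min_deviation": self.min_deviation,
                "accuracy": self.accuracy,
                "f1": self.f1,
            },
            "confusion": {
                "tp": self.confusion.tp,
                "tn": self.confusion.tn,
                "fp": self.confusion.fp,
                "fn": self.confusion.fn,
            },
            "n_positions": self.n_positions,
            "tolerance": {
                "freq_tol_factor": self.rule.freq_tol_factor,
                "pos_window": self.rule.pos_window,
            },
            "n_matches": len(self.matches),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def evaluate(
    truth: list[SiteRecord],
    predictions: list[SiteRecord],
    reference_length: int,
    rule: ToleranceRule = ToleranceRule(),
) -> EvalReport:
    """Full metric suite for one truth/prediction pair on one reference.

    Error metrics pair positions strictly (no window); the tolerance rule
    applies only to the TP/TN classification behind accuracy and F1.
    """
    if not truth:
        raise ValueError("empty truth set")
    chroms = {r.chrom for r in truth} | {r.chrom for r in predictions}
    if len(chroms) > 1:
        raise ValueError(f"records span multiple references: {sorted(chroms)}")
    truth = sorted(truth, key=lambda r: r.start)
    predictions = sorted(predictions, key=lambda r: r.start)
    for rec in truth + predictions:
        if rec.end > reference_length:
            raise ValueError(f"site at {rec.start} beyond reference length {reference_length}")

    y = np.zeros(reference_length)
    yhat = np.zeros(reference_length)
    for rec in truth:
        y[rec.start] = rec.frequency
    for rec in predictions:
        yhat[rec.start] = rec.frequency
    pair = PairedVectors(y=y, yhat=yhat)

    modified_truth = [r for r in truth if r.frequency > 0]
    matching = match_predictions(modified_truth, predictions, rule)
    counts = confusion_counts(matching, modified_truth, predictions, reference_length)

    return EvalReport(
        rmse=rmse(pair),
        mae=mae(pair),
        median_ae=median_ae(pair),
        max_deviation=max_deviation(pair),
        min_deviation=min_deviation(pair),
        accuracy=accuracy(counts, reference_length),
        f1=f1(counts),
        confusion=counts,
        n_positions=reference_length,
        rule=rule,
        matches=matching,
    )
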