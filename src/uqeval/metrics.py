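"""Predictive entropy, the uncertainty confusion matrix and its metrics.

The evaluation idea mirrors the ordinary classification confusion matrix:
each prediction is *correct* or *incorrect* (against the ground-truth
label) and, separately, *certain* or *uncertain* (its uncertainty score
against a threshold).  Crossing the two binary outcomes yields four cells

=============  =========================  ==========================
               certain                    uncertain
=============  =========================  ==========================
correct        TC  (true certainty)       FU  (false uncertainty)
incorrect      FC  (false certainty)      TU  (true uncertainty)
=============  =========================  ==========================

TC and TU are the favourable diagonal; FC — a confidently wrong
prediction — is the worst outcome.  From the four counts the analogues of
sensitivity, specificity, precision and accuracy follow:

    USen = TU / (TU + FC)        fraction of errors that were flagged
    USpe = TC / (TC + FU)        fraction of correct predictions kept
    UPre = TU / (TU + FU)        fraction of flags that were errors
    UAcc = (TU + TC) / n         overall self-awareness

A zero denominator yields :data:`math.nan` (an explicit "undefined"
marker), never 0 or 1, so perfect batches do not silently inflate scores.

The default uncertainty score is the predictive entropy of the
posterior-mean class probabilities, but any non-negative per-sample score
stored in a :class:`LabeledPredictions` table is accepted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import xlogy

from ._utils import as_prob_array
from .errors import ValidationError

__all__ = [
    "LabeledPredictions",
    "UncertaintyConfusion",
    "UncertaintyMetrics",
    "ThresholdSweep",
    "GroupSummary",
    "predictive_entropy",
    "uncertainty_confusion",
    "uncertainty_metrics",
    "threshold_sweep",
    "group_uncertainty_summary",
    "DEFAULT_THRESHOLD_GRID",
]

#: threshold grid used by reports: 0.1 ... 0.9 in steps of 0.1
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(1, 10) * 0.1, 10))

#: the single threshold highlighted in tabular reports
DEFAULT_THRESHOLD = 0.3


def predictive_entropy(probs, base: float = 2.0):
    """Entropy of class-probability vector(s): ``-sum_c p_c log_base p_c``.

    ``0 * log 0`` is taken as 0.  For a C-class vector the result lies in
    ``[0, log_base C]``; with ``base=2`` a binary vector maps onto [0, 1],
    which is the scale the default threshold grid assumes.

    Parameters
    ----------
    probs
        A single vector ``(C,)`` or batch ``(..., C)``; each vector must be
        non-negative and sum to 1 within 1e-6.
    base
        Logarithm base, > 1.

    Returns
    -------
    float or ndarray with the leading shape of ``probs``.
    """
    if not base > 1:
        raise ValidationError(f"entropy base must be > 1, got {base!r}")
    arr = as_prob_array(probs, name="probs")
    ent = -xlogy(arr, arr).sum(axis=-1) / math.log(base)
    # roundoff can leave a tiny negative on one-hot vectors
    ent = np.maximum(ent, 0.0)
    return float(ent) if ent.ndim == 0 else ent


@dataclass
class LabeledPredictions:
    """Per-sample predictions joined with ground truth and an uncertainty score.

    Attributes
    ----------
    true_label, predicted_class
        Integer class indices in ``[0, n_classes)``.
    uncertainty
        Non-negative per-sample score; by convention the predictive entropy
        of the posterior-mean probabilities, but any score works.
    confidence
        Max posterior-mean probability per sample, in [0, 1].
    n_classes
        Number of classes C (>= 2).
    probs
        Optional ``(N, C)`` posterior-mean probabilities (kept for table
        export; not required by the metrics).
    sample_ids
        Optional stable identifiers for table export.
    uncertainty_source
        Provenance of the score, e.g. ``"file"`` or
        ``"predictive_entropy(base=2)"``.
    """

    true_label: np.ndarray
    predicted_class: np.ndarray
    uncertainty: np.ndarray
    confidence: np.ndarray
    n_classes: int
    probs: np.ndarray | None = None
    sample_ids: list[str] | None = None
    uncertainty_source: str | None = None

    def __post_init__(self):
        self.true_label = np.asarray(self.true_label, dtype=int)
        self.predicted_class = np.asarray(self.predicted_class, dtype=int)
        self.uncertainty = np.asarray(self.uncertainty, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        n = len(self.true_label)
        if n < 1:
            raise ValidationError("need at least one prediction")
        for name in ("predicted_class", "uncertainty", "confidence"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} has length {len(getattr(self, name))}, expected {n}")
        if self.n_classes < 2:
            raise ValidationError("n_classes must be >= 2")
        for name in ("true_label", "predicted_class"):
            lab = getattr(self, name)
            if lab.min() < 0 or lab.max() >= self.n_classes:
                raise ValidationError(f"{name} outside [0, {self.n_classes})")
        if not np.all(np.isfinite(self.uncertainty)) or np.any(self.uncertainty < 0):
            raise ValidationError("uncertainty must be finite and >= 0")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValidationError("confidence must lie in [0, 1]")
        if self.probs is not None:
            self.probs = as_prob_array(self.probs, name="probs")
            if self.probs.shape != (n, self.n_classes):
                raise ValidationError("probs shape does not match (n, n_classes)")
        if self.sample_ids is not None and len(self.sample_ids) != n:
            raise ValidationError("sample_ids length mismatch")

    def __len__(self) -> int:
        return len(self.true_label)

    @property
    def correct(self) -> np.ndarray:
        return self.predicted_class == self.true_label

    @property
    def accuracy(self) -> float:
        return float(self.correct.mean())

    @classmethod
    def from_summary(cls, summary, true_label, sample_ids=None) -> "LabeledPredictions":
        """Build from a :class:`~uqeval.posterior.PredictiveSummary`,
        scoring uncertainty by predictive entropy."""
        return cls(
            true_label=true_label,
            predicted_class=summary.predicted_class,
            uncertainty=summary.entropy,
            confidence=summary.confidence,
            n_classes=summary.mean_probs.shape[1],
            probs=summary.mean_probs,
            sample_ids=sample_ids,
            uncertainty_source=f"predictive_entropy(base={summary.entropy_base:g})",
        )


@dataclass(frozen=True)
class UncertaintyConfusion:
    """Counts of the four correctness x certainty outcomes at a threshold."""

    tc: int
    tu: int
    fu: int
    fc: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tc + self.tu + self.fu + self.fc

    def as_dict(self) -> dict:
        return {"threshold": self.threshold, "tc": self.tc, "tu": self.tu,
                "fu": self.fu, "fc": self.fc}


@dataclass(frozen=True)
class UncertaintyMetrics:
    """USen/USpe/UPre/UAcc at one threshold; nan marks an undefined ratio."""

    usen: float
    uspe: float
    upre: float
    uacc: float
    threshold: float

    def as_dict(self) -> dict:
        return {"threshold": self.threshold, "usen": self.usen,
                "uspe": self.uspe, "upre": self.upre, "uacc": self.uacc}


def uncertainty_confusion(lp: LabeledPredictions, threshold: float) -> UncertaintyConfusion:
    """Cross prediction correctness with the certainty decision.

    A prediction is *uncertain* iff its score strictly exceeds ``threshold``
    (ties count as certain, so a threshold at the maximum attainable score
    flags nothing).
    """
    if not np.isfinite(threshold):
        raise ValidationError("threshold must be finite")
    correct = lp.correct
    uncertain = lp.uncertainty > threshold
    tc = int(np.sum(correct & ~uncertain))
    fu = int(np.sum(correct & uncertain))
    tu = int(np.sum(~correct & uncertain))
    fc = int(np.sum(~correct & ~uncertain))
    return UncertaintyConfusion(tc=tc, tu=tu, fu=fu, fc=fc, threshold=float(threshold))


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def uncertainty_metrics(uc: UncertaintyConfusion) -> UncertaintyMetrics:
    """Derive USen, USpe, UPre and UAcc from the four outcome counts.

    Zero denominators (e.g. no incorrect predictions for USen) yield nan,
    the explicit undefined marker — never an exception and never 0 or 1.
    """
    if uc.n == 0:
        raise ValidationError("uncertainty confusion has no outcomes (n = 0)")
    return UncertaintyMetrics(
        usen=_ratio(uc.tu, uc.tu + uc.fc),
        uspe=_ratio(uc.tc, uc.tc + uc.fu),
        upre=_ratio(uc.tu, uc.tu + uc.fu),
        uacc=(uc.tu + uc.tc) / uc.n,
        threshold=uc.threshold,
    )


@dataclass
class ThresholdSweep:
    """Uncertainty confusion counts and metrics over an increasing grid."""

    thresholds: np.ndarray
    confusions: list[UncertaintyConfusion]
    metrics: list[UncertaintyMetrics]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table, one row per threshold; fixed column order."""
        rows = []
        for uc, um in zip(self.confusions, self.metrics):
            rows.append({**uc.as_dict(), "usen": um.usen, "uspe": um.uspe,
                         "upre": um.upre, "uacc": um.uacc})
        return pd.DataFrame(rows, columns=["threshold", "tc", "tu", "fu", "fc",
                                           "usen", "uspe", "upre", "uacc"])

    def at(self, threshold: float) -> UncertaintyMetrics:
        """Metrics row at an exact grid point."""
        idx = np.flatnonzero(np.isclose(self.thresholds, threshold))
        if len(idx) == 0:
            raise KeyError(f"threshold {threshold} not in sweep grid")
        return self.metrics[int(idx[0])]


def threshold_sweep(lp: LabeledPredictions,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLD_GRID) -> ThresholdSweep:
    """Evaluate the uncertainty confusion matrix over a threshold grid.

    The default grid runs 0.1-0.9 in steps of 0.1 (0.3 being the value
    highlighted in single-threshold reports).  The grid must be strictly
    increasing.
    """
    grid = np.asarray(list(thresholds), dtype=float)
    if grid.size == 0:
        raise ValidationError("threshold grid is empty")
    if grid.size > 1 and not np.all(np.diff(grid) > 0):
        raise ValidationError("threshold grid must be strictly increasing")
    confusions = [uncertainty_confusion(lp, t) for t in grid]
    metrics = [uncertainty_metrics(uc) for uc in confusions]
    return ThresholdSweep(thresholds=grid, confusions=confusions, metrics=metrics)


@dataclass
class GroupSummary:
    """Uncertainty/confidence distribution summaries for the correct and
    incorrect prediction groups.

    ``mean_uncertainty_difference`` is (incorrect - correct) group mean;
    nan when one group is empty (then ``complete`` is False).
    """

    table: pd.DataFrame
    mean_uncertainty_difference: float
    complete: bool = field(default=True)


def _describe(values: np.ndarray, prefix: str) -> dict:
    return {
        f"{prefix}_mean": float(np.mean(values)),
        f"{prefix}_median": float(np.median(values)),
        f"{prefix}_q25": float(np.quantile(values, 0.25)),
        f"{prefix}_q75": float(np.quantile(values, 0.75)),
    }


def group_uncertainty_summary(lp: LabeledPredictions) -> GroupSummary:
    """Summarise uncertainty and confidence separately for correctly and
    incorrectly classified samples.

    A well-behaved posterior assigns systematically higher uncertainty to
    the misclassified group, so ``mean_uncertainty_difference`` should be
    positive for a model whose uncertainty is informative.
    """
    rows = {}
    for name, mask in (("correct", lp.correct), ("incorrect", ~lp.correct)):
        if not mask.any():
            continue
        rows[name] = {
            "count": int(mask.sum()),
            **_describe(lp.uncertainty[mask], "uncertainty"),
            **_describe(lp.confidence[mask], "confidence"),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "group"
    if {"correct", "incorrect"} <= rows.keys():
        diff = rows["incorrect"]["uncertainty_mean"] - rows["correct"]["uncertainty_mean"]
        return GroupSummary(table=table, mean_uncertainty_difference=float(diff))
    return GroupSummary(table=table, mean_uncertainty_difference=math.nan, complete=False)
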