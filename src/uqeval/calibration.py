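"""Confidence binning and the expected calibration error (ECE).

Predictions are grouped into M equal-width confidence bins on [0, 1];
confidence is the max of the posterior-mean class probabilities.  For
each occupied bin B_m the accuracy acc(B_m) is the fraction of correct
predictions and the confidence conf(B_m) is the mean max-probability.
ECE is the occupancy-weighted mean absolute gap

    ECE = sum_m (|B_m| / n) * |acc(B_m) - conf(B_m)|

so ECE = 0 iff every occupied bin is perfectly calibrated, and ECE is at
most 1.  Empty bins carry weight 0 and are reported as nan.  Bins are
left-open right-closed, (m-1)/M < p <= m/M, with the first bin closed at
0; M defaults to 10, the usual reliability-diagram choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .metrics import LabeledPredictions

__all__ = ["CalibrationResult", "bin_predictions", "ece", "DEFAULT_N_BINS"]

DEFAULT_N_BINS = 10


@dataclass
class CalibrationResult:
    """Per-bin occupancy, accuracy, confidence, and the ECE scalar."""

    m_bins: int
    bin_edges: np.ndarray          # (M + 1,) spanning [0, 1]
    bin_count: np.ndarray          # (M,) int
    bin_acc: np.ndarray            # (M,) float, nan on empty bins
    bin_conf: np.ndarray           # (M,) float, nan on empty bins
    n: int
    ece: float

    @property
    def ece_percent(self) -> float:
        """ECE on the 0-100 scale used in printed reports."""
        return 100.0 * self.ece

    def to_frame(self) -> pd.DataFrame:
        """Reliability-diagram table: one row per bin."""
        gap = np.abs(self.bin_acc - self.bin_conf)
        return pd.DataFrame({
            "bin_low": self.bin_edges[:-1],
            "bin_high": self.bin_edges[1:],
            "count": self.bin_count,
            "acc": self.bin_acc,
            "conf": self.bin_conf,
            "gap": gap,
        })


def bin_predictions(lp: LabeledPredictions, m_bins: int = DEFAULT_N_BINS) -> CalibrationResult:
    """Bin predictions by confidence and compute per-bin accuracy,
    per-bin mean confidence, and ECE.

    A sample with confidence p falls in bin ``ceil(p * M)`` (1-based);
    p = 0 joins the first bin.
    """
    if m_bins < 1:
        raise ValidationError("m_bins must be >= 1")
    conf = lp.confidence
    if np.any(conf < 0) or np.any(conf > 1):
        raise ValidationError("confidence values outside [0, 1]")
    n = len(lp)
    idx = np.ceil(conf * m_bins).astype(int)
    idx[idx == 0] = 1
    idx -= 1  # 0-based bin index

    count = np.bincount(idx, minlength=m_bins)
    correct_sum = np.bincount(idx, weights=lp.correct.astype(float), minlength=m_bins)
    conf_sum = np.bincount(idx, weights=conf, minlength=m_bins)

    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(count > 0, correct_sum / np.maximum(count, 1), math.nan)
        mean_conf = np.where(count > 0, conf_sum / np.maximum(count, 1), math.nan)

    occupied = count > 0
    ece_val = float(np.sum(count[occupied] / n * np.abs(acc[occupied] - mean_conf[occupied])))
    return CalibrationResult(
        m_bins=m_bins,
        bin_edges=np.linspace(0.0, 1.0, m_bins + 1),
        bin_count=count,
        bin_acc=acc,
        bin_conf=mean_conf,
        n=n,
        ece=ece_val,
    )


def ece(lp: LabeledPredictions, m_bins: int = DEFAULT_N_BINS) -> float:
    """Expected calibration error; convenience wrapper over
    :func:`bin_predictions`."""
    return bin_predictions(lp, m_bins).ece
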