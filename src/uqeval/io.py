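"""Prediction tables and evaluation reports on disk.

The interchange format is a flat table, CSV by default (JSON as a list
of row objects), with the fixed header

    sample_id, true_label, prob_c0, ..., prob_c{C-1} [, uncertainty]

Row probabilities must sum to 1 within 1e-4 — looser than the internal
1e-6 tolerance so text round-tripping cannot invalidate a table.  When
the ``uncertainty`` column is absent it is filled with the predictive
entropy of the (renormalised) probabilities and that provenance is
recorded on the returned object.

Reports are written with a deterministic field order; CSV cells carry 4
significant digits while JSON keeps full precision; undefined metrics
(nan) are emitted as empty cells / JSON null, never as 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CalibrationResult
from .errors import ValidationError
from .metrics import GroupSummary, LabeledPredictions, ThresholdSweep, predictive_entropy

__all__ = ["read_predictions", "write_predictions", "write_report", "EvaluationReport"]

_ROW_SUM_TOL = 1e-4


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "json"):
        return suffix
    raise ValidationError(f"cannot infer format from {path.name!r}; pass format='csv'|'json'")


def _prob_columns(columns) -> list[str]:
    cols = []
    while f"prob_c{len(cols)}" in columns:
        cols.append(f"prob_c{len(cols)}")
    return cols


def read_predictions(path, format: str | None = None, *,
                     entropy_base: float = 2.0) -> LabeledPredictions:
    """Read and validate a prediction table.

    Raises :class:`ValidationError` naming the first offending row for
    missing columns, non-normalised probability rows, or out-of-range
    labels.  Predicted class and confidence are derived from the
    probabilities (argmax / max after renormalisation).
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        table = pd.read_csv(path, float_precision="round_trip")
    elif fmt == "json":
        table = pd.DataFrame(json.loads(path.read_text()))
    else:
        raise ValidationError(f"unknown format {fmt!r}")

    for col in ("sample_id", "true_label"):
        if col not in table.columns:
            raise ValidationError(f"{path.name}: missing required column {col!r}")
    prob_cols = _prob_columns(table.columns)
    if len(prob_cols) < 2:
        raise ValidationError(
            f"{path.name}: need consecutive probability columns prob_c0, prob_c1, ...")

    probs = table[prob_cols].to_numpy(dtype=float)
    sums = probs.sum(axis=1)
    bad = np.abs(sums - 1.0) > _ROW_SUM_TOL
    if bad.any():
        i = int(np.argmax(bad))
        raise ValidationError(
            f"{path.name}: row {i} (sample_id={table['sample_id'].iloc[i]!r}) "
            f"probabilities sum to {sums[i]:.6g}, outside 1 +/- {_ROW_SUM_TOL:g}")
    n_classes = len(prob_cols)
    labels = table["true_label"].to_numpy(dtype=int)
    out_of_range = (labels < 0) | (labels >= n_classes)
    if out_of_range.any():
        i = int(np.argmax(out_of_range))
        raise ValidationError(
            f"{path.name}: row {i} (sample_id={table['sample_id'].iloc[i]!r}) "
            f"true_label {labels[i]} outside [0, {n_classes})")

    probs = probs / sums[:, None]
    if "uncertainty" in table.columns:
        uncertainty = table["uncertainty"].to_numpy(dtype=float)
        source = "file"
    else:
        uncertainty = np.atleast_1d(predictive_entropy(probs, base=entropy_base))
        source = f"predictive_entropy(base={entropy_base:g})"
    return LabeledPredictions(
        true_label=labels,
        predicted_class=probs.argmax(axis=1),
        uncertainty=uncertainty,
        confidence=probs.max(axis=1),
        n_classes=n_classes,
        probs=probs,
        sample_ids=[str(s) for s in table["sample_id"]],
        uncertainty_source=source,
    )


def write_predictions(lp: LabeledPredictions, path, format: str | None = None) -> Path:
    """Write a prediction table (requires per-class probabilities)."""
    if lp.probs is None:
        raise ValidationError("cannot export a table without per-class probabilities")
    path = Path(path)
    fmt = _infer_format(path, format)
    ids = lp.sample_ids or [f"s{i}" for i in range(len(lp))]
    table = pd.DataFrame({"sample_id": ids, "true_label": lp.true_label})
    for c in range(lp.n_classes):
        table[f"prob_c{c}"] = lp.probs[:, c]
    table["uncertainty"] = lp.uncertainty
    if fmt == "csv":
        table.to_csv(path, index=False)
    else:
        path.write_text(json.dumps(table.to_dict(orient="records")))
    return path


@dataclass
class EvaluationReport:
    """Bundle of evaluation outputs for one prediction table / method."""

    sweep: ThresholdSweep | None = None
    calibration: CalibrationResult | None = None
    groups: GroupSummary | None = None
    metadata: dict = field(default_factory=dict)


def _json_safe(obj):
    """Recursively convert to JSON-encodable values; nan -> null."""
    if isinstance(obj, dict):
        return {k: _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        return None if math.isnan(float(obj)) else float(obj)
    if isinstance(obj, np.ndarray):
        return _json_safe(obj.tolist())
    return obj


def _frame_to_csv(frame: pd.DataFrame, path: Path, index: bool) -> None:
    frame.to_csv(path, index=index, float_format="%.4g", na_rep="")


def write_report(report: EvaluationReport, path, format: str | None = None) -> list[Path]:
    """Write an evaluation report; returns the file(s) written.

    JSON produces one file.  CSV produces one tidy file per section
    (``<stem>_sweep.csv``, ``<stem>_calibration.csv``, ``<stem>_groups.csv``)
    since the sections have different schemas.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        payload: dict = {"metadata": _json_safe(report.metadata)}
        if report.sweep is not None:
            payload["sweep"] = _json_safe(report.sweep.to_frame().to_dict(orient="records"))
        if report.calibration is not None:
            cal = report.calibration
            payload["calibration"] = _json_safe({
                "m_bins": cal.m_bins, "n": cal.n, "ece": cal.ece,
                "ece_percent": cal.ece_percent,
                "bins": cal.to_frame().to_dict(orient="records"),
            })
        if report.groups is not None:
            payload["groups"] = _json_safe({
                "table": report.groups.table.reset_index().to_dict(orient="records"),
                "mean_uncertainty_difference": report.groups.mean_uncertainty_difference,
                "complete": report.groups.complete,
            })
        path.write_text(json.dumps(payload, indent=2, allow_nan=False))
        return [path]

    stem = path.with_suffix("")
    written: list[Path] = []
    if report.sweep is not None:
        p = Path(f"{stem}_sweep.csv")
        _frame_to_csv(report.sweep.to_frame(), p, index=False)
        written.append(p)
    if report.calibration is not None:
        p = Path(f"{stem}_calibration.csv")
        _frame_to_csv(report.calibration.to_frame(), p, index=False)
        written.append(p)
    if report.groups is not None:
        p = Path(f"{stem}_groups.csv")
        _frame_to_csv(report.groups.table.reset_index(), p, index=False)
        written.append(p)
    return written
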