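"""Evaluate predictions produced by any external classifier.

The metrics only need a table of (sample id, true label, per-class
probabilities); this writes one by hand, reads it back — the uncertainty
column is filled with predictive entropy automatically — and evaluates
it at the default threshold.
"""

import tempfile
from pathlib import Path

import pandas as pd

from uqeval import read_predictions, threshold_sweep

table = pd.DataFrame({
    "sample_id": [f"patient-{i}" for i in range(6)],
    "true_label": [0, 0, 0, 1, 1, 1],
    "prob_c0":   [0.97, 0.62, 0.25, 0.10, 0.48, 0.85],
    "prob_c1":   [0.03, 0.38, 0.75, 0.90, 0.52, 0.15],
})

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "external_predictions.csv"
    table.to_csv(path, index=False)
    lp = read_predictions(path)          # entropy filled in, rows validated

print("uncertainty source:", lp.uncertainty_source)
print("accuracy:", round(lp.accuracy, 3))
frame = threshold_sweep(lp, [0.3]).to_frame()
print(frame.round(3).to_string(index=False))
# both errors (patient-2, patient-5) carry enough entropy to be flagged
# (TU=2, FC=0, so USen=1), but three correct borderline predictions are
# flagged too (FU=3), which is what drags UPre down to 0.4
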