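"""Score a small prediction table with the uncertainty confusion matrix.

Builds a four-sample table by hand, computes predictive entropy, the
four outcome counts at threshold 0.3, and the derived metrics.
"""

import numpy as np

from uqeval import (LabeledPredictions, predictive_entropy, uncertainty_confusion,
                    uncertainty_metrics)

# four predictions: two correct/confident, one error flagged by high
# uncertainty, one confidently wrong (the worst outcome)
lp = LabeledPredictions(
    true_label=[0, 0, 1, 1],
    predicted_class=[0, 1, 1, 0],
    uncertainty=[0.10, 0.50, 0.20, 0.25],
    confidence=[0.95, 0.70, 0.90, 0.80],
    n_classes=2,
)

print("binary entropy of (0.9, 0.1):", round(predictive_entropy([0.9, 0.1]), 4))

uc = uncertainty_confusion(lp, threshold=0.3)
print(f"TC={uc.tc} TU={uc.tu} FU={uc.fu} FC={uc.fc} (n={uc.n})")

um = uncertainty_metrics(uc)
print(f"USen={um.usen:.3f}  USpe={um.uspe:.3f}  UPre={um.upre:.3f}  UAcc={um.uacc:.3f}")
# USen: half of the errors were flagged; UAcc: 3 of 4 outcomes are on the
# favourable diagonal (correct&certain or incorrect&uncertain).
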