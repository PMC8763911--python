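"""Measure calibration with equal-width confidence bins and ECE.

Evaluates the ensemble posterior from a reduced study and prints the
reliability table (per-bin accuracy vs mean confidence) and the expected
calibration error.
"""

from uqeval import StudyConfig, run_study

result = run_study(StudyConfig(n_members=10, mc_passes=50, seed=4,
                               methods=("ensemble",)))
cal = result.methods["ensemble"].report.calibration

table = cal.to_frame()
print(table[table["count"] > 0].round(3).to_string(index=False))
print(f"\nECE = {cal.ece:.4f}  ({cal.ece_percent:.2f} on the percent scale)")
# each row compares how often predictions in a confidence bin were right
# (acc) with how confident they claimed to be (conf); ECE is the
# occupancy-weighted mean of the |acc - conf| gaps
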