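"""Classify events with the two threshold rules and sweep the thresholds.

The moving-SD rule fires when >10 of 75 bins in a row stay below sigma =
0.003 (normalized units) after fractional position 0.7; the spectral-entropy
rule fires when any spectrogram frame past 0.7 drops below SE = 0.495.
"""

import numpy as np

from poredelay.rules import classify_msd, classify_se, dynamic_range, sweep_threshold
from poredelay.sim import SimConfig, generate_dataset

cfg = SimConfig()
events = generate_dataset(cfg, 60, 60, seed=3)

msd_calls = [classify_msd(ev) for ev in events]
se_calls = [classify_se(ev) for ev in events]
for name, calls in (("MSD", msd_calls), ("SE", se_calls)):
    tp = sum(c.label == "delayed" and e.label == "delayed" for c, e in zip(calls, events))
    fp = sum(c.label == "delayed" and e.label != "delayed" for c, e in zip(calls, events))
    print(f"{name}: recall {tp / 60:.3f}, false positives {fp}/60")

# Threshold calibration: emulate a 0 nM vs 100 nM pair of cohorts and plot
# the dynamic range (difference in % delayed) across thresholds.
for i, ev in enumerate(events):
    ev.meta["concentration"] = 100.0 if ev.label == "delayed" else 0.0

thresholds = [0.001, 0.002, 0.003, 0.004, 0.005]
sweep = sweep_threshold(events, "msd", thresholds)
dr = dynamic_range(sweep, high_group=100.0, low_group=0.0)
print("\nMSD threshold sweep (dynamic range = % delayed at 100 nM - at 0 nM):")
for _, row in dr.iterrows():
    print(f"  sigma < {row['threshold']:.3f}  ->  dynamic range {row['dynamic_range']:5.1f}%")
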