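"""Compute the 12 per-frame features on a spindle frame vs a quiet frame.

Shows which feature families (PSD band powers, CWT sigma-scale summaries,
the probability-plot score NGS, the bispectrum band ratio BGS) separate
the two classes on a single high-SNR example.
"""
import numpy as np

from spindilometer.features import FEATURE_NAMES, assemble_features
from spindilometer.simkit import SimConfig, label_segments, simulate_recording

config = SimConfig(seed=7, duration_s=120.0, amp_sigma_ratio=4.0,
                   channels=("C4-M1",))
recording, events = simulate_recording(config)
labels = label_segments(events, recording.channel_labels,
                        recording.duration_s)[0]

frame_len = int(10 * config.fs)
spindle_k = int(np.flatnonzero(labels == 1)[0])
quiet_k = int(np.flatnonzero(labels == 0)[0])

rows = {}
for name, k in (("spindle", spindle_k), ("quiet", quiet_k)):
    x = recording.samples[0, k * frame_len:(k + 1) * frame_len]
    rows[name] = assemble_features(x, config.fs)

print(f"{'feature':18s} {'spindle frame':>14s} {'quiet frame':>12s}")
for feat in FEATURE_NAMES:
    print(f"{feat:18s} {rows['spindle'][feat]:14.4f} {rows['quiet'][feat]:12.4f}")

print("\nrelative sigma power, sigma-scale wavelet energy and BGS rise on the")
print("spindle frame; NGS drops below the Gaussian background's score of ~1.")
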