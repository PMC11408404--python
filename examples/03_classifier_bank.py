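"""Benchmark all five classifiers on the same simulated feature table.

Runs the full pipeline (simulate -> features -> ANOVA-F selection -> train
-> frame-level evaluation) once per algorithm on a small 3-recording
problem and prints the comparison table.
"""
import tempfile

from spindilometer.modelkit import ALGORITHMS
from spindilometer.pipeline import RunConfig, run_pipeline
from spindilometer.simkit import SimConfig

print(f"{'algorithm':10s} {'accuracy':>9s} {'sens':>7s} {'spec':>7s} "
      f"{'F1':>7s} {'AUC':>7s}")
for algorithm in ALGORITHMS:
    config = RunConfig(sim=SimConfig(duration_s=240.0), n_records=3,
                       algorithm=algorithm)
    with tempfile.TemporaryDirectory() as tmp:
        report = run_pipeline(config, tmp)
    m = report["metrics"]
    print(f"{algorithm:10s} {m['accuracy']:9.4f} {m['sensitivity']:7.4f} "
          f"{m['specificity']:7.4f} {m['f1']:7.4f} {report['auc']:7.4f}")

print("\nAll five detect high-SNR spindle frames well; differences grow at")
print("lower amplitude ratios (try SimConfig(amp_sigma_ratio=1.2)).")
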