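"""Fit the presence/pseudo-absence ensemble and project suitability.

Runs the sdm stage and reports held-out AUC and TSS per species and
algorithm (the model-performance table of the analysis).
"""

import importlib.util
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).with_name("00_config.py"))
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from refugia.pipeline import PipelineConfig, run_stage

run_dir = cfg00.RUN_DIR
cfg = PipelineConfig.from_yaml(run_dir / "config.yaml")
run_stage("sdm", cfg, run_dir)

cfg00.publish(run_dir / "sdm" / "evals.csv", run_dir / "sdm" / "evals_summary.csv")
summary = pd.read_csv(run_dir / "sdm" / "evals_summary.csv")
print("held-out model performance (mean over PA sets x split repeats, sd in brackets):")
for _, row in summary.iterrows():
    print(f"  {row['species']:>16} {row['algorithm']:>15}: "
          f"AUC {row['auc_mean']:.3f} ({row['auc_std']:.3f})  "
          f"TSS {row['tss_mean']:.3f} ({row['tss_std']:.3f})")
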