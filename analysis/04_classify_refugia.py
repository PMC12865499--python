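"""Type persistence areas and measure distances to suitable habitat.

Runs the classify stage and reports, per species and scenario, the share of
occurrences in long-term refugia, holdouts and stepping-stone service areas,
plus the median distance to the nearest suitable cell at each future slice.
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
run_stage("classify", cfg, run_dir)

cfg00.publish(run_dir / "classify" / "refugia_percentages.csv",
              run_dir / "classify" / "occurrence_status.csv")
pct = pd.read_csv(run_dir / "classify" / "refugia_percentages.csv")
print("occurrences by persistence category (%):")
print(pct.round(1).to_string(index=False))

status = pd.read_csv(run_dir / "classify" / "occurrence_status.csv")
dist_cols = [c for c in status.columns if c.startswith("distance_km")]
med = status.groupby(["species", "scenario"])[dist_cols].median()
print("\nmedian distance to nearest suitable cell (km; NaN = none anywhere):")
print(med.round(2).to_string())
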