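"""Summary statistics: suitability trajectories and refugia placement.

Runs the summarise stage and reports the headline patterns: how median
suitability at known occurrences changes through the time slices under each
scenario, and where the refugia types sit on the elevation gradient.
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
run_stage("summarise", cfg, run_dir)

cfg00.publish(run_dir / "summarise" / "hs_trajectories.csv",
              run_dir / "summarise" / "hs_by_elevation.csv",
              run_dir / "summarise" / "refugia_positions.csv")
traj = pd.read_csv(run_dir / "summarise" / "hs_trajectories.csv")
piv = traj.pivot_table(index=["species", "scenario"], columns="slice",
                       values="median")
piv = piv[["current", "2021-2040", "2041-2060", "2061-2080"]]
print("median habitat suitability at occurrences, by time slice:")
print(piv.round(3).to_string())

pos = pd.read_csv(run_dir / "summarise" / "refugia_positions.csv")
elev = pos[pos["variable"] == "elevation_m"].pivot_table(
    index=["species", "scenario"], columns="category", values="median")
print("\nmedian elevation (m) of persistence-area cells by category:")
print(elev.round(0).to_string())
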