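"""Reduce the pooled bioclim bands to two PCs and downscale them to 300 m.

Runs the prep stage and reports the PCA variance split and how faithfully
the downscaled fields re-aggregate onto the coarse climate grid.
"""

import importlib.util
from pathlib import Path

import numpy as np

spec = importlib.util.spec_from_file_location(
    "cfg00", Path(__file__).with_name("00_config.py"))
cfg00 = importlib.util.module_from_spec(spec)
spec.loader.exec_module(cfg00)

from refugia.climate_prep import PcaBasis
from refugia.pipeline import PipelineConfig, run_stage
from refugia.raster import read_stack

run_dir = cfg00.RUN_DIR
cfg = PipelineConfig.from_yaml(run_dir / "config.yaml")
run_stage("prep", cfg, run_dir)

basis = PcaBasis.from_json(run_dir / "prep" / "pca_basis.json")
evr = basis.explained_variance_ratio
print(f"pooled PCA: axis 1 explains {100 * evr[0]:.1f}% of band variance, "
      f"axis 2 {100 * evr[1]:.1f}%")

for scen in cfg.scenarios:
    coarse = read_stack(run_dir / "simulate" / f"climate_{scen}_slice0.json")
    fine = read_stack(run_dir / "prep" / f"pc_fine_{scen}_slice0.json")
    reagg = fine.band(0).block_aggregate(cfg.landscape.coarse_factor)
    # correlation against the coarse PC1 requires reprojecting the coarse
    # bands onto the shared basis
    pc_coarse = basis.project_raster(coarse).band(0)
    r = np.corrcoef(reagg.data.ravel(), pc_coarse.data.ravel())[0, 1]
    print(f"{scen}: downscaled PC1 re-aggregates onto the coarse grid at r={r:.3f}")
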