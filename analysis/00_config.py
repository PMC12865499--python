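"""Shared study configuration for the numbered analysis scripts.

Two synthetic species on one 48x48 landscape (300 m cells, ~1 km coarse
climate): a summit specialist whose thermal optimum lies beyond the coldest
cell on the map, and a montane species centred at 1500 m. Both emission
scenarios are carried through every stage. Import `RUN_DIR` and `config()`
from the later scripts; run 01..05 in order.
"""

import shutil
from pathlib import Path

from refugia.pipeline import PipelineConfig, SpeciesConfig
from refugia.synthetic import ClimateConfig, LandscapeConfig

_ROOT = Path(__file__).resolve().parent.parent
RUN_DIR = _ROOT / "scratch" / "analysis_run"   # rasters and intermediates
TABLES_DIR = _ROOT / "results"                 # published tables


def publish(*paths: Path) -> None:
    """Copy stage tables into results/ (the run directory holds the rasters)."""
    TABLES_DIR.mkdir(parents=True, exist_ok=True)
    for p in paths:
        shutil.copy2(p, TABLES_DIR / p.name)


def config(master_seed: int = 1) -> PipelineConfig:
    return PipelineConfig(
        landscape=LandscapeConfig(nrows=48, ncols=48, relief_smoothness=5.0, seed=1),
        climate=ClimateConfig(n_bioclim=19, seed=2),
        species=[
            SpeciesConfig(name="summit_endemic", n_occurrences=120),
            SpeciesConfig(name="montane_endemic", optimum_elev_m=1500.0,
                          breadth_K=2.0, n_occurrences=120),
        ],
        n_pa_sets=5,
        n_pa_each=1000,
        cv_repeats=5,
        master_seed=master_seed,
    )
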