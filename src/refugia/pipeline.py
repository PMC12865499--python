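"""End-to-end orchestration: simulate -> prep -> sdm -> classify -> summarise.

Each stage writes its outputs under its own subdirectory of the run
directory and consumes the previous stage's files, so stages can be re-run
independently from the command line. A provenance manifest records the
configuration hash, derived seeds and package versions. The whole run is a
pure function of the configuration: identical config (including the master
seed) gives byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import derive_seed
from .climate_prep import PcaBasis, derive_physiography, gwr_downscale, pool_pca
from .raster import Raster, read_ascii_grid, read_stack, write_ascii_grid, write_stack
from .refugia import classify_refugia, occurrence_distances
from .sdm import (SuitabilityStack, build_presence_background, ensemble_predict,
                  evals_table, fit_ensemble, sample_pseudo_absences,
                  summarize_evals, thin_occurrences)
from .summaries import (refugia_position_stats, suitability_by_elevation,
                        suitability_trajectories)
from .synthetic import (SLICE_LABELS, ClimateConfig, LandscapeConfig, OccurrenceSet,
                        cold_adapted_niche, generate_climate_series, generate_dem,
                        niche_at_elevation, sample_occurrences,
                        true_suitability_series)

log = logging.getLogger("refugia")

STAGES = ["simulate", "prep", "sdm", "classify", "summarise"]


@dataclass
class SpeciesConfig:
    """A synthetic species: its thermal niche and how many occurrences to draw.

    ``optimum_elev_m=None`` places the thermal optimum just beyond the
    coldest cell on the map (a summit specialist); otherwise the optimum is
    the current temperature at that elevation.
    """

    name: str = "species_1"
    optimum_elev_m: float | None = None
    breadth_K: float = 2.5
    max_prevalence: float = 0.9
    n_occurrences: int = 80
    margin_K: float = 1.0


@dataclass
class PipelineConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    species: list[SpeciesConfig] = field(default_factory=lambda: [SpeciesConfig()])
    scenarios: list[str] = field(default_factory=lambda: ["ssp245", "ssp585"])
    algorithms: list[str] = field(default_factory=lambda: ["sre", "logistic_poly2"])
    n_pa_sets: int = 10
    n_pa_each: int = 10_000
    cv_repeats: int = 10
    train_frac: float = 0.7
    sre_quantile: float = 0.025
    tss_min: float = 0.4
    suitability_threshold: float = 0.5
    adjacency: int = 8
    bandwidth_cells: float = 5.0
    elevation_band_m: float = 250.0
    pca_standardize: bool = True
    master_seed: int = 1

    def __post_init__(self) -> None:
        unknown = [s for s in self.scenarios if s not in self.climate.warming_deltas_K]
        if unknown:
            raise ValueError(
                f"unknown scenario label(s) {unknown}; configured: "
                f"{self.climate.scenarios}"
            )
        if not self.species:
            raise ValueError("at least one species must be configured")
        if self.adjacency not in (4, 8):
            raise ValueError("adjacency must be 4 or 8")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["landscape"]["elev_range_m"] = list(d["landscape"]["elev_range_m"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ls = dict(d.pop("landscape", {}))
        if "elev_range_m" in ls:
            ls["elev_range_m"] = tuple(ls["elev_range_m"])
        cl = dict(d.pop("climate", {}))
        sp = [SpeciesConfig(**s) for s in d.pop("species", [])] or None
        kwargs = dict(landscape=LandscapeConfig(**ls), climate=ClimateConfig(**cl), **d)
        if sp is not None:
            kwargs["species"] = sp
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def reduced_config(master_seed: int = 1) -> PipelineConfig:
    """A desk-scale configuration for smoke runs and determinism checks."""
    return PipelineConfig(
        landscape=LandscapeConfig(nrows=24, ncols=24, relief_smoothness=4.0),
        species=[SpeciesConfig(name="summit_endemic", n_occurrences=50)],
        n_pa_sets=2,
        n_pa_each=500,
        cv_repeats=3,
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _niche(sp: SpeciesConfig, dem: Raster, climate: ClimateConfig):
    if sp.optimum_elev_m is None:
        return cold_adapted_niche(dem, climate, margin_K=sp.margin_K,
                                  breadth_K=sp.breadth_K,
                                  max_prevalence=sp.max_prevalence)
    return niche_at_elevation(dem, climate, sp.optimum_elev_m,
                              breadth_K=sp.breadth_K,
                              max_prevalence=sp.max_prevalence)


def synthetic_coastline(cfg: LandscapeConfig, offset_km: float = 12.0) -> np.ndarray:
    """A straight coastline south of the grid (the sea lies below the map)."""
    width = cfg.ncols * cfg.cell_size_m
    y = -offset_km * 1000.0
    return np.array([[-width, y], [2 * width, y]])


def stage_simulate(cfg: PipelineConfig, run_dir: Path) -> None:
    """Terrain, coarse climates, true suitability and sampled occurrences."""
    out = run_dir / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    dem = generate_dem(cfg.landscape)
    write_ascii_grid(dem, out / "dem.asc")
    coast = synthetic_coastline(cfg.landscape)
    pd.DataFrame(coast, columns=["x", "y"]).to_csv(out / "coastline.csv", index=False)
    for scen in cfg.scenarios:
        series = generate_climate_series(dem, cfg.climate, scen,
                                         coarse_factor=cfg.landscape.coarse_factor)
        for s, raster in enumerate(series):
            write_stack(raster, out, f"climate_{scen}_slice{s}")
    occ_tables = []
    for sp in cfg.species:
        niche = _niche(sp, dem, cfg.climate)
        truth = true_suitability_series(dem, cfg.climate, cfg.scenarios[0], niche)
        write_ascii_grid(truth[0], out / f"truth_current_{sp.name}.asc")
        occ = sample_occurrences(truth[0], sp.n_occurrences,
                                 seed=derive_seed(cfg.master_seed, "occ", sp.name),
                                 species=sp.name, dem=dem)
        occ_tables.append(occ.table)
    pd.concat(occ_tables, ignore_index=True).to_csv(out / "occurrences.csv", index=False)


def stage_prep(cfg: PipelineConfig, run_dir: Path) -> None:
    """Physiography, pooled PCA and GWR-downscaled fine PC predictors."""
    sim, out = run_dir / "simulate", run_dir / "prep"
    out.mkdir(parents=True, exist_ok=True)
    dem = read_ascii_grid(sim / "dem.asc")
    coast = pd.read_csv(sim / "coastline.csv").to_numpy()
    physio = derive_physiography(dem, coast)
    write_stack(physio.as_raster(), out, "physiography",
                band_names=["elevation", "slope", "northness", "eastness",
                            "irradiation", "coast_distance"])
    stacks = {
        (scen, s): read_stack(sim / f"climate_{scen}_slice{s}.json")
        for scen in cfg.scenarios for s in range(4)
    }
    basis, pc_coarse = pool_pca(stacks, standardize=cfg.pca_standardize)
    basis.to_json(out / "pca_basis.json")
    for (scen, s), pc in pc_coarse.items():
        fine_bands = [
            gwr_downscale(pc.band(i), physio, bandwidth_cells=cfg.bandwidth_cells)
            for i in range(2)
        ]
        fine = dem.like(np.stack([b.data for b in fine_bands]))
        write_stack(fine, out, f"pc_fine_{scen}_slice{s}", band_names=["pc1", "pc2"])


def _read_pc_fine(run_dir: Path, scen: str) -> dict[str, Raster]:
    return {SLICE_LABELS[s]: read_stack(run_dir / "prep" / f"pc_fine_{scen}_slice{s}.json")
            for s in range(4)}


def stage_sdm(cfg: PipelineConfig, run_dir: Path) -> None:
    """Thinning, pseudo-absences, ensemble fitting, evaluation, projection."""
    sim, out = run_dir / "simulate", run_dir / "sdm"
    out.mkdir(parents=True, exist_ok=True)
    all_occ = pd.read_csv(sim / "occurrences.csv")
    pc_by_scen = {scen: _read_pc_fine(run_dir, scen) for scen in cfg.scenarios}
    domain = pc_by_scen[cfg.scenarios[0]]["current"]
    evals, summaries = [], []
    for sp in cfg.species:
        occ = OccurrenceSet(all_occ[all_occ["species"] == sp.name])
        occ = thin_occurrences(occ, domain)
        pa = sample_pseudo_absences(
            domain, occ, n_sets=cfg.n_pa_sets, n_each=cfg.n_pa_each,
            seed=derive_seed(cfg.master_seed, "pa", sp.name))
        pb = build_presence_background(occ, domain, pa)
        members = fit_ensemble(
            pb, algorithms=cfg.algorithms, sre_quantile=cfg.sre_quantile,
            train_frac=cfg.train_frac, repeats=cfg.cv_repeats,
            seed=derive_seed(cfg.master_seed, "ensemble", sp.name))
        et = evals_table(members)
        et.insert(0, "species", sp.name)
        evals.append(et)
        st = summarize_evals(members)
        st.insert(0, "species", sp.name)
        summaries.append(st)
        for scen in cfg.scenarios:
            stack = ensemble_predict(members, pc_by_scen[scen],
                                     tss_min=cfg.tss_min, species=sp.name,
                                     scenario=scen)
            for s, raster in enumerate(stack.rasters):
                write_ascii_grid(raster, out / f"hs_{sp.name}_{scen}_slice{s}.asc")
    pd.concat(evals, ignore_index=True).to_csv(out / "evals.csv", index=False)
    pd.concat(summaries, ignore_index=True).to_csv(out / "evals_summary.csv", index=False)


def _read_hs_stack(run_dir: Path, species: str, scen: str) -> SuitabilityStack:
    rasters = [read_ascii_grid(run_dir / "sdm" / f"hs_{species}_{scen}_slice{s}.asc")
               for s in range(4)]
    return SuitabilityStack(species=species, scenario=scen, rasters=rasters)


def stage_classify(cfg: PipelineConfig, run_dir: Path) -> None:
    """Refugia typing, occurrence statuses and nearest-suitable distances."""
    sim, out = run_dir / "simulate", run_dir / "classify"
    out.mkdir(parents=True, exist_ok=True)
    all_occ = pd.read_csv(sim / "occurrences.csv")
    pct_rows, status_tables = [], []
    for sp in cfg.species:
        occ = OccurrenceSet(all_occ[all_occ["species"] == sp.name])
        for scen in cfg.scenarios:
            stack = _read_hs_stack(run_dir, sp.name, scen)
            occ_t = thin_occurrences(occ, stack.grid)
            refmap = classify_refugia(stack, occ_t,
                                      threshold=cfg.suitability_threshold,
                                      adjacency=cfg.adjacency)
            write_ascii_grid(refmap.categories,
                             out / f"refugia_{sp.name}_{scen}.asc")
            st = refmap.status.merge(
                occurrence_distances(occ_t, stack, cfg.suitability_threshold),
                on=list(occ_t.table.columns))
            st.insert(0, "scenario", scen)
            status_tables.append(st)
            pct_rows.append({"species": sp.name, "scenario": scen,
                             **{f"pct_{k}": v for k, v in refmap.percentages.items()}})
    pd.concat(status_tables, ignore_index=True).to_csv(
        out / "occurrence_status.csv", index=False)
    pd.DataFrame(pct_rows).to_csv(out / "refugia_percentages.csv", index=False)


def stage_summarise(cfg: PipelineConfig, run_dir: Path) -> None:
    """Boxplot statistics behind the trajectory, elevation and position figures."""
    sim, out = run_dir / "simulate", run_dir / "summarise"
    out.mkdir(parents=True, exist_ok=True)
    dem = read_ascii_grid(sim / "dem.asc")
    all_occ = pd.read_csv(sim / "occurrences.csv")
    stacks, occs = {}, {}
    for sp in cfg.species:
        occ = OccurrenceSet(all_occ[all_occ["species"] == sp.name])
        occs[sp.name] = thin_occurrences(occ, dem)
        for scen in cfg.scenarios:
            stacks[(sp.name, scen)] = _read_hs_stack(run_dir, sp.name, scen)
    suitability_trajectories(stacks, occs).to_csv(
        out / "hs_trajectories.csv", index=False)
    suitability_by_elevation(stacks, occs, band_width_m=cfg.elevation_band_m).to_csv(
        out / "hs_by_elevation.csv", index=False)
    pos_rows = []
    for (sp_name, scen), stack in stacks.items():
        refmap = classify_refugia(stack, occs[sp_name],
                                  threshold=cfg.suitability_threshold,
                                  adjacency=cfg.adjacency)
        ps = refugia_position_stats(refmap, occs[sp_name], dem)
        ps.insert(0, "scenario", scen)
        ps.insert(0, "species", sp_name)
        pos_rows.append(ps)
    pd.concat(pos_rows, ignore_index=True).to_csv(
        out / "refugia_positions.csv", index=False)


_STAGE_FN = {
    "simulate": stage_simulate,
    "prep": stage_prep,
    "sdm": stage_sdm,
    "classify": stage_classify,
    "summarise": stage_summarise,
}


def run_stage(name: str, cfg: PipelineConfig, run_dir: str | Path) -> None:
    """Run one named stage; on failure its partial outputs move to failed/."""
    run_dir = Path(run_dir)
    t0 = time.perf_counter()
    log.info("stage %s: starting", name)
    try:
        _STAGE_FN[name](cfg, run_dir)
    except Exception as exc:
        partial = run_dir / name
        if partial.exists():
            dest = run_dir / "failed" / name
            dest.parent.mkdir(parents=True, exist_ok=True)
            if dest.exists():
                shutil.rmtree(dest)
            partial.rename(dest)
        raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def run_pipeline(cfg: PipelineConfig, run_dir: str | Path) -> Path:
    """Execute all stages and write a provenance manifest. Returns run_dir."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(run_dir / "config.yaml")
    handler = logging.FileHandler(run_dir / "run.log")
    log.addHandler(handler)
    try:
        for name in STAGES:
            run_stage(name, cfg, run_dir)
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest = {
        "config_hash": cfg.config_hash(),
        "master_seed": cfg.master_seed,
        "stages": STAGES,
        "versions": {"refugia": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return run_dir
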