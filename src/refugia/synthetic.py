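"""Seeded synthetic landscapes, climates, niches and occurrences.

The generator emulates the statistical structure the downstream analysis
assumes: a fine-resolution DEM with controllable relief, coarse multi-band
"bioclimatic" fields whose temperature band cools with elevation and warms
through three future time slices (more under the harsher emission scenario),
a known Gaussian-kernel "true" niche, and presence points sampled from the
true suitability surface. Because the truth is known, every downstream stage
(downscaling, SDM fitting, refugia typing) can be tested for recovery, not
just for internal consistency.

All generators are pure functions of (config, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ._seeds import derive_seed
from .raster import Raster

SLICE_LABELS = ["current", "2021-2040", "2041-2060", "2061-2080"]


# ---------------------------------------------------------------------------
# Configurations
# ---------------------------------------------------------------------------

@dataclass
class LandscapeConfig:
    """Fine-grid terrain generator settings.

    The fine grid emulates a 300 m analysis grid; ``coarse_factor`` is the
    ratio of the coarse climate grid to the fine grid (3 emulates ~1 km
    climate over 300 m terrain).
    """

    nrows: int = 48
    ncols: int = 48
    cell_size_m: float = 300.0
    coarse_factor: int = 3
    elev_range_m: tuple[float, float] = (0.0, 3000.0)
    seed: int = 0
    relief_smoothness: float = 6.0  # Gaussian-filter sigma, in cells

    def __post_init__(self) -> None:
        if self.nrows < 8 or self.ncols < 8:
            raise ValueError("grid must be at least 8x8")
        if self.coarse_factor < 1:
            raise ValueError("coarse_factor must be >= 1")
        if self.nrows % self.coarse_factor or self.ncols % self.coarse_factor:
            raise ValueError(
                f"coarse_factor {self.coarse_factor} must divide grid "
                f"({self.nrows}x{self.ncols})"
            )
        lo, hi = self.elev_range_m
        if not hi > lo:
            raise ValueError("elev_range_m must be (min, max) with max > min")
        if not self.relief_smoothness > 0:
            raise ValueError("relief_smoothness must be positive")


@dataclass
class ClimateConfig:
    """Coarse climate generator settings.

    Band 1 is temperature-like (deg C): a sea-level baseline plus a linear
    elevational lapse plus a per-slice warming delta plus seeded noise. The
    remaining bands are affine transforms of the temperature signal plus
    independent noise — enough correlation structure to make a principal
    component analysis of the pooled bands non-trivial. The second half of
    the bands is treated as moisture-like and additionally scaled by the
    per-slice ``precip_trend`` factor.

    Warming deltas are Kelvin offsets for the three future slices and must
    be non-decreasing within each scenario; when both default scenarios are
    configured the harsher one (ssp585) must end strictly warmer.
    """

    n_bioclim: int = 19
    baseline_temp_C: float = 14.0
    lapse_rate_K_per_km: float = -6.0
    warming_deltas_K: dict[str, list[float]] = field(
        default_factory=lambda: {"ssp245": [0.8, 1.4, 1.9], "ssp585": [1.0, 2.2, 3.6]}
    )
    precip_trend: dict[str, list[float]] = field(
        default_factory=lambda: {"ssp245": [0.98, 0.96, 0.94], "ssp585": [0.97, 0.92, 0.86]}
    )
    noise_sd: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bioclim < 1:
            raise ValueError("n_bioclim must be >= 1")
        for scen, deltas in self.warming_deltas_K.items():
            if len(deltas) != 3:
                raise ValueError(f"scenario {scen!r} needs 3 warming deltas")
            if any(b < a for a, b in zip(deltas, deltas[1:])):
                raise ValueError(f"warming deltas for {scen!r} must be non-decreasing")
        for scen in self.warming_deltas_K:
            if scen not in self.precip_trend:
                raise ValueError(f"scenario {scen!r} missing from precip_trend")
        d = self.warming_deltas_K
        if "ssp245" in d and "ssp585" in d and not d["ssp585"][-1] > d["ssp245"][-1]:
            raise ValueError("ssp585 end-of-century delta must exceed ssp245's")

    @property
    def scenarios(self) -> list[str]:
        return list(self.warming_deltas_K)


@dataclass
class TrueNiche:
    """Gaussian-kernel niche: a product of per-predictor Gaussian kernels.

    True suitability at predictor vector z is
    ``max_prevalence * prod_k exp(-0.5 ((z_k - optimum_k)/breadth_k)^2)``,
    which lies in (0, max_prevalence] and peaks at ``optimum``.
    """

    optimum: np.ndarray
    breadth: np.ndarray
    max_prevalence: float = 0.9

    def __post_init__(self) -> None:
        self.optimum = np.atleast_1d(np.asarray(self.optimum, dtype=float))
        self.breadth = np.atleast_1d(np.asarray(self.breadth, dtype=float))
        if self.optimum.shape != self.breadth.shape:
            raise ValueError("optimum and breadth must have the same length")
        if not np.all(self.breadth > 0):
            raise ValueError("breadth must be positive")
        if not (0 < self.max_prevalence <= 1):
            raise ValueError("max_prevalence must be in (0, 1]")

    @property
    def dim(self) -> int:
        return self.optimum.size


# ---------------------------------------------------------------------------
# Occurrences
# ---------------------------------------------------------------------------

OCC_COLUMNS = ["species", "x", "y", "row", "col", "elevation"]


@dataclass
class OccurrenceSet:
    """Presence points with species label, grid indices and elevation."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in OCC_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"occurrence table missing columns {missing}")
        self.table = self.table[OCC_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def rc(self) -> np.ndarray:
        """(n, 2) integer array of (row, col) grid indices."""
        return self.table[["row", "col"]].to_numpy(dtype=int)

    def cell_mask(self, grid: Raster) -> np.ndarray:
        """Boolean occupancy mask on ``grid``."""
        m = np.zeros(grid.shape, dtype=bool)
        rc = self.rc
        if np.any((rc < 0) | (rc >= [grid.nrows, grid.ncols])):
            raise ValueError("occurrence indices fall outside the grid")
        m[rc[:, 0], rc[:, 1]] = True
        return m

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.table.to_csv(path, index=False)
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def generate_dem(config: LandscapeConfig) -> Raster:
    """Seeded Gaussian-filtered white noise rescaled to the elevation range.

    In the infinite-smoothness limit the relief collapses to a constant
    surface at mid-range elevation.
    """
    lo, hi = config.elev_range_m
    mid = 0.5 * (lo + hi)
    if not math.isfinite(config.relief_smoothness):
        data = np.full((config.nrows, config.ncols), mid)
    else:
        rng = np.random.default_rng(derive_seed(config.seed, "dem"))
        noise = rng.standard_normal((config.nrows, config.ncols))
        smooth = gaussian_filter(noise, sigma=config.relief_smoothness, mode="reflect")
        span = np.ptp(smooth)
        if span == 0:
            data = np.full_like(smooth, mid)
        else:
            data = np.clip(lo + (smooth - smooth.min()) * (hi - lo) / span, lo, hi)
    return Raster(data, x_origin=0.0, y_origin=config.nrows * config.cell_size_m,
                  cell_size=config.cell_size_m)


def _temperature_signal(elev_m: np.ndarray, config: ClimateConfig) -> np.ndarray:
    return config.baseline_temp_C + config.lapse_rate_K_per_km * (elev_m / 1000.0)


def _band_coefficients(config: ClimateConfig, band: int) -> tuple[float, float]:
    rng = np.random.default_rng(derive_seed(config.seed, "band_coef", band))
    slope = rng.uniform(0.4, 1.2) * rng.choice([-1.0, 1.0])
    intercept = rng.uniform(-3.0, 3.0)
    return intercept, slope


def generate_climate_series(dem: Raster, config: ClimateConfig, scenario: str,
                            coarse_factor: int = 3) -> list[Raster]:
    """Four coarse multi-band climate rasters (current + three future slices).

    Noise fields are derived from (seed, slice, band) only, i.e. shared
    between scenarios: the two scenarios form a paired design that differs
    exactly by the configured warming deltas and moisture trends, so
    scenario-ordering properties hold per seed rather than only on average.
    """
    if scenario not in config.warming_deltas_K:
        raise ValueError(
            f"scenario {scenario!r} not configured; known: {config.scenarios}"
        )
    elev_c = dem.block_aggregate(coarse_factor)
    t_signal = _temperature_signal(elev_c.data, config)
    deltas = [0.0] + list(config.warming_deltas_K[scenario])
    trends = [1.0] + list(config.precip_trend[scenario])
    moisture_from = max(1, config.n_bioclim // 2)  # bands [moisture_from:] get the trend
    out = []
    for s, (delta, trend) in enumerate(zip(deltas, trends)):
        bands = np.empty((config.n_bioclim, elev_c.nrows, elev_c.ncols))
        for b in range(config.n_bioclim):
            rng = np.random.default_rng(derive_seed(config.seed, "climate_noise", s, b))
            noise = config.noise_sd * rng.standard_normal(elev_c.shape)
            if b == 0:
                bands[b] = t_signal + delta + noise
            else:
                intercept, slope = _band_coefficients(config, b)
                base = intercept + slope * (t_signal + delta)
                if b >= moisture_from:
                    base = base * trend
                bands[b] = base + noise
        out.append(elev_c.like(bands))
    return out


def generate_true_suitability(climate: Raster, niche: TrueNiche) -> Raster:
    """True suitability of a multi-band predictor raster under a Gaussian niche."""
    nb = climate.nbands
    if nb != niche.dim:
        raise ValueError(f"climate has {nb} bands but niche has dimension {niche.dim}")
    bands = climate.data if climate.data.ndim == 3 else climate.data[None]
    z = (bands - niche.optimum[:, None, None]) / niche.breadth[:, None, None]
    suit = niche.max_prevalence * np.exp(-0.5 * np.sum(z * z, axis=0))
    suit = np.where(climate.mask, suit, climate.nodata)
    return Raster(suit, climate.x_origin, climate.y_origin, climate.cell_size, climate.nodata)


def fine_temperature_series(dem: Raster, config: ClimateConfig, scenario: str) -> list[Raster]:
    """Noise-free fine-grid temperature for the four slices (truth oracle)."""
    if scenario not in config.warming_deltas_K:
        raise ValueError(f"scenario {scenario!r} not configured")
    t = _temperature_signal(dem.data, config)
    deltas = [0.0] + list(config.warming_deltas_K[scenario])
    return [dem.like(t + d) for d in deltas]


def true_suitability_series(dem: Raster, config: ClimateConfig, scenario: str,
                            niche: TrueNiche) -> list[Raster]:
    """True fine-grid suitability for the four slices from noise-free temperature.

    Requires a one-dimensional (temperature-space) niche.
    """
    if niche.dim != 1:
        raise ValueError("true_suitability_series expects a 1-D temperature niche")
    return [generate_true_suitability(t, niche)
            for t in fine_temperature_series(dem, config, scenario)]


def cold_adapted_niche(dem: Raster, config: ClimateConfig, margin_K: float = 1.0,
                       breadth_K: float = 2.5, max_prevalence: float = 0.9) -> TrueNiche:
    """A summit specialist: thermal optimum colder than any cell on the map.

    Every cell then sits on the warm side of the optimum, so any warming
    strictly lowers true suitability everywhere — the cleanest possible
    test-bed for scenario-ordering properties.
    """
    t_min = _temperature_signal(dem.data, config).min()
    return TrueNiche(optimum=[t_min - margin_K], breadth=[breadth_K],
                     max_prevalence=max_prevalence)


def niche_at_elevation(dem: Raster, config: ClimateConfig, elev_m: float,
                       breadth_K: float = 2.0, max_prevalence: float = 0.9) -> TrueNiche:
    """A niche whose thermal optimum is the current temperature at ``elev_m``."""
    opt = config.baseline_temp_C + config.lapse_rate_K_per_km * elev_m / 1000.0
    return TrueNiche(optimum=[opt], breadth=[breadth_K], max_prevalence=max_prevalence)


def sample_occurrences(truth: Raster, n_target: int, seed: int,
                       species: str = "species_1", dem: Raster | None = None) -> OccurrenceSet:
    """Sample occurrence cells ∝ true suitability, without replacement.

    Weighted sampling without replacement (exponential-keys method) gives an
    exact count n_target with at most one occurrence per cell, i.e. the
    output is already thinned. Cells with zero truth are never selected.
    """
    vals = truth.data
    candidates = truth.mask & (vals > 0)
    if np.any(vals[truth.mask] < 0) or np.any(vals[truth.mask] > 1):
        raise ValueError("truth values must lie in [0, 1]")
    rows, cols = np.nonzero(candidates)
    w = vals[rows, cols]
    if n_target > rows.size:
        raise ValueError(
            f"n_target={n_target} exceeds the {rows.size} cells with positive truth"
        )
    if n_target > 0:
        rng = np.random.default_rng(derive_seed(seed, "occurrences", species))
        keys = np.log(rng.random(rows.size)) / w
        pick = np.argsort(keys)[-n_target:]
        pick = pick[np.argsort(rows[pick] * truth.ncols + cols[pick])]  # stable order
        rows, cols = rows[pick], cols[pick]
    else:
        rows = cols = np.empty(0, dtype=int)
    xs = truth.x_origin + (cols + 0.5) * truth.cell_size
    ys = truth.y_origin - (rows + 0.5) * truth.cell_size
    elev = dem.data[rows, cols] if dem is not None else np.full(rows.size, np.nan)
    return OccurrenceSet(pd.DataFrame({
        "species": species, "x": xs, "y": ys, "row": rows, "col": cols, "elevation": elev,
    }))
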