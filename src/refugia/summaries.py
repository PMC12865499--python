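"""Descriptive statistics over suitability surfaces and refugia maps.

All summaries are five-number boxplot statistics (min, q1, median, q3, max,
plus n) on tidy long tables, grouped by species, time slice, scenario,
elevation band or persistence category. Quantiles use linear interpolation
(numpy default, type 7). Habitat suitability is reported on the [0, 1]
scale; multiply by 1000 for the 0-1000 display scale some SDM toolchains
use.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .raster import Raster
from .refugia import CATEGORY_CODES, RefugiaMap
from .sdm import SuitabilityStack
from .synthetic import OccurrenceSet

BOX_FIELDS = ["min", "q1", "median", "q3", "max", "n"]


def boxplot_stats(df: pd.DataFrame, value: str, groups: list[str]) -> pd.DataFrame:
    """Five-number summaries of ``value`` per group; empty groups are omitted."""
    def _stats(s: pd.Series) -> pd.Series:
        v = s.dropna().to_numpy(dtype=float)
        if v.size == 0:
            return pd.Series({f: np.nan for f in BOX_FIELDS})
        q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
        return pd.Series({"min": v.min(), "q1": q1, "median": med,
                          "q3": q3, "max": v.max(), "n": v.size})
    out = (df.groupby(groups, sort=False, observed=True)[value]
             .apply(_stats).unstack().reset_index())
    out = out[out["n"].notna() & (out["n"] > 0)].reset_index(drop=True)
    out["n"] = out["n"].astype(int)
    return out


def _species_order(occs: Mapping[str, OccurrenceSet]) -> list[str]:
    """Species sorted by mean occurrence elevation (low to high)."""
    mean_elev = {sp: occ.table["elevation"].mean() for sp, occ in occs.items()}
    return sorted(mean_elev, key=lambda sp: mean_elev[sp])


def _hs_at_occurrences(stack: SuitabilityStack, occ: OccurrenceSet) -> pd.DataFrame:
    rc = occ.rc
    rows = []
    for label, r in zip(stack.slice_labels, stack.rasters):
        hs = r.data[rc[:, 0], rc[:, 1]]
        hs = np.where(r.mask[rc[:, 0], rc[:, 1]], hs, np.nan)
        rows.append(pd.DataFrame({
            "species": stack.species, "scenario": stack.scenario, "slice": label,
            "elevation": occ.table["elevation"].to_numpy(), "hs": hs,
        }))
    return pd.concat(rows, ignore_index=True)


def suitability_trajectories(
    stacks: Mapping[tuple[str, str], SuitabilityStack],
    occs: Mapping[str, OccurrenceSet],
) -> pd.DataFrame:
    """Suitability-at-occurrences boxplot stats per species x slice x scenario.

    ``stacks`` maps (species, scenario) to a stack. Species appear in order
    of mean occurrence elevation.
    """
    long = pd.concat(
        [_hs_at_occurrences(stacks[k], occs[k[0]]) for k in stacks],
        ignore_index=True,
    )
    out = boxplot_stats(long, "hs", ["species", "scenario", "slice"])
    order = {sp: i for i, sp in enumerate(_species_order(occs))}
    return (out.assign(_o=out["species"].map(order))
               .sort_values(["_o", "scenario", "slice"], kind="stable")
               .drop(columns="_o").reset_index(drop=True))


def elevation_band_label(elev: np.ndarray, band_width_m: float) -> np.ndarray:
    """Half-open [lo, hi) elevation band label per value, e.g. '1500-1750'."""
    idx = np.floor(np.asarray(elev, dtype=float) / band_width_m).astype(int)
    lo = idx * band_width_m
    return np.array([f"{int(a)}-{int(a + band_width_m)}" for a in lo])


def suitability_by_elevation(
    stacks: Mapping[tuple[str, str], SuitabilityStack],
    occs: Mapping[str, OccurrenceSet],
    band_width_m: float = 250.0,
) -> pd.DataFrame:
    """Suitability stats per species x elevation band x slice x scenario."""
    long = pd.concat(
        [_hs_at_occurrences(stacks[k], occs[k[0]]) for k in stacks],
        ignore_index=True,
    )
    long = long[long["elevation"].notna()].copy()
    long["band"] = elevation_band_label(long["elevation"].to_numpy(), band_width_m)
    long["band_low"] = (np.floor(long["elevation"] / band_width_m) * band_width_m)
    out = boxplot_stats(long, "hs", ["species", "scenario", "band_low", "band", "slice"])
    return out.sort_values(["species", "scenario", "band_low", "slice"],
                           kind="stable").reset_index(drop=True)


def refugia_position_stats(refmap: RefugiaMap, occ: OccurrenceSet,
                           dem: Raster) -> pd.DataFrame:
    """Latitudinal offset (km, north positive) and elevation per refugia type.

    Offsets are the projected y-coordinates of category member cells minus
    the median y of the current occurrences; elevations come from the DEM at
    member cells. Absent categories are omitted.
    """
    cat = refmap.categories
    if not cat.same_grid(dem):
        raise ValueError("refugia map and DEM are not co-registered")
    y_med = float(np.median(occ.table["y"]))
    rows = []
    for name, code in CATEGORY_CODES.items():
        if name == "none":
            continue
        rr, cc = np.nonzero(cat.data == code)
        if rr.size == 0:
            continue
        ys = cat.y_origin - (rr + 0.5) * cat.cell_size
        off_km = (ys - y_med) / 1000.0
        elev = dem.data[rr, cc]
        for var, vals in (("lat_offset_km", off_km), ("elevation_m", elev)):
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            rows.append({"category": name, "variable": var, "min": vals.min(),
                         "q1": q1, "median": med, "q3": q3, "max": vals.max(),
                         "n": rr.size})
    return pd.DataFrame(rows)


def quicklook_boxplots(stats: pd.DataFrame, x: str, path: str | Path,
                       hue: str | None = None) -> Path:
    """Optional quick-look plot of precomputed boxplot stats (median +- IQR)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    labels = stats[x].astype(str) + (":" + stats[hue].astype(str) if hue else "")
    pos = np.arange(len(stats))
    ax.errorbar(pos, stats["median"],
                yerr=[stats["median"] - stats["q1"], stats["q3"] - stats["median"]],
                fmt="o", capsize=3)
    ax.set_xticks(pos, labels, rotation=90, fontsize=6)
    ax.set_ylabel("median (IQR)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
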