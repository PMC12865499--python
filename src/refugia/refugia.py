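"""Persistence-area typing from habitat-suitability time series.

A cell is *suitable* at a time slice when its habitat suitability strictly
exceeds a threshold (default 0.5; a value of exactly 0.5 is unsuitable).
Over the three future slices this yields three persistence categories:

* **long-term refugium** — suitable in all three future slices; supports
  persistence in place for the whole horizon.
* **holdout** — suitable in exactly two of three future slices; buys time
  but not the full horizon.
* **stepping stone** — a non-occurrence cell, immediately adjacent to a
  current occurrence, suitable at the first future slice, and connected
  through adjacency to cells suitable at the second and third slices (a
  cell may serve consecutive slices itself); enables range tracking.

Categories are mutually exclusive per cell with precedence
refugium > holdout > stepping stone > none. Each occurrence is assigned the
status of its own cell, or ``stepping_stone`` when its cell is none of the
above but at least one adjacent cell is a stepping stone.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt

from .raster import Raster
from .sdm import SuitabilityStack
from .synthetic import OccurrenceSet

CATEGORY_CODES = {"none": 0, "refugium": 1, "holdout": 2, "stepping_stone": 3}
CODE_NODATA = 255


def _structure(adjacency: int) -> np.ndarray:
    if adjacency == 8:
        return np.ones((3, 3), dtype=bool)
    if adjacency == 4:
        s = np.zeros((3, 3), dtype=bool)
        s[1, :] = s[:, 1] = True
        return s
    raise ValueError("adjacency must be 4 or 8")


@dataclass
class TemporalProfile:
    """Per-cell suitability booleans for current and future slices."""

    grid: Raster
    suitable_now: np.ndarray          # (nrows, ncols) bool
    suitable_future: np.ndarray       # (3, nrows, ncols) bool
    valid: np.ndarray                 # (nrows, ncols) bool

    @property
    def count_future(self) -> np.ndarray:
        return self.suitable_future.sum(axis=0)


def classify_temporal_profile(stack: SuitabilityStack, threshold: float = 0.5
                              ) -> TemporalProfile:
    """Threshold the four suitability rasters (strictly greater-than)."""
    valid = np.ones(stack.grid.shape, dtype=bool)
    for r in stack.rasters:
        valid &= r.mask
    now = (stack.current.data > threshold) & valid
    fut = np.stack([(r.data > threshold) & valid for r in stack.future])
    return TemporalProfile(grid=stack.grid, suitable_now=now,
                           suitable_future=fut, valid=valid)


def find_stepping_stones(stack: SuitabilityStack, occ_mask: np.ndarray,
                         adjacency: int = 8, threshold: float = 0.5) -> np.ndarray:
    """Stepping-stone cells as a boolean array.

    Cell s qualifies iff it is not an occurrence cell, is adjacent to at
    least one occurrence cell, is suitable at future slice 1, and a chain
    s2 in N(s) u {s} suitable at slice 2 and s3 in N(s2) u {s2} suitable at
    slice 3 exists (self-chains allowed: one cell may serve several slices).
    """
    occ_mask = np.asarray(occ_mask, dtype=bool)
    if occ_mask.shape != stack.grid.shape:
        raise ValueError("occurrence mask is not co-registered with the stack")
    if not occ_mask.any():
        warnings.warn("empty occurrence mask: no stepping stones possible")
        return np.zeros(stack.grid.shape, dtype=bool)
    profile = classify_temporal_profile(stack, threshold)
    s1, s2, s3 = profile.suitable_future
    st = _structure(adjacency)
    chain2 = s2 & binary_dilation(s3, structure=st)
    return ~occ_mask & binary_dilation(occ_mask, structure=st) & s1 \
        & binary_dilation(chain2, structure=st)


def build_category_map(profile: TemporalProfile, stones: np.ndarray) -> Raster:
    """Per-cell categorical raster (0 none, 1 refugium, 2 holdout, 3 stone).

    Categories are made mutually exclusive by precedence
    refugium > holdout > stepping stone; nodata cells get code 255.
    """
    count = profile.count_future
    cat = np.zeros(profile.grid.shape, dtype=float)
    cat[np.asarray(stones, dtype=bool)] = CATEGORY_CODES["stepping_stone"]
    cat[count == 2] = CATEGORY_CODES["holdout"]
    cat[count == 3] = CATEGORY_CODES["refugium"]
    cat[~profile.valid] = CODE_NODATA
    out = profile.grid.like(cat)
    out.nodata = CODE_NODATA
    return out


def assign_occurrence_status(profile: TemporalProfile, stones: np.ndarray,
                             occ: OccurrenceSet, adjacency: int = 8
                             ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-occurrence persistence status and category percentages.

    Precedence for an occurrence cell: refugium (suitable all 3 future
    slices) > holdout (exactly 2) > stepping_stone (>= 1 adjacent
    stepping-stone cell) > none. Percentages are category counts over the
    total number of occurrences, x100.
    """
    nr, nc = profile.grid.shape
    rc = occ.rc
    for idx, (r, c) in enumerate(rc):
        if not (0 <= r < nr and 0 <= c < nc):
            rec = occ.table.iloc[idx]
            raise ValueError(
                f"occurrence {idx} ({rec['species']} at row={r}, col={c}) "
                "falls outside the grid"
            )
    stones = np.asarray(stones, dtype=bool)
    served = binary_dilation(stones, structure=_structure(adjacency))
    count = profile.count_future
    statuses = []
    for r, c in rc:
        if count[r, c] == 3:
            statuses.append("refugium")
        elif count[r, c] == 2:
            statuses.append("holdout")
        elif served[r, c]:
            statuses.append("stepping_stone")
        else:
            statuses.append("none")
    table = occ.table.copy()
    table["status"] = statuses
    n = max(len(statuses), 1)
    pct = {k: 100.0 * statuses.count(k) / n for k in CATEGORY_CODES}
    return table, pct


def nearest_suitable_distance(occ: OccurrenceSet, hs: Raster,
                              threshold: float = 0.5) -> np.ndarray:
    """Distance (km) from each occurrence cell centre to the nearest suitable cell.

    Zero when the occurrence's own cell is suitable; +inf when no suitable
    cell exists anywhere on the grid (reported as missing downstream).
    """
    suitable = (hs.data > threshold) & hs.mask
    rc = occ.rc
    if rc.size and np.any((rc < 0) | (rc >= [hs.nrows, hs.ncols])):
        raise ValueError("occurrences fall outside the suitability grid")
    if not suitable.any():
        return np.full(len(occ), np.inf)
    dist = distance_transform_edt(~suitable, sampling=hs.cell_size)
    return dist[rc[:, 0], rc[:, 1]] / 1000.0


@dataclass
class RefugiaMap:
    """Per-cell persistence categories plus the per-occurrence status table."""

    categories: Raster                # codes per CATEGORY_CODES, 255 nodata
    status: pd.DataFrame              # occurrence table + status column
    percentages: dict[str, float]     # category -> % of occurrences
    stones: np.ndarray                # boolean stepping-stone mask
    profile: TemporalProfile


def classify_refugia(stack: SuitabilityStack, occ: OccurrenceSet,
                     threshold: float = 0.5, adjacency: int = 8) -> RefugiaMap:
    """Full persistence typing of one suitability stack against occurrences."""
    profile = classify_temporal_profile(stack, threshold)
    occ_mask = occ.cell_mask(stack.grid)
    if occ_mask.any():
        stones = find_stepping_stones(stack, occ_mask, adjacency, threshold)
    else:
        stones = np.zeros(stack.grid.shape, dtype=bool)
    status, pct = assign_occurrence_status(profile, stones, occ, adjacency)
    return RefugiaMap(
        categories=build_category_map(profile, stones),
        status=status,
        percentages=pct,
        stones=stones,
        profile=profile,
    )


def occurrence_distances(occ: OccurrenceSet, stack: SuitabilityStack,
                         threshold: float = 0.5) -> pd.DataFrame:
    """Nearest-suitable-area distance (km) per occurrence for each future slice."""
    out = occ.table.copy()
    for label, hs in zip(stack.slice_labels[1:], stack.future):
        d = nearest_suitable_distance(occ, hs, threshold)
        out[f"distance_km_{label}"] = np.where(np.isfinite(d), d, np.nan)
    return out
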