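"""Climate predictor preparation: physiography, pooled PCA, GWR downscaling.

The coarse multi-band bioclimatic rasters of every time slice and scenario
are pooled, reduced to the first two principal components on a shared basis
(so current and future climates live in the same predictor space), and then
statistically downscaled to the fine terrain grid with a geographically
weighted regression (GWR) of the coarse PC values on six physiographic
covariates: elevation, slope, northness, eastness, an irradiation proxy and
distance to the coastline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString

from .raster import Raster, assert_same_grid

PHYSIO_NAMES = ["elevation", "slope", "northness", "eastness", "irradiation", "coast_distance"]


@dataclass
class PhysioStack:
    """Six co-registered fine-grid physiographic covariates.

    elevation (m), slope (degrees), northness = cos(aspect),
    eastness = sin(aspect), irradiation proxy (kWh/m^2), coast distance (m).
    """

    elevation: Raster
    slope: Raster
    northness: Raster
    eastness: Raster
    irradiation: Raster
    coast_distance: Raster

    def __post_init__(self) -> None:
        assert_same_grid(*self.rasters)

    @property
    def rasters(self) -> list[Raster]:
        return [getattr(self, n) for n in PHYSIO_NAMES]

    @property
    def grid(self) -> Raster:
        return self.elevation

    def as_raster(self) -> Raster:
        """All six covariates as one multi-band raster."""
        return self.grid.like(np.stack([r.data for r in self.rasters]))


def _default_irradiation(slope_deg: np.ndarray, northness: np.ndarray) -> np.ndarray:
    # South-facing steep slopes receive more direct irradiation (N hemisphere);
    # 1600 kWh/m^2 flat-terrain baseline with a +/-600 orientation term.
    return 1600.0 + 600.0 * np.sin(np.radians(slope_deg)) * (-northness)


def derive_physiography(
    dem: Raster,
    coastline: LineString | np.ndarray | Sequence[tuple[float, float]],
    irradiation_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
) -> PhysioStack:
    """Slope, aspect components, irradiation and coast distance from a DEM.

    Slope and aspect come from the standard Horn 3x3 finite-difference
    stencil (edges padded by replication). Aspect is measured in radians
    clockwise from north and points downslope; flat cells have undefined
    aspect and get northness = eastness = 0 (neutral exposure). The coast
    distance is the planar Euclidean distance from each cell centre to the
    coastline polyline.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3 for the Horn stencil")
    cs = dem.cell_size
    z = np.pad(dem.data, 1, mode="edge")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]   # northern row
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]      # southern row
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)          # east +
    dzdy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8 * cs)          # north +
    grad = np.hypot(dzdx, dzdy)
    slope_deg = np.degrees(np.arctan(grad))
    flat = grad == 0
    aspect = np.arctan2(-dzdx, -dzdy)  # downslope direction, clockwise from N
    northness = np.where(flat, 0.0, np.cos(aspect))
    eastness = np.where(flat, 0.0, np.sin(aspect))

    irr_fn = irradiation_fn or _default_irradiation
    irradiation = irr_fn(slope_deg, northness)

    if not isinstance(coastline, LineString):
        coastline = LineString(np.asarray(coastline, dtype=float))
    X, Y = dem.center_grids()
    pts = shapely.points(X.ravel(), Y.ravel())
    coast = shapely.distance(pts, coastline).reshape(dem.shape)

    bad = ~dem.mask
    def _mk(arr: np.ndarray) -> Raster:
        return dem.like(np.where(bad, dem.nodata, arr))

    return PhysioStack(
        elevation=_mk(dem.data),
        slope=_mk(slope_deg),
        northness=_mk(northness),
        eastness=_mk(eastness),
        irradiation=_mk(irradiation),
        coast_distance=_mk(coast),
    )


# ---------------------------------------------------------------------------
# Pooled PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaBasis:
    """Shared 2-axis PCA basis fitted on pooled, standardised climate bands."""

    means: np.ndarray                 # per retained band
    sds: np.ndarray                   # per retained band (1.0 if not standardised)
    loadings: np.ndarray              # (2, n_retained), orthonormal rows
    explained_variance_ratio: np.ndarray  # (2,)
    band_mask: np.ndarray             # (n_original,) True where band retained

    def transform(self, bands: np.ndarray) -> np.ndarray:
        """Project (n, n_original) band values onto (n, 2) PC scores."""
        kept = np.asarray(bands, dtype=float)[:, self.band_mask]
        z = (kept - self.means) / self.sds
        return z @ self.loadings.T

    def project_raster(self, stack: Raster) -> Raster:
        """A 2-band (PC1, PC2) raster from a multi-band climate raster."""
        m = stack.mask
        scores = self.transform(stack.values())
        out = np.full((2, stack.nrows, stack.ncols), stack.nodata)
        out[0][m], out[1][m] = scores[:, 0], scores[:, 1]
        return stack.like(out)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps({
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "band_mask": self.band_mask.astype(int).tolist(),
        }, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PcaBasis":
        d = json.loads(Path(path).read_text())
        return cls(
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            explained_variance_ratio=np.array(d["explained_variance_ratio"]),
            band_mask=np.array(d["band_mask"], dtype=bool),
        )


def pool_pca(
    stacks: Mapping[object, Raster],
    standardize: bool = True,
) -> tuple[PcaBasis, dict[object, Raster]]:
    """Fit one PCA on all pooled climate rasters; project each onto axes 1-2.

    All stacks must share a band count (grids may differ). Bands with zero
    pooled variance are dropped with a warning. ``standardize=True`` performs
    a correlation PCA (bands have heterogeneous units); ``False`` centres
    only. Loadings are sign-fixed so each axis's largest-magnitude loading
    is positive.
    """
    keys = list(stacks)
    if not keys:
        raise ValueError("no climate stacks given")
    mats = [stacks[k].values() for k in keys]
    nb = {m.shape[1] for m in mats}
    if len(nb) != 1:
        raise ValueError(f"stacks disagree on band count: {sorted(nb)}")
    pooled = np.vstack(mats)
    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0)
    keep = sds > 1e-12
    if not np.all(keep):
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance band(s) from PCA")
    if keep.sum() < 2:
        raise ValueError("fewer than 2 bands with variance; PCA needs at least 2")
    z = pooled[:, keep] - means[keep]
    if standardize:
        z = z / sds[keep]
    # SVD of the centred matrix == eigendecomposition of the covariance
    _, svals, vt = np.linalg.svd(z, full_matrices=False)
    loadings = vt[:2]
    sign = np.sign(loadings[np.arange(2), np.argmax(np.abs(loadings), axis=1)])
    loadings = loadings * sign[:, None]
    evr = (svals**2 / (svals**2).sum())[:2]
    basis = PcaBasis(
        means=means[keep],
        sds=sds[keep] if standardize else np.ones(int(keep.sum())),
        loadings=loadings,
        explained_variance_ratio=evr,
        band_mask=keep,
    )
    return basis, {k: basis.project_raster(stacks[k]) for k in keys}


# ---------------------------------------------------------------------------
# GWR downscaling
# ---------------------------------------------------------------------------

def gwr_downscale(
    coarse_pc: Raster,
    fine_physio: PhysioStack,
    bandwidth_cells: float = 5.0,
    extrapolation_factor: float | None = 1.0,
    min_weight: float = 1e-12,
) -> Raster:
    """Downscale a coarse field to the fine grid by local weighted regression.

    For every fine cell a weighted least-squares regression of the coarse
    field on the six physiographic covariates (block-mean aggregated to the
    coarse grid) is fitted with Gaussian kernel weights
    ``w = exp(-d^2 / (2 b^2))`` over coarse-cell centres (``b`` =
    ``bandwidth_cells`` coarse cells) and evaluated at the fine cell's own
    covariates. Covariates are standardised on pooled fine-grid statistics;
    covariates with (near-)zero variance are dropped from the regression.

    A singular local normal matrix falls back to a ridge-stabilised solve
    (lambda = 1e-8 * trace) and, failing that, to the local weighted mean.
    Output cells with fewer than p+1 positively weighted coarse cells are
    nodata. Unless ``extrapolation_factor`` is None, predictions are clipped
    to the coarse-field range widened by that fraction of the range on each
    side (a guard against local-regression extrapolation).
    """
    if bandwidth_cells <= 0:
        raise ValueError("bandwidth must be positive")
    fine = fine_physio.grid
    ratio = coarse_pc.cell_size / fine.cell_size
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError("coarse grid cell size must be an integer multiple of fine")
    if (abs(coarse_pc.x_origin - fine.x_origin) > 1e-6
            or abs(coarse_pc.y_origin - fine.y_origin) > 1e-6):
        raise ValueError("coarse grid must share the fine grid origin")

    # standardise covariates on pooled fine statistics, drop degenerate ones
    cov_fine = np.stack([r.data for r in fine_physio.rasters])
    valid_fine = fine_physio.as_raster().mask
    mu = np.array([c[valid_fine].mean() for c in cov_fine])
    sd = np.array([c[valid_fine].std() for c in cov_fine])
    retained = sd > 1e-10
    cov_std = (cov_fine[retained] - mu[retained, None, None]) / sd[retained, None, None]
    cov_std[:, ~valid_fine] = fine.nodata
    p = int(retained.sum())

    agg = [fine.like(c).block_aggregate(factor) for c in cov_std]
    cov_coarse = np.stack([a.data for a in agg])
    valid_coarse = coarse_pc.mask
    for a in agg:
        valid_coarse = valid_coarse & a.mask
    rows_c, cols_c = np.nonzero(valid_coarse)
    y = coarse_pc.data[rows_c, cols_c]
    Xc = np.column_stack([np.ones(rows_c.size)]
                         + [cov_coarse[k][rows_c, cols_c] for k in range(p)])
    xc = coarse_pc.x_origin + (cols_c + 0.5) * coarse_pc.cell_size
    yc = coarse_pc.y_origin - (rows_c + 0.5) * coarse_pc.cell_size

    rows_f, cols_f = np.nonzero(valid_fine)
    xf = fine.x_origin + (cols_f + 0.5) * fine.cell_size
    yf = fine.y_origin - (rows_f + 0.5) * fine.cell_size
    Xf = np.column_stack([np.ones(rows_f.size)]
                         + [cov_std[k][rows_f, cols_f] for k in range(p)])

    b = bandwidth_cells * coarse_pc.cell_size
    d2 = (xf[:, None] - xc[None, :]) ** 2 + (yf[:, None] - yc[None, :]) ** 2
    W = np.exp(-d2 / (2 * b * b))
    W[W < min_weight] = 0.0
    enough = (W > 0).sum(axis=1) >= p + 1

    # batched weighted least squares: A_i = Xc' diag(W_i) Xc, r_i = Xc' diag(W_i) y
    A = np.einsum("ij,jk,jl->ikl", W, Xc, Xc, optimize=True)
    r = np.einsum("ij,jk,j->ik", W, Xc, y, optimize=True)
    pred = np.full(rows_f.size, np.nan)
    try:
        theta = np.linalg.solve(A[enough], r[enough][..., None])[..., 0]
        pred[enough] = np.einsum("ik,ik->i", Xf[enough], theta)
    except np.linalg.LinAlgError:
        pass
    bad = enough & ~np.isfinite(pred)
    for i in np.nonzero(bad)[0]:
        pred[i] = _local_fit_fallback(A[i], r[i], Xf[i], W[i], y)

    if extrapolation_factor is not None:
        lo, hi = y.min(), y.max()
        span = hi - lo
        pred = np.clip(pred, lo - extrapolation_factor * span,
                       hi + extrapolation_factor * span)

    out = np.full(fine.shape, fine.nodata)
    ok = np.isfinite(pred)
    out[rows_f[ok], cols_f[ok]] = pred[ok]
    return fine.like(out)


def _local_fit_fallback(A: np.ndarray, r: np.ndarray, x_eval: np.ndarray,
                        w: np.ndarray, y: np.ndarray) -> float:
    lam = 1e-8 * np.trace(A)
    try:
        theta = np.linalg.solve(A + lam * np.eye(A.shape[0]), r)
        val = float(x_eval @ theta)
        if np.isfinite(val):
            return val
    except np.linalg.LinAlgError:
        pass
    sw = w.sum()
    return float((w @ y) / sw) if sw > 0 else np.nan
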