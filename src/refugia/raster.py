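"""Lightweight gridded rasters on a planar metric CRS.

Grids are row-major with row 0 at the *northern* edge. Cell centres sit at

    x = x_origin + (col + 0.5) * cell_size
    y = y_origin - (row + 0.5) * cell_size

so ``x_origin``/``y_origin`` are the west/north edges of the grid. All
coordinates are metres in a projected CRS and all distances are planar
Euclidean. Files are exchanged as ESRI ASCII grids (one band per plain-text
file, readable by any GIS); multi-band rasters get one file per band plus a
small JSON sidecar naming the bands.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA = -9999.0


@dataclass
class Raster:
    """A single- or multi-band grid with geotransform and nodata mask.

    ``data`` is ``(nrows, ncols)`` for a single band or
    ``(nbands, nrows, ncols)`` for a stack of co-registered bands.
    """

    data: np.ndarray
    x_origin: float = 0.0
    y_origin: float = 0.0
    cell_size: float = 300.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError("raster data must be 2-D or 3-D (bands, rows, cols)")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- shape ------------------------------------------------------------
    @property
    def nbands(self) -> int:
        return 1 if self.data.ndim == 2 else self.data.shape[0]

    @property
    def nrows(self) -> int:
        return self.data.shape[-2]

    @property
    def ncols(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def band(self, i: int) -> "Raster":
        """Band ``i`` (0-based) as a single-band raster sharing the grid."""
        if self.data.ndim == 2:
            if i != 0:
                raise IndexError("single-band raster has only band 0")
            return self
        return Raster(self.data[i], self.x_origin, self.y_origin, self.cell_size, self.nodata)

    # -- masks and values --------------------------------------------------
    @property
    def mask(self) -> np.ndarray:
        """Boolean (nrows, ncols) array, True where every band is valid."""
        d = self.data if self.data.ndim == 3 else self.data[None]
        finite = np.isfinite(d) & (d != self.nodata)
        return finite.all(axis=0)

    def values(self) -> np.ndarray:
        """Valid cell values: (n_valid,) or (n_valid, nbands)."""
        m = self.mask
        if self.data.ndim == 2:
            return self.data[m]
        return np.stack([self.data[b][m] for b in range(self.nbands)], axis=1)

    # -- geometry ----------------------------------------------------------
    @property
    def x_centers(self) -> np.ndarray:
        return self.x_origin + (np.arange(self.ncols) + 0.5) * self.cell_size

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_origin - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin - (row + 0.5) * self.cell_size,
        )

    def center_grids(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) centre-coordinate arrays, each (nrows, ncols)."""
        return np.meshgrid(self.x_centers, self.y_centers)

    def same_grid(self, other: "Raster", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.x_origin - other.x_origin) <= tol
            and abs(self.y_origin - other.y_origin) <= tol
        )

    def like(self, data: np.ndarray) -> "Raster":
        """A new raster with this grid's geotransform and the given data."""
        data = np.asarray(data, dtype=float)
        if data.shape[-2:] != self.shape:
            raise ValueError(f"data shape {data.shape} does not match grid {self.shape}")
        return Raster(data, self.x_origin, self.y_origin, self.cell_size, self.nodata)

    # -- resampling --------------------------------------------------------
    def block_aggregate(self, factor: int) -> "Raster":
        """Block-mean aggregation to a grid ``factor`` times coarser.

        Each coarse cell is the mean of the valid fine cells it covers; a
        coarse cell with no valid fine cell becomes nodata.
        """
        if factor < 1 or self.nrows % factor or self.ncols % factor:
            raise ValueError(f"block factor {factor} must divide grid {self.shape}")
        if self.data.ndim == 3:
            bands = [self.band(b).block_aggregate(factor).data for b in range(self.nbands)]
            return Raster(np.stack(bands), self.x_origin, self.y_origin,
                          self.cell_size * factor, self.nodata)
        nr, nc = self.nrows // factor, self.ncols // factor
        blocks = self.data.reshape(nr, factor, nc, factor)
        valid = self.mask.reshape(nr, factor, nc, factor)
        s = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
        n = valid.sum(axis=(1, 3))
        out = np.full((nr, nc), self.nodata)
        np.divide(s, n, out=out, where=n > 0)
        return Raster(out, self.x_origin, self.y_origin, self.cell_size * factor, self.nodata)


def assert_same_grid(*rasters: Raster) -> None:
    ref = rasters[0]
    for r in rasters[1:]:
        if not ref.same_grid(r):
            raise ValueError("rasters are not co-registered on the same grid")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write a single-band raster as an ESRI ASCII grid (.asc)."""
    if raster.nbands != 1:
        raise ValueError("write_ascii_grid handles single-band rasters; use write_stack")
    path = Path(path)
    data = np.where(raster.mask, raster.data, raster.nodata)
    header = (
        f"ncols {raster.ncols}\n"
        f"nrows {raster.nrows}\n"
        f"xllcorner {raster.x_origin!r}\n"
        f"yllcorner {raster.y_origin - raster.nrows * raster.cell_size!r}\n"
        f"cellsize {raster.cell_size!r}\n"
        f"NODATA_value {raster.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.10g")
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid` (or any GIS)."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    cs = header["cellsize"]
    nodata = header.get("nodata_value", NODATA)
    return Raster(
        data,
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cs,
        cell_size=cs,
        nodata=nodata,
    )


def write_stack(raster: Raster, directory: str | Path, stem: str,
                band_names: list[str] | None = None) -> Path:
    """Write a (multi-band) raster as one .asc per band plus a JSON sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = band_names or [f"band{i + 1}" for i in range(raster.nbands)]
    if len(names) != raster.nbands:
        raise ValueError("band_names length must equal band count")
    files = []
    for i, name in enumerate(names):
        f = f"{stem}.{name}.asc"
        write_ascii_grid(raster.band(i), directory / f)
        files.append(f)
    meta = directory / f"{stem}.json"
    meta.write_text(json.dumps({"stem": stem, "bands": names, "files": files}, indent=1))
    return meta


def read_stack(meta_path: str | Path) -> Raster:
    meta_path = Path(meta_path)
    meta = json.loads(meta_path.read_text())
    bands = [read_ascii_grid(meta_path.parent / f) for f in meta["files"]]
    first = bands[0]
    assert_same_grid(*bands)
    data = np.stack([b.data for b in bands]) if len(bands) > 1 else bands[0].data
    return Raster(data, first.x_origin, first.y_origin, first.cell_size, first.nodata)
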