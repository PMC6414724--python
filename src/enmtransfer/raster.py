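"""Planar raster grids and the grid-level operations the pipeline needs.

A :class:`RasterGrid` is the atom for every mapped quantity in the package:
monthly climate layers, land-cover classes, vegetation-index composites,
derived predictors and predicted suitability surfaces.  Grids are planar
(metre coordinates, no projection/datum handling): row 0 is the top row,
cells are square, and a point (x, y) falls in the cell whose half-open
interval [left, right) x [top, bottom) contains it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

NODATA = -9999.0


class GeometryError(ValueError):
    """Grids passed to an operation do not share the required geometry."""


class ConfigurationError(ValueError):
    """An operation received an invalid configuration value."""


class DegenerateLayerError(ValueError):
    """A layer is constant where variation is required (e.g. standardization)."""


@dataclass
class RasterGrid:
    """A georeferenced single-band 2D layer with an optional nodata mask.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; finite wherever unmasked.
    cell_size : float
        Cell edge length in metres (> 0).
    origin : (float, float)
        (x, y) of the outer corner of the top-left cell; x grows rightwards,
        y grows upwards, so rows advance in the -y direction.
    nodata_mask : ndarray of bool, optional
        True where the cell carries no data.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ConfigurationError("raster values must be a non-empty 2D array")
        if not self.cell_size > 0:
            raise ConfigurationError("cell_size must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise GeometryError("nodata mask shape differs from values shape")
        unmasked = self.values[~self.nodata_mask]
        if unmasked.size and not np.all(np.isfinite(unmasked.astype(float))):
            raise ConfigurationError("unmasked raster values must be finite")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) of the outer grid edges."""
        x0, y0 = self.origin
        return (
            x0,
            x0 + self.n_cols * self.cell_size,
            y0 - self.n_rows * self.cell_size,
            y0,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinates of cell centers as 1D arrays (cols, rows)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.n_rows) + 0.5) * self.cell_size
        return xs, ys

    def point_to_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); half-open cell intervals."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        if not np.all(inside):
            raise GeometryError("point outside the grid extent")
        return row, col

    def sample(self, x, y) -> np.ndarray:
        """Value of the cell containing each point."""
        row, col = self.point_to_index(x, y)
        return self.values[row, col]

    def with_values(self, values: np.ndarray, mask: np.ndarray | None = None) -> "RasterGrid":
        """A new grid with the same geometry and different values."""
        return RasterGrid(
            values=np.asarray(values),
            cell_size=self.cell_size,
            origin=self.origin,
            nodata_mask=self.nodata_mask.copy() if mask is None else mask,
        )

    def copy(self) -> "RasterGrid":
        return RasterGrid(
            self.values.copy(), self.cell_size, self.origin, self.nodata_mask.copy()
        )


def _check_stack(layers: dict[str, RasterGrid]) -> None:
    grids = list(layers.values())
    for g in grids[1:]:
        if not g.same_geometry(grids[0]):
            raise GeometryError("stack layers are not co-registered")


def resample_grid(grid: RasterGrid, target_cell_size: float, method: str = "bilinear") -> RasterGrid:
    """Resample a grid to a new cell size over the same extent.

    ``bilinear`` (continuous layers, the default), ``nearest`` (categorical
    layers) or ``block_mean`` (integer downscaling ratio only).  Nodata
    propagates: any masked contributor masks the output cell for bilinear
    and block_mean; nearest copies the source cell's mask.
    """
    if method not in ("nearest", "bilinear", "block_mean"):
        raise ConfigurationError(f"unknown resampling method: {method!r}")
    if not target_cell_size > 0:
        raise ConfigurationError("target cell size must be positive")

    if method == "block_mean":
        ratio = target_cell_size / grid.cell_size
        if abs(ratio - round(ratio)) > 1e-9:
            raise GeometryError(
                "block_mean requires the target cell size to be an integer "
                "multiple of the source cell size"
            )
        k = int(round(ratio))
        vals, mask = _block_reduce(grid.values.astype(float), grid.nodata_mask, k)
        return RasterGrid(vals, target_cell_size, grid.origin, mask)

    xmin, xmax, ymin, ymax = grid.extent
    n_cols = max(1, int(np.ceil((xmax - xmin) / target_cell_size - 1e-9)))
    n_rows = max(1, int(np.ceil((ymax - ymin) / target_cell_size - 1e-9)))
    # fractional source indices of the target cell centers
    xs = xmin + (np.arange(n_cols) + 0.5) * target_cell_size
    ys = ymax - (np.arange(n_rows) + 0.5) * target_cell_size
    ci = (xs - xmin) / grid.cell_size - 0.5
    ri = (ymax - ys) / grid.cell_size - 0.5
    rr, cc = np.meshgrid(ri, ci, indexing="ij")
    order = 1 if method == "bilinear" else 0
    vals = ndimage.map_coordinates(
        grid.values.astype(float), [rr, cc], order=order, mode="nearest"
    )
    mfrac = ndimage.map_coordinates(
        grid.nodata_mask.astype(float), [rr, cc], order=order, mode="nearest"
    )
    mask = mfrac > 1e-12 if method == "bilinear" else mfrac > 0.5
    vals = np.where(mask, NODATA, vals)
    return RasterGrid(vals, target_cell_size, grid.origin, mask)


def _block_reduce(values: np.ndarray, mask: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean over k x k blocks; partial edge blocks use covered cells only."""
    nr, nc = values.shape
    out_r = int(np.ceil(nr / k))
    out_c = int(np.ceil(nc / k))
    out = np.empty((out_r, out_c), dtype=float)
    out_mask = np.zeros((out_r, out_c), dtype=bool)
    for i in range(out_r):
        for j in range(out_c):
            blk = values[i * k : (i + 1) * k, j * k : (j + 1) * k]
            mblk = mask[i * k : (i + 1) * k, j * k : (j + 1) * k]
            if mblk.any():
                out[i, j] = NODATA
                out_mask[i, j] = True
            else:
                out[i, j] = blk.mean()
    return out, out_mask


def standardize_stack(
    layers: dict[str, RasterGrid],
    reference_stats: dict[str, tuple[float, float]] | None = None,
) -> tuple[dict[str, RasterGrid], dict[str, tuple[float, float]]]:
    """Z-score each layer over its unmasked cells.

    When ``reference_stats`` is given (projection onto a later epoch or
    another grid), those means/SDs are reused verbatim and never recomputed —
    cross-epoch consistency of the standardized scale depends on this.
    Returns the transformed layers and the stats used, keyed by layer name.
    SDs are sample (n-1) SDs.
    """
    _check_stack(layers)
    out: dict[str, RasterGrid] = {}
    stats: dict[str, tuple[float, float]] = {}
    for name, grid in layers.items():
        if reference_stats is not None:
            if name not in reference_stats:
                raise KeyError(f"no reference statistics for layer {name!r}")
            mean, sd = reference_stats[name]
        else:
            unmasked = grid.values[~grid.nodata_mask].astype(float)
            mean = float(unmasked.mean())
            sd = float(unmasked.std(ddof=1)) if unmasked.size > 1 else 0.0
        if sd <= 0 or not np.isfinite(sd):
            raise DegenerateLayerError(
                f"layer {name!r} has zero variance and cannot be standardized"
            )
        z = (grid.values.astype(float) - mean) / sd
        z = np.where(grid.nodata_mask, NODATA, z)
        out[name] = grid.with_values(z)
        stats[name] = (mean, sd)
    return out, stats


# -- I/O -------------------------------------------------------------------

def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a grid as single-band float32 TIFF plus a JSON georeference sidecar."""
    import tifffile

    path = Path(path)
    data = grid.values.astype(np.float32).copy()
    data[grid.nodata_mask] = NODATA
    tifffile.imwrite(path, data)
    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "nodata": NODATA,
        "n_rows": grid.n_rows,
        "n_cols": grid.n_cols,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path) -> RasterGrid:
    import tifffile

    path = Path(path)
    data = tifffile.imread(path).astype(np.float64)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    mask = data == meta["nodata"]
    return RasterGrid(data, meta["cell_size"], tuple(meta["origin"]), mask)
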