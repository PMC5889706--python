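"""Vegetation-cover rasters and the discrete activity-center state space.

The density model places latent activity centers on a discrete grid of
cells (the *state space*).  This module builds that grid from a canopy
height raster: a circular moving window converts pixel heights into a
vegetation-cover fraction, a strict threshold turns cover into a habitat
mask, and cells within a buffer of the survey stations become the state
space, each carrying its mean cover and habitat flag.

Grid convention: ``values[row, col]`` with the origin at the *lower-left*
corner of the raster; the center of pixel ``(row, col)`` is at
``(x0 + (col + 0.5) * pixel_size, y0 + (row + 0.5) * pixel_size)``.
Coordinates are planar projected meters throughout; missing data is NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "CanopyGrid",
    "CoverGrid",
    "StateSpace",
    "compute_cover_fraction",
    "make_habitat_mask",
    "build_state_space",
]


@dataclass
class CanopyGrid:
    """Single-band canopy-height raster (meters above ground)."""

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("canopy raster must be a nonempty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite < 0).any():
            raise ValueError("canopy heights must be >= 0 (NaN for nodata)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of pixel centers, shaped like the raster."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        x = x0 + (np.arange(ncol) + 0.5) * self.pixel_size
        y = y0 + (np.arange(nrow) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)


@dataclass
class CoverGrid(CanopyGrid):
    """Vegetation-cover fraction in [0, 1] per pixel, same georeferencing as its source."""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("cover raster must be a nonempty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and ((finite < 0).any() or (finite > 1).any()):
            raise ValueError("cover fractions must lie in [0, 1]")


@dataclass
class StateSpace:
    """Discrete cells on which activity centers live and density is defined.

    Attributes
    ----------
    x, y
        Cell centroid coordinates (m).
    area_km2
        Cell areas (km^2); uniform for a regular grid.
    veg
        Mean vegetation-cover fraction of each cell, in [0, 1].
    habitat
        Boolean flag; density is defined over habitat cells only.
    cell_size
        Cell edge length (m).
    """

    x: np.ndarray
    y: np.ndarray
    area_km2: np.ndarray
    veg: np.ndarray
    habitat: np.ndarray
    cell_size: float
    # (row, col) of each cell on the enclosing regular grid, plus grid metadata,
    # so samplers can make local moves without a geometric search.
    row: np.ndarray = field(default=None, repr=False)
    col: np.ndarray = field(default=None, repr=False)
    grid_shape: tuple[int, int] = (0, 0)
    grid_origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("x", "y", "area_km2", "veg"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.habitat = np.asarray(self.habitat, dtype=bool)
        n = self.x.size
        if not all(getattr(self, a).size == n for a in ("y", "area_km2", "veg", "habitat")):
            raise ValueError("state-space field lengths disagree")
        if n == 0:
            raise ValueError("state space has no cells")
        if (self.area_km2 <= 0).any():
            raise ValueError("cell areas must be positive")
        if ((self.veg < 0) | (self.veg > 1)).any():
            raise ValueError("veg fractions must lie in [0, 1]")

    @property
    def n_cells(self) -> int:
        return self.x.size

    @property
    def total_area_km2(self) -> float:
        return float(self.area_km2.sum())

    @property
    def habitat_area_km2(self) -> float:
        return float(self.area_km2[self.habitat].sum())

    def cell_index_map(self) -> np.ndarray:
        """Dense (nrow, ncol) array mapping grid position -> cell index, -1 where absent."""
        out = np.full(self.grid_shape, -1, dtype=np.int64)
        out[self.row, self.col] = np.arange(self.n_cells)
        return out


def compute_cover_fraction(
    canopy: CanopyGrid, radius: float, height_threshold: float
) -> CoverGrid:
    """Fraction of pixels above ``height_threshold`` within ``radius`` of each pixel.

    A pixel belongs to the circular window of a focal pixel iff the Euclidean
    distance between pixel *centers* is <= ``radius``.  Nodata pixels are
    excluded from numerator and denominator; windows are truncated at the
    raster edge (no padding).
    """
    if radius < canopy.pixel_size:
        raise ValueError("window radius must be at least one pixel")
    if height_threshold < 0:
        raise ValueError("height threshold must be >= 0")

    values = canopy.values
    valid = np.isfinite(values)
    tall = (values > height_threshold) & valid

    # Disk footprint on the pixel lattice.
    r_pix = int(np.floor(radius / canopy.pixel_size))
    offs = np.arange(-r_pix, r_pix + 1)
    di, dj = np.meshgrid(offs, offs, indexing="ij")
    kernel = ((di**2 + dj**2) * canopy.pixel_size**2 <= radius**2).astype(float)

    num = ndimage.convolve(tall.astype(float), kernel, mode="constant", cval=0.0)
    den = ndimage.convolve(valid.astype(float), kernel, mode="constant", cval=0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(den > 0, num / den, np.nan)
    # Convolution is float arithmetic; clip the roundoff outside [0, 1].
    frac = np.clip(frac, 0.0, 1.0)
    frac[~valid] = np.nan
    return CoverGrid(frac, origin=canopy.origin, pixel_size=canopy.pixel_size)


def make_habitat_mask(cover: CoverGrid, cover_threshold: float = 0.40) -> np.ndarray:
    """Boolean habitat mask: cover strictly greater than ``cover_threshold``.

    The inequality is strict, so a pixel at exactly the threshold is open
    (non-habitat).  Nodata pixels are never habitat.
    """
    if not 0.0 <= cover_threshold <= 1.0:
        raise ValueError("cover_threshold must lie in [0, 1]")
    with np.errstate(invalid="ignore"):
        return np.where(np.isfinite(cover.values), cover.values > cover_threshold, False)


def build_state_space(
    stations: np.ndarray,
    buffer: float,
    cell_size: float,
    cover: CoverGrid,
    exclusion_mask: np.ndarray | None = None,
    cover_threshold: float = 0.40,
) -> StateSpace:
    """Lay a regular grid of cells within ``buffer`` of any station.

    Parameters
    ----------
    stations
        (n, 2) array of station coordinates (m).
    buffer
        A cell is retained iff its *centroid* is within this distance of the
        nearest station.
    cell_size
        Cell edge length (m); the survey used 100 m.
    cover
        Vegetation-cover raster; each cell's ``veg`` is the mean cover of the
        pixels whose centers fall inside the cell (nodata excluded, zero
        where the raster does not reach).
    exclusion_mask
        Optional boolean array on the *candidate cell grid* (True = drop the
        cell), e.g. open water.  Shape must match the candidate grid, which is
        the bounding box of the stations padded by ``buffer`` and snapped to
        ``cell_size``.
    cover_threshold
        Habitat flag: ``veg > cover_threshold`` (strict).
    """
    stations = np.atleast_2d(np.asarray(stations, dtype=float))
    if stations.size == 0:
        raise ValueError("at least one station is required")
    if stations.shape[1] != 2:
        raise ValueError("stations must be an (n, 2) array of x, y")
    if buffer <= 0 or cell_size <= 0:
        raise ValueError("buffer and cell_size must be positive")

    x_lo = np.floor((stations[:, 0].min() - buffer) / cell_size) * cell_size
    y_lo = np.floor((stations[:, 1].min() - buffer) / cell_size) * cell_size
    x_hi = np.ceil((stations[:, 0].max() + buffer) / cell_size) * cell_size
    y_hi = np.ceil((stations[:, 1].max() + buffer) / cell_size) * cell_size
    ncol = int(round((x_hi - x_lo) / cell_size))
    nrow = int(round((y_hi - y_lo) / cell_size))

    cx = x_lo + (np.arange(ncol) + 0.5) * cell_size
    cy = y_lo + (np.arange(nrow) + 0.5) * cell_size
    CX, CY = np.meshgrid(cx, cy)

    d2min = np.full(CX.shape, np.inf)
    for sx, sy in stations:
        d2 = (CX - sx) ** 2 + (CY - sy) ** 2
        np.minimum(d2min, d2, out=d2min)
    keep = d2min <= buffer**2

    if exclusion_mask is not None:
        exclusion_mask = np.asarray(exclusion_mask, dtype=bool)
        if exclusion_mask.shape != keep.shape:
            raise ValueError(
                f"exclusion mask shape {exclusion_mask.shape} does not match "
                f"candidate grid {keep.shape}"
            )
        keep &= ~exclusion_mask

    if not keep.any():
        raise ValueError("no cells qualify: buffer too small or everything excluded")

    rows, cols = np.nonzero(keep)
    xs, ys = CX[keep], CY[keep]
    veg = _mean_cover_per_cell(cover, x_lo, y_lo, cell_size, nrow, ncol)[keep]
    area = np.full(xs.size, (cell_size / 1000.0) ** 2)
    return StateSpace(
        x=xs,
        y=ys,
        area_km2=area,
        veg=veg,
        habitat=veg > cover_threshold,
        cell_size=cell_size,
        row=rows,
        col=cols,
        grid_shape=(nrow, ncol),
        grid_origin=(x_lo, y_lo),
    )


def _mean_cover_per_cell(
    cover: CoverGrid, x_lo: float, y_lo: float, cell_size: float, nrow: int, ncol: int
) -> np.ndarray:
    """Mean cover of raster pixels whose centers fall in each candidate cell.

    Pixels are equal-area, so the mean over contained pixel centers is the
    area-weighted mean up to edge discretization.  Cells the raster does not
    reach get zero cover.
    """
    px, py = cover.pixel_centers()
    vals = cover.values
    ok = np.isfinite(vals)
    ci = np.floor((px[ok] - x_lo) / cell_size).astype(np.int64)
    ri = np.floor((py[ok] - y_lo) / cell_size).astype(np.int64)
    inside = (ri >= 0) & (ri < nrow) & (ci >= 0) & (ci < ncol)
    flat = ri[inside] * ncol + ci[inside]
    sums = np.bincount(flat, weights=vals[ok][inside], minlength=nrow * ncol)
    counts = np.bincount(flat, minlength=nrow * ncol)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return mean.reshape(nrow, ncol)
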