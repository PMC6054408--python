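"""Raster container, ASCII-grid I/O and circular focal (moving-window) statistics.

Habitat covariates enter the occurrence models as focal means over circular
windows of increasing radius; for a 0/1 indicator layer the focal mean is the
within-window class proportion.  All geometry is metric: a raster lives on a
regular grid with square cells, the window of radius ``r`` contains every cell
whose centre lies within ``r`` metres of the focal cell's centre, and windows
are truncated at the raster boundary (the mean is taken over available,
non-nodata cells only).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve

#: Focal radii (metres) of the multi-scale analysis, fine to broad.
DEFAULT_SCALES_M: tuple[float, ...] = (120, 240, 480, 960, 1920, 3840, 7680)

CONTINUOUS = "continuous"
CATEGORICAL = "categorical-indicator"


@dataclass
class Raster:
    """Single-band raster on a regular metric grid.

    values
        2-D float array, row 0 at the top (north); NaN marks nodata.
    cell_size
        Cell edge length in metres.
    x0, y0
        Coordinates of the lower-left corner of the grid.
    kind
        ``"continuous"`` or ``"categorical-indicator"`` (cells in {0, 1, nodata}).
    """

    values: np.ndarray
    cell_size: float
    x0: float = 0.0
    y0: float = 0.0
    kind: str = CONTINUOUS
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.size == 0:
            raise ValueError("raster values must be a non-empty 2-D array")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.kind == CATEGORICAL:
            finite = self.values[np.isfinite(self.values)]
            if finite.size and not np.all(np.isin(finite, (0.0, 1.0))):
                raise ValueError("categorical-indicator cells must be 0, 1 or nodata")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def cell_index(self, x: float | np.ndarray, y: float | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col), half-open cell convention [x0, x0+cell)."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell_size).astype(int)
        nrows = self.values.shape[0]
        row_from_bottom = np.floor((np.asarray(y) - self.y0) / self.cell_size).astype(int)
        row = nrows - 1 - row_from_bottom
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.cell_index(x, y)
        nr, nc = self.values.shape
        return (row >= 0) & (row < nr) & (col >= 0) & (col < nc)


@dataclass
class ScaledCovariate:
    """Per-station values of one covariate at one focal radius."""

    name: str
    scale: float
    station_values: np.ndarray
    standardized: bool = False
    degenerate: bool = False
    mean: float = 0.0
    sd: float = 1.0


def circular_footprint(radius_m: float, cell_size: float) -> np.ndarray:
    """0/1 window mask: cells whose centre is within radius_m of the focal centre."""
    r_cells = int(np.floor(radius_m / cell_size))
    offsets = np.arange(-r_cells, r_cells + 1)
    dy, dx = np.meshgrid(offsets, offsets, indexing="ij")
    dist = np.hypot(dx, dy) * cell_size
    return (dist <= radius_m + 1e-9).astype(float)


def focal_mean(raster: Raster, radius_m: float) -> Raster:
    """Mean over the circular window at each cell, truncated at the boundary.

    Nodata cells are excluded from the mean; a cell whose entire window is
    nodata stays nodata.  For an indicator raster the result is the class
    proportion (a continuous raster).
    """
    if radius_m < 0:
        raise ValueError("radius_m must be non-negative")
    footprint = circular_footprint(radius_m, raster.cell_size)
    vals = raster.values
    valid = np.isfinite(vals).astype(float)
    filled = np.where(np.isfinite(vals), vals, 0.0)
    if footprint.size == 1:
        out = vals.copy()
    else:
        num = fftconvolve(filled, footprint, mode="same")
        den = fftconvolve(valid, footprint, mode="same")
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(den > 0.5, num / np.maximum(den, 1e-12), np.nan)
    out_kind = CONTINUOUS  # class proportions are continuous
    return Raster(out, raster.cell_size, raster.x0, raster.y0, out_kind,
                  name=f"{raster.name}@{radius_m:g}m" if raster.name else "")


def scale_stack(raster: Raster, scales: tuple[float, ...] = DEFAULT_SCALES_M) -> list[Raster]:
    """One focal-mean raster per analysis scale (default: the 7 radii)."""
    if any(s <= 0 for s in scales):
        raise ValueError("scales must be positive")
    if list(scales) != sorted(scales):
        raise ValueError("scales must be sorted ascending")
    return [focal_mean(raster, s) for s in scales]


def extract_at_stations(raster: Raster, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Raster value of the cell containing each station point."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    inside = raster.contains(x, y)
    if not np.all(inside):
        bad = np.where(~inside)[0]
        raise ValueError(f"stations outside raster extent at indices {bad.tolist()}")
    row, col = raster.cell_index(x, y)
    return raster.values[row, col]


def extract_standardize(raster: Raster, x: np.ndarray, y: np.ndarray,
                        name: str = "", scale: float = 0.0) -> ScaledCovariate:
    """Extract station values and z-score them across the station set.

    A covariate with zero variance across stations is flagged degenerate and
    is excluded from downstream model building.
    """
    vals = extract_at_stations(raster, x, y)
    if np.any(~np.isfinite(vals)):
        bad = np.where(~np.isfinite(vals))[0]
        raise ValueError(f"station falls on nodata cell at indices {bad.tolist()}")
    mean = float(np.mean(vals))
    sd = float(np.std(vals, ddof=0))
    if sd < 1e-12:
        return ScaledCovariate(name or raster.name, scale, np.zeros_like(vals),
                               standardized=False, degenerate=True, mean=mean, sd=0.0)
    z = (vals - mean) / sd
    return ScaledCovariate(name or raster.name, scale, z, standardized=True,
                           mean=mean, sd=sd)


# ---------------------------------------------------------------------------
# ASCII-grid text I/O (ESRI .asc layout: header then rows, top row first)

_NODATA = -9999.0


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    path = Path(path)
    vals = np.where(np.isfinite(raster.values), raster.values, _NODATA)
    nrows, ncols = vals.shape
    header = (
        f"ncols {ncols}\nnrows {nrows}\n"
        f"xllcorner {float(raster.x0)!r}\nyllcorner {float(raster.y0)!r}\n"
        f"cellsize {float(raster.cell_size)!r}\nNODATA_value {_NODATA!r}\n"
    )
    body = "\n".join(" ".join(repr(float(v)) for v in row) for row in vals)
    path.write_text(header + body + "\n")


def read_ascii_grid(path: str | Path, kind: str = CONTINUOUS, name: str = "") -> Raster:
    path = Path(path)
    text = path.read_text().strip().splitlines()
    hdr: dict[str, float] = {}
    i = 0
    while i < len(text) and re.match(r"^[A-Za-z_]+\s", text[i]):
        key, val = text[i].split(None, 1)
        hdr[key.lower()] = float(val)
        i += 1
    ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
    nodata = hdr.get("nodata_value", _NODATA)
    data = np.loadtxt(text[i:], dtype=float).reshape(nrows, ncols)
    data = np.where(data == nodata, np.nan, data)
    return Raster(data, hdr["cellsize"], hdr.get("xllcorner", 0.0),
                  hdr.get("yllcorner", 0.0), kind, name=name or path.stem)
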