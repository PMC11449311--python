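"""Lightweight projected-meter raster grids with text (ESRI ASCII) and GeoTIFF I/O.

Rasters are row-major from the top-left corner: row 0 is the northernmost row,
``origin_y`` is the y coordinate of the *top* edge, and cell values are sampled
at cell centers.  Coordinates throughout are projected meters (UTM-like).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_NODATA = -9999.0

# GeoTIFF tag ids (ModelPixelScaleTag, ModelTiepointTag, GDAL_NODATA)
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    """Single-band raster on a regular grid of square cells.

    Parameters
    ----------
    values
        2D float array, shape (nrow, ncol); ``nodata`` marks missing cells.
    origin_x, origin_y
        Coordinates (m) of the top-left *corner* of the grid.
    cell_size
        Side length of a square cell, meters, > 0.
    nodata
        Sentinel for missing cells.
    season_tag
        One of ``wet``, ``dry``, ``static``.
    """

    values: np.ndarray
    origin_x: float
    origin_y: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    season_tag: str = "static"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or min(self.values.shape) < 1:
            raise ValueError("raster values must be a 2D array with >= 1 row/col")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be > 0")
        if self.season_tag not in ("wet", "dry", "static"):
            raise ValueError(f"invalid season_tag {self.season_tag!r}")
        finite = self.values[~self.is_nodata()]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("non-nodata raster cells must be finite")

    # -- geometry -----------------------------------------------------------
    @property
    def nrow(self) -> int:
        return self.values.shape[0]

    @property
    def ncol(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.nrow * self.cell_size,
            self.origin_x + self.ncol * self.cell_size,
            self.origin_y,
        )

    def is_nodata(self) -> np.ndarray:
        return ~np.isfinite(self.values) | (self.values == self.nodata)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-center coordinates, shape (nrow, ncol)."""
        cs = self.cell_size
        xs = self.origin_x + (np.arange(self.ncol) + 0.5) * cs
        ys = self.origin_y - (np.arange(self.nrow) + 0.5) * cs
        return np.meshgrid(xs, ys)

    def xy_to_rowcol(self, x, y):
        """Row/col of the cell containing (x, y); raises if outside extent."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        xmin, ymin, xmax, ymax = self.bounds
        if np.any(x < xmin) or np.any(x > xmax) or np.any(y < ymin) or np.any(y > ymax):
            raise ValueError("coordinates outside raster extent")
        col = np.clip(((x - self.origin_x) / self.cell_size).astype(int), 0, self.ncol - 1)
        row = np.clip(((self.origin_y - y) / self.cell_size).astype(int), 0, self.nrow - 1)
        return row, col

    def rowcol_to_xy(self, row, col):
        """Center coordinates of cell (row, col)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def sample(self, x, y):
        """Nearest-cell (cell-center) sample; nodata cells return NaN."""
        row, col = self.xy_to_rowcol(x, y)
        out = self.values[row, col]
        out = np.where(self.is_nodata()[row, col], np.nan, out)
        return out

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def copy_with(self, values: np.ndarray, season_tag: str | None = None) -> "RasterGrid":
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            season_tag=season_tag if season_tag is not None else self.season_tag,
        )

    # -- I/O ----------------------------------------------------------------
    def write_ascii(self, path) -> None:
        """Write as ESRI ASCII grid (plain text)."""
        xmin, ymin, _, _ = self.bounds
        header = (
            f"ncols {self.ncol}\n"
            f"nrows {self.nrow}\n"
            f"xllcorner {xmin!r}\n"
            f"yllcorner {ymin!r}\n"
            f"cellsize {self.cell_size!r}\n"
            f"NODATA_value {self.nodata!r}\n"
        )
        body = np.where(self.is_nodata(), self.nodata, self.values)
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, body, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, season_tag: str = "static") -> "RasterGrid":
        with open(path) as fh:
            hdr = {}
            for _ in range(6):
                key, val = fh.readline().split()
                hdr[key.lower()] = float(val)
            values = np.loadtxt(fh, ndmin=2)
        nrow = int(hdr["nrows"])
        cs = hdr["cellsize"]
        if values.shape != (nrow, int(hdr["ncols"])):
            raise ValueError(f"ASCII grid body shape {values.shape} does not match header")
        return cls(
            values=values,
            origin_x=hdr["xllcorner"],
            origin_y=hdr["yllcorner"] + nrow * cs,
            cell_size=cs,
            nodata=hdr["nodata_value"],
            season_tag=season_tag,
        )

    def write_geotiff(self, path) -> None:
        """Write a single-band float32 GeoTIFF with pixel-scale/tiepoint/nodata tags."""
        import tifffile

        data = np.where(self.is_nodata(), self.nodata, self.values).astype(np.float32)
        extratags = [
            (_TAG_PIXEL_SCALE, "d", 3, (self.cell_size, self.cell_size, 0.0)),
            (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, self.origin_x, self.origin_y, 0.0)),
            (_TAG_GDAL_NODATA, "s", 0, str(self.nodata)),
        ]
        tifffile.imwrite(path, data, extratags=extratags)

    @classmethod
    def read_geotiff(cls, path, season_tag: str = "static") -> "RasterGrid":
        import tifffile

        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            scale = tags[_TAG_PIXEL_SCALE].value
            tie = tags[_TAG_TIEPOINT].value
            nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else DEFAULT_NODATA
        if abs(scale[0] - scale[1]) > 1e-9 * scale[0]:
            raise ValueError("only square cells are supported")
        return cls(
            values=values,
            origin_x=tie[3],
            origin_y=tie[4],
            cell_size=float(scale[0]),
            nodata=nodata,
            season_tag=season_tag,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )
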