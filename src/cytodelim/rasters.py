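"""Single-band georeferenced raster layers with plain-text (ESRI ASCII grid) I/O.

Environmental predictors (BIO1..BIO19, elevation) are modelled as rectangular
grids in geographic coordinates (WGS84). Grids follow the usual raster
convention: row 0 is the northernmost row and latitude decreases down the
array. The ESRI ASCII grid format stores the lower-left corner, so the reader
and writer convert between the two conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thinning import WGS84

DEFAULT_NODATA = -9999.0


@dataclass
class EnvLayer:
    """One environmental variable on a regular lon/lat grid.

    ``west`` and ``north`` are the outer edges of the upper-left cell;
    ``cell_size`` is in decimal degrees and identical in both axes.
    """

    name: str
    values: np.ndarray  # (nrows, ncols), row 0 = north
    west: float
    north: float
    cell_size: float
    nodata: float = DEFAULT_NODATA
    crs: str = field(default=WGS84)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster grid must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def south(self) -> float:
        return self.north - self.nrows * self.cell_size

    @property
    def east(self) -> float:
        return self.west + self.ncols * self.cell_size

    def cell_index(self, lon: float, lat: float) -> tuple[int, int] | None:
        """(row, col) of the cell containing the point, or None if outside."""
        col = int(np.floor((lon - self.west) / self.cell_size))
        row = int(np.floor((self.north - lat) / self.cell_size))
        if 0 <= row < self.nrows and 0 <= col < self.ncols:
            return row, col
        return None

    def value_at(self, lon: float, lat: float) -> float | None:
        """Containing-cell value (no interpolation); None outside or at nodata."""
        idx = self.cell_index(lon, lat)
        if idx is None:
            return None
        v = float(self.values[idx])
        if v == self.nodata or np.isnan(v):
            return None
        return v

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon_centers[ncols], lat_centers[nrows]); lat decreasing."""
        lons = self.west + (np.arange(self.ncols) + 0.5) * self.cell_size
        lats = self.north - (np.arange(self.nrows) + 0.5) * self.cell_size
        return lons, lats

    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.west!r}\n")
            fh.write(f"yllcorner {self.south!r}\n")
            fh.write(f"cellsize {self.cell_size!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            np.savetxt(fh, self.values, fmt="%.10g")

    @classmethod
    def read_ascii(cls, path, name: str | None = None) -> "EnvLayer":
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
                else:  # headerless line: data starts here
                    break
            fh.seek(pos)
            values = np.loadtxt(fh, ndmin=2)
        nrows = int(header["nrows"])
        ncols = int(header["ncols"])
        if values.shape != (nrows, ncols):
            raise ValueError(
                f"grid shape {values.shape} does not match header ({nrows}, {ncols})"
            )
        cell = header["cellsize"]
        if name is None:
            import os

            name = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(
            name=name,
            values=values,
            west=header["xllcorner"],
            north=header["yllcorner"] + nrows * cell,
            cell_size=cell,
            nodata=header.get("nodata_value", DEFAULT_NODATA),
        )
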