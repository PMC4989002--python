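"""Minimal ESRI ASCII grid (.asc) reader/writer.

The package's rasters (land-use maps, NDVI composites, density maps) are
small and exchanged as plain text in the ESRI ASCII grid format: a
six-line header (ncols, nrows, xllcorner, yllcorner, cellsize,
NODATA_value) followed by row-major cell values, top row first.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """A single-band raster: data array plus geometry."""

    data: np.ndarray  # (nrows, ncols), top row first
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata: float = DEFAULT_NODATA

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares when cellsize is in metres."""
        return self.cellsize**2 / 10_000.0


def write_ascii_grid(path: str | Path, grid: Grid, fmt: str = "%.6g") -> None:
    data = np.asarray(grid.data)
    if data.ndim != 2:
        raise ValueError("grid data must be 2-D")
    nrows, ncols = data.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {grid.xllcorner:.6f}\n"
        f"yllcorner {grid.yllcorner:.6f}\n"
        f"cellsize {grid.cellsize:.6f}\n"
        f"NODATA_value {grid.nodata:.6g}\n"
    )
    body = "\n".join(" ".join(fmt % v for v in row) for row in data)
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> Grid:
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    for i, line in enumerate(lines):
        key, _, value = line.partition(" ")
        key = key.lower()
        if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                   "nodata_value"}:
            header[key] = float(value)
        else:
            break
    data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise ValueError(
            f"grid body shape {data.shape} does not match header ({nrows}, {ncols})"
        )
    return Grid(
        data=data,
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header.get("cellsize", 1.0),
        nodata=header.get("nodata_value", DEFAULT_NODATA),
    )
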