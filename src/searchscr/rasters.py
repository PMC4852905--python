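"""Minimal ESRI ASCII grid reader/writer.

The habitat-suitability mask and the exported density surface both travel as
plain-text ASCII grids (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA header
followed by row-major values, top row first). Coordinates are planar km.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["AsciiGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class AsciiGrid:
    """A regular raster with lower-left origin metadata.

    ``values`` is stored the way the file lays it out: row 0 is the *top*
    (northern-most) row.
    """

    values: np.ndarray
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("AsciiGrid values must be 2-D")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the covered rectangle."""
        return (
            self.xllcorner,
            self.yllcorner,
            self.xllcorner + self.ncols * self.cellsize,
            self.yllcorner + self.nrows * self.cellsize,
        )

    def value_at(self, x: float, y: float) -> float:
        """Nearest-cell lookup; returns ``nodata`` outside the raster."""
        col = int(np.floor((x - self.xllcorner) / self.cellsize))
        row_from_bottom = int(np.floor((y - self.yllcorner) / self.cellsize))
        row = self.nrows - 1 - row_from_bottom
        if col < 0 or col >= self.ncols or row < 0 or row >= self.nrows:
            return self.nodata
        return float(self.values[row, col])


def read_ascii_grid(path: str | Path) -> AsciiGrid:
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"} and len(parts) == 2:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for req in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if req not in header:
            raise ValueError(f"ASCII grid missing header field {req!r}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        values = values.reshape(int(header["nrows"]), int(header["ncols"]))
    return AsciiGrid(
        values=values,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(path: str | Path, grid: AsciiGrid, fmt: str = "%.6g") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.10g}\n")
        fh.write(f"yllcorner {grid.yllcorner:.10g}\n")
        fh.write(f"cellsize {grid.cellsize:.10g}\n")
        fh.write(f"NODATA_value {grid.nodata:.10g}\n")
        np.savetxt(fh, grid.values, fmt=fmt)
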