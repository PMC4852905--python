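"""State-space and trap grids for spatially explicit capture-recapture.

Two regular axis-aligned grids are maintained, following the usual
search-encounter SECR layout:

* the **state space**: a fine grid (default 0.65 km pixels) of candidate
  activity-centre locations, with a habitat-suitability mask — unsuitable
  pixels carry zero prior probability of hosting an activity centre;
* the **trap grid**: a coarser grid (default 1 km pixels) whose cells act as
  "traps"; a trap is active on an occasion if it was searched that day.

All coordinates are planar projected kilometres; distances are Euclidean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rasters import AsciiGrid

__all__ = [
    "StateSpace",
    "TrapGrid",
    "build_state_space",
    "build_trap_grid",
    "distance_matrix",
]


def _grid_centroids(extent, side):
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError(f"empty extent {extent!r}")
    if side <= 0:
        raise ValueError("pixel side must be positive")
    # tolerance keeps float noise (e.g. 99*0.65/0.65 = 99.0000...01) from
    # adding a spurious row or column of pixels
    nx = int(np.ceil((xmax - xmin) / side - 1e-9))
    ny = int(np.ceil((ymax - ymin) / side - 1e-9))
    cx = xmin + (np.arange(nx) + 0.5) * side
    cy = ymin + (np.arange(ny) + 0.5) * side
    # row-major over y (slow axis) then x; index = iy * nx + ix
    xx, yy = np.meshgrid(cx, cy)
    return nx, ny, xx.ravel(), yy.ravel()


@dataclass(frozen=True)
class StateSpace:
    """Discrete grid of candidate activity-centre pixels with a mask.

    ``x``/``y`` are pixel-centroid coordinates (km) over *all* pixels in
    row-major order (``index = iy * nx + ix``, y increasing from the grid's
    lower edge). ``suitable`` flags the pixels available to activity centres.
    """

    x: np.ndarray
    y: np.ndarray
    side: float
    suitable: np.ndarray
    nx: int
    ny: int
    origin: tuple[float, float]
    crs: str = "planar-km"

    @property
    def n_pixels(self) -> int:
        return self.x.size

    @property
    def n_suitable(self) -> int:
        return int(self.suitable.sum())

    @property
    def pixel_area(self) -> float:
        return self.side**2

    @property
    def total_area(self) -> float:
        return self.n_pixels * self.pixel_area

    @property
    def suitable_area(self) -> float:
        return self.n_suitable * self.pixel_area

    @property
    def percent_unsuitable(self) -> float:
        return 100.0 * (1.0 - self.n_suitable / self.n_pixels)

    @property
    def suitable_xy(self) -> np.ndarray:
        """(n_suitable, 2) centroids of suitable pixels."""
        return np.column_stack([self.x[self.suitable], self.y[self.suitable]])

    @property
    def suitable_indices(self) -> np.ndarray:
        return np.flatnonzero(self.suitable)

    def to_ascii_grid(self, values: np.ndarray | None = None) -> AsciiGrid:
        """Export ``values`` (length n_pixels, row-major from bottom) or the
        suitability mask itself on this grid's geometry."""
        if values is None:
            values = self.suitable.astype(float)
        arr = np.asarray(values, dtype=float).reshape(self.ny, self.nx)
        return AsciiGrid(
            values=arr[::-1],  # file convention: top row first
            xllcorner=self.origin[0],
            yllcorner=self.origin[1],
            cellsize=self.side,
        )

    @classmethod
    def from_ascii_grid(cls, grid: AsciiGrid) -> "StateSpace":
        """Build directly from a suitability raster (1 suitable, 0/NODATA not)."""
        vals = grid.values[::-1]  # back to bottom-row-first
        suitable = (vals == 1).ravel()
        ny, nx = vals.shape
        xmin, ymin = grid.xllcorner, grid.yllcorner
        side = grid.cellsize
        _, _, x, y = _grid_centroids(
            (xmin, ymin, xmin + nx * side, ymin + ny * side), side
        )
        if not suitable.any():
            raise ValueError("all pixels unsuitable: no support for activity centres")
        return cls(x=x, y=y, side=side, suitable=suitable, nx=nx, ny=ny,
                   origin=(xmin, ymin))


@dataclass(frozen=True)
class TrapGrid:
    """Regular grid of detector ('trap') pixels covering the searched extent."""

    x: np.ndarray
    y: np.ndarray
    side: float
    nx: int
    ny: int
    origin: tuple[float, float]
    crs: str = "planar-km"

    @property
    def n_traps(self) -> int:
        return self.x.size

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def trap_index(self, x, y):
        """Trap pixel containing planar point(s); -1 if outside the grid."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.side).astype(int)
        iy = np.floor((y - self.origin[1]) / self.side).astype(int)
        inside = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        idx = np.where(inside, iy * self.nx + ix, -1)
        return idx if idx.ndim else int(idx)


def build_state_space(extent, side, mask: AsciiGrid | None = None) -> StateSpace:
    """Construct the masked state space over ``extent`` = (xmin, ymin, xmax, ymax).

    The suitability ``mask`` raster is sampled with a nearest-cell lookup at
    each pixel centroid (value 1 = suitable; anything else, including NODATA,
    = unsuitable). ``mask=None`` marks every pixel suitable.
    """
    nx, ny, x, y = _grid_centroids(extent, side)
    if mask is None:
        suitable = np.ones(x.size, dtype=bool)
    else:
        suitable = np.array(
            [mask.value_at(xi, yi) == 1 for xi, yi in zip(x, y)], dtype=bool
        )
    if not suitable.any():
        raise ValueError("all pixels unsuitable: no support for activity centres")
    return StateSpace(x=x, y=y, side=side, suitable=suitable, nx=nx, ny=ny,
                      origin=(extent[0], extent[1]))


def build_trap_grid(extent, side: float = 1.0) -> TrapGrid:
    nx, ny, x, y = _grid_centroids(extent, side)
    return TrapGrid(x=x, y=y, side=side, nx=nx, ny=ny,
                    origin=(extent[0], extent[1]))


def distance_matrix(space: StateSpace, traps: TrapGrid,
                    suitable_only: bool = True) -> np.ndarray:
    """Centroid-to-centroid Euclidean distances (km).

    Returns an (n_pixels, n_traps) matrix; with ``suitable_only`` the rows
    are restricted to the suitable pixels (the activity-centre support), in
    the order of ``space.suitable_indices``.
    """
    if space.crs != traps.crs:
        raise ValueError(
            f"coordinate systems differ: {space.crs!r} vs {traps.crs!r}"
        )
    if suitable_only:
        px = space.x[space.suitable]
        py = space.y[space.suitable]
    else:
        px, py = space.x, space.y
    dx = px[:, None] - traps.x[None, :]
    dy = py[:, None] - traps.y[None, :]
    return np.hypot(dx, dy)
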