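"""Search-effort rasterization: GPS tracks -> km driven per trap pixel per day.

Search effort is the observation-process covariate in search-encounter SECR:
a trap pixel counts as *active* on an occasion (one calendar day) if any
searcher drove through it that day, and the encounter model uses
log(kilometres driven in the pixel on the day).

Each inter-fix segment's length is assigned to the trap pixel containing the
segment *midpoint*, on the occasion of the segment's start time; with fixes a
few seconds apart segments are far shorter than a pixel, so midpoint
assignment is indistinguishable from exact polyline clipping. Segments that
span midnight are split at the day boundary by linear interpolation in time.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np

from .grids import TrapGrid

__all__ = ["Track", "EffortGrid", "rasterize_effort"]

logger = logging.getLogger(__name__)

_DAY_NS = 86_400_000_000_000


@dataclass
class Track:
    """One searcher's ordered GPS fixes: times plus planar (x, y) in km."""

    searcher_id: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.size == self.x.size == self.y.size):
            raise ValueError("times, x, y must have equal length")
        if self.times.size >= 2 and not np.all(np.diff(self.times).astype(np.int64) > 0):
            raise ValueError(
                f"track {self.searcher_id!r}: timestamps not strictly increasing"
            )

    @property
    def length_km(self) -> float:
        """Total Euclidean polyline length."""
        if self.x.size < 2:
            return 0.0
        return float(np.hypot(np.diff(self.x), np.diff(self.y)).sum())

    @property
    def dates(self) -> list[_dt.date]:
        days = np.unique(self.times.astype("datetime64[D]"))
        return [d.astype(_dt.date) for d in days]


@dataclass
class EffortGrid:
    """J x K matrix of kilometres driven per trap pixel per occasion."""

    effort: np.ndarray  # (J, K), km
    occasions: list  # ordered list of datetime.date

    def __post_init__(self) -> None:
        self.effort = np.asarray(self.effort, dtype=float)
        if self.effort.ndim != 2:
            raise ValueError("effort must be a J x K matrix")
        if self.effort.shape[1] != len(self.occasions):
            raise ValueError("effort columns must match occasion calendar")
        if np.any(self.effort < 0):
            raise ValueError("effort entries must be non-negative")

    @property
    def n_traps(self) -> int:
        return self.effort.shape[0]

    @property
    def n_occasions(self) -> int:
        return self.effort.shape[1]

    @property
    def active(self) -> np.ndarray:
        """Boolean (J, K) activity mask: trap searched on the occasion."""
        return self.effort > 0

    @property
    def total_km(self) -> float:
        return float(self.effort.sum())

    def occasion_index(self, date: _dt.date) -> int:
        try:
            return self.occasions.index(date)
        except ValueError:
            raise KeyError(f"date {date} is not in the occasion calendar") from None

    def copy(self) -> "EffortGrid":
        return EffortGrid(self.effort.copy(), list(self.occasions))


def _split_at_midnights(t0, t1, x0, y0, x1, y1):
    """Yield (t_start, xm, ym, length) subsegments of one fix-to-fix segment,
    cut at each midnight crossed, with midpoint coordinates per piece."""
    n0 = t0.astype("datetime64[ns]").astype(np.int64)
    n1 = t1.astype("datetime64[ns]").astype(np.int64)
    cuts = [n0]
    first_mid = (n0 // _DAY_NS + 1) * _DAY_NS
    m = first_mid
    while m < n1:
        cuts.append(m)
        m += _DAY_NS
    cuts.append(n1)
    span = n1 - n0
    out = []
    for a, b in zip(cuts[:-1], cuts[1:]):
        fa = (a - n0) / span
        fb = (b - n0) / span
        xa, ya = x0 + fa * (x1 - x0), y0 + fa * (y1 - y0)
        xb, yb = x0 + fb * (x1 - x0), y0 + fb * (y1 - y0)
        out.append((np.int64(a).astype("datetime64[ns]"),
                    0.5 * (xa + xb), 0.5 * (ya + yb),
                    float(np.hypot(xb - xa, yb - ya))))
    return out


def rasterize_effort(tracks, traps: TrapGrid, occasions) -> EffortGrid:
    """Accumulate track segment lengths into a (trap, occasion) effort matrix.

    ``occasions`` is the ordered calendar of sampling days and must cover
    every date a retained segment starts on. Segments whose midpoint falls
    outside the trap grid are dropped with a logged warning.
    """
    occasions = list(occasions)
    occ_idx = {d: k for k, d in enumerate(occasions)}
    J, K = traps.n_traps, len(occasions)
    effort = np.zeros((J, K))
    n_dropped = 0
    dropped_km = 0.0

    for tr in tracks:
        if tr.times.size < 2:
            continue
        t = tr.times
        days = t.astype("datetime64[D]")
        same_day = days[:-1] == days[1:]

        # fast path: same-day segments, vectorized
        i = np.flatnonzero(same_day)
        if i.size:
            mx = 0.5 * (tr.x[i] + tr.x[i + 1])
            my = 0.5 * (tr.y[i] + tr.y[i + 1])
            seg_len = np.hypot(tr.x[i + 1] - tr.x[i], tr.y[i + 1] - tr.y[i])
            j = traps.trap_index(mx, my)
            inside = j >= 0
            n_dropped += int((~inside).sum())
            dropped_km += float(seg_len[~inside].sum())
            dates = days[i][inside]
            ks = np.empty(dates.size, dtype=int)
            for u in np.unique(dates):
                d = u.astype(_dt.date)
                if d not in occ_idx:
                    raise ValueError(f"track date {d} not covered by occasion calendar")
                ks[dates == u] = occ_idx[d]
            np.add.at(effort, (j[inside], ks), seg_len[inside])

        # slow path: midnight-crossing segments, split by interpolation
        for i0 in np.flatnonzero(~same_day):
            for t_start, mx, my, seg_len in _split_at_midnights(
                t[i0], t[i0 + 1], tr.x[i0], tr.y[i0], tr.x[i0 + 1], tr.y[i0 + 1]
            ):
                if seg_len == 0.0:
                    continue
                j = traps.trap_index(mx, my)
                if j < 0:
                    n_dropped += 1
                    dropped_km += seg_len
                    continue
                d = t_start.astype("datetime64[D]").astype(_dt.date)
                if d not in occ_idx:
                    raise ValueError(f"track date {d} not covered by occasion calendar")
                effort[j, occ_idx[d]] += seg_len

    if n_dropped:
        logger.warning(
            "rasterize_effort: dropped %d segments (%.3f km) outside trap grid",
            n_dropped, dropped_km,
        )
    return EffortGrid(effort, occasions)
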