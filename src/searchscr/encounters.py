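"""Sighting records -> the standard 3-D spatial capture-recapture array.

Detections are binary per (individual, trap pixel, day): repeated sightings
of the same animal in the same pixel on the same day collapse to a single 1,
since search routes are not reused within a day and the observation model is
Bernoulli per cell. The module also computes the movement summary used to
justify the state-space buffer: the mean maximum distance moved (MMDM).
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np

from .effort import EffortGrid
from .grids import TrapGrid

__all__ = ["SightingRecord", "EncounterData", "build_encounter_array", "mmdm"]

logger = logging.getLogger(__name__)

_SEX_CODE = {"F": 0, "f": 0, 0: 0, "M": 1, "m": 1, 1: 1}

#: default km of search effort imputed in a cell holding a detection but no
#: recorded track (opportunistic sightings reported by third parties: the
#: team drove there to photograph the animal, so effort existed but was
#: under-recorded)
DEFAULT_EFFORT_FLOOR = 0.1


@dataclass(frozen=True)
class SightingRecord:
    """One verified sighting of an identified adult."""

    individual_id: str
    sex: int  # 0 = female, 1 = male
    x: float  # km, planar
    y: float
    date: _dt.date
    time: _dt.time | None = None

    def __post_init__(self):
        if self.sex not in _SEX_CODE:
            raise ValueError(f"unknown sex code {self.sex!r} (use F/M or 0/1)")
        object.__setattr__(self, "sex", _SEX_CODE[self.sex])


@dataclass
class EncounterData:
    """Binary detections y[i, j, k] with the observed sex per individual."""

    y: np.ndarray  # (n, J, K) bool
    sex: np.ndarray  # (n,) int, 0 female / 1 male
    ids: list  # individual identifiers, length n

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=bool)
        self.sex = np.asarray(self.sex, dtype=int)
        if self.y.ndim != 3:
            raise ValueError("y must be (individuals, traps, occasions)")
        if len(self.ids) != self.y.shape[0] or self.sex.size != self.y.shape[0]:
            raise ValueError("ids/sex length must match the individual axis")
        if self.y.shape[0] and not self.y.any(axis=(1, 2)).all():
            raise ValueError("every individual must have at least one detection")

    @property
    def n_individuals(self) -> int:
        return self.y.shape[0]

    @property
    def n_detections(self) -> int:
        return int(self.y.sum())

    @property
    def individual_totals(self) -> np.ndarray:
        """Total detections per individual, y_i."""
        return self.y.sum(axis=(1, 2))


def build_encounter_array(
    sightings,
    traps: TrapGrid,
    effort: EffortGrid,
    effort_floor: float = DEFAULT_EFFORT_FLOOR,
):
    """Binarize sightings into y[i, j, k] and reconcile them with effort.

    Returns ``(EncounterData, EffortGrid)`` — the effort grid is a copy in
    which any cell holding a detection but zero recorded effort has been
    floored to ``effort_floor`` km (with a logged warning), so that every
    detection sits in an active trap downstream.
    """
    sightings = list(sightings)
    if not sightings:
        raise ValueError("no sightings: cannot build an encounter array")

    ids: list = []
    sex_of: dict = {}
    for rec in sightings:
        if rec.individual_id in sex_of:
            if sex_of[rec.individual_id] != rec.sex:
                raise ValueError(
                    f"conflicting sex labels for individual {rec.individual_id!r}"
                )
        else:
            sex_of[rec.individual_id] = rec.sex
            ids.append(rec.individual_id)

    row = {iid: i for i, iid in enumerate(ids)}
    J, K = effort.n_traps, effort.n_occasions
    y = np.zeros((len(ids), J, K), dtype=bool)
    for rec in sightings:
        j = traps.trap_index(rec.x, rec.y)
        if j < 0:
            raise ValueError(
                f"sighting outside trap grid: {rec.individual_id!r} at "
                f"({rec.x:.3f}, {rec.y:.3f}) on {rec.date}"
            )
        k = effort.occasion_index(rec.date)
        y[row[rec.individual_id], j, k] = True

    out_effort = effort.copy()
    det_j, det_k = np.nonzero(y.any(axis=0))
    zero = out_effort.effort[det_j, det_k] == 0
    if zero.any():
        logger.warning(
            "build_encounter_array: %d detection cells had no recorded effort; "
            "imputing a %.3g km floor", int(zero.sum()), effort_floor
        )
        out_effort.effort[det_j[zero], det_k[zero]] = effort_floor

    sex = np.array([sex_of[iid] for iid in ids], dtype=int)
    return EncounterData(y=y, sex=sex, ids=ids), out_effort


def mmdm(sightings, group: str = "all"):
    """Mean maximum distance moved (km).

    Per individual: the largest pairwise Euclidean distance among that
    animal's sighting locations (0 for a single sighting). The group value is
    the arithmetic mean over individuals; ``group="sex"`` splits into
    ``{"F": ..., "M": ...}``.

    Returns ``(group_means, per_individual)`` where ``per_individual`` maps
    individual id -> its maximum distance.
    """
    sightings = list(sightings)
    if not sightings:
        raise ValueError("mmdm requires at least one sighting")
    if group not in {"all", "sex"}:
        raise ValueError("group must be 'all' or 'sex'")

    locs: dict = {}
    sexes: dict = {}
    for rec in sightings:
        locs.setdefault(rec.individual_id, []).append((rec.x, rec.y))
        sexes[rec.individual_id] = rec.sex

    per_ind = {}
    for iid, pts in locs.items():
        p = np.asarray(pts)
        if len(p) < 2:
            per_ind[iid] = 0.0
        else:
            d = np.hypot(p[:, None, 0] - p[None, :, 0], p[:, None, 1] - p[None, :, 1])
            per_ind[iid] = float(d.max())

    if group == "all":
        means = {"all": float(np.mean(list(per_ind.values())))}
    else:
        means = {}
        for label, code in (("F", 0), ("M", 1)):
            vals = [per_ind[iid] for iid in per_ind if sexes[iid] == code]
            means[label] = float(np.mean(vals)) if vals else float("nan")
    return means, per_ind
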