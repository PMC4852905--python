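"""Readers and writers for the package's plain-text interchange formats.

Everything round-trips: each writer's output is readable by its paired
reader without loss. Formats: CSV for tracks, sightings, effort, encounter
cells and posterior draws; ESRI ASCII grids for rasters; YAML for configs.
All coordinates are planar kilometres.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .effort import EffortGrid, Track
from .encounters import EncounterData, SightingRecord
from .grids import TrapGrid
from .model import ModelVariant
from .sampler import PARAM_NAMES, PosteriorDraws, SamplerConfig

__all__ = [
    "read_tracks_csv", "write_tracks_csv",
    "read_sightings_csv", "write_sightings_csv",
    "read_effort_csv", "write_effort_csv",
    "read_encounters_csv", "write_encounters_csv",
    "write_draws", "read_draws",
    "RunConfig",
]


# --------------------------------------------------------------------- #
# tracks

def write_tracks_csv(tracks, path) -> None:
    rows = []
    for tr in tracks:
        for t, x, y in zip(tr.times, tr.x, tr.y):
            rows.append((tr.searcher_id, np.datetime_as_string(t, unit="s"), x, y))
    pd.DataFrame(rows, columns=["searcher_id", "timestamp", "x_km", "y_km"]).to_csv(
        path, index=False
    )


#: gap between consecutive fixes (seconds) above which a searcher's log is
#: cut into separate track sessions, so the off-duty jump between two search
#: bouts is never counted as driven effort
TRACK_SESSION_GAP_S = 3600.0


def read_tracks_csv(path) -> list[Track]:
    df = pd.read_csv(path)
    out = []
    for sid, grp in df.groupby("searcher_id", sort=False):
        grp = grp.assign(_t=pd.to_datetime(grp["timestamp"])).sort_values("_t")
        t = grp["_t"].to_numpy("datetime64[ns]")
        gaps = np.diff(t).astype("timedelta64[s]").astype(float)
        bounds = [0, *(np.flatnonzero(gaps > TRACK_SESSION_GAP_S) + 1), t.size]
        for a, b in zip(bounds[:-1], bounds[1:]):
            out.append(Track(
                searcher_id=str(sid),
                times=t[a:b],
                x=grp["x_km"].to_numpy(float)[a:b],
                y=grp["y_km"].to_numpy(float)[a:b],
            ))
    return out


# --------------------------------------------------------------------- #
# sightings

def write_sightings_csv(sightings, path) -> None:
    rows = [
        (s.individual_id, "M" if s.sex == 1 else "F", s.x, s.y,
         s.date.isoformat(), s.time.isoformat() if s.time else "")
        for s in sightings
    ]
    pd.DataFrame(rows, columns=["individual_id", "sex", "x_km", "y_km",
                                "date", "time"]).to_csv(path, index=False)


def read_sightings_csv(path) -> list[SightingRecord]:
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str})
    out = []
    for _, r in df.iterrows():
        tm = None
        if isinstance(r.get("time"), str) and r["time"]:
            tm = _dt.time.fromisoformat(r["time"])
        out.append(SightingRecord(
            individual_id=r["individual_id"], sex=r["sex"],
            x=float(r["x_km"]), y=float(r["y_km"]),
            date=_dt.date.fromisoformat(str(r["date"])), time=tm,
        ))
    return out


# --------------------------------------------------------------------- #
# effort (long format, zero cells omitted)

def write_effort_csv(effort: EffortGrid, path) -> None:
    j, k = np.nonzero(effort.effort)
    df = pd.DataFrame({
        "trap_id": j,
        "occasion": [effort.occasions[kk].isoformat() for kk in k],
        "effort_km": effort.effort[j, k],
    })
    # calendar bounds survive even if the first/last day saw no effort
    with open(path, "w") as fh:
        fh.write(f"# occasions {effort.occasions[0].isoformat()} "
                 f"{effort.occasions[-1].isoformat()}\n")
        df.to_csv(fh, index=False)


def read_effort_csv(path, n_traps: int) -> EffortGrid:
    with open(path) as fh:
        header = fh.readline().split()
        d0 = _dt.date.fromisoformat(header[2])
        d1 = _dt.date.fromisoformat(header[3])
        df = pd.read_csv(fh)
    occasions = [d0 + _dt.timedelta(days=i) for i in range((d1 - d0).days + 1)]
    occ_idx = {d.isoformat(): k for k, d in enumerate(occasions)}
    eff = np.zeros((n_traps, len(occasions)))
    for _, r in df.iterrows():
        eff[int(r["trap_id"]), occ_idx[str(r["occasion"])]] = r["effort_km"]
    return EffortGrid(eff, occasions)


# --------------------------------------------------------------------- #
# encounters (long format of 1-cells; the sex column doubles as the sex table)

def write_encounters_csv(enc: EncounterData, effort: EffortGrid, path) -> None:
    i, j, k = np.nonzero(enc.y)
    pd.DataFrame({
        "individual_id": [enc.ids[ii] for ii in i],
        "sex": ["M" if enc.sex[ii] == 1 else "F" for ii in i],
        "trap_id": j,
        "occasion": [effort.occasions[kk].isoformat() for kk in k],
    }).to_csv(path, index=False)


def read_encounters_csv(path, effort: EffortGrid, n_traps: int) -> EncounterData:
    df = pd.read_csv(path, dtype={"individual_id": str, "sex": str})
    ids = list(dict.fromkeys(df["individual_id"]))
    row = {iid: i for i, iid in enumerate(ids)}
    y = np.zeros((len(ids), n_traps, effort.n_occasions), dtype=bool)
    sex = np.zeros(len(ids), dtype=int)
    for _, r in df.iterrows():
        i = row[r["individual_id"]]
        sex[i] = 1 if r["sex"] == "M" else 0
        k = effort.occasion_index(_dt.date.fromisoformat(str(r["occasion"])))
        y[i, int(r["trap_id"]), k] = True
    return EncounterData(y=y, sex=sex, ids=ids)


# --------------------------------------------------------------------- #
# posterior draws (one CSV per chain + a key-value metadata sidecar)

def write_draws(draws: PosteriorDraws, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T = draws.n_draws_per_chain
    for c in range(draws.n_chains):
        df = pd.DataFrame({"iteration": np.arange(T)})
        for name in PARAM_NAMES:
            df[name] = draws.params[name][c]
        df["nsuper"] = draws.nsuper[c]
        df["density"] = draws.density[c]
        df.to_csv(outdir / f"chain_{c}.csv", index=False)
    meta = {
        "variant": draws.variant.number,
        "theta_fixed_value": draws.variant.theta_fixed_value,
        "chains": draws.n_chains,
        "draws_per_chain": T,
        "m_total": draws.m_total,
        "n_detected": draws.n_detected,
        "suitable_area_km2": draws.suitable_area,
        "iterations": draws.config.iterations,
        "burn_in": draws.config.burn_in,
        "thin": draws.config.thin,
        "seed": draws.config.seed,
    }
    meta.update({f"meta_{k}": v for k, v in draws.metadata.items()})
    with open(outdir / "run_metadata.txt", "w") as fh:
        for k, v in meta.items():
            fh.write(f"{k}={v}\n")


def read_draws(outdir) -> PosteriorDraws:
    """Reload serialized draws (latent-state traces are not serialized)."""
    outdir = Path(outdir)
    meta = {}
    for line in (outdir / "run_metadata.txt").read_text().splitlines():
        k, _, v = line.partition("=")
        meta[k] = v
    n_chains = int(meta["chains"])
    frames = [pd.read_csv(outdir / f"chain_{c}.csv") for c in range(n_chains)]
    params = {name: np.stack([f[name].to_numpy() for f in frames])
              for name in PARAM_NAMES}
    cfg = SamplerConfig(
        iterations=int(meta["iterations"]), burn_in=int(meta["burn_in"]),
        thin=int(meta["thin"]), chains=n_chains, seed=int(meta["seed"]),
    )
    return PosteriorDraws(
        params=params,
        nsuper=np.stack([f["nsuper"].to_numpy() for f in frames]),
        density=np.stack([f["density"].to_numpy() for f in frames]),
        traces=None,
        acceptance=[],
        config=cfg,
        variant=ModelVariant(int(meta["variant"]),
                             float(meta["theta_fixed_value"])),
        suitable_area=float(meta["suitable_area_km2"]),
        m_total=int(meta["m_total"]),
        n_detected=int(meta["n_detected"]),
        metadata={k[5:]: v for k, v in meta.items() if k.startswith("meta_")},
    )


# --------------------------------------------------------------------- #
# run configuration

@dataclass
class RunConfig:
    """Paths and settings for a command-line fit."""

    tracks: str = "tracks.csv"
    sightings: str = "sightings.csv"
    mask: str = "mask.asc"
    out: str = "fit"
    model: int = 1
    theta_fixed_value: float = 0.75
    trap_extent: tuple = (0.0, 0.0, 20.0, 20.0)
    trap_pixel_km: float = 1.0
    effort_floor_km: float = 0.1
    m_total: int = 0  # 0 = choose automatically (n detected + 3n padding)
    iterations: int = 11_000
    burn_in: int = 1_000
    thin: int = 2
    chains: int = 8
    seed: int = 0

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["trap_extent"] = list(d["trap_extent"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown run-config keys: {sorted(bad)}")
        if "trap_extent" in d:
            d["trap_extent"] = tuple(d["trap_extent"])
        return cls(**d)
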