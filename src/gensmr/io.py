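"""Readers, writers, and photo-event preprocessing.

All files are plain CSV.  Internal coordinates are planar km; longitude and
latitude columns, when present, are converted at read time with a simple
local equal-area projection about a reference point and never touch the
model math.

Schemas
-------
traps.csv        trap_id, kind, x_km, y_km, occ_1..occ_K (0/1 or effort-days)
detections.csv   record_id, trap_id, occasion, status {marked, unmarked},
                 individual_id (blank for unmarked), observed_sex {F, M, U}
marking.csv      individual_id, sex {F, M}, trap_id, count
                 [, marked_occasion, death_occasion]
telemetry.csv    individual_id, occasion, x_km, y_km
truth.csv        individual, x_m, y_m, x_r, y_r, sex, marked
photo events     trap_id, timestamp, status {marked_id, marked_unid,
                 unmarked, unknown}, individual_id, observed_sex, age_class
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .geometry import TrapArray
from .mcmc import Chains, MCMCConfig
from .model import ModelSpec

__all__ = [
    "read_traps",
    "write_traps",
    "write_detections",
    "read_detections",
    "write_telemetry",
    "read_telemetry",
    "lonlat_to_km",
    "PhotoEvent",
    "collapse_events",
    "reconcile_mark_status",
    "thin_telemetry",
    "write_chains",
    "read_chains",
    "load_config",
]

logger = logging.getLogger("gensmr")

_SEX_TO_CODE = {"F": 1, "M": 0, "U": -1}
_CODE_TO_SEX = {1: "F", 0: "M", -1: "U"}

_EARTH_RADIUS_KM = 6371.0088


def lonlat_to_km(
    lon: np.ndarray, lat: np.ndarray, ref: tuple[float, float] | None = None
) -> np.ndarray:
    """Project lon/lat (degrees) to planar km with a local sinusoidal
    (equal-area) projection about ``ref`` (defaults to the centroid).

    Adequate for survey extents of a few hundred km; for continental extents
    use a proper equal-area projection upstream.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    if ref is None:
        ref = (float(lon.mean()), float(lat.mean()))
    lon0, lat0 = np.radians(ref[0]), np.radians(ref[1])
    lam, phi = np.radians(lon), np.radians(lat)
    x = _EARTH_RADIUS_KM * (lam - lon0) * np.cos(phi)
    y = _EARTH_RADIUS_KM * (phi - lat0)
    return np.column_stack([x, y])


def _fail(path, row, msg):
    raise ValueError(f"{path}, line {row + 2}: {msg}")  # +2: header and 0-base


def read_traps(path: str | Path, projection_ref: tuple[float, float] | None = None) -> TrapArray:
    """Read a trap file.  Either ``x_km``/``y_km`` or ``lon``/``lat`` columns
    are required, plus one ``occ_*`` column per occasion."""
    path = Path(path)
    df = pd.read_csv(path)
    occ_cols = [c for c in df.columns if c.startswith("occ_")]
    if not occ_cols:
        raise ValueError(f"{path}: no occasion (occ_*) columns")
    kinds = df["kind"].unique()
    if len(kinds) != 1:
        raise ValueError(f"{path}: mixed detector kinds in one file")
    if {"x_km", "y_km"}.issubset(df.columns):
        coords = df[["x_km", "y_km"]].to_numpy(dtype=float)
    elif {"lon", "lat"}.issubset(df.columns):
        coords = lonlat_to_km(df["lon"].to_numpy(), df["lat"].to_numpy(), projection_ref)
    else:
        raise ValueError(f"{path}: need x_km/y_km or lon/lat columns")
    for row, vals in enumerate(df[occ_cols].to_numpy()):
        if np.any(pd.isna(vals)) or np.any(vals < 0):
            _fail(path, row, "operation entries must be nonnegative numbers")
    return TrapArray(
        str(kinds[0]),
        coords,
        df[occ_cols].to_numpy(dtype=float),
        trap_ids=df["trap_id"].astype(str).tolist(),
    )


def write_traps(array: TrapArray, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "trap_id": array.trap_ids,
            "kind": array.kind,
            "x_km": array.coords[:, 0],
            "y_km": array.coords[:, 1],
        }
    )
    for k in range(array.n_occasions):
        df[f"occ_{k + 1}"] = array.operation[:, k]
    df.to_csv(path, index=False)


def write_detections(
    unmarked: pd.DataFrame,
    path: str | Path,
    marked_records: pd.DataFrame | None = None,
    trap_ids: list[str] | None = None,
) -> None:
    """Write unmarked (and optionally marked) detection records."""
    rows = unmarked.copy()
    rows["status"] = "unmarked"
    rows["individual_id"] = ""
    if marked_records is not None:
        mk = marked_records.copy()
        mk["status"] = "marked"
        rows = pd.concat([rows, mk], ignore_index=True)
    out = pd.DataFrame(
        {
            "record_id": np.arange(len(rows)),
            "trap_id": (
                [trap_ids[t] for t in rows["trap"]] if trap_ids else rows["trap"]
            ),
            "occasion": rows["occasion"].astype(int),
            "status": rows["status"],
            "individual_id": rows["individual_id"],
            "observed_sex": [_CODE_TO_SEX[s] for s in rows["obs_sex"]],
        }
    )
    out.to_csv(path, index=False)


def read_detections(
    path: str | Path, trap_ids: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read detections; returns ``(unmarked, marked)`` record tables with
    numeric trap indices when ``trap_ids`` is given."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"individual_id": str}, keep_default_na=False)
    for row, s in enumerate(df["observed_sex"]):
        if s not in _SEX_TO_CODE:
            _fail(path, row, f"observed_sex must be F/M/U, got {s!r}")
    for row, s in enumerate(df["status"]):
        if s not in ("marked", "unmarked"):
            _fail(path, row, f"status must be marked/unmarked, got {s!r}")
        if s == "marked" and not str(df["individual_id"].iloc[row]):
            _fail(path, row, "marked detection lacks individual_id")
    df["obs_sex"] = df["observed_sex"].map(_SEX_TO_CODE)
    if trap_ids is not None:
        index = {t: i for i, t in enumerate(trap_ids)}
        for row, t in enumerate(df["trap_id"].astype(str)):
            if t not in index:
                _fail(path, row, f"unknown trap_id {t!r}")
        df["trap"] = df["trap_id"].astype(str).map(index)
    else:
        df["trap"] = df["trap_id"]
    df["occasion"] = df["occasion"].astype(int)
    unmarked = df[df["status"] == "unmarked"][["trap", "occasion", "obs_sex"]]
    marked = df[df["status"] == "marked"][
        ["trap", "occasion", "obs_sex", "individual_id"]
    ]
    return unmarked.reset_index(drop=True), marked.reset_index(drop=True)


def write_telemetry(telemetry: Iterable[np.ndarray], path: str | Path,
                    individual_ids: list[str] | None = None) -> None:
    rows = []
    for i, locs in enumerate(telemetry):
        locs = np.atleast_2d(locs)
        name = individual_ids[i] if individual_ids else str(i)
        for occ, x, y in locs:
            rows.append((name, int(occ), x, y))
    pd.DataFrame(rows, columns=["individual_id", "occasion", "x_km", "y_km"]).to_csv(
        path, index=False
    )


def read_telemetry(path: str | Path, individual_ids: list[str] | None = None) -> list[np.ndarray]:
    df = pd.read_csv(Path(path), dtype={"individual_id": str})
    ids = individual_ids or sorted(df["individual_id"].unique(), key=str)
    out = []
    for name in ids:
        sub = df[df["individual_id"] == str(name)]
        out.append(sub[["occasion", "x_km", "y_km"]].to_numpy(dtype=float))
    return out


# --------------------------------------------------------------- photo events


@dataclass
class PhotoEvent:
    """One classified photograph (or photo burst) of the focal species."""

    trap_id: str
    timestamp: pd.Timestamp
    status: str  # marked_id | marked_unid | unmarked | unknown
    individual_id: str | None = None
    observed_sex: str = "U"  # F | M | U
    age_class: str = "independent"  # independent | kitten

    def __post_init__(self) -> None:
        self.timestamp = pd.Timestamp(self.timestamp)
        if self.status not in ("marked_id", "marked_unid", "unmarked", "unknown"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "marked_id" and not self.individual_id:
            raise ValueError("marked_id events require individual_id")
        if self.observed_sex not in ("F", "M", "U"):
            raise ValueError(f"bad observed_sex {self.observed_sex!r}")


def _compatible(a: PhotoEvent, b: PhotoEvent) -> bool:
    if a.status != b.status:
        return False
    if a.status == "marked_id" and a.individual_id != b.individual_id:
        return False
    return True


def collapse_events(
    events: list[PhotoEvent],
    survey_start: pd.Timestamp | str,
    window_hr: float = 1.0,
    occasion_days: int = 7,
    n_occasions: int = 17,
) -> pd.DataFrame:
    """Collapse photographs into unique detections and assign occasions.

    Dependent kittens are excluded.  Consecutive photographs at the same
    detector of compatible status/identity less than ``window_hr`` apart
    merge into one detection (photographs >= ``window_hr`` apart are unique);
    a merged detection's sex is the non-unknown value if one exists, and a
    sex conflict within the window downgrades it to unknown with a warning.
    Timestamps outside the survey window are dropped with a warning.
    """
    start = pd.Timestamp(survey_start)
    end = start + pd.Timedelta(days=occasion_days * n_occasions)
    window = pd.Timedelta(hours=window_hr)

    usable = []
    for ev in events:
        if ev.age_class == "kitten":
            continue
        if not (start <= ev.timestamp < end):
            warnings.warn(f"photo at {ev.timestamp} outside the survey window; dropped")
            continue
        usable.append(ev)
    usable.sort(key=lambda e: (e.trap_id, e.timestamp))

    detections: list[dict] = []
    open_det: dict | None = None
    for ev in usable:
        if (
            open_det is not None
            and ev.trap_id == open_det["trap_id"]
            and ev.timestamp - open_det["last_time"] < window
            and _compatible(open_det["proto"], ev)
        ):
            open_det["last_time"] = ev.timestamp
            if ev.observed_sex != "U":
                if open_det["sex"] == "U":
                    open_det["sex"] = ev.observed_sex
                elif open_det["sex"] != ev.observed_sex:
                    warnings.warn(
                        f"conflicting sexes within one detection at "
                        f"{ev.trap_id}; recording unknown"
                    )
                    open_det["sex"] = "U"
            continue
        if open_det is not None:
            detections.append(open_det)
        open_det = {
            "trap_id": ev.trap_id,
            "first_time": ev.timestamp,
            "last_time": ev.timestamp,
            "status": ev.status,
            "individual_id": ev.individual_id or "",
            "sex": ev.observed_sex,
            "proto": ev,
        }
    if open_det is not None:
        detections.append(open_det)

    rows = [
        {
            "trap_id": d["trap_id"],
            "timestamp": d["first_time"],
            "occasion": int((d["first_time"] - start).days // occasion_days) + 1,
            "status": d["status"],
            "individual_id": d["individual_id"],
            "observed_sex": d["sex"],
        }
        for d in detections
    ]
    return pd.DataFrame(
        rows,
        columns=["trap_id", "timestamp", "occasion", "status", "individual_id", "observed_sex"],
    )


def reconcile_mark_status(
    detections: pd.DataFrame,
    telemetry_fixes: pd.DataFrame,
    trap_coords: dict[str, tuple[float, float]],
    time_tol_hr: float = 2.0,
    dist_tol_km: float = 1.0,
) -> pd.DataFrame:
    """Resolve ``marked_unid`` and ``unknown`` statuses against telemetry.

    A detection matches a collared individual iff that individual has a
    telemetry fix within ``time_tol_hr`` and ``dist_tol_km`` of the
    detection's camera.  Matched detections become ``marked_id`` with that
    identity; unmatched ``unknown`` become ``unmarked``; an unmatched
    ``marked_unid`` is an error (a collared animal must be resolvable), and a
    detection matching several collared individuals is flagged for manual
    resolution rather than silently assigned.

    ``telemetry_fixes`` needs columns individual_id, timestamp, x_km, y_km.
    """
    fixes = telemetry_fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    out = detections.copy()
    tol = pd.Timedelta(hours=time_tol_hr)
    for idx, det in out.iterrows():
        if det["status"] not in ("marked_unid", "unknown"):
            continue
        x0, y0 = trap_coords[det["trap_id"]]
        t0 = pd.Timestamp(det["timestamp"])
        near = fixes[
            ((fixes["timestamp"] - t0).abs() <= tol)
            & (np.hypot(fixes["x_km"] - x0, fixes["y_km"] - y0) <= dist_tol_km)
        ]
        matches = sorted(near["individual_id"].unique())
        if len(matches) > 1:
            out.loc[idx, "status"] = "ambiguous"
            warnings.warn(
                f"detection at {det['trap_id']} {t0} matches several collared "
                f"individuals {matches}; flagged for manual resolution"
            )
        elif len(matches) == 1:
            out.loc[idx, "status"] = "marked_id"
            out.loc[idx, "individual_id"] = matches[0]
        elif det["status"] == "unknown":
            out.loc[idx, "status"] = "unmarked"
        else:
            raise ValueError(
                f"marked-but-unidentified detection at {det['trap_id']} {t0} "
                "matched no collared individual"
            )
    return out


def thin_telemetry(
    fixes: pd.DataFrame,
    survey_start: pd.Timestamp | str,
    occasion_days: int = 7,
    n_occasions: int = 17,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Keep one uniformly chosen fix per individual per occasion.

    Fixes outside the survey window are ignored; occasions with no fixes for
    an individual yield nothing.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    fixes = fixes.copy()
    fixes["timestamp"] = pd.to_datetime(fixes["timestamp"])
    start = pd.Timestamp(survey_start)
    days = (fixes["timestamp"] - start).dt.total_seconds() / 86400.0
    fixes["occasion"] = np.floor(days / occasion_days).astype(int) + 1
    fixes = fixes[(fixes["occasion"] >= 1) & (fixes["occasion"] <= n_occasions)]
    kept = []
    for (_, _), grp in fixes.groupby(["individual_id", "occasion"], sort=True):
        kept.append(grp.index[rng.integers(len(grp))])
    return fixes.loc[sorted(kept)].reset_index(drop=True)


# ------------------------------------------------------------- full datasets


def write_dataset(data, out_dir: str | Path, truth=None) -> None:
    """Write a complete SMR dataset to a directory of CSV files.

    Files: ``traps_camera.csv``, ``traps_live.csv`` (if present),
    ``detections.csv`` (marked and unmarked records), ``marking.csv``
    (live-trap capture counts plus per-individual sex and mid-survey
    marking/death occasions), ``telemetry.csv``, and optionally
    ``truth.csv`` for recovery tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_traps(data.cameras, out / "traps_camera.csv")
    if data.live is not None:
        write_traps(data.live, out / "traps_live.csv")

    ids = [f"M{i:03d}" for i in range(data.n_marked)]
    marked_rows = []
    for i, j, k in zip(*np.nonzero(data.y_resight_marked)):
        for _ in range(data.y_resight_marked[i, j, k]):
            marked_rows.append(
                {
                    "trap": j,
                    "occasion": k + 1,
                    "obs_sex": int(data.marked_sex[i]),
                    "individual_id": ids[i],
                }
            )
    write_detections(
        data.unmarked[["trap", "occasion", "obs_sex"]],
        out / "detections.csv",
        marked_records=pd.DataFrame(
            marked_rows, columns=["trap", "occasion", "obs_sex", "individual_id"]
        ),
        trap_ids=data.cameras.trap_ids,
    )

    m = data.exposure.m
    mark_rows = []
    for i in range(data.n_marked):
        marked_occ = int(np.argmax(m[i] == 1)) + 1 if (m[i] == 1).any() else 0
        if m[i, 0] == 1:
            marked_occ = 1
        death_occ = int(np.argmax(m[i] == 2)) + 1 if (m[i] == 2).any() else ""
        if (m[i] == 2).all():
            death_occ = 0
        base = {
            "individual_id": ids[i],
            "sex": _CODE_TO_SEX[int(data.marked_sex[i])],
            "marked_occasion": marked_occ,
            "death_occasion": death_occ,
        }
        traps = np.nonzero(data.y_mark[i])[0] if data.y_mark is not None else []
        if len(traps) == 0:
            mark_rows.append({**base, "trap_id": "", "count": 0})
        for j in traps:
            mark_rows.append(
                {**base, "trap_id": data.live.trap_ids[j], "count": int(data.y_mark[i, j])}
            )
    pd.DataFrame(
        mark_rows,
        columns=["individual_id", "sex", "trap_id", "count", "marked_occasion", "death_occasion"],
    ).to_csv(out / "marking.csv", index=False)

    write_telemetry(data.telemetry, out / "telemetry.csv", individual_ids=ids)

    if truth is not None:
        pd.DataFrame(
            {
                "individual": np.arange(truth.n),
                "x_m": truth.s_m[:, 0],
                "y_m": truth.s_m[:, 1],
                "x_r": truth.s_r[:, 0],
                "y_r": truth.s_r[:, 1],
                "sex": truth.sex,
                "marked": truth.marked.astype(int),
            }
        ).to_csv(out / "truth.csv", index=False)


def read_dataset(in_dir: str | Path):
    """Read a dataset directory written by :func:`write_dataset`."""
    from .data import SMRData
    from .geometry import build_exposure

    src = Path(in_dir)
    cameras = read_traps(src / "traps_camera.csv")
    live = read_traps(src / "traps_live.csv") if (src / "traps_live.csv").exists() else None

    mark = pd.read_csv(
        src / "marking.csv", dtype={"individual_id": str, "trap_id": str},
        keep_default_na=False,
    )
    ids = sorted(mark["individual_id"].unique())
    n_m = len(ids)
    row_of = {name: i for i, name in enumerate(ids)}

    events = []
    marked_sex = np.zeros(n_m, dtype=int)
    y_mark = np.zeros((n_m, live.n_traps), dtype=int) if live is not None else None
    live_index = {t: j for j, t in enumerate(live.trap_ids)} if live is not None else {}
    for _, r in mark.iterrows():
        i = row_of[r["individual_id"]]
        marked_sex[i] = _SEX_TO_CODE[r["sex"]]
        occ = int(r["marked_occasion"])
        if occ > 1:
            events.append((i, occ, "marked"))
        death = str(r["death_occasion"])
        if death != "":
            events.append((i, int(float(death)), "died"))
        if y_mark is not None and str(r["trap_id"]):
            y_mark[i, live_index[str(r["trap_id"])]] = int(r["count"])
    # one event per individual per kind
    events = sorted(set(events))
    exposure = build_exposure(live, cameras, n_m, events)

    unmarked, marked_det = read_detections(src / "detections.csv", cameras.trap_ids)
    y_resight = np.zeros((n_m, cameras.n_traps, cameras.n_occasions), dtype=int)
    for _, r in marked_det.iterrows():
        y_resight[row_of[r["individual_id"]], int(r["trap"]), int(r["occasion"]) - 1] += 1

    telemetry = read_telemetry(src / "telemetry.csv", individual_ids=ids)
    return SMRData(
        cameras=cameras,
        live=live,
        exposure=exposure,
        y_mark=y_mark,
        y_resight_marked=y_resight,
        marked_sex=marked_sex,
        unmarked=unmarked,
        telemetry=telemetry,
    )


# ------------------------------------------------------------- chains/config


def write_chains(chains: Chains, path: str | Path, config: MCMCConfig | None = None,
                 spec: ModelSpec | None = None) -> None:
    """Chains to CSV (one row per retained draw) with a JSON sidecar of the
    run configuration for exact re-runs."""
    path = Path(path)
    chains.to_dataframe().to_csv(path, index=False)
    side = {
        "area_km2": chains.area,
        "seed": chains.seed,
        "acceptance": chains.acceptance,
    }
    if config is not None:
        side["mcmc"] = {
            k: v for k, v in config.__dict__.items() if not k.startswith("_") and k != "init"
        }
    if spec is not None:
        side["model"] = dict(spec.__dict__)
    path.with_suffix(".json").write_text(json.dumps(side, indent=2, default=str))


def read_chains(path: str | Path) -> Chains:
    path = Path(path)
    df = pd.read_csv(path)
    side = json.loads(path.with_suffix(".json").read_text())
    return Chains(
        draws={c: df[c].to_numpy() for c in df.columns},
        area=side["area_km2"],
        acceptance=side.get("acceptance", {}),
        seed=side.get("seed", 0),
    )


def load_config(path: str | Path) -> tuple[ModelSpec, MCMCConfig, dict]:
    """Load a YAML run configuration with ``model:`` and ``mcmc:`` sections;
    unknown extra sections are returned verbatim for provenance logging."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    spec = ModelSpec(**raw.get("model", {}))
    mcmc = MCMCConfig(**raw.get("mcmc", {}))
    extras = {k: v for k, v in raw.items() if k not in ("model", "mcmc")}
    logger.info("loaded config: model=%s mcmc=%s", spec, mcmc)
    return spec, mcmc, extras
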