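"""Camera-event geotagging from PPK position tracks.

The onboard microcomputer logs one line per thermal snapshot (serial
number, per-frame min/max temperature, the NMEA sentences current at
trigger time). The GNSS rover's raw data is post-processed externally
into an RTKLIB-style ``.pos`` track at 5 Hz. This module joins the two:
each trigger event is matched to the nearest-in-time post-processed
track point, and the PPK solution quality is converted to a nominal
positional accuracy (fix: 0.5 m, float: 2 m, single: 10 m) for the
mosaicking software.

Time bases: the event log carries NMEA (UTC) time, the ``.pos`` track
GPS time; both are reduced to seconds-of-day and reconciled with a
configurable leap-second offset (default 18 s, GPST − UTC since 2017).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np

from etmap.raster import haversine

GPS_UTC_LEAP_SECONDS = 18.0

QUALITY_ACCURACY_M = {"fix": 0.5, "float": 2.0, "single": 10.0}

_POS_QUALITY = {1: "fix", 2: "float", 5: "single"}


@dataclass(frozen=True)
class EventRecord:
    snapshot_id: int
    timestamp: float | None  # UTC seconds-of-day, None if no valid NMEA
    t_min: float
    t_max: float
    lat: float | None = None
    lon: float | None = None
    alt: float | None = None
    nmea_quality: int | None = None


@dataclass(frozen=True)
class TrackPoint:
    time: float  # GPS seconds-of-day
    lat: float
    lon: float
    height: float
    quality: str  # fix | float | single
    n_satellites: int
    sd_n: float = 0.0
    sd_e: float = 0.0
    sd_u: float = 0.0


@dataclass(frozen=True)
class CameraEvent:
    snapshot_id: int
    time: float
    lat: float
    lon: float
    height: float
    accuracy: float  # m
    source_track_time: float
    matched: bool = True


@dataclass(frozen=True)
class GCPRecord:
    id: str
    measured_lat: float
    measured_lon: float
    mosaic_lat: float
    mosaic_lon: float
    held_out: bool = False


# -- NMEA ------------------------------------------------------------------


def nmea_checksum(sentence: str) -> int:
    """XOR checksum over the characters between '$' and '*'."""
    body = sentence
    if body.startswith("$"):
        body = body[1:]
    body = body.split("*")[0]
    cs = 0
    for ch in body:
        cs ^= ord(ch)
    return cs


def _nmea_coord(value: str, hemi: str) -> float:
    """ddmm.mmmm / dddmm.mmmm -> signed decimal degrees."""
    v = float(value)
    deg = math.floor(v / 100.0)
    minutes = v - deg * 100.0
    dec = deg + minutes / 60.0
    if hemi in ("S", "W"):
        dec = -dec
    return dec


def parse_gga(sentence: str) -> dict:
    """Parse a GGA sentence; raises ValueError on bad checksum/format."""
    sentence = sentence.strip()
    if "*" in sentence:
        stated = int(sentence.rsplit("*", 1)[1], 16)
        if stated != nmea_checksum(sentence):
            raise ValueError("NMEA checksum mismatch")
    fields = sentence.split("*")[0].split(",")
    if not fields[0].endswith("GGA") or len(fields) < 10:
        raise ValueError("not a GGA sentence")
    hhmmss = fields[1]
    t = int(hhmmss[0:2]) * 3600 + int(hhmmss[2:4]) * 60 + float(hhmmss[4:])
    return {
        "time": t,  # UTC seconds-of-day
        "lat": _nmea_coord(fields[2], fields[3]),
        "lon": _nmea_coord(fields[4], fields[5]),
        "quality": int(fields[6]),
        "n_satellites": int(fields[7]) if fields[7] else None,
        "alt": float(fields[9]) if fields[9] else None,
    }


def format_gga(time_s: float, lat: float, lon: float, alt: float, quality: int = 1, nsat: int = 12) -> str:
    """Build a valid GGA sentence (used by the flight simulator)."""
    h = int(time_s // 3600) % 24
    m = int(time_s // 60) % 60
    s = time_s % 60
    def dm(v, width):
        a = abs(v)
        d = int(a)
        return f"{d * 100 + (a - d) * 60:0{width}.4f}"
    body = (
        f"GPGGA,{h:02d}{m:02d}{s:05.2f},{dm(lat, 9)},{'N' if lat >= 0 else 'S'},"
        f"{dm(lon, 10)},{'E' if lon >= 0 else 'W'},{quality},{nsat:02d},0.9,{alt:.1f},M,0.0,M,,"
    )
    return f"${body}*{nmea_checksum(body):02X}"


# -- event log -------------------------------------------------------------


def parse_event_log(path: str | Path):
    """Parse the snapshot event log.

    One record per line: ``<id> <t_min> <t_max> <NMEA sentence>``.
    Lines with a corrupt NMEA sentence yield a record with an absent
    position; lines that cannot be parsed at all go to the rejects
    list. Returns ``(records, rejects)`` with records ordered by id.
    """
    records: list[EventRecord] = []
    rejects: list[tuple[int, str, str]] = []
    with open(path, "r", encoding="ascii") as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 3)
            try:
                sid = int(parts[0])
                t_min = float(parts[1])
                t_max = float(parts[2])
                if not t_max > t_min:
                    raise ValueError("t_max <= t_min")
            except (ValueError, IndexError) as exc:
                rejects.append((lineno, line, str(exc)))
                continue
            lat = lon = alt = timestamp = quality = None
            if len(parts) == 4:
                try:
                    gga = parse_gga(parts[3])
                    lat, lon, alt = gga["lat"], gga["lon"], gga["alt"]
                    timestamp, quality = gga["time"], gga["quality"]
                except ValueError as exc:
                    rejects.append((lineno, line, str(exc)))
            records.append(
                EventRecord(
                    snapshot_id=sid, timestamp=timestamp, t_min=t_min, t_max=t_max,
                    lat=lat, lon=lon, alt=alt, nmea_quality=quality,
                )
            )
    records.sort(key=lambda r: r.snapshot_id)
    return records, rejects


# -- RTKLIB .pos -----------------------------------------------------------


def parse_pos(path: str | Path) -> list[TrackPoint]:
    """Parse an RTKLIB-style .pos track.

    Header lines begin with '%'. Data columns: date, time (GPST), lat,
    lon, height, Q, ns, sdn, sde, sdu, ... . Q maps 1 -> fix,
    2 -> float, 5 -> single; any other Q is a format error naming the
    line. Times are reduced to GPS seconds-of-day.
    """
    points: list[TrackPoint] = []
    with open(path, "r", encoding="ascii") as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line or line.startswith("%"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise ValueError(f"{path}:{lineno}: too few columns in .pos record")
            dt = datetime.strptime(parts[0] + " " + parts[1].split(".")[0], "%Y/%m/%d %H:%M:%S")
            frac = float("0." + parts[1].split(".")[1]) if "." in parts[1] else 0.0
            tod = dt.hour * 3600 + dt.minute * 60 + dt.second + frac
            q = int(parts[5])
            if q not in _POS_QUALITY:
                raise ValueError(f"{path}:{lineno}: unknown quality code Q={q}")
            sds = [float(v) for v in parts[7:10]] if len(parts) >= 10 else [0.0, 0.0, 0.0]
            points.append(
                TrackPoint(
                    time=tod, lat=float(parts[2]), lon=float(parts[3]),
                    height=float(parts[4]), quality=_POS_QUALITY[q],
                    n_satellites=int(parts[6]), sd_n=sds[0], sd_e=sds[1], sd_u=sds[2],
                )
            )
    return points


def quality_to_accuracy(q: str) -> float:
    """Nominal accuracy of a PPK solution quality: fix 0.5, float 2, single 10 m."""
    try:
        return QUALITY_ACCURACY_M[q]
    except KeyError:
        raise ValueError(f"unknown quality code {q!r} (expected fix/float/single)") from None


def match_events(
    events,
    track,
    tolerance: float = 0.2,
    leap_seconds: float = GPS_UTC_LEAP_SECONDS,
) -> list[CameraEvent]:
    """Join each trigger event to the nearest-in-time track point.

    Event timestamps are UTC seconds-of-day, track times GPS
    seconds-of-day; ``leap_seconds`` bridges the two (GPST = UTC +
    leap). Nearest point wins; exact ties go to the earlier point.
    Events farther than ``tolerance`` seconds from every track point
    are returned flagged unmatched (position from the nearest point
    anyway, accuracy from its quality).
    """
    if not track:
        raise ValueError("track must be non-empty")
    tt = np.array([p.time for p in track])
    if np.any(np.diff(tt) <= 0):
        raise ValueError("track times must be strictly increasing")
    out = []
    for ev in events:
        if ev.timestamp is None:
            continue
        t_gps = ev.timestamp + leap_seconds
        pos = np.searchsorted(tt, t_gps)
        lo = max(pos - 1, 0)
        hi = min(pos, len(tt) - 1)
        # tie -> earlier point
        i = lo if abs(t_gps - tt[lo]) <= abs(t_gps - tt[hi]) else hi
        p = track[i]
        dt = abs(t_gps - tt[i])
        out.append(
            CameraEvent(
                snapshot_id=ev.snapshot_id, time=t_gps, lat=p.lat, lon=p.lon,
                height=p.height, accuracy=quality_to_accuracy(p.quality),
                source_track_time=p.time, matched=bool(dt <= tolerance),
            )
        )
    out.sort(key=lambda e: e.snapshot_id)
    return out


def write_camera_positions(events, path: str | Path, allow_partial: bool = False) -> None:
    """Write the camera-position CSV consumed by the mosaicking software.

    Columns: label, lon, lat, alt, accuracy_m; one row per snapshot,
    ordered by id; refuses unmatched events unless ``allow_partial``.
    Deterministic: identical input produces a byte-identical file.
    """
    events = sorted(events, key=lambda e: e.snapshot_id)
    unmatched = [e.snapshot_id for e in events if not e.matched]
    if unmatched and not allow_partial:
        raise ValueError(f"unmatched events present (ids {unmatched}); pass allow_partial=True")
    with open(path, "w", encoding="ascii", newline="\n") as f:
        f.write("label,lon,lat,alt,accuracy_m\n")
        for e in events:
            if not e.matched and not allow_partial:
                continue
            f.write(f"{e.snapshot_id},{e.lon:.9f},{e.lat:.9f},{e.height:.4f},{e.accuracy:g}\n")


# -- mosaic alignment and GCP error ----------------------------------------


def fit_alignment(pairs):
    """Least-squares planar affine mapping source points onto targets.

    ``pairs`` is a sequence of ((sx, sy), (tx, ty)). Needs at least 3
    non-collinear source points. Returns ``(affine, rms)`` where affine
    is an :class:`etmap.raster.Affine` and rms the residual
    root-mean-square distance in target units.
    """
    from etmap.raster import Affine

    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("need at least 3 control-point pairs")
    src = np.array([p[0] for p in pairs], dtype=float)
    dst = np.array([p[1] for p in pairs], dtype=float)
    A = np.column_stack([src[:, 0], src[:, 1], np.ones(len(pairs))])
    if np.linalg.matrix_rank(A, tol=1e-9 * max(1.0, np.abs(A).max())) < 3:
        raise ValueError("control points are collinear")
    coef, *_ = np.linalg.lstsq(A, dst, rcond=None)
    affine = Affine(
        a=coef[0, 0], b=coef[1, 0], c=coef[2, 0],
        d=coef[0, 1], e=coef[1, 1], f=coef[2, 1],
    )
    fitted = A @ coef
    rms = float(np.sqrt(np.mean(np.sum((fitted - dst) ** 2, axis=1))))
    return affine, rms


def gcp_spatial_error(gcps):
    """Per-GCP distance between surveyed and mosaic positions, plus
    mean/sd over the held-out subset.

    Distances are great-circle (haversine, R=6 378 137 m). Returns
    ``(distances, summary)`` where distances maps GCP id -> meters and
    summary is ``{"avg": m, "sd": m, "n": count}`` over held-out GCPs,
    or None when none are held out (sd is the population sd, 0 for a
    single point).
    """
    gcps = list(gcps)
    if not gcps:
        raise ValueError("need at least one GCP record")
    distances = {
        g.id: float(haversine(g.measured_lat, g.measured_lon, g.mosaic_lat, g.mosaic_lon))
        for g in gcps
    }
    held = [distances[g.id] for g in gcps if g.held_out]
    summary = None
    if held:
        arr = np.array(held)
        summary = {"avg": float(arr.mean()), "sd": float(arr.std(ddof=0)), "n": len(held)}
    return distances, summary
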