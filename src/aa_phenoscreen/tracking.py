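"""Tracking data containers, CSV readers/writers and the startle-battery schedule.

A behavioural run consists of larvae held individually in square wells of a
96-well plate, acclimatised in the dark and then exposed to repeated cycles of
a 60-s acoustic/light startle string. Video tracking exports, per fish, a time
series of position, heading and per-frame distance. This module holds the
:class:`Track` container for one fish, the well geometry used for thigmotaxis,
the :class:`StimulusSchedule` describing the battery, and the derivation of
the per-cycle analysis windows:

* **SRB** (startle-response behaviour): the 60-s stimulus string itself;
* **PSRB** (post-startle response behaviour): the first 10 min that follow it.

Coordinates are in mm with the origin at the well's lower-left corner; heading
is in degrees in [0, 360), 0 = +x axis, counter-clockwise positive; time in
seconds. These conventions are the package's own (the tracker GUI does not fix
them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

TRACK_COLUMNS = ["fish_id", "t_s", "x_mm", "y_mm", "heading_deg", "dist_mm"]
METADATA_COLUMNS = [
    "fish_id",
    "plate_id",
    "well_id",
    "treatment",
    "dose_level",
    "dose_value",
    "dose_unit",
]


class TrackingFormatError(ValueError):
    """A tracking or metadata file does not conform to the declared dialect."""


class TrackingDataError(ValueError):
    """A structurally valid file contains inconsistent data."""


@dataclass
class Track:
    """One fish's tracked time series plus its plate/treatment metadata.

    ``step_dist[i]`` is the distance travelled between frame ``i-1`` and
    frame ``i``; ``step_dist[0]`` is 0 by definition.
    """

    fish_id: str
    plate_id: str
    well_id: str
    treatment: str
    dose_level: int
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    step_dist: np.ndarray
    dose_value: float = 0.0
    dose_unit: str = ""
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        for name in ("t", "x", "y", "heading", "step_dist"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if n < 2:
            raise TrackingDataError(f"fish {self.fish_id}: need >= 2 frames, got {n}")
        for name in ("x", "y", "heading", "step_dist"):
            if getattr(self, name).size != n:
                raise TrackingDataError(
                    f"fish {self.fish_id}: column {name} length mismatch"
                )
        if not np.all(np.diff(self.t) > 0):
            raise TrackingDataError(f"fish {self.fish_id}: time is not strictly increasing")
        if np.any(self.step_dist < 0):
            raise TrackingDataError(f"fish {self.fish_id}: negative step distance")

    @property
    def n_frames(self) -> int:
        return int(self.t.size)

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Index slice of frames with ``start_s <= t < end_s``."""
        i0 = int(np.searchsorted(self.t, start_s, side="left"))
        i1 = int(np.searchsorted(self.t, end_s, side="left"))
        return slice(i0, i1)


@dataclass(frozen=True)
class WellGeometry:
    """Axis-aligned square/rectangular well, with the centred inner zone used
    to score thigmotaxis (wall-hugging). The inner zone is a rectangle whose
    width and height are ``inner_fraction`` of the well's, so at the default
    0.40 the inner zone covers 16% of the well area."""

    x_min: float = 0.0
    x_max: float = 8.0
    y_min: float = 0.0
    y_max: float = 8.0
    inner_fraction: float = 0.40

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError("degenerate well geometry")
        if not 0.0 < self.inner_fraction < 1.0:
            raise ValueError("inner_fraction must be in (0, 1)")

    @property
    def inner_bounds(self) -> tuple[float, float, float, float]:
        cx = 0.5 * (self.x_min + self.x_max)
        cy = 0.5 * (self.y_min + self.y_max)
        hw = 0.5 * self.inner_fraction * (self.x_max - self.x_min)
        hh = 0.5 * self.inner_fraction * (self.y_max - self.y_min)
        return cx - hw, cx + hw, cy - hh, cy + hh

    def outside_inner(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Boolean mask: True where a position lies strictly outside the inner
        zone (boundary points count as inside)."""
        ix0, ix1, iy0, iy1 = self.inner_bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x < ix0) | (x > ix1) | (y < iy0) | (y > iy1)


@dataclass(frozen=True)
class StimulusEvent:
    onset_s: float
    kind: str
    duration_s: float


TAP_KINDS = ("tap_L", "tap_H")
LIGHT_KINDS = (
    "dark",
    "light_red",
    "light_blue",
    "light_purple",
    "light_white",
    "light_flicker",
)

# Tap timeline of the 60-s string; each tap occupies a 0.5-s slot (the tap and
# the break that follows it), which makes the printed pauses (37 s) plus the
# 46 taps (23 s) tile the minute exactly.
_TAP_PROGRAM: tuple[tuple[float, int, str], ...] = (
    # (pause before run, number of taps, tap kind)
    (1.0, 6, "tap_L"),
    (4.0, 4, "tap_H"),
    (1.0, 8, "tap_L"),
    (8.0, 2, "tap_L"),
    (0.0, 10, "tap_H"),
    (7.0, 2, "tap_H"),
    (13.0, 14, "tap_H"),
)
_FINAL_PAUSE_S = 3.0


def default_startle_events() -> list[StimulusEvent]:
    """The default 60-s acoustic/light string.

    Light epochs change colour every 10 s (darkness, red, blue, purple, white,
    flicker); low/high-intensity taps follow the printed pause/run pattern with
    one 0.5-s slot per tap.
    """
    events: list[StimulusEvent] = []
    t = 0.0
    for pause, n_taps, kind in _TAP_PROGRAM:
        t += pause
        for _ in range(n_taps):
            events.append(StimulusEvent(onset_s=round(t, 6), kind=kind, duration_s=0.5))
            t += 0.5
    t += _FINAL_PAUSE_S
    assert abs(t - 60.0) < 1e-9
    for i, kind in enumerate(LIGHT_KINDS):
        events.append(StimulusEvent(onset_s=10.0 * i, kind=kind, duration_s=10.0))
    return events


@dataclass
class StimulusSchedule:
    """Timing of the whole battery: acclimation, then ``n_cycles`` repeats of
    a ``startle_s`` stimulus string each followed by an intermission."""

    acclimation_s: float = 3600.0
    n_cycles: int = 5
    startle_s: float = 60.0
    intermission_s: float = 1740.0
    psrb_s: float = 600.0
    events: list[StimulusEvent] = field(default_factory=default_startle_events)

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if min(self.acclimation_s, self.intermission_s) < 0 or self.startle_s <= 0:
            raise ValueError("negative schedule timing")
        for ev in self.events:
            if not (0.0 <= ev.onset_s <= self.startle_s):
                raise ValueError(f"event at {ev.onset_s}s outside the startle string")

    @property
    def cycle_s(self) -> float:
        return self.startle_s + self.intermission_s

    @property
    def total_s(self) -> float:
        return self.acclimation_s + self.n_cycles * self.cycle_s

    def cycle_start(self, cycle_index: int) -> float:
        """Absolute onset of the startle string of cycle ``cycle_index`` (1-based)."""
        if not 1 <= cycle_index <= self.n_cycles:
            raise ValueError(f"cycle_index {cycle_index} outside 1..{self.n_cycles}")
        return self.acclimation_s + (cycle_index - 1) * self.cycle_s

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "acclimation_s": self.acclimation_s,
            "n_cycles": self.n_cycles,
            "startle_s": self.startle_s,
            "intermission_s": self.intermission_s,
            "psrb_s": self.psrb_s,
            "events": [
                {"onset_s": ev.onset_s, "kind": ev.kind, "duration_s": ev.duration_s}
                for ev in self.events
            ],
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StimulusSchedule":
        payload = yaml.safe_load(Path(path).read_text())
        events = [StimulusEvent(**ev) for ev in payload.pop("events", [])]
        if not events:
            events = default_startle_events()
        return cls(events=events, **payload)


@dataclass(frozen=True)
class AnalysisWindow:
    """A labelled absolute-time interval ``[start_s, end_s)`` of the run."""

    label: str  # "SRB", "PSRB" or "custom"
    cycle_index: int
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("empty analysis window")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def battery_windows(schedule: StimulusSchedule) -> list[AnalysisWindow]:
    """Derive the SRB and PSRB windows of every cycle.

    SRB of cycle k spans its 60-s startle string; PSRB spans the first
    ``psrb_s`` seconds of the following intermission (clipped to the
    intermission if the schedule is shorter than the default 10 min).
    """
    windows: list[AnalysisWindow] = []
    psrb = min(schedule.psrb_s, schedule.intermission_s)
    for k in range(1, schedule.n_cycles + 1):
        s0 = schedule.cycle_start(k)
        windows.append(AnalysisWindow("SRB", k, s0, s0 + schedule.startle_s))
        if psrb > 0:
            windows.append(
                AnalysisWindow("PSRB", k, s0 + schedule.startle_s, s0 + schedule.startle_s + psrb)
            )
    return windows


# ---------------------------------------------------------------------------
# CSV IO (tidy long dialect: one tracking file per plate with a fish_id column)
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-fish metadata table, validating the declared columns."""
    meta = pd.read_csv(path, comment="#")
    missing = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing:
        raise TrackingFormatError(f"metadata file {path} missing column(s): {missing}")
    meta["fish_id"] = meta["fish_id"].astype(str)
    meta["dose_level"] = meta["dose_level"].astype(int)
    return meta


def read_tracks(
    path: str | Path,
    metadata: pd.DataFrame | str | Path,
    frame_rate: float = 60.0,
) -> list[Track]:
    """Read tracking data and join per-fish metadata.

    Two dialects are accepted: a tidy long CSV (columns ``fish_id, t_s, x_mm,
    y_mm, heading_deg, dist_mm``, one file per plate), or a directory of
    per-fish CSV files in the same column layout (a file without a
    ``fish_id`` column takes its file stem as the fish id).

    Frames with missing position are dropped (and logged with their row
    numbers); the step distance following a dropped frame is recomputed from
    the surviving positions so that total distance stays consistent.
    """
    path = Path(path)
    if path.is_dir():
        parts = []
        for f in sorted(path.glob("*.csv")):
            part = pd.read_csv(f, comment="#")
            if "fish_id" not in part.columns:
                part.insert(0, "fish_id", f.stem)
            parts.append(part)
        if not parts:
            raise TrackingFormatError(f"directory {path} contains no CSV files")
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.read_csv(path, comment="#")
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise TrackingFormatError(f"tracking file {path} missing column(s): {missing}")
    if isinstance(metadata, (str, Path)):
        metadata = read_metadata(metadata)
    meta = metadata.set_index("fish_id")

    df = df.copy()
    df["fish_id"] = df["fish_id"].astype(str)
    bad = df[["t_s", "x_mm", "y_mm"]].isna().any(axis=1)
    if bad.any():
        rows = (df.index[bad] + 2).tolist()  # 1-based, plus header line
        logger.warning("%s: dropping %d frame(s) with missing position (rows %s)",
                       path, int(bad.sum()), rows[:20])
        df = df[~bad]

    tracks: list[Track] = []
    for fish_id, sub in df.groupby("fish_id", sort=True):
        if fish_id not in meta.index:
            raise TrackingDataError(f"fish {fish_id} has no metadata row")
        t = sub["t_s"].to_numpy(dtype=float)
        if not np.all(np.diff(t) > 0):
            raise TrackingDataError(f"fish {fish_id}: time is not strictly increasing")
        x = sub["x_mm"].to_numpy(dtype=float)
        y = sub["y_mm"].to_numpy(dtype=float)
        heading = np.mod(sub["heading_deg"].to_numpy(dtype=float), 360.0)
        step = sub["dist_mm"].to_numpy(dtype=float)
        step[0] = 0.0
        gap = np.flatnonzero(np.diff(sub.index.to_numpy()) != 1) + 1
        if gap.size:  # recompute steps that straddle dropped frames
            step[gap] = np.hypot(x[gap] - x[gap - 1], y[gap] - y[gap - 1])
        row = meta.loc[fish_id]
        tracks.append(
            Track(
                fish_id=str(fish_id),
                plate_id=str(row["plate_id"]),
                well_id=str(row["well_id"]),
                treatment=str(row["treatment"]),
                dose_level=int(row["dose_level"]),
                dose_value=float(row["dose_value"]),
                dose_unit=str(row["dose_unit"]),
                frame_rate=frame_rate,
                t=t,
                x=x,
                y=y,
                heading=heading,
                step_dist=step,
            )
        )
    return tracks


def tracks_frame(tracks: Iterable[Track]) -> pd.DataFrame:
    parts = []
    for tr in tracks:
        parts.append(
            pd.DataFrame(
                {
                    "fish_id": tr.fish_id,
                    "t_s": tr.t,
                    "x_mm": tr.x,
                    "y_mm": tr.y,
                    "heading_deg": tr.heading,
                    "dist_mm": tr.step_dist,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_tracks(tracks: Sequence[Track], path: str | Path) -> None:
    """Write tracks to the tidy long CSV dialect (lossless round-trip)."""
    tracks_frame(tracks).to_csv(path, index=False, float_format="%.9f")


def metadata_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = [
        {
            "fish_id": tr.fish_id,
            "plate_id": tr.plate_id,
            "well_id": tr.well_id,
            "treatment": tr.treatment,
            "dose_level": tr.dose_level,
            "dose_value": tr.dose_value,
            "dose_unit": tr.dose_unit,
        }
        for tr in tracks
    ]
    return pd.DataFrame(rows)


def write_metadata(tracks: Sequence[Track], path: str | Path) -> None:
    metadata_frame(tracks).to_csv(path, index=False)
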