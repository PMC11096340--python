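"""Extraction of the six behavioural syllables and plate-control normalization.

The syllables summarise one fish inside one analysis window:

``distance_mm``
    total distance travelled (sum of per-frame step distances).
``turning_rel``
    relative turning angle, deg/mm: the summed magnitude of heading changes
    (each folded to the smaller angle in [0, 180]) divided by the distance
    travelled in the same window. Undefined for a fish that did not move.
``pause_time_s``
    total time spent at zero (or sub-threshold) step distance.
``spurt_velocity``
    mean over movement bouts of the bout's peak frame velocity (mm/s), a bout
    being a maximal run of consecutive non-pause frames. Undefined if the fish
    never moved.
``thigmo_time_ratio`` / ``thigmo_dist_ratio``
    fraction of time / of distance spent outside the centred inner zone
    (wall-hugging, an anxiety-like behaviour).

Group comparisons and the classifier consume these features as percent change
versus the mean of same-plate control (zero-dose) fish, computed separately
per window label and cycle, which absorbs plate-to-plate baseline differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracking import AnalysisWindow, Track, WellGeometry

FEATURE_NAMES = (
    "distance_mm",
    "turning_rel",
    "pause_time_s",
    "spurt_velocity",
    "thigmo_time_ratio",
    "thigmo_dist_ratio",
)


@dataclass
class FeatureVector:
    fish_id: str
    window: AnalysisWindow
    distance_mm: float
    turning_rel: float | None
    pause_time_s: float
    spurt_velocity: float | None
    thigmo_time_ratio: float
    thigmo_dist_ratio: float | None

    def as_dict(self) -> dict:
        return {
            "fish_id": self.fish_id,
            "window_label": self.window.label,
            "cycle": self.window.cycle_index,
            "distance_mm": self.distance_mm,
            "turning_rel": _nan(self.turning_rel),
            "pause_time_s": self.pause_time_s,
            "spurt_velocity": _nan(self.spurt_velocity),
            "thigmo_time_ratio": self.thigmo_time_ratio,
            "thigmo_dist_ratio": _nan(self.thigmo_dist_ratio),
        }


def _nan(v: float | None) -> float:
    return float("nan") if v is None else float(v)


def step_turning(h_prev, h_curr):
    """Magnitude of the heading change, folded to the smaller angle in [0, 180].

    Accepts scalars or arrays of headings in degrees.
    """
    d = np.abs(np.mod(np.asarray(h_curr) - np.asarray(h_prev) + 180.0, 360.0) - 180.0)
    if d.ndim == 0:
        return float(d)
    return d


def _window_arrays(track: Track, window: AnalysisWindow):
    """Frames of the window plus the step quantities attributed to them.

    Frame ``i`` belongs to the window if ``start <= t[i] < end``; the step
    (distance, heading change) attributed to frame ``i`` is the one from
    frame ``i-1``, so the step *into* the first window frame is included
    whenever a preceding frame exists.
    """
    if window.start_s < track.t[0] - 0.5 / track.frame_rate or window.end_s > track.t[-1] + 1.0 / track.frame_rate:
        raise ValueError(
            f"window [{window.start_s}, {window.end_s}) outside track span "
            f"[{track.t[0]}, {track.t[-1]}] for fish {track.fish_id}"
        )
    sl = track.window_slice(window.start_s, window.end_s)
    if sl.stop - sl.start == 0:
        raise ValueError(f"window [{window.start_s}, {window.end_s}) contains no frames")
    step = track.step_dist[sl].copy()
    turn = step_turning(track.heading[max(sl.start - 1, 0): sl.stop - 1],
                        track.heading[max(sl.start, 1): sl.stop])
    if sl.start == 0:  # no step into the very first frame of the track
        step = step.copy()
        step[0] = 0.0
        turn = np.concatenate([[0.0], turn])
    return sl, step, turn


def relative_turning(track: Track, window: AnalysisWindow) -> float | None:
    """Summed step-turning over the window per mm travelled; ``None`` (missing)
    for a stationary fish."""
    _, step, turn = _window_arrays(track, window)
    total = float(step.sum())
    if total <= 0.0:
        return None
    return float(turn.sum()) / total


def pause_time(track: Track, window: AnalysisWindow, eps: float = 0.0) -> float:
    """Total time (s) at step distance <= ``eps`` within the window."""
    if eps < 0:
        raise ValueError("eps must be >= 0")
    _, step, _ = _window_arrays(track, window)
    return float(np.count_nonzero(step <= eps)) / track.frame_rate


def _bout_bounds(paused: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal runs of non-paused frames."""
    moving = ~paused
    if not moving.any():
        return []
    edges = np.flatnonzero(np.diff(moving.astype(np.int8)))
    starts = [0] if moving[0] else []
    starts += (edges[moving[edges + 1]] + 1).tolist()
    ends = (edges[~moving[edges + 1]] + 1).tolist()
    if moving[-1]:
        ends.append(moving.size)
    return list(zip(starts, ends))


def spurt_velocity(track: Track, window: AnalysisWindow, eps: float = 0.0) -> float | None:
    """Mean over movement bouts of each bout's maximum frame velocity (mm/s);
    ``None`` if the window has no movement bout."""
    _, step, _ = _window_arrays(track, window)
    paused = step <= eps
    bouts = _bout_bounds(paused)
    if not bouts:
        return None
    vel = step * track.frame_rate
    return float(np.mean([vel[a:b].max() for a, b in bouts]))


def thigmotaxis(
    track: Track, window: AnalysisWindow, geom: WellGeometry
) -> tuple[float, float | None]:
    """(time_ratio, dist_ratio) of travel outside the inner zone.

    Each frame is classified by its own endpoint position; the distance ratio
    is missing for a stationary fish.
    """
    sl, step, _ = _window_arrays(track, window)
    outside = geom.outside_inner(track.x[sl], track.y[sl])
    time_ratio = float(np.count_nonzero(outside)) / outside.size
    total = float(step.sum())
    dist_ratio = float(step[outside].sum()) / total if total > 0 else None
    return time_ratio, dist_ratio


def extract_features(
    track: Track,
    window: AnalysisWindow,
    geom: WellGeometry,
    eps: float = 0.0,
) -> FeatureVector:
    """Assemble all six syllables of one fish in one window."""
    _, step, turn = _window_arrays(track, window)
    distance = float(step.sum())
    total = distance
    turning = float(turn.sum()) / total if total > 0 else None
    paused = step <= eps
    pause_s = float(np.count_nonzero(paused)) / track.frame_rate
    bouts = _bout_bounds(paused)
    vel = step * track.frame_rate
    spurt = float(np.mean([vel[a:b].max() for a, b in bouts])) if bouts else None
    time_ratio, dist_ratio = thigmotaxis(track, window, geom)
    return FeatureVector(
        fish_id=track.fish_id,
        window=window,
        distance_mm=distance,
        turning_rel=turning,
        pause_time_s=pause_s,
        spurt_velocity=spurt,
        thigmo_time_ratio=time_ratio,
        thigmo_dist_ratio=dist_ratio,
    )


def feature_table(
    tracks: Sequence[Track],
    windows: Iterable[AnalysisWindow],
    geom: WellGeometry,
    eps: float = 0.0,
) -> pd.DataFrame:
    """Tidy feature table: one row per fish x window x cycle, with metadata."""
    windows = list(windows)
    rows = []
    for tr in tracks:
        for w in windows:
            fv = extract_features(tr, w, geom, eps=eps)
            d = fv.as_dict()
            d.update(
                plate_id=tr.plate_id,
                well_id=tr.well_id,
                treatment=tr.treatment,
                dose_level=tr.dose_level,
            )
            rows.append(d)
    cols = [
        "fish_id", "plate_id", "well_id", "treatment", "dose_level",
        "window_label", "cycle", *FEATURE_NAMES,
    ]
    return pd.DataFrame(rows)[cols]


class MissingControlError(ValueError):
    """A plate has no usable zero-dose control fish."""


def normalize_to_controls(features: pd.DataFrame) -> pd.DataFrame:
    """Percent change of each feature versus the same-plate control mean.

    Control means are taken over dose-level-0 fish of the same plate, window
    label and cycle; missing feature values are excluded pairwise from the
    control mean and stay missing in the output. A control mean of exactly 0
    leaves that feature undefined (NaN) for the whole group.
    """
    req = {"plate_id", "window_label", "cycle", "dose_level"}
    if not req.issubset(features.columns):
        raise ValueError(f"feature table missing columns {req - set(features.columns)}")
    out = features.copy()
    keys = ["plate_id", "window_label", "cycle"]
    controls = features[features["dose_level"] == 0]
    plates_without = set(features["plate_id"]) - set(controls["plate_id"])
    if plates_without:
        raise MissingControlError(f"plate(s) with no control fish: {sorted(plates_without)}")
    ctrl_means = controls.groupby(keys)[list(FEATURE_NAMES)].mean()
    for name in FEATURE_NAMES:
        m = ctrl_means[name].reindex(pd.MultiIndex.from_frame(out[keys])).to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (out[name].to_numpy() - m) / m
        pct[np.isclose(m, 0.0)] = np.nan
        out[name + "_pct"] = pct
    return out
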