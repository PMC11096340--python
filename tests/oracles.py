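"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain Python loops, independent of
the vectorised implementations it checks.
"""

from __future__ import annotations

import numpy as np

from aa_phenoscreen.tracking import AnalysisWindow, Track, WellGeometry


def fold_angle(h_prev: float, h_curr: float) -> float:
    d = abs(h_curr - h_prev) % 360.0
    return min(d, 360.0 - d)


def brute_features(track: Track, window: AnalysisWindow, geom: WellGeometry,
                   eps: float = 0.0) -> dict:
    """Loop-based reimplementation of the six syllables.

    Frame i belongs to the window if start <= t[i] < end; the step and
    heading change attributed to frame i are those from frame i-1 (zero for
    the first frame of the whole track).
    """
    fr = track.frame_rate
    idx = [i for i in range(track.n_frames)
           if window.start_s <= track.t[i] < window.end_s]
    assert idx, "window contains no frames"
    ix0, ix1, iy0, iy1 = geom.inner_bounds

    dist = 0.0
    turn = 0.0
    pause_n = 0
    out_n = 0
    out_dist = 0.0
    bout_maxima: list[float] = []
    current_max: float | None = None
    for i in idx:
        step = float(track.step_dist[i]) if i > 0 else 0.0
        d_ang = fold_angle(float(track.heading[i - 1]), float(track.heading[i])) if i > 0 else 0.0
        dist += step
        turn += d_ang
        outside = not (ix0 <= track.x[i] <= ix1 and iy0 <= track.y[i] <= iy1)
        if outside:
            out_n += 1
            out_dist += step
        if step <= eps:
            pause_n += 1
            if current_max is not None:
                bout_maxima.append(current_max)
                current_max = None
        else:
            v = step * fr
            current_max = v if current_max is None else max(current_max, v)
    if current_max is not None:
        bout_maxima.append(current_max)

    return {
        "distance_mm": dist,
        "turning_rel": (turn / dist) if dist > 0 else None,
        "pause_time_s": pause_n / fr,
        "spurt_velocity": (sum(bout_maxima) / len(bout_maxima)) if bout_maxima else None,
        "thigmo_time_ratio": out_n / len(idx),
        "thigmo_dist_ratio": (out_dist / dist) if dist > 0 else None,
    }


def make_track(step_dist, heading=None, x=None, y=None, frame_rate=1.0,
               fish_id="F1", plate_id="P1", well_id="W1", treatment="control",
               dose_level=0) -> Track:
    """Toy track from explicit arrays; defaults keep the fish at the centre
    of the default 8 mm well."""
    step = np.asarray(step_dist, dtype=float)
    n = step.size
    t = np.arange(n) / frame_rate
    if heading is None:
        heading = np.zeros(n)
    if x is None:
        x = np.full(n, 4.0)
    if y is None:
        y = np.full(n, 4.0)
    return Track(fish_id=fish_id, plate_id=plate_id, well_id=well_id,
                 treatment=treatment, dose_level=dose_level, frame_rate=frame_rate,
                 t=t, x=np.asarray(x, float), y=np.asarray(y, float),
                 heading=np.asarray(heading, float), step_dist=step)


def bh_stepup(p):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def exact_ranksum_p(a, b) -> float:
    """Two-sided exact rank-sum p by enumerating all group assignments."""
    from itertools import combinations

    a = list(map(float, a))
    b = list(map(float, b))
    pooled = a + b
    n1 = len(a)
    ranks = {}
    s = sorted(pooled)
    for v in set(pooled):
        positions = [i + 1 for i, w in enumerate(s) if w == v]
        ranks[v] = sum(positions) / len(positions)
    r_obs = sum(ranks[v] for v in a)
    u_obs = r_obs - n1 * (n1 + 1) / 2
    us = []
    for comb in combinations(range(len(pooled)), n1):
        r = sum(ranks[pooled[i]] for i in comb)
        us.append(r - n1 * (n1 + 1) / 2)
    total = len(us)
    p_low = sum(u <= u_obs for u in us) / total
    p_high = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_low, p_high))
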