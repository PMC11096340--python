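"""Synthetic-data generators with planted ground truth for every pipeline arm.

Trajectories come from a paused/spurting correlated random walk with wall
bias — deliberately the simplest process whose sufficient statistics are
exactly the six behavioural syllables:

* per frame a fish pauses with probability ``p_pause`` (bout lengths are
  therefore geometric);
* a moving fish updates its heading by wrapped-Gaussian noise plus a drift
  toward the nearest wall (positive wall bias, thigmotaxis) or toward the
  well centre (negative bias);
* frame speed is a lognormal-noisy cruise speed with occasional spurt spikes;
  during the startle string it is multiplied by a per-peak startle gain;
* walls are reflective — a fish cannot leave the well.

A :class:`BehaviourArchetype` modulates these parameters multiplicatively
(drug effects), scaled linearly with the ordinal dose level so dose 0 is
always the unperturbed control. Planted truth is recorded for every generated
unit, for behaviour, phosphoproteome and network generators alike.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .phospho import KO_COLS, TABLE_COLS, WT_COLS
from .tracking import StimulusSchedule, Track, WellGeometry

# baseline (control-fish) walk parameters
BASE_SPEED_MM_S = 1.2
BASE_PAUSE_P = 0.35
BASE_TURN_SD_DEG = 25.0
BASE_SPURT_P = 0.05
BASE_SPURT_FACTOR = 4.0
SPEED_NOISE_SD = 0.3  # lognormal sigma of frame speed
FISH_SPEED_SD = 0.08  # lognormal sigma of per-fish baseline speed
BASE_STARTLE_GAIN = (2.5, 3.0, 2.2, 2.0, 1.8, 2.6)  # motility gain in P1..P6
# wall-preference map: bias(m) = WALL_SLOPE * m - WALL_OFFSET, so the control
# multiplier 1 gives a mild attraction toward the wall and multipliers < ~0.8
# flip to centre attraction
WALL_SLOPE = 0.20
WALL_OFFSET = 0.16


@dataclass(frozen=True)
class BehaviourArchetype:
    """Multiplicative effects of a treatment archetype at the top dose.

    All multipliers are > 0 and equal to 1 for the control archetype; the
    effect at dose level d in 0..3 is ``1 + (m - 1) * d / 3``.
    """

    name: str
    speed: float = 1.0
    pause: float = 1.0
    turning: float = 1.0
    spurt: float = 1.0
    thigmo: float = 1.0
    startle_gain: tuple[float, ...] = (1.0,) * 6

    def __post_init__(self) -> None:
        vals = (self.speed, self.pause, self.turning, self.spurt, self.thigmo,
                *self.startle_gain)
        if any(v <= 0 for v in vals):
            raise ValueError("archetype multipliers must be > 0")
        if len(self.startle_gain) != 6:
            raise ValueError("startle_gain needs one multiplier per peak P1..P6")

    def at_dose(self, dose_level: int) -> "BehaviourArchetype":
        f = dose_level / 3.0
        scale = lambda m: 1.0 + (m - 1.0) * f
        return BehaviourArchetype(
            name=self.name,
            speed=scale(self.speed),
            pause=scale(self.pause),
            turning=scale(self.turning),
            spurt=scale(self.spurt),
            thigmo=scale(self.thigmo),
            startle_gain=tuple(scale(g) for g in self.startle_gain),
        )


#: The four stock archetypes. The AA direction pattern (distance, thigmotaxis
#: and spurting down, turning and pausing up) mirrors the behavioural
#: signature shared by clinically proven antidepressant/anxiolytic drugs in
#: this assay; "other" reverses it and "stressor" mimics an osmotic-stress
#: hyperlocomotion profile.
ARCHETYPES: dict[str, BehaviourArchetype] = {
    "control": BehaviourArchetype("control"),
    "AA": BehaviourArchetype("AA", speed=0.70, pause=1.30, turning=1.40,
                             spurt=0.80, thigmo=0.75),
    "other": BehaviourArchetype("other", speed=1.30, pause=0.75, turning=0.70,
                                spurt=1.20, thigmo=1.25),
    "stressor": BehaviourArchetype("stressor", speed=1.40, pause=0.85,
                                   turning=0.75, spurt=0.80, thigmo=1.20),
}


def _wall_bias(m_thigmo: np.ndarray) -> np.ndarray:
    return np.clip(WALL_SLOPE * m_thigmo - WALL_OFFSET, -0.9, 0.95)


def _peak_epoch_per_frame(schedule: StimulusSchedule, t: np.ndarray) -> np.ndarray:
    """Peak index 0..5 during a startle string's six 10-s epochs, else -1."""
    epoch = np.full(t.size, -1, dtype=np.int8)
    seg = schedule.startle_s / 6.0
    for k in range(1, schedule.n_cycles + 1):
        s0 = schedule.cycle_start(k)
        inside = (t >= s0) & (t < s0 + schedule.startle_s)
        epoch[inside] = np.minimum(((t[inside] - s0) / seg).astype(np.int8), 5)
    return epoch


def _simulate_cohort(
    archetypes: Sequence[BehaviourArchetype],
    schedule: StimulusSchedule,
    geom: WellGeometry,
    rng: np.random.Generator,
    frame_rate: float,
):
    """Vectorised walk for a cohort of fish; returns (t, x, y, heading, step)
    with per-fish rows. ``archetypes`` are already dose-scaled."""
    n = len(archetypes)
    n_frames = int(round(schedule.total_s * frame_rate))
    dt = 1.0 / frame_rate
    t = np.arange(n_frames) * dt

    speed = np.array([a.speed for a in archetypes]) * BASE_SPEED_MM_S
    speed = speed * rng.lognormal(0.0, FISH_SPEED_SD, n)  # fish heterogeneity
    p_pause = np.clip(np.array([a.pause for a in archetypes]) * BASE_PAUSE_P, 0.0, 1.0)
    turn_sd = np.array([a.turning for a in archetypes]) * BASE_TURN_SD_DEG
    spurt_factor = 1.0 + (BASE_SPURT_FACTOR - 1.0) * np.array([a.spurt for a in archetypes])
    bias = _wall_bias(np.array([a.thigmo for a in archetypes]))
    gains = np.array([a.startle_gain for a in archetypes]) * np.asarray(BASE_STARTLE_GAIN)

    epoch = _peak_epoch_per_frame(schedule, t)

    cx = 0.5 * (geom.x_min + geom.x_max)
    cy = 0.5 * (geom.y_min + geom.y_max)
    x = np.empty((n, n_frames), dtype=np.float32)
    y = np.empty((n, n_frames), dtype=np.float32)
    h = np.empty((n, n_frames), dtype=np.float32)
    step = np.zeros((n, n_frames), dtype=np.float32)

    xc = geom.x_min + rng.random(n) * (geom.x_max - geom.x_min)
    yc = geom.y_min + rng.random(n) * (geom.y_max - geom.y_min)
    hc = rng.random(n) * 360.0
    x[:, 0], y[:, 0], h[:, 0] = xc, yc, hc

    pos_strength = np.maximum(bias, 0.0)
    neg_strength = np.maximum(-bias, 0.0)

    for i in range(1, n_frames):
        moving = rng.random(n) >= p_pause
        # heading update: Gaussian wiggle plus drift toward wall or centre
        dh = rng.normal(0.0, 1.0, n) * turn_sd
        dl = xc - geom.x_min
        dr = geom.x_max - xc
        db = yc - geom.y_min
        dtp = geom.y_max - yc
        wall_angle = np.select(
            [dl <= np.minimum(dr, np.minimum(db, dtp)),
             dr <= np.minimum(db, dtp),
             db <= dtp],
            [180.0, 0.0, 270.0],
            default=90.0,
        )
        centre_angle = np.degrees(np.arctan2(cy - yc, cx - xc))
        target = np.where(bias >= 0, wall_angle, centre_angle)
        strength = pos_strength + neg_strength
        delta = (target - hc + 180.0) % 360.0 - 180.0
        dh = dh + strength * delta
        hc = np.where(moving, (hc + dh) % 360.0, hc)

        v = speed * np.exp(rng.normal(0.0, SPEED_NOISE_SD, n) - 0.5 * SPEED_NOISE_SD**2)
        spike = rng.random(n) < BASE_SPURT_P
        v = np.where(spike, v * spurt_factor, v)
        if epoch[i] >= 0:
            v = v * gains[:, epoch[i]]
        d = np.where(moving, v * dt, 0.0)

        xn = xc + d * np.cos(np.radians(hc))
        yn = yc + d * np.sin(np.radians(hc))
        # reflective walls (repeat in case a large spurt overshoots twice)
        for _ in range(3):
            over = xn > geom.x_max
            xn = np.where(over, 2 * geom.x_max - xn, xn)
            hc = np.where(over, (180.0 - hc) % 360.0, hc)
            under = xn < geom.x_min
            xn = np.where(under, 2 * geom.x_min - xn, xn)
            hc = np.where(under, (180.0 - hc) % 360.0, hc)
            over = yn > geom.y_max
            yn = np.where(over, 2 * geom.y_max - yn, yn)
            hc = np.where(over, (-hc) % 360.0, hc)
            under = yn < geom.y_min
            yn = np.where(under, 2 * geom.y_min - yn, yn)
            hc = np.where(under, (-hc) % 360.0, hc)
        xn = np.clip(xn, geom.x_min, geom.x_max)
        yn = np.clip(yn, geom.y_min, geom.y_max)

        xc, yc = xn, yn
        x[:, i], y[:, i], h[:, i] = xc, yc, hc
        step[:, i] = d
    return t, x, y, h, step


def simulate_track(
    archetype: BehaviourArchetype | str,
    dose_level: int,
    schedule: StimulusSchedule,
    geom: WellGeometry,
    seed: int = 0,
    frame_rate: float = 60.0,
    fish_id: str = "F0001",
    plate_id: str = "PL01",
    well_id: str = "A01",
    treatment: str | None = None,
) -> Track:
    """Simulate one fish for the whole schedule (pure function of its
    arguments and the seed)."""
    if isinstance(archetype, str):
        archetype = ARCHETYPES[archetype]
    rng = np.random.default_rng(seed)
    t, x, y, h, step = _simulate_cohort(
        [archetype.at_dose(dose_level)], schedule, geom, rng, frame_rate
    )
    return Track(
        fish_id=fish_id,
        plate_id=plate_id,
        well_id=well_id,
        treatment=treatment if treatment is not None else archetype.name,
        dose_level=int(dose_level),
        dose_value=float(dose_level),
        dose_unit="level",
        frame_rate=frame_rate,
        t=t,
        x=x[0],
        y=y[0],
        heading=h[0],
        step_dist=step[0],
    )


@dataclass
class SyntheticTruth:
    """Planted ground truth of one behaviour plate."""

    fish: pd.DataFrame  # fish_id, treatment, archetype, dose_level


def simulate_plate(
    panel: Mapping[str, tuple[BehaviourArchetype | str, Sequence[int]]],
    n_fish: int | Mapping[str, int],
    schedule: StimulusSchedule,
    geom: WellGeometry,
    seed: int = 0,
    frame_rate: float = 60.0,
    plate_id: str = "PL01",
) -> tuple[list[Track], pd.DataFrame, SyntheticTruth]:
    """Simulate one plate: ``n_fish`` larvae per (drug, dose) arm plus the
    mandatory same-plate control arm.

    ``panel`` maps a treatment name to (archetype, dose levels); a
    ``"control"`` entry (or any arm containing dose level 0) provides the
    zero-dose plate controls required by the normalization. Wells are assigned
    in fish order.
    """
    import warnings

    arms: list[tuple[str, BehaviourArchetype, int, int]] = []
    for drug, (arch, doses) in panel.items():
        arch = ARCHETYPES[arch] if isinstance(arch, str) else arch
        n_arm = int(n_fish[drug]) if isinstance(n_fish, Mapping) else int(n_fish)
        if n_arm == 0:
            warnings.warn(f"arm {drug!r} has 0 fish; omitted", stacklevel=2)
            continue
        if n_arm < 0:
            raise ValueError("n_fish must be >= 0")
        for dose in doses:
            arms.append((drug, arch, int(dose), n_arm))
    if not any(dose == 0 for _, _, dose, _ in arms):
        raise ValueError("panel has no control arm (dose level 0)")

    rng = np.random.default_rng(seed)
    fish_arch: list[BehaviourArchetype] = []
    meta_rows = []
    truth_rows = []
    idx = 0
    for drug, arch, dose, n_arm in arms:
        for _ in range(n_arm):
            idx += 1
            fid = f"{plate_id}_F{idx:04d}"
            fish_arch.append(arch.at_dose(dose))
            meta_rows.append({
                "fish_id": fid, "plate_id": plate_id, "well_id": f"W{idx:03d}",
                "treatment": drug, "dose_level": dose,
                "dose_value": float(dose), "dose_unit": "level",
            })
            truth_rows.append({"fish_id": fid, "treatment": drug,
                               "archetype": arch.name, "dose_level": dose})
    t, x, y, h, step = _simulate_cohort(fish_arch, schedule, geom, rng, frame_rate)
    tracks = []
    for i, row in enumerate(meta_rows):
        tracks.append(Track(
            fish_id=row["fish_id"], plate_id=plate_id, well_id=row["well_id"],
            treatment=row["treatment"], dose_level=row["dose_level"],
            dose_value=row["dose_value"], dose_unit=row["dose_unit"],
            frame_rate=frame_rate, t=t,
            x=x[i], y=y[i], heading=h[i], step_dist=step[i],
        ))
    return tracks, pd.DataFrame(meta_rows), SyntheticTruth(fish=pd.DataFrame(truth_rows))


# ---------------------------------------------------------------------------
# phosphoproteome
# ---------------------------------------------------------------------------

def simulate_phosphoproteome(
    n_entries: int = 500,
    n_true: int = 20,
    effect_fold: float = 4.0,
    missing_rate: float = 0.10,
    seed: int = 0,
    frac_up: float = 0.5,
    n_slices: int = 5,
    dup_fraction: float = 0.2,
    rep_sigma: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal phosphopeptide intensity table (2 genotypes x 3 replicates,
    5 gel slices) with ``n_true`` planted differential entries shifted by
    ``effect_fold`` in the KO genotype (a ``frac_up`` fraction up, the rest
    down), missingness completely at random, and a ``dup_fraction`` of entries
    split across two slices to exercise the merge step.

    Returns (table, truth); truth has one row per unique entry with its
    planted direction.
    """
    if n_true > n_entries:
        raise ValueError("n_true must be <= n_entries")
    if effect_fold <= 1.0:
        raise ValueError("effect_fold must be > 1")
    rng = np.random.default_rng(seed)
    base = rng.normal(14.0, 1.0, n_entries)  # log-intensity per entry
    true_idx = rng.choice(n_entries, size=n_true, replace=False)
    up = np.zeros(n_entries, dtype=bool)
    n_up = int(round(frac_up * n_true))
    up[true_idx[:n_up]] = True
    is_true = np.zeros(n_entries, dtype=bool)
    is_true[true_idx] = True

    shift = np.zeros(n_entries)
    shift[is_true & up] = np.log(effect_fold)
    shift[is_true & ~up] = -np.log(effect_fold)

    wt = np.exp(base[:, None] + rng.normal(0.0, rep_sigma, (n_entries, 3)))
    ko = np.exp(base[:, None] + shift[:, None] + rng.normal(0.0, rep_sigma, (n_entries, 3)))

    rows = []
    slices = rng.integers(1, n_slices + 1, n_entries)
    dup = rng.random(n_entries) < dup_fraction
    for i in range(n_entries):
        key = {
            "sequence": f"PEPTIDE{i:05d}K",
            "protein": f"P{i:05d}",
            "site_positions": str(int(rng.integers(1, 200))),
            "n_sites": 1,
        }
        if dup[i]:
            frac = 0.3 + 0.4 * rng.random()
            other = int(slices[i] % n_slices + 1)
            for sl, f in ((int(slices[i]), frac), (other, 1.0 - frac)):
                rows.append({**key, "slice": sl,
                             **{c: f * wt[i, j] for j, c in enumerate(WT_COLS)},
                             **{c: f * ko[i, j] for j, c in enumerate(KO_COLS)}})
        else:
            rows.append({**key, "slice": int(slices[i]),
                         **{c: wt[i, j] for j, c in enumerate(WT_COLS)},
                         **{c: ko[i, j] for j, c in enumerate(KO_COLS)}})
    table = pd.DataFrame(rows)[TABLE_COLS]
    if missing_rate > 0:
        mask = rng.random((len(table), 6)) < missing_rate
        vals = table[WT_COLS + KO_COLS].to_numpy(dtype=float)
        vals[mask] = np.nan
        table[WT_COLS + KO_COLS] = vals

    truth = pd.DataFrame({
        "sequence": [f"PEPTIDE{i:05d}K" for i in range(n_entries)],
        "protein": [f"P{i:05d}" for i in range(n_entries)],
        "is_true": is_true,
        "direction": np.where(~is_true, "", np.where(up, "up", "down")),
        "effect_fold": np.where(is_true, effect_fold, 1.0),
    })
    return table, truth


# ---------------------------------------------------------------------------
# interaction network
# ---------------------------------------------------------------------------

def simulate_network(
    n_nodes: int = 500,
    mean_degree: float = 50.0,
    n_hubs: int = 5,
    density_boost: float = 3.0,
    diff_size: int = 100,
    seed: int = 0,
    w_max: float = 0.1,
) -> tuple[nx.Graph, list[str], list[str], dict]:
    """Erdos-Renyi background network with planted high-connectivity hubs.

    The differential set contains the ``n_hubs`` planted hubs plus random
    members. Each planted hub is wired to a fixed
    ``round(density_boost * p_edge * |diff_set|)`` distinct differential-set
    neighbours (topping up the background edges), i.e. the boosted expected
    connectivity without extra binomial noise. Edge weights are uniform on
    (0, ``w_max``]. ``density_boost=1`` leaves the planted flags without
    signal.

    Returns (network, universe, diff_set, truth) with
    ``truth = {"hubs": [...], "p_edge": float}``.
    """
    if density_boost < 1.0:
        raise ValueError("density_boost must be >= 1")
    if diff_size < n_hubs or diff_size > n_nodes:
        raise ValueError("need n_hubs <= diff_size <= n_nodes")
    rng = np.random.default_rng(seed)
    nodes = [f"N{i:04d}" for i in range(n_nodes)]
    p_edge = mean_degree / (n_nodes - 1)

    g = nx.fast_gnp_random_graph(n_nodes, p_edge, seed=int(rng.integers(2**31 - 1)))
    net = nx.Graph()
    net.add_nodes_from(nodes)
    for a, b in g.edges():
        net.add_edge(nodes[a], nodes[b], weight=float(rng.uniform(0.0, w_max)) or w_max)

    hubs = [nodes[i] for i in rng.choice(n_nodes, size=n_hubs, replace=False)]
    remaining = [v for v in nodes if v not in hubs]
    extra = list(rng.choice(len(remaining), size=diff_size - n_hubs, replace=False))
    diff_set = sorted(hubs + [remaining[i] for i in extra])

    target = int(round(density_boost * p_edge * (diff_size - 1)))
    for hub in hubs:
        current = [v for v in diff_set if v != hub and net.has_edge(hub, v)]
        need = target - len(current)
        if need > 0:
            candidates = [v for v in diff_set if v != hub and not net.has_edge(hub, v)]
            chosen = rng.choice(len(candidates), size=min(need, len(candidates)),
                                replace=False)
            for j in np.atleast_1d(chosen):
                net.add_edge(hub, candidates[int(j)],
                             weight=float(rng.uniform(0.0, w_max)) or w_max)
    truth = {"hubs": sorted(hubs), "p_edge": p_edge}
    return net, nodes, diff_set, truth
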