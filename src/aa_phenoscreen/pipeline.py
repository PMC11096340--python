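"""End-to-end orchestration of the two analysis arms.

``run_behavior`` executes read -> windows -> features -> plate normalization
-> rank-sum panel -> model training -> paired-control ROC, writing every
intermediate table; ``run_phospho`` executes merge -> missingness filter ->
rank product -> differential set -> hub candidates -> background null ->
significance. Both are deterministic functions of (config, input files): each
output table carries the config hash in a header comment and reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, features, hubs, phospho, stats, tracking

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds and seeds of one pipeline run; round-trips to YAML."""

    # behaviour arm inputs
    tracks: str | None = None
    metadata: str | None = None
    schedule: str | None = None  # YAML; None = default battery
    frame_rate: float = 60.0
    well_mm: float = 8.0
    inner_fraction: float = 0.40
    pause_eps_mm: float = 0.0
    windows: tuple[str, ...] = ("SRB", "PSRB")
    assignment: dict = field(default_factory=dict)  # drug -> AA/other/test
    pairing: dict = field(default_factory=dict)  # test drug -> putative class
    # phospho arm inputs
    phospho_table: str | None = None
    network: str | None = None
    universe: str | None = None
    candidate_filter: str | None = None
    ratio_thresh: float = 2.0
    p_thresh: float = 0.05
    diff_mode: str = "protein"
    k_min: int = 7
    k_high: int = 3
    w_high: float = 0.04
    B_rankprod: int = 1000
    B_hubs: int = 1000
    # seeds
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "windows" in payload:
            payload["windows"] = tuple(payload["windows"])
        return cls(**payload)

    @property
    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d["windows"] = list(d["windows"])
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash}\n")
        df.to_csv(fh, index=False, float_format="%.10g")


class StageError(RuntimeError):
    """An orchestrated stage failed; names the stage and offending unit."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_behavior(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Behaviour arm end to end; returns the written table paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.tracks is None or config.metadata is None:
        raise StageError("stage 'read' failed: tracks/metadata path not set")
    for p in (config.tracks, config.metadata):
        if not Path(p).exists():
            raise StageError(f"stage 'read' failed: missing input file {p}")

    schedule = (tracking.StimulusSchedule.from_yaml(config.schedule)
                if config.schedule else tracking.StimulusSchedule())
    geom = tracking.WellGeometry(0.0, config.well_mm, 0.0, config.well_mm,
                                 config.inner_fraction)
    tracks = _stage("read")(tracking.read_tracks)(config.tracks, config.metadata,
                                                  frame_rate=config.frame_rate)
    windows = [w for w in tracking.battery_windows(schedule)
               if w.label in config.windows]
    feats = _stage("features")(features.feature_table)(
        tracks, windows, geom, eps=config.pause_eps_mm)
    norm = _stage("normalize")(features.normalize_to_controls)(feats)

    paths: dict[str, Path] = {}
    paths["features"] = outdir / "features.csv"
    _write_table(feats, paths["features"], config)
    paths["normalized"] = outdir / "features_normalized.csv"
    _write_table(norm, paths["normalized"], config)

    stats_tables = []
    for label in config.windows:
        tab = _stage("stats")(stats.feature_ranksum_panel)(
            norm, features.FEATURE_NAMES, label)
        tab.insert(0, "window_label", label)
        stats_tables.append(tab)
    paths["stats"] = outdir / "feature_stats.csv"
    _write_table(pd.concat(stats_tables, ignore_index=True), paths["stats"], config)

    assignment = config.assignment or classify.DEFAULT_ASSIGNMENT
    auc_tables = []
    for label in config.windows:
        matrix = _stage("matrix")(classify.build_training_matrix)(
            norm, assignment, window_label=label)
        models = _stage("train")(classify.train_models)(matrix, seed=config.seed)
        acc = pd.DataFrame([
            {"window_label": label, "model": k,
             "training_accuracy": m.training_accuracy, "cv_accuracy": m.cv_accuracy}
            for k, m in models.items()
        ])
        auc_tables.append(("accuracy", acc))
        if len(matrix.test_meta):
            evals = _stage("roc")(classify.evaluate_test_drugs)(
                models, matrix, norm, pairing=config.pairing)
            auc_tables.append(("auc", evals))
    acc_all = pd.concat([t for k, t in auc_tables if k == "accuracy"], ignore_index=True)
    paths["model_accuracy"] = outdir / "model_accuracy.csv"
    _write_table(acc_all, paths["model_accuracy"], config)
    aucs = [t for k, t in auc_tables if k == "auc"]
    if aucs:
        paths["auc_summary"] = outdir / "auc_summary.csv"
        _write_table(pd.concat(aucs, ignore_index=True), paths["auc_summary"], config)
    logger.info("behaviour arm complete: %d tracks, config %s",
                len(tracks), config.config_hash)
    return paths


def run_phospho(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Phosphoproteomics + hub arm end to end; returns written table paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if config.B_rankprod < 100 or config.B_hubs < 1:
        raise StageError("stage 'config' failed: permutation counts too small")
    for name, p in (("phospho_table", config.phospho_table),
                    ("network", config.network), ("universe", config.universe)):
        if p is None or not Path(p).exists():
            raise StageError(f"stage 'read' failed: missing input {name} ({p})")

    entries = _stage("read")(phospho.read_phospho_table)(config.phospho_table)
    net = _stage("read")(hubs.read_network)(config.network)
    universe = [l.strip() for l in Path(config.universe).read_text().splitlines()
                if l.strip()]

    diff = _stage("rankprod")(phospho.run_differential)(
        entries, B=config.B_rankprod, seed=config.seed,
        ratio_thresh=config.ratio_thresh, p_thresh=config.p_thresh,
        mode=config.diff_mode)
    paths: dict[str, Path] = {}
    paths["differential"] = outdir / "differential.csv"
    _write_table(diff.results, paths["differential"], config)
    paths["differential_set"] = outdir / "differential_set.csv"
    _write_table(diff.selected, paths["differential_set"], config)

    pool = None
    if config.candidate_filter:
        pool = [l.strip() for l in Path(config.candidate_filter).read_text().splitlines()
                if l.strip()]
        pool = [p for p in pool if p in set(diff.proteins)]
    if not diff.proteins:
        logger.warning("empty differential set; hub table will be empty")
        hub_table = pd.DataFrame(columns=["candidate", "observed_count",
                                          "high_weight_count", "degree_universe",
                                          "p_hyper", "p_empirical", "p_adj",
                                          "meets_criteria", "selected"])
    else:
        hub_table = _stage("hubs")(hubs.run_hub_analysis)(
            net, diff.proteins, universe, B=config.B_hubs, seed=config.seed,
            k_min=config.k_min, k_high=config.k_high, w_high=config.w_high,
            candidate_pool=pool)
    paths["hubs"] = outdir / "hubs.csv"
    _write_table(hub_table, paths["hubs"], config)
    logger.info("phospho arm complete: %d entries, %d differential, config %s",
                len(entries), len(diff.selected), config.config_hash)
    return paths
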