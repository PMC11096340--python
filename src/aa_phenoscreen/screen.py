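"""A fully synthetic end-to-end screen: the study design in miniature.

``run_synthetic_screen`` simulates a training panel shaped like the published
screen — four AA-archetype training drugs (diazepam, fluoxetine, imipramine,
LiCl stand-ins), two opposite-archetype "other" drugs (ketamine, MK801
stand-ins) and shared plate controls — plus held-out test drugs, extracts and
normalizes the six syllables for the SRB and PSRB windows, trains the three
model kinds and evaluates every test drug with the paired-control ROC scheme.

``null_auc_replicates`` re-scores freshly simulated effect-free plates with
already-trained models, giving the distribution of paired AUC under the null
(no planted drug effect), which should concentrate around 0.5.

Defaults run at reduced problem size (10 frames/s, 60 s acclimation, 600 s
intermission) so a full screen completes in about a minute on one core; the
fish counts (~40 per drug across three dose levels) mirror the published
screen's per-drug numbers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import classify
from .features import FEATURE_NAMES, feature_table, normalize_to_controls
from .simulate import ARCHETYPES, simulate_plate
from .tracking import StimulusSchedule, WellGeometry, battery_windows

TRAIN_PANEL: dict[str, tuple[str, tuple[int, ...]]] = {
    "control": ("control", (0,)),
    "diazepam": ("AA", (1, 2, 3)),
    "fluoxetine": ("AA", (1, 2, 3)),
    "imipramine": ("AA", (1, 2, 3)),
    "licl": ("AA", (1, 2, 3)),
    "ketamine": ("other", (1, 2, 3)),
    "mk801": ("other", (1, 2, 3)),
}


@dataclass
class ScreenResult:
    normalized: pd.DataFrame
    models: dict[str, dict[str, classify.TrainedModel]]  # window -> kind -> model
    accuracy: pd.DataFrame
    auc: pd.DataFrame
    matrices: dict[str, classify.LabelledMatrix]


def run_synthetic_screen(
    seed: int = 0,
    test_drugs: Mapping[str, str] | None = None,
    n_fish_per_dose: int = 13,
    n_control: int = 40,
    frame_rate: float = 10.0,
    acclimation_s: float = 60.0,
    intermission_s: float = 600.0,
    windows: Sequence[str] = ("SRB", "PSRB"),
    null_effects: bool = False,
) -> ScreenResult:
    """Simulate, train and evaluate one complete synthetic screen.

    ``test_drugs`` maps held-out drug names to the archetype they are
    simulated with (e.g. ``{"jnk_inhibitor": "AA"}``); their putative class
    for the ROC pairing is the archetype name. With ``null_effects`` every
    arm is simulated as the control archetype (labels keep their names), so
    any classification signal is spurious.
    """
    test_drugs = dict(test_drugs or {"test_aa": "AA"})
    schedule = StimulusSchedule(acclimation_s=acclimation_s,
                                intermission_s=intermission_s)
    geom = WellGeometry()
    panel: dict[str, tuple[str, tuple[int, ...]]] = dict(TRAIN_PANEL)
    for drug, arch in test_drugs.items():
        if drug in panel:
            raise ValueError(f"test drug {drug!r} collides with a training drug")
        panel[drug] = (arch, (1, 2, 3))
    if null_effects:
        panel = {d: ("control", doses) for d, (a, doses) in panel.items()}
    n_fish = {d: (n_control if doses == (0,) else n_fish_per_dose)
              for d, (a, doses) in panel.items()}

    tracks, meta, truth = simulate_plate(panel, n_fish, schedule, geom,
                                         seed=seed, frame_rate=frame_rate)
    wins = [w for w in battery_windows(schedule) if w.label in windows]
    feats = feature_table(tracks, wins, geom)
    norm = normalize_to_controls(feats)

    assignment = dict(classify.DEFAULT_ASSIGNMENT)
    for drug in test_drugs:
        assignment[drug] = classify.TEST
    pairing = {drug: (classify.AA if arch == "AA" else classify.OTHER)
               for drug, arch in test_drugs.items()}

    models: dict[str, dict[str, classify.TrainedModel]] = {}
    matrices: dict[str, classify.LabelledMatrix] = {}
    acc_rows, auc_tables = [], []
    for label in windows:
        matrix = classify.build_training_matrix(norm, assignment, window_label=label)
        fitted = classify.train_models(matrix, seed=seed)
        models[label] = fitted
        matrices[label] = matrix
        for kind, m in fitted.items():
            acc_rows.append({"window_label": label, "model": kind,
                             "training_accuracy": m.training_accuracy,
                             "cv_accuracy": m.cv_accuracy})
        auc_tables.append(classify.evaluate_test_drugs(fitted, matrix, norm,
                                                       pairing=pairing))
    return ScreenResult(
        normalized=norm,
        models=models,
        accuracy=pd.DataFrame(acc_rows),
        auc=pd.concat(auc_tables, ignore_index=True),
        matrices=matrices,
    )


def null_auc_replicates(
    models: Mapping[str, classify.TrainedModel],
    n_replicates: int = 100,
    seed: int = 0,
    n_fish_per_dose: int = 13,
    n_control: int = 40,
    frame_rate: float = 10.0,
) -> np.ndarray:
    """Paired AUC of an effect-free test drug vs an effect-free paired
    control, scored with already-trained SRB models, one AUC per replicate
    (first model kind in ``models`` is used).

    Every simulated arm uses the control archetype, so the test drug and its
    paired control are exchangeable and the AUC should fall near 0.5.
    """
    model = next(iter(models.values()))
    schedule = StimulusSchedule(acclimation_s=0.0, n_cycles=5,
                                intermission_s=0.0, psrb_s=0.0)
    geom = WellGeometry()
    panel = {
        "control": ("control", (0,)),
        "test_null": ("control", (1, 2, 3)),
        "paired_null": ("control", (1, 2, 3)),
    }
    n_fish = {"control": n_control, "test_null": n_fish_per_dose,
              "paired_null": n_fish_per_dose}
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_replicates)
    for r in range(n_replicates):
        tracks, meta, _ = simulate_plate(panel, n_fish, schedule, geom,
                                         seed=int(rng.integers(2**31 - 1)),
                                         frame_rate=frame_rate)
        wins = [w for w in battery_windows(schedule) if w.label == "SRB"]
        norm = normalize_to_controls(feature_table(tracks, wins, geom))
        sub = norm[norm["dose_level"] > 0]
        s_test = classify.score(model, classify._design(sub[sub["treatment"] == "test_null"]))
        s_ctrl = classify.score(model, classify._design(sub[sub["treatment"] == "paired_null"]))
        roc = classify.paired_roc(s_test, classify.AA, s_ctrl, classify.OTHER)
        aucs[r] = roc.auc
    return aucs
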