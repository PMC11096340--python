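"""AA-vs-other phenotype classification with the paired-control ROC scheme.

Rows of the classifier matrix are fish x cycle observations of the six
normalized behavioural syllables (% change vs same-plate controls) plus the
ordinal dose level; training drugs carry the class label AA (antidepressant/
anxiolytic) or "other". Three model families are fitted per analysis window:

* a penalized (elastic-net) logistic regression,
* a polynomial-kernel SVM,
* a random forest,

each tuned by stratified 5-fold cross-validation grouped by fish (all cycles
of one fish stay in the same fold, avoiding leakage between folds).

A test drug is evaluated with the paired-control ROC scheme: its scored
observations, labelled with the drug's putative class, are pooled with the
observations of a paired control drug of the *opposite* class (ketamine as
negative control for putative-AA drugs; fluoxetine as positive control for
putative-other drugs), and the ROC/AUC of the AA score against those labels
quantifies how well the drug separates from the opposite phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedGroupKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_NAMES

AA = "AA"
OTHER = "other"
TEST = "test"

#: Training-set drug -> class assignment used in the screen: four clinically
#: proven antidepressant/anxiolytic drugs vs the two NMDA-receptor "other"
#: drugs; everything else is a test compound.
DEFAULT_ASSIGNMENT: dict[str, str] = {
    "diazepam": AA,
    "fluoxetine": AA,
    "imipramine": AA,
    "licl": AA,
    "ketamine": OTHER,
    "mk801": OTHER,
}

MODEL_KINDS = ("penalized_glm", "svm_poly", "random_forest")

PCT_FEATURES = [f + "_pct" for f in FEATURE_NAMES]


@dataclass
class LabelledMatrix:
    """Per-window design matrix with labels and fish grouping."""

    window_label: str
    X: pd.DataFrame  # feature columns (+ missingness indicators) + dose_level
    y: np.ndarray  # class labels for training rows ("AA"/"other")
    groups: np.ndarray  # fish ids, for grouped cross-validation
    test_X: pd.DataFrame = field(default_factory=pd.DataFrame)
    test_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)


@dataclass
class TrainedModel:
    model_kind: str
    window_label: str
    estimator: object
    columns: list[str]
    training_accuracy: float  # resubstitution
    cv_accuracy: float  # grouped, stratified 5-fold


@dataclass
class ROCResult:
    test_drug: str
    control_drug: str
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    call: str  # class call: the putative class if AUC >= 0.5 separation holds


def _design(rows: pd.DataFrame) -> pd.DataFrame:
    """Feature columns with NaN imputed to 0% change plus missingness
    indicators (a missing syllable, e.g. spurt of a fully paused fish, is
    informative in itself)."""
    X = rows[PCT_FEATURES + ["dose_level"]].copy()
    for col in PCT_FEATURES:
        miss = X[col].isna()
        X[col + "_missing"] = miss.astype(float)
        X[col] = X[col].fillna(0.0)
    return X


def build_training_matrix(
    normalized: pd.DataFrame,
    assignment: Mapping[str, str] | None = None,
    window_label: str = "SRB",
) -> LabelledMatrix:
    """Assemble the labelled matrix of one window from a normalized feature
    table (rows: fish x cycle; columns as written by
    :func:`aa_phenoscreen.features.normalize_to_controls`).

    ``assignment`` maps lower-cased treatment names to ``"AA"``, ``"other"``
    or ``"test"``; control (dose 0) fish and unassigned treatments are left
    out of training, treatments marked ``"test"`` go to the test partition.
    """
    assignment = {k.lower(): v for k, v in (assignment or DEFAULT_ASSIGNMENT).items()}
    for drug, cls in assignment.items():
        if cls not in (AA, OTHER, TEST):
            raise ValueError(f"bad class {cls!r} for drug {drug!r}")
    sub = normalized[(normalized["window_label"] == window_label)
                     & (normalized["dose_level"] > 0)].copy()
    sub["__cls"] = sub["treatment"].str.lower().map(assignment)
    train = sub[sub["__cls"].isin([AA, OTHER])]
    test = sub[sub["__cls"] == TEST]
    return LabelledMatrix(
        window_label=window_label,
        X=_design(train),
        y=train["__cls"].to_numpy(),
        groups=train["fish_id"].to_numpy(),
        test_X=_design(test),
        test_meta=test[["fish_id", "treatment", "dose_level", "cycle"]].reset_index(drop=True),
    )


def _make_estimators(seed: int) -> dict[str, GridSearchCV]:
    cv = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=seed)
    glm = Pipeline([
        ("scale", StandardScaler()),
        ("clf", LogisticRegression(solver="saga", l1_ratio=0.5,
                                   max_iter=5000, class_weight="balanced")),
    ])
    svm = Pipeline([
        ("scale", StandardScaler()),
        ("clf", SVC(kernel="poly", degree=3, class_weight="balanced")),
    ])
    rf = RandomForestClassifier(n_estimators=300, class_weight="balanced",
                                random_state=seed, n_jobs=1)
    return {
        "penalized_glm": GridSearchCV(glm, {"clf__C": [0.01, 0.1, 1.0, 10.0]}, cv=cv),
        "svm_poly": GridSearchCV(svm, {"clf__C": [0.1, 1.0, 10.0]}, cv=cv),
        "random_forest": GridSearchCV(rf, {"min_samples_leaf": [1, 5]}, cv=cv),
    }


def train_models(matrix: LabelledMatrix, seed: int = 0) -> dict[str, TrainedModel]:
    """Fit the three model kinds on one window's matrix.

    Hyperparameters are chosen by grouped stratified cross-validation; both
    the resubstitution training accuracy and the grouped CV accuracy of the
    selected configuration are recorded.
    """
    classes = np.unique(matrix.y)
    if classes.size < 2:
        raise ValueError(f"training matrix has a single class: {classes}")
    X = matrix.X.to_numpy(dtype=float)
    y = (matrix.y == AA).astype(int)  # AA = positive class
    models: dict[str, TrainedModel] = {}
    for kind, gs in _make_estimators(seed).items():
        gs.fit(X, y, groups=matrix.groups)
        est = gs.best_estimator_
        cv = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=seed)
        cv_acc = float(np.mean(cross_val_score(est, X, y, groups=matrix.groups, cv=cv)))
        models[kind] = TrainedModel(
            model_kind=kind,
            window_label=matrix.window_label,
            estimator=est,
            columns=matrix.columns,
            training_accuracy=float(est.score(X, y)),
            cv_accuracy=cv_acc,
        )
    return models


def score(model: TrainedModel, rows: pd.DataFrame) -> np.ndarray:
    """Continuous AA score per row (higher = more AA-like).

    Probabilistic models return P(AA); the SVM's decision value is mapped
    through a logistic link so all scores live on (0, 1).
    """
    if list(rows.columns) != model.columns:
        raise ValueError(
            f"column mismatch: expected {model.columns}, got {list(rows.columns)}"
        )
    X = rows.to_numpy(dtype=float)
    est = model.estimator
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, 1]
    return expit(est.decision_function(X))


def paired_roc(
    test_scores: Sequence[float],
    putative_class: str,
    control_scores: Sequence[float],
    control_class: str,
    test_drug: str = "test",
    control_drug: str = "control",
) -> ROCResult:
    """ROC of the AA score over the pooled test-drug + paired-control
    observations, the test drug labelled with its putative class and the
    control with the opposite class."""
    if putative_class == control_class:
        raise ValueError("test drug and paired control must carry opposite classes")
    if putative_class not in (AA, OTHER) or control_class not in (AA, OTHER):
        raise ValueError("classes must be 'AA' or 'other'")
    test_scores = np.asarray(test_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    scores = np.concatenate([test_scores, control_scores])
    # ROC is computed on the AA score vs the AA/other labels
    labels = np.concatenate([
        np.full(test_scores.size, putative_class == AA, dtype=int),
        np.full(control_scores.size, control_class == AA, dtype=int),
    ])
    fpr, tpr, _ = roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    call = putative_class if auc >= 0.5 else control_class
    return ROCResult(test_drug, control_drug, fpr, tpr, auc, call)


def auc_rank_statistic(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney concordance of positive vs negative scores."""
    pos = np.asarray(pos_scores, dtype=float)[:, None]
    neg = np.asarray(neg_scores, dtype=float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size))


def evaluate_test_drugs(
    models: Mapping[str, TrainedModel],
    matrix: LabelledMatrix,
    normalized: pd.DataFrame,
    pairing: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Paired-control AUC of every test drug under every model of one window.

    ``pairing`` maps each test drug (lower case) to ``(putative_class)``;
    putative-AA drugs are paired with ketamine (labelled other), putative-
    other drugs with fluoxetine (labelled AA). Control-drug observations are
    taken from the training partition.
    """
    pairing = {k.lower(): v for k, v in (pairing or {}).items()}
    sub = normalized[(normalized["window_label"] == matrix.window_label)
                     & (normalized["dose_level"] > 0)]
    rows = []
    for drug in sorted(matrix.test_meta["treatment"].str.lower().unique()):
        putative = pairing.get(drug, AA)
        ctrl_drug = "ketamine" if putative == AA else "fluoxetine"
        ctrl_rows = sub[sub["treatment"].str.lower() == ctrl_drug]
        if not len(ctrl_rows):
            raise ValueError(f"paired control drug {ctrl_drug!r} absent from data")
        mask = matrix.test_meta["treatment"].str.lower() == drug
        for kind, model in models.items():
            s_test = score(model, matrix.test_X[mask.to_numpy()])
            s_ctrl = score(model, _design(ctrl_rows))
            roc = paired_roc(s_test, putative, s_ctrl,
                             OTHER if putative == AA else AA,
                             test_drug=drug, control_drug=ctrl_drug)
            rows.append({"test_drug": drug, "control_drug": ctrl_drug,
                         "model": kind, "window_label": matrix.window_label,
                         "putative_class": putative, "auc": roc.auc,
                         "call": roc.call, "n_test": int(mask.sum())})
    return pd.DataFrame(rows)
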