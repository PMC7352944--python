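"""Classifier training on synthetic cohorts and validation on real data.

Four classifier families are supported, mirroring the caret-style model
zoo used for small-n omics panels:

* ``NN`` — single-hidden-layer neural network, grid over hidden sizes
  {1, 3, 5} x weight decay {0.001, 0.01, 0.1};
* ``BGLM`` — Bayesian-flavoured logistic regression: weakly-informative
  shrinkage priors realized as fixed ridge regularization (no grid);
* ``C5TREE`` — an information-gain decision tree with a cost-complexity
  pruning grid (the defining elements of the C5.0 family);
* ``RF`` — random forest, paired only with RF-derived feature panels (it
  serves as the reference algorithm for its own selection route).

Hyperparameters are tuned by stratified k-fold cross-validation on the
training cohort maximizing AUC; inputs are z-scored by training moments
and the same standardization is applied at prediction time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .containers import CohortLabels, FeatureTable
from .select import FeaturePanel, mann_whitney_auc

__all__ = [
    "TuningConfig",
    "TrainedModel",
    "EvalResult",
    "ComboResult",
    "train_model",
    "predict_scores",
    "evaluate_classifier",
    "select_best_combo",
]

ALGORITHMS = ("NN", "BGLM", "C5TREE", "RF")


@dataclass
class TuningConfig:
    cv_folds: int = 3
    nn_hidden: tuple[int, ...] = (1, 3, 5)
    nn_decay: tuple[float, ...] = (0.001, 0.01, 0.1)
    nn_max_iter: int = 300
    tree_ccp_alpha: tuple[float, ...] = (0.0, 0.001, 0.01)
    rf_n_trees: tuple[int, ...] = (100,)
    rf_max_features: tuple = ("sqrt", 1.0)


@dataclass
class TrainedModel:
    algorithm: str
    panel: FeaturePanel
    positive_label: str
    negative_label: str
    center: np.ndarray
    scale: np.ndarray
    estimator: object                    # fitted sklearn-like estimator
    tuning_trace: list[tuple[dict, float]] = field(default_factory=list)
    best_params: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class EvalResult:
    auc: float
    roc: pd.DataFrame                    # threshold, fpr, tpr
    threshold: float
    sensitivity: float
    specificity: float
    confusion: dict                      # tp, fp, tn, fn at the threshold


@dataclass
class ComboResult:
    panel: FeaturePanel
    algorithm: str
    evaluation: EvalResult
    rank: int | None = None


def _grid(algorithm: str, cfg: TuningConfig) -> list[dict]:
    if algorithm == "NN":
        return [{"hidden": h, "decay": d} for h in cfg.nn_hidden for d in cfg.nn_decay]
    if algorithm == "BGLM":
        return [{}]
    if algorithm == "C5TREE":
        return [{"ccp_alpha": a} for a in cfg.tree_ccp_alpha]
    if algorithm == "RF":
        return [{"n_trees": t, "max_features": m}
                for t in cfg.rf_n_trees for m in cfg.rf_max_features]
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


def _build(algorithm: str, params: dict, cfg: TuningConfig, seed: int):
    if algorithm == "NN":
        return MLPClassifier(hidden_layer_sizes=(params["hidden"],),
                             alpha=params["decay"], solver="lbfgs",
                             max_iter=cfg.nn_max_iter, random_state=seed)
    if algorithm == "BGLM":
        # fixed ridge penalty standing in for weakly-informative priors
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
    if algorithm == "C5TREE":
        return DecisionTreeClassifier(criterion="entropy",
                                      ccp_alpha=params["ccp_alpha"],
                                      random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=params["n_trees"],
                                      max_features=params["max_features"],
                                      random_state=seed)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train_model(train_table: FeatureTable, train_labels: CohortLabels,
                panel: FeaturePanel, algorithm: str,
                positive_label: str, tuning: TuningConfig | None = None,
                seed: int = 0) -> TrainedModel:
    """Tune and fit one algorithm on one panel.

    The RF algorithm is accepted only with RF-sourced panels: it enters
    the comparison as the reference for its own selection route, not as a
    general-purpose learner for the other panels.
    """
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if algorithm == "RF" and panel.method != "RF":
        raise ValueError("the RF algorithm is only paired with RF-derived panels")
    tuning = tuning or TuningConfig()
    labels = train_labels.align_to(train_table)
    groups = labels.groups
    if len(groups) != 2:
        raise ValueError("binary labels required for training")
    if positive_label not in groups:
        raise ValueError(f"positive label {positive_label!r} not in groups {groups}")
    negative = next(g for g in groups if g != positive_label)

    sub = train_table.subset(panel.features)
    x = sub.values.astype(float)
    y = (labels.series.to_numpy() == positive_label).astype(int)
    center = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)
    xz = (x - center) / scale

    grid = _grid(algorithm, tuning)
    trace: list[tuple[dict, float]] = []
    with warnings.catch_warnings():
        # small lbfgs networks legitimately stop at max_iter; tuning is by
        # cross-validated AUC, not by the optimizer's own stopping flag
        warnings.simplefilter("ignore", ConvergenceWarning)
        if len(grid) == 1:
            best_params = grid[0]
        else:
            skf = StratifiedKFold(n_splits=tuning.cv_folds, shuffle=True,
                                  random_state=seed)
            folds = list(skf.split(xz, y))
            best_params, best_score = None, -np.inf
            for params in grid:
                scores = []
                for tr, te in folds:
                    est = _build(algorithm, params, tuning, seed)
                    est.fit(xz[tr], y[tr])
                    prob = est.predict_proba(xz[te])[:, list(est.classes_).index(1)]
                    scores.append(mann_whitney_auc(prob, y[te].astype(bool)))
                mean_auc = float(np.mean(scores))
                trace.append((params, mean_auc))
                if mean_auc > best_score:  # ties keep the earlier grid entry
                    best_params, best_score = params, mean_auc
        est = _build(algorithm, best_params, tuning, seed)
        est.fit(xz, y)
    return TrainedModel(algorithm=algorithm, panel=panel,
                        positive_label=positive_label, negative_label=negative,
                        center=center, scale=scale, estimator=est,
                        tuning_trace=trace, best_params=best_params, seed=seed)


def predict_scores(model: TrainedModel, table: FeatureTable) -> pd.Series:
    """Probability of the positive class per sample; errors if any panel
    feature is absent, and ignores all columns outside the panel."""
    missing = [f for f in model.panel.features if f not in table.data.columns]
    if missing:
        raise KeyError(f"panel features missing from table: {missing}")
    x = table.data.loc[:, model.panel.features].to_numpy().astype(float)
    xz = (x - model.center) / model.scale
    prob = model.estimator.predict_proba(xz)
    idx = list(model.estimator.classes_).index(1)
    return pd.Series(prob[:, idx], index=table.sample_ids, name="score")


def evaluate_classifier(scores: pd.Series | np.ndarray, labels: CohortLabels | np.ndarray,
                        positive_label: str | None = None) -> EvalResult:
    """ROC-based evaluation of continuous scores against binary labels.

    AUC is the normalized Mann–Whitney U with midrank tie handling
    (identical to the trapezoidal ROC area).  The operating threshold
    maximizes Youden's J = sensitivity + specificity - 1; ties prefer
    higher specificity, then the higher threshold.
    """
    s = np.asarray(scores, dtype=float)
    if isinstance(labels, CohortLabels):
        lab = labels.series.to_numpy()
    else:
        lab = np.asarray(labels)
    classes = pd.unique(lab)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if positive_label is None:
        positive_label = classes[1]
    pos = lab == positive_label
    n1, n0 = int(pos.sum()), int((~pos).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")

    auc = mann_whitney_auc(s, pos)

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    tpr = np.array([(s[pos] >= t).mean() for t in thresholds])
    fpr = np.array([(s[~pos] >= t).mean() for t in thresholds])
    roc = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})

    j = tpr - fpr
    best = 0
    for i in range(1, thresholds.size):
        if (j[i] > j[best]
                or (j[i] == j[best] and fpr[i] < fpr[best])
                or (j[i] == j[best] and fpr[i] == fpr[best]
                    and thresholds[i] > thresholds[best])):
            best = i
    t = float(thresholds[best])
    pred = s >= t
    tp = int(np.sum(pred & pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    tn = int(np.sum(~pred & ~pos))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return EvalResult(auc=float(auc), roc=roc, threshold=t, sensitivity=sens,
                      specificity=spec,
                      confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn})


def select_best_combo(combos: list[ComboResult]) -> ComboResult:
    """Highest validation AUC; ties broken by fewer panel features, then
    higher sensitivity, then lexicographic algorithm name."""
    if not combos:
        raise ValueError("no combos to select from")
    key = lambda c: (-c.evaluation.auc, c.panel.size, -c.evaluation.sensitivity,
                     c.algorithm)
    ordered = sorted(combos, key=key)
    for i, c in enumerate(ordered):
        c.rank = i + 1
    return ordered[0]
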