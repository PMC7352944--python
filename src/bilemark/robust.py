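"""Five permutation tests probing the robustness of a selected model.

All five share the same AUC evaluator as the training module and the
add-one p-value convention p = (b + 1) / (n_perm + 1):

1. **Label permutation** — shuffle the validation labels against the
   model's (fixed) scores: the chance of matching the observed AUC by
   random labelling.  The model is *not* refit; pipeline-level
   overfitting is test 5's job.
2. **Single-variable noise** — permute one panel feature's column across
   the cohort and re-apply the model: small p means performance depends
   on that feature's true values (a measurement error there would hurt).
3. **All-variable noise** — permute every panel feature independently:
   the background/noise prediction level of the fitted model.
4. **Single-variable signal** — keep one feature intact and permute all
   the others: can that feature alone, amid noise, carry the prediction?
   Large p here is the expected outcome when the panel works as a whole.
5. **Overfit check** — shuffle the real labels, then re-run the entire
   pipeline (moments -> synthetic data -> selection -> training) on the
   shuffled cohort and validate on it: compares the real pipeline's AUC
   against the distribution achievable from unstructured data, exposing
   any tendency of moment-based augmentation to manufacture signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .containers import CohortLabels, FeatureTable
from .learn import TrainedModel, predict_scores
from .select import mann_whitney_auc

__all__ = [
    "RobustnessReport",
    "test1_label_permutation",
    "test2_variable_noise",
    "test3_all_noise",
    "test4_single_variable_signal",
    "test5_overfit_check",
    "run_robustness",
]


def _observed_auc(model: TrainedModel, table: FeatureTable,
                  labels: CohortLabels) -> tuple[np.ndarray, np.ndarray, float]:
    labels = labels.align_to(table)
    scores = predict_scores(model, table).to_numpy()
    pos = labels.series.to_numpy() == model.positive_label
    return scores, pos, mann_whitney_auc(scores, pos)


def test1_label_permutation(model: TrainedModel, table: FeatureTable,
                            labels: CohortLabels, n_perm: int = 999,
                            seed: int = 0) -> float:
    """p-value of the observed AUC under random relabelling of the
    validation samples (scores stay fixed)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    scores, pos, observed = _observed_auc(model, table, labels)
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        if mann_whitney_auc(scores, rng.permutation(pos)) >= observed:
            b += 1
    return (b + 1) / (n_perm + 1)


def _column_permutation_test(model: TrainedModel, table: FeatureTable,
                             labels: CohortLabels, permute: list[str],
                             n_perm: int, seed: int) -> float:
    """Shared engine for tests 2-4: permute the given panel columns each
    round (independently, in panel order) and re-apply the model."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = labels.align_to(table)
    _, pos, observed = _observed_auc(model, table, labels)
    rng = np.random.default_rng(seed)
    work = table.data.copy()
    b = 0
    n = table.n_samples
    for _ in range(n_perm):
        for feat in permute:
            work[feat] = table.data[feat].to_numpy()[rng.permutation(n)]
        scores = predict_scores(model, FeatureTable(work, kind=table.kind)).to_numpy()
        if mann_whitney_auc(scores, pos) >= observed:
            b += 1
        for feat in permute:  # restore for the next round
            work[feat] = table.data[feat]
    return (b + 1) / (n_perm + 1)


def test2_variable_noise(model: TrainedModel, table: FeatureTable,
                         labels: CohortLabels, feature: str,
                         n_perm: int = 999, seed: int = 0) -> float:
    if feature not in model.panel.features:
        raise ValueError(f"feature {feature!r} is not in the model's panel")
    return _column_permutation_test(model, table, labels, [feature], n_perm, seed)


def test3_all_noise(model: TrainedModel, table: FeatureTable,
                    labels: CohortLabels, n_perm: int = 999, seed: int = 0) -> float:
    return _column_permutation_test(model, table, labels,
                                    list(model.panel.features), n_perm, seed)


def test4_single_variable_signal(model: TrainedModel, table: FeatureTable,
                                 labels: CohortLabels, feature: str,
                                 n_perm: int = 999, seed: int = 0) -> float:
    if feature not in model.panel.features:
        raise ValueError(f"feature {feature!r} is not in the model's panel")
    if model.panel.size < 2:
        raise ValueError("test 4 is undefined for a single-feature panel")
    others = [f for f in model.panel.features if f != feature]
    return _column_permutation_test(model, table, labels, others, n_perm, seed)


def test5_overfit_check(fit_pipeline: Callable[[FeatureTable, CohortLabels, int], float],
                        table: FeatureTable, labels: CohortLabels,
                        real_auc: float, n_shuffles: int = 49,
                        seed: int = 0) -> tuple[float, np.ndarray, float]:
    """Label-shuffled pipeline re-runs.

    ``fit_pipeline(table, labels, seed) -> validation AUC`` must re-run
    the configured pipeline end to end (moment estimation, synthetic
    generation, feature selection, training, validation).  Returns the
    real AUC, the sample of shuffled-pipeline AUCs and the add-one p.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    labels = labels.align_to(table)
    rng = np.random.default_rng(seed)
    shuffled_aucs = np.empty(n_shuffles)
    lab = labels.series.to_numpy()
    for i in range(n_shuffles):
        perm = pd.Series(lab[rng.permutation(lab.size)], index=labels.series.index)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        shuffled_aucs[i] = fit_pipeline(table, CohortLabels(perm), sub_seed)
    p = (int(np.count_nonzero(shuffled_aucs >= real_auc)) + 1) / (n_shuffles + 1)
    return real_auc, shuffled_aucs, p


@dataclass
class RobustnessReport:
    observed_auc: float
    test1_p: float
    test2_p: pd.Series                   # per panel feature
    test3_p: float
    test4_p: pd.Series | None            # None for single-feature panels
    test5_real_auc: float | None = None
    test5_shuffled_aucs: np.ndarray | None = None
    test5_p: float | None = None
    n_perm: int = 999
    n_shuffles: int | None = None
    seeds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("test1_label_permutation", "", self.test1_p)]
        rows += [("test2_variable_noise", f, p) for f, p in self.test2_p.items()]
        rows.append(("test3_all_noise", "", self.test3_p))
        if self.test4_p is not None:
            rows += [("test4_single_variable_signal", f, p)
                     for f, p in self.test4_p.items()]
        if self.test5_p is not None:
            rows.append(("test5_overfit_check", "", self.test5_p))
        return pd.DataFrame(rows, columns=["test", "feature", "p_value"])


def run_robustness(model: TrainedModel, table: FeatureTable, labels: CohortLabels,
                   n_perm: int = 999, seed: int = 0,
                   fit_pipeline: Callable[[FeatureTable, CohortLabels, int], float] | None = None,
                   n_shuffles: int = 49) -> RobustnessReport:
    """Run tests 1-4 (and 5 when a pipeline refitter is supplied) with
    independent sub-seeds derived from ``seed``."""
    ss = np.random.SeedSequence(seed)

    def sub() -> int:
        return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))

    seeds = {"test1": sub()}
    _, _, observed = _observed_auc(model, table, labels)
    t1 = test1_label_permutation(model, table, labels, n_perm, seeds["test1"])

    t2 = {}
    for f in model.panel.features:
        seeds[f"test2:{f}"] = sub()
        t2[f] = test2_variable_noise(model, table, labels, f, n_perm,
                                     seeds[f"test2:{f}"])
    seeds["test3"] = sub()
    t3 = test3_all_noise(model, table, labels, n_perm, seeds["test3"])

    t4 = None
    if model.panel.size >= 2:
        t4 = {}
        for f in model.panel.features:
            seeds[f"test4:{f}"] = sub()
            t4[f] = test4_single_variable_signal(model, table, labels, f, n_perm,
                                                 seeds[f"test4:{f}"])

    t5_real = t5_sample = t5_p = None
    if fit_pipeline is not None:
        seeds["test5"] = sub()
        t5_real, t5_sample, t5_p = test5_overfit_check(
            fit_pipeline, table, labels, observed, n_shuffles, seeds["test5"])

    return RobustnessReport(
        observed_auc=float(observed), test1_p=t1,
        test2_p=pd.Series(t2), test3_p=t3,
        test4_p=pd.Series(t4) if t4 is not None else None,
        test5_real_auc=t5_real, test5_shuffled_aucs=t5_sample, test5_p=t5_p,
        n_perm=n_perm, n_shuffles=n_shuffles if fit_pipeline is not None else None,
        seeds=seeds,
    )
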