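"""End-to-end biomarker-panel pipeline as a fit/results object pair.

:class:`StricturePipeline` is built from a real (or fixture) two-group
feature table plus labels; :meth:`StricturePipeline.fit` executes the
full flow —

    impute -> PCA/DAPC overview of the real data -> per-group moments
    -> synthetic cohort -> DAPC / RF / AUC rankings on synthetic data
    -> nested candidate panels (3-10 features)
    -> NN / BGLM / C5TREE training on every panel (+ RF on RF panels)
    -> validation on the real table -> best-combo selection
    -> permutation robustness tests on the winner

— and returns a :class:`PipelineResult` carrying the leaderboard, the
winning combination, the fitted model and the robustness report.  The
validation set is the real table itself: moment estimation and
validation deliberately share those samples, which reproduces the
train-on-synthetic / validate-on-real design (and its leakage) rather
than hiding it; test 5 of the robustness suite is the dedicated check on
that design.

Reruns with the same configuration and seed are bitwise reproducible:
every stochastic step derives its own sub-seed from the master seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import augment, learn, prep, robust, select
from .containers import CohortLabels, FeatureTable

__all__ = ["PipelineConfig", "StricturePipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    impute_k: int = 5
    synth_n_per_group: int = 500
    synth_mode: str | None = None        # default: follow the input table's kind
    selection_methods: tuple[str, ...] = ("DAPC", "RF", "AUC")
    k_min: int = 3
    k_max: int = 10
    dapc_threshold: float = 0.02
    dapc_var_threshold: float = 0.90
    rf_trees: int = 200
    rf_perm_repeats: int = 5
    algorithms: tuple[str, ...] = ("NN", "BGLM", "C5TREE")
    include_rf_algorithm: bool = True
    tuning: learn.TuningConfig = field(default_factory=learn.TuningConfig)
    n_perm: int = 999
    n_shuffles: int = 49
    run_test5: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["selection_methods"] = list(self.selection_methods)
        d["algorithms"] = list(self.algorithms)
        return d


def _subseeds(master: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


@dataclass
class PipelineResult:
    config: PipelineConfig
    pca_explained: np.ndarray
    real_dapc: select.DapcModel
    real_dapc_selected: select.FeatureRanking
    moments: augment.GroupMoments
    rankings: dict[str, select.FeatureRanking]
    leaderboard: pd.DataFrame
    best: learn.ComboResult
    best_model: learn.TrainedModel
    robustness: robust.RobustnessReport | None
    positive_label: str
    reference_label: str

    def summary(self) -> str:
        e = self.best.evaluation
        lines = [
            "StricturePipeline results",
            "=" * 60,
            f"groups                 {self.reference_label} (ref) vs "
            f"{self.positive_label} (positive)",
            f"synthetic cohort       {self.config.synth_n_per_group} per group, "
            f"seed {self.config.seed}",
            f"combos evaluated       {len(self.leaderboard)}",
            f"best combination       {self.best.panel.method} panel "
            f"(k={self.best.panel.size}) x {self.best.algorithm}",
            f"validation AUC         {e.auc:.3f}",
            f"sensitivity            {100 * e.sensitivity:.1f}%",
            f"specificity            {100 * e.specificity:.1f}%",
        ]
        if self.robustness is not None:
            r = self.robustness
            lines += [
                f"test 1 (labels)        p = {r.test1_p:.4g}",
                f"test 2 (per feature)   min p = {r.test2_p.min():.4g}, "
                f"max p = {r.test2_p.max():.4g}",
                f"test 3 (all noise)     p = {r.test3_p:.4g}",
            ]
            if r.test4_p is not None:
                lines.append(f"test 4 (single signal) min p = {r.test4_p.min():.4g}, "
                             f"max p = {r.test4_p.max():.4g}")
            if r.test5_p is not None:
                lines.append(f"test 5 (overfit)       p = {r.test5_p:.4g}")
        lines.append("=" * 60)
        return "\n".join(lines)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "config.json").write_text(json.dumps(self.config.to_dict(), indent=2))
        self.leaderboard.to_csv(outdir / "leaderboard.tsv", sep="\t", index=False)
        best = {
            "method": self.best.panel.method,
            "panel": self.best.panel.features,
            "algorithm": self.best.algorithm,
            "auc": self.best.evaluation.auc,
            "sensitivity": self.best.evaluation.sensitivity,
            "specificity": self.best.evaluation.specificity,
            "threshold": self.best.evaluation.threshold,
        }
        (outdir / "best_combo.json").write_text(json.dumps(best, indent=2))
        self.best.evaluation.roc.to_csv(outdir / "best_roc.tsv", sep="\t", index=False)
        for method, ranking in self.rankings.items():
            ranking.to_frame().to_csv(outdir / f"ranking_{method.lower()}.tsv",
                                      sep="\t", index=False)
        if self.robustness is not None:
            self.robustness.to_frame().to_csv(outdir / "robustness.tsv", sep="\t",
                                              index=False)
        (outdir / "summary.txt").write_text(self.summary() + "\n")


class StricturePipeline:
    """The full benign-vs-malignant discrimination pipeline.

    Parameters
    ----------
    table, labels
        The real (or fixture) cohort.  Exactly two groups; the first
        group in label order is the reference (benign) class and the
        second is the positive (malignant) class.
    config
        Pipeline settings; see :class:`PipelineConfig`.
    validation_table, validation_labels
        Optional held-out cohort.  By default the pipeline validates on
        ``table`` itself (the train-on-synthetic / validate-on-real
        design, leakage included); supplying an independent cohort gives
        the clean held-out variant used for null-calibration checks.
    """

    def __init__(self, table: FeatureTable, labels: CohortLabels,
                 config: PipelineConfig | None = None,
                 validation_table: FeatureTable | None = None,
                 validation_labels: CohortLabels | None = None):
        self.config = config or PipelineConfig()
        self.labels = labels.align_to(table)  # errors early on id mismatch
        groups = self.labels.groups
        if len(groups) != 2:
            raise ValueError("the pipeline requires exactly two groups")
        self.labels.require_groups(min_groups=2, min_per_group=2)
        self.table = table
        self.reference_label, self.positive_label = groups
        if (validation_table is None) != (validation_labels is None):
            raise ValueError("provide both validation table and labels, or neither")
        self.validation_table = validation_table
        self.validation_labels = (validation_labels.align_to(validation_table)
                                  if validation_table is not None else None)
        if self.validation_labels is not None and set(
                self.validation_labels.groups) != set(groups):
            raise ValueError("validation labels must use the same two groups")

    @classmethod
    def from_files(cls, table_path, labels_path, kind: str = "decimal",
                   config: PipelineConfig | None = None) -> "StricturePipeline":
        return cls(FeatureTable.read(table_path, kind=kind),
                   CohortLabels.read(labels_path), config)

    # -- internal stages ----------------------------------------------------
    def _rankings(self, synth: augment.SyntheticCohort,
                  seeds: list[int]) -> dict[str, select.FeatureRanking]:
        cfg = self.config
        out: dict[str, select.FeatureRanking] = {}
        for method in cfg.selection_methods:
            if method == "DAPC":
                model = select.fit_dapc(synth.table, synth.labels,
                                        var_threshold=cfg.dapc_var_threshold)
                out[method] = select.dapc_rank(model)
            elif method == "RF":
                out[method] = select.rf_importance(synth.table, synth.labels,
                                                   n_trees=cfg.rf_trees,
                                                   seed=seeds[1],
                                                   n_repeats=cfg.rf_perm_repeats)
            elif method == "AUC":
                out[method] = select.auc_rank(synth.table, synth.labels)
            else:
                raise ValueError(f"unknown selection method {method!r}")
        return out

    def _train_and_validate(self, synth: augment.SyntheticCohort,
                            rankings: dict[str, select.FeatureRanking],
                            val_table: FeatureTable, val_labels: CohortLabels,
                            seeds: list[int]) -> tuple[pd.DataFrame, list[learn.ComboResult], list[learn.TrainedModel]]:
        cfg = self.config
        combos: list[learn.ComboResult] = []
        models: list[learn.TrainedModel] = []
        rows = []
        seed_iter = iter(_subseeds(seeds[2], 10_000))
        for method, ranking in rankings.items():
            panels = select.candidate_panels(ranking, cfg.k_min, cfg.k_max)
            algos = list(cfg.algorithms)
            if cfg.include_rf_algorithm and method == "RF":
                algos = algos + ["RF"]
            for panel in panels:
                for algo in algos:
                    model = learn.train_model(synth.table, synth.labels, panel,
                                              algo, self.positive_label,
                                              tuning=cfg.tuning,
                                              seed=next(seed_iter))
                    scores = learn.predict_scores(model, val_table)
                    ev = learn.evaluate_classifier(scores, val_labels,
                                                   self.positive_label)
                    combos.append(learn.ComboResult(panel=panel, algorithm=algo,
                                                    evaluation=ev))
                    models.append(model)
                    rows.append({"method": method, "panel_size": panel.size,
                                 "algorithm": algo, "auc": ev.auc,
                                 "sensitivity": ev.sensitivity,
                                 "specificity": ev.specificity,
                                 "panel": ",".join(panel.features)})
        leaderboard = pd.DataFrame(rows)
        return leaderboard, combos, models

    def _refit_auc(self, method: str, algorithm: str, panel_size: int):
        """Closure for robustness test 5: full pipeline re-run (moments,
        synthetic data, selection with the winning route, training) under
        shuffled labels, validated on the same (shuffled-label) table."""
        cfg = self.config

        def fit(table: FeatureTable, labels: CohortLabels, seed: int) -> float:
            sub = _subseeds(seed, 4)
            complete = prep.impute_missing(table, k=cfg.impute_k)
            moments = augment.estimate_moments(complete, labels)
            mode = cfg.synth_mode or table.kind
            synth = augment.generate_synthetic(moments, cfg.synth_n_per_group,
                                               mode=mode, seed=sub[0])
            if method == "DAPC":
                ranking = select.dapc_rank(select.fit_dapc(
                    synth.table, synth.labels, var_threshold=cfg.dapc_var_threshold))
            elif method == "RF":
                ranking = select.rf_importance(synth.table, synth.labels,
                                               n_trees=cfg.rf_trees, seed=sub[1],
                                               n_repeats=cfg.rf_perm_repeats)
            else:
                ranking = select.auc_rank(synth.table, synth.labels)
            panel = select.FeaturePanel(features=ranking.order[:panel_size],
                                        method=method)
            positive = self.positive_label
            model = learn.train_model(synth.table, synth.labels, panel, algorithm,
                                      positive, tuning=cfg.tuning, seed=sub[2])
            scores = learn.predict_scores(model, complete)
            return learn.evaluate_classifier(scores, labels.align_to(complete),
                                             positive).auc

        return fit

    # -- public API ----------------------------------------------------------
    def fit(self) -> PipelineResult:
        cfg = self.config
        seeds = _subseeds(cfg.seed, 6)

        complete = prep.impute_missing(self.table, k=cfg.impute_k)

        # multivariate overview of the real data
        pca = select.fit_pca(complete)
        real_dapc = select.fit_dapc(complete, self.labels,
                                    var_threshold=cfg.dapc_var_threshold)
        real_selected = select.dapc_select(real_dapc, cfg.dapc_threshold)

        moments = augment.estimate_moments(complete, self.labels)
        mode = cfg.synth_mode or self.table.kind
        synth = augment.generate_synthetic(moments, cfg.synth_n_per_group,
                                           mode=mode, seed=seeds[0])

        if self.validation_table is not None:
            val_table = prep.impute_missing(self.validation_table, k=cfg.impute_k)
            val_labels = self.validation_labels
        else:
            val_table, val_labels = complete, self.labels

        rankings = self._rankings(synth, seeds)
        leaderboard, combos, models = self._train_and_validate(synth, rankings,
                                                               val_table, val_labels,
                                                               seeds)
        best = learn.select_best_combo(combos)
        best_model = next(m for c, m in zip(combos, models) if c is best)
        leaderboard = leaderboard.sort_values(
            ["auc", "panel_size", "sensitivity", "algorithm"],
            ascending=[False, True, False, True]).reset_index(drop=True)
        leaderboard.insert(0, "rank", np.arange(1, len(leaderboard) + 1))

        robustness = None
        if cfg.n_perm > 0:
            fit_pipeline = None
            if cfg.run_test5 and cfg.n_shuffles > 0:
                fit_pipeline = self._refit_auc(best.panel.method, best.algorithm,
                                               best.panel.size)
            robustness = robust.run_robustness(best_model, val_table, val_labels,
                                               n_perm=cfg.n_perm, seed=seeds[4],
                                               fit_pipeline=fit_pipeline,
                                               n_shuffles=cfg.n_shuffles)

        return PipelineResult(
            config=cfg, pca_explained=pca.explained_variance_ratio,
            real_dapc=real_dapc, real_dapc_selected=real_selected,
            moments=moments, rankings=rankings, leaderboard=leaderboard,
            best=best, best_model=best_model, robustness=robustness,
            positive_label=self.positive_label, reference_label=self.reference_label,
        )
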