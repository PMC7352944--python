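"""PCA, DAPC contributions, RF importance, AUC ranking and panels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bilemark as bm
from bilemark.select import FeatureRanking, mann_whitney_auc
from conftest import make_labels, make_table


def auc_pairs_oracle(values, positive):
    """All-pairs concordance count with half-credit ties."""
    values = np.asarray(values, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    pos, neg = values[positive], values[~positive]
    total = concordant = 0.0
    for a in pos:
        for b in neg:
            total += 1
            if a > b:
                concordant += 1
            elif a == b:
                concordant += 0.5
    return concordant / total


class TestFitPca:
    def test_collinear_data_loads_on_one_component(self):
        t_vals = np.outer(np.arange(1.0, 9.0), [1.0, 2.0, -0.5])
        res = bm.fit_pca(make_table(t_vals))
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_explained_variance_shares_sum_to_one(self):
        rng = np.random.default_rng(0)
        res = bm.fit_pca(make_table(rng.normal(size=(10, 4))))
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(8, 5))
        res = bm.fit_pca(make_table(vals))
        recon = res.scores.to_numpy() @ res.loadings.to_numpy().T + res.mean
        assert np.allclose(recon, vals, atol=1e-9)

    def test_constant_feature_with_scaling_rejected(self):
        t = make_table([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]])
        with pytest.raises(ValueError, match="constant"):
            bm.fit_pca(t, scale=True)


class TestFitDapc:
    def _planted(self, seed=0, n=50, noise_features=5, effect=3.0):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2 * n, noise_features + 1))
        x[n:, 0] += effect
        t = make_table(x)
        labels = make_labels(["a"] * n + ["b"] * n)
        return t, labels

    def test_planted_feature_dominates_contributions(self):
        t, labels = self._planted()
        model = bm.fit_dapc(t, labels)
        assert model.contributions.idxmax() == "f0"
        assert model.contributions["f0"] > 0.5

    def test_contributions_sum_to_one(self, small_planted_cohort):
        table, labels, _ = small_planted_cohort
        model = bm.fit_dapc(table, labels)
        assert model.contributions.sum() == pytest.approx(1.0, abs=1e-9)
        assert (model.contributions >= 0).all()

    def test_column_permutation_permutes_contributions(self):
        t, labels = self._planted(seed=3)
        model = bm.fit_dapc(t, labels)
        perm = ["f3", "f0", "f5", "f1", "f2", "f4"]
        model_p = bm.fit_dapc(t.subset(perm), labels)
        assert np.allclose(model_p.contributions[perm].to_numpy(),
                           model.contributions[perm].to_numpy(), atol=1e-9)

    def test_contributions_invariant_to_feature_rescaling(self):
        t, labels = self._planted(seed=4)
        base = bm.fit_dapc(t, labels).contributions
        scaled = t.data.copy()
        scaled["f1"] = scaled["f1"] * 1000 - 7.0
        rescaled = bm.fit_dapc(make_table(scaled.to_numpy()), labels).contributions
        assert np.allclose(rescaled.to_numpy(), base.to_numpy(), atol=1e-8)

    def test_npcs_clamped_with_warning(self):
        t, labels = self._planted(n=5)
        with pytest.warns(UserWarning, match="clamp"):
            model = bm.fit_dapc(t, labels, n_pcs=50)
        assert model.n_pcs <= 8  # n - groups

    def test_three_group_model_has_two_axes(self):
        table, labels, _ = bm.generate_cohort(bm.lipidomics_spec(seed=2))
        model = bm.fit_dapc(table, labels)
        assert model.axes.shape[1] == 2
        assert model.axis_shares.sum() == pytest.approx(1.0)


class TestDapcSelect:
    def _model_with(self, contributions):
        t = make_table(np.random.default_rng(0).normal(size=(10, len(contributions))))
        labels = make_labels(["a"] * 5 + ["b"] * 5)
        model = bm.fit_dapc(t, labels)
        model.contributions = model.contributions * 0 + np.asarray(contributions)
        return model

    def test_two_percent_rule_counts(self):
        contribs = [0.5, 0.3, 0.15, 0.04, 0.005, 0.005]
        ranking = bm.dapc_select(self._model_with(contribs), threshold=0.02)
        assert len(ranking) == 4
        assert ranking.order == ["f0", "f1", "f2", "f3"]

    def test_impossible_threshold_warns_empty(self):
        ranking_model = self._model_with([0.4, 0.3, 0.2, 0.05, 0.03, 0.02])
        with pytest.warns(UserWarning, match="no feature"):
            ranking = bm.dapc_select(ranking_model, threshold=1.0)
        assert len(ranking) == 0


class TestRfImportance:
    def test_constant_feature_has_negligible_importance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(60, 4))
        x[:, 2] = 7.0
        x[30:, 0] += 3.0
        t = make_table(x)
        labels = make_labels(["a"] * 30 + ["b"] * 30)
        ranking = bm.rf_importance(t, labels, n_trees=50, seed=1, n_repeats=3)
        assert abs(ranking.scores["f2"]) < 1e-3
        assert ranking.scores.idxmax() == "f0"

    def test_fixed_seed_reproducible(self):
        table, labels, _ = bm.generate_cohort(bm.GroundTruthSpec(
            n_per_group=(15, 15), n_features=10, planted_features=(0,),
            effect_size=2.0, seed=1))
        a = bm.rf_importance(table, labels, n_trees=30, seed=9, n_repeats=2)
        b = bm.rf_importance(table, labels, n_trees=30, seed=9, n_repeats=2)
        assert a.scores.equals(b.scores)

    def test_single_class_rejected(self):
        t = make_table(np.random.default_rng(0).normal(size=(4, 3)))
        with pytest.raises(ValueError, match="two classes"):
            bm.rf_importance(t, make_labels(["a"] * 4), n_trees=10)


class TestAucRank:
    def test_perfect_separation_scores_one(self):
        t = make_table([[0.0], [1.0], [10.0], [11.0]])
        labels = make_labels(["neg", "neg", "pos", "pos"])
        assert bm.auc_rank(t, labels).scores["f0"] == 1.0

    def test_hand_counted_three_quarters(self):
        t = make_table([[1.0], [3.0], [2.0], [4.0]])
        labels = make_labels(["neg", "neg", "pos", "pos"])
        assert bm.auc_rank(t, labels).scores["f0"] == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        t = make_table([[5.0]] * 6)
        labels = make_labels(["neg"] * 3 + ["pos"] * 3)
        assert bm.auc_rank(t, labels).scores["f0"] == pytest.approx(0.5)

    def test_score_is_direction_free(self):
        t = make_table([[10.0], [11.0], [0.0], [1.0]])
        labels = make_labels(["neg", "neg", "pos", "pos"])
        assert bm.auc_rank(t, labels).scores["f0"] == 1.0

    @given(st.integers(2, 20), st.integers(0, 2**31 - 1), st.booleans())
    @settings(max_examples=60)
    def test_matches_all_pairs_oracle(self, n, seed, with_ties):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(1, n))
        values = rng.normal(size=n)
        if with_ties:
            values = np.round(values)  # force ties
        positive = np.zeros(n, dtype=bool)
        positive[rng.choice(n, n1, replace=False)] = True
        assert mann_whitney_auc(values, positive) == pytest.approx(
            auc_pairs_oracle(values, positive), abs=1e-12)


class TestCandidatePanels:
    def _ranking(self, n):
        import pandas as pd
        scores = pd.Series(np.linspace(1, 0.1, n), index=[f"f{i}" for i in range(n)])
        return FeatureRanking(method="AUC", scores=scores, semantics="per-feature AUC")

    def test_twelve_features_give_eight_nested_panels(self):
        panels = bm.candidate_panels(self._ranking(12))
        assert [p.size for p in panels] == list(range(3, 11))
        for small, big in zip(panels, panels[1:]):
            assert big.features[:small.size] == small.features

    def test_five_features_give_three_panels(self):
        panels = bm.candidate_panels(self._ranking(5))
        assert [p.size for p in panels] == [3, 4, 5]

    def test_short_ranking_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            bm.candidate_panels(self._ranking(2))
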