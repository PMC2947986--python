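"""AUC, cross-validation, deletion contributions, interaction score, nulls."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import imtrisk as ir
from imtrisk import (
    MixedNaiveBayes,
    cross_validated_auc,
    deletion_delta_auc,
    evaluation_report,
    interaction_score,
    percent_contributions,
    roc_auc,
    validate_independent,
)
from imtrisk.evaluation import randomized_null


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_enumerated_pairs_example(self):
        # high-low pairs: 3 concordant of 4
        assert roc_auc([0.9, 0.8, 0.4, 0.2], [1, 0, 1, 0]) == 0.75

    def test_ties_count_one_half(self):
        assert roc_auc([0.5, 0.5], [0, 1]) == 0.5
        # pairs: (.5,.3)=1, (.5,.5)=.5, (.7,.3)=1, (.7,.5)=1 -> 3.5/4
        assert roc_auc([0.3, 0.5, 0.5, 0.7], [0, 0, 1, 1]) == 0.875

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_mann_whitney_u(self, seed):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(seed)
        n1, n0 = rng.integers(2, 30, size=2)
        scores = np.r_[rng.integers(0, 5, n1) * 0.1, rng.integers(0, 5, n0) * 0.1]
        y = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        u = mannwhitneyu(scores[y == 1], scores[y == 0]).statistic
        assert roc_auc(scores, y) == pytest.approx(u / (n1 * n0), abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(size=40)
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        a = roc_auc(scores, y)
        assert roc_auc(np.exp(2 * scores) + 5, y) == pytest.approx(a, abs=1e-12)

    def test_random_scores_average_half(self):
        rng = np.random.default_rng(3)
        n = 10_000
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        aucs = [roc_auc(rng.normal(size=n), y) for _ in range(200)]
        assert abs(np.mean(aucs) - 0.5) < 0.01


class TestCrossValidatedAuc:
    def test_determinism(self, toy_features):
        X, y = toy_features
        a = cross_validated_auc(X, y, k=5, seed=3)
        b = cross_validated_auc(X, y, k=5, seed=3)
        assert a.fold_aucs == b.fold_aucs

    def test_permuted_labels_near_half(self, toy_features):
        X, y = toy_features
        rng = np.random.default_rng(9)
        aucs = [cross_validated_auc(X, rng.permutation(y), k=5, seed=s).outer_auc
                for s in range(10)]
        assert abs(np.mean(aucs) - 0.5) < 0.06

    def test_folds_reduced_when_class_small(self):
        X = pd.DataFrame({"x": np.r_[np.zeros(3), np.ones(30)]})
        y = np.r_[np.ones(3, int), np.zeros(30, int)]
        rep = cross_validated_auc(X, y, k=10, seed=0)
        assert len(rep.fold_aucs) == 3

    def test_report_roundtrips_to_json(self, toy_features, tmp_path):
        X, y = toy_features
        rep = cross_validated_auc(X, y, k=5, seed=3)
        rep.to_json(tmp_path / "rep.json")
        import json

        doc = json.loads((tmp_path / "rep.json").read_text())
        assert doc["outer_auc"] == pytest.approx(rep.outer_auc)


class TestDeletionDelta:
    def test_empty_deletion_is_exactly_zero(self, toy_features):
        X, y = toy_features
        assert deletion_delta_auc(X, y, list(X.columns), [], k=5, seed=1) == 0.0

    def test_deleting_planted_feature_costs_auc(self):
        rng = np.random.default_rng(4)
        n = 300
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"noise1": rng.normal(size=n),
                          "noise2": rng.normal(size=n),
                          "signal": y + rng.normal(0, 0.5, n)})
        d = deletion_delta_auc(X, y, list(X.columns), ["signal"], k=5, seed=2)
        assert d > 0.2

    def test_uninformative_deletion_near_zero(self, toy_features):
        X, y = toy_features
        d = deletion_delta_auc(X, y, list(X.columns), ["bmi"], k=5, seed=5)
        assert abs(d) < 0.1

    def test_repeatable_under_same_seed(self, toy_features):
        X, y = toy_features
        args = (X, y, list(X.columns), ["snpA"])
        assert deletion_delta_auc(*args, k=5, seed=7) == deletion_delta_auc(*args, k=5, seed=7)

    def test_deleting_everything_rejected(self, toy_features):
        X, y = toy_features
        with pytest.raises(ValueError, match="every"):
            deletion_delta_auc(X, y, ["snpA"], ["snpA"], k=5, seed=0)

    def test_delete_outside_selected_rejected(self, toy_features):
        X, y = toy_features
        with pytest.raises(ValueError, match="subset"):
            deletion_delta_auc(X, y, ["snpA"], ["zzz"], k=5, seed=0)


class TestPercentContributions:
    def test_equal_deltas_split_evenly(self):
        pct = percent_contributions({"a": 0.05, "b": 0.05})
        assert pct == {"a": 50.0, "b": 50.0}

    def test_single_positive_among_zeros_gets_everything(self):
        pct = percent_contributions({"a": 0.07, "b": 0.0, "c": -0.02})
        assert pct["a"] == 100.0
        assert pct["b"] == 0.0

    def test_sum_is_hundred(self, rng):
        deltas = {f"f{i}": d for i, d in enumerate(rng.random(12) * 0.1)}
        assert sum(percent_contributions(deltas).values()) == pytest.approx(100.0, abs=0.5)

    def test_all_nonpositive_is_undefined(self):
        with pytest.raises(ValueError, match="undefined|nonpositive"):
            percent_contributions({"a": -0.01, "b": 0.0})


class TestInteractionScore:
    def test_symmetry_is_exact(self, toy_features):
        X, y = toy_features
        feats = list(X.columns)
        i_xy = interaction_score(X, y, feats, "snpA", "snpB", k=5, seed=3)
        i_yx = interaction_score(X, y, feats, "snpB", "snpA", k=5, seed=3)
        assert i_xy == i_yx

    def test_duplicate_constant_columns_score_zero(self):
        rng = np.random.default_rng(6)
        n = 100
        y = rng.integers(0, 2, n)
        X = pd.DataFrame({"c1": np.ones(n), "c2": np.ones(n),
                          "x": rng.normal(size=n) + y})
        i = interaction_score(X, y, list(X.columns), "c1", "c2", k=5, seed=1)
        assert i == 0.0

    def test_same_feature_twice_rejected(self, toy_features):
        X, y = toy_features
        with pytest.raises(ValueError, match="distinct"):
            interaction_score(X, y, list(X.columns), "snpA", "snpA", k=5, seed=0)


class TestEvaluationReport:
    def test_contributions_come_from_shared_fold_split(self, toy_features):
        X, y = toy_features
        rep = evaluation_report(X, y, list(X.columns), k=5, seed=11)
        for f, delta in rep.per_feature_delta.items():
            direct = deletion_delta_auc(X, y, list(X.columns), [f], k=5, seed=11)
            assert delta == pytest.approx(direct, abs=1e-12)

    def test_interaction_scores_present_for_requested_pairs(self, toy_features):
        X, y = toy_features
        rep = evaluation_report(X, y, list(X.columns),
                                interaction_pairs=[("snpA", "snpB")], k=5, seed=2)
        assert "snpA|snpB" in rep.interaction_scores


class TestRandomizedNull:
    def test_single_rep_reproducible(self, null_cohort):
        X = null_cohort.features()
        a = randomized_null(X, (40, 40), n_reps=1, seed=5)
        b = randomized_null(X, (40, 40), n_reps=1, seed=5)
        assert a["aucs"][0] == b["aucs"][0]

    def test_mean_near_half_without_selection(self, null_cohort):
        X = null_cohort.features()
        out = randomized_null(X, (50, 50), n_reps=20, seed=6)
        assert abs(out["mean_auc"] - 0.5) < 0.05
        assert out["max_auc"] >= out["mean_auc"]

    def test_class_sizes_validated(self, null_cohort):
        X = null_cohort.features()
        with pytest.raises(ValueError, match="class sizes"):
            randomized_null(X, (300, 300), n_reps=1, seed=0)


class TestValidateIndependent:
    def _model_and_cutoffs(self, cohort, q=0.15):
        labels = ir.assign_risk_classes(cohort.imt_baseline, q, "baseline")
        y = labels.binary()
        X = cohort.features().loc[y.index]
        nb = MixedNaiveBayes(categories={c: (0, 1, 2) for c in cohort.genotypes.columns})
        nb.fit(X, y.to_numpy())
        return nb, (labels.cutoff_low, labels.cutoff_high), X.index

    def test_subject_overlap_rejected(self, null_cohort):
        nb, cutoffs, train_ids = self._model_and_cutoffs(null_cohort)
        X_all = null_cohort.features()
        with pytest.raises(ValueError, match="overlap"):
            validate_independent(nb, X_all, null_cohort.imt_baseline, cutoffs,
                                 0.15, train_ids)

    def test_validation_cohort_from_same_model_scores_above_half(self):
        train = ir.generate_cohort(600, seed=31)
        nb, cutoffs, train_ids = self._model_and_cutoffs(train)
        new = ir.generate_cohort(600, seed=32)
        new_feats = new.features().rename(index=lambda s: "v_" + s)
        new_vals = new.imt_baseline.rename(index=lambda s: "v_" + s)
        res = validate_independent(nb, new_feats, new_vals, cutoffs, 0.15,
                                   train_ids)
        assert res["n_low"] > 0 and res["n_high"] > 0
        assert res["auc"] > 0.5  # CRF effects carry over to new subjects

    def test_shuffled_validation_labels_near_half(self):
        train = ir.generate_cohort(500, seed=33)
        nb, cutoffs, train_ids = self._model_and_cutoffs(train)
        new = ir.generate_cohort(2000, seed=34)
        rng = np.random.default_rng(0)
        shuffled = pd.Series(rng.permutation(new.imt_baseline.to_numpy()),
                             index=new.imt_baseline.index)
        res = validate_independent(nb, new.features().rename(index=lambda s: "v_" + s),
                                   shuffled.rename(index=lambda s: "v_" + s),
                                   cutoffs, 0.15, train_ids)
        assert abs(res["auc"] - 0.5) < 0.1

    def test_no_subject_in_classes_rejected(self, null_cohort):
        nb, cutoffs, train_ids = self._model_and_cutoffs(null_cohort)
        new_feats = null_cohort.features().iloc[:5].rename(index=lambda s: "v_" + s)
        mid = (cutoffs[0] + cutoffs[1]) / 2
        new_vals = pd.Series(mid, index=new_feats.index)
        with pytest.raises(ValueError, match="risk classes"):
            validate_independent(nb, new_feats, new_vals, cutoffs, 0.15, train_ids)
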