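import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from msremip.classify import (
    ConfusionTable,
    EnsembleLdaClassifier,
    ReferenceNormalizer,
    confusion_metrics,
    cv_auc,
    cumulative_undigested_counts,
    ensemble_vote_cutoff,
    filter_smmips,
    fit_lda_1d,
    ModelEval,
    normalize,
    pick_best_tile,
    roc_auc,
    single_model_cutoff,
    stratified_folds,
    train_ensemble,
    TrainedModel,
)
from msremip.simulate import SimConfig, default_sample_sheet, simulate_counts

from conftest import manual_count_matrix


# ---------------------------------------------------------------------------
# Normalization


class TestNormalize:
    @staticmethod
    def _cm():
        categories = {"cpg1": "cpg", "cpg2": "cpg", "ref1": "ref_no_site", "ref2": "ref_no_cpg"}
        counts = {
            "s1": {"cpg1": 10, "cpg2": 0, "ref1": 60, "ref2": 40},
            "s2": {"cpg1": 30, "cpg2": 0, "ref1": 100, "ref2": 100},
        }
        return manual_count_matrix(counts, categories)

    def test_division_by_reference_sum(self):
        norm = normalize(self._cm())
        assert norm.values.loc["s1", "cpg1"] == pytest.approx(0.1)
        assert norm.reference_ids == ["ref1", "ref2"]

    def test_zero_count_row_stays_zero(self):
        norm = normalize(self._cm())
        assert (norm.values["cpg2"] == 0).all()

    def test_scale_invariance(self):
        cm = self._cm()
        doubled = cm.subset()
        doubled.counts.loc["s1"] = cm.counts.loc["s1"] * 2
        pd.testing.assert_series_equal(
            normalize(cm).values.loc["s1"], normalize(doubled).values.loc["s1"]
        )

    def test_zero_reference_sum_names_sample(self):
        cm = self._cm()
        cm.counts.loc["s1", ["ref1", "ref2"]] = 0
        with pytest.raises(ValueError, match="s1"):
            normalize(cm)

    def test_transformer_matches_function(self):
        cm = self._cm()
        est = ReferenceNormalizer(reference_ids=["ref1", "ref2"]).fit(cm.counts)
        pd.testing.assert_frame_equal(est.transform(cm.counts), normalize(cm).values)


# ---------------------------------------------------------------------------
# Folds


class TestStratifiedFolds:
    def test_balanced_strata_split_evenly(self):
        strata = ["lung|tumor"] * 10 + ["lung|normal"] * 10
        folds = stratified_folds(strata, n_folds=5, seed=1)
        for f in range(5):
            sel = folds == f
            assert sel[:10].sum() == 2 and sel[10:].sum() == 2

    def test_deterministic_under_seed(self):
        strata = ["a"] * 13 + ["b"] * 9
        f1 = stratified_folds(strata, seed=7)
        f2 = stratified_folds(strata, seed=7)
        assert (f1 == f2).all()
        assert not (f1 == stratified_folds(strata, seed=8)).all()

    def test_small_stratum_pigeonhole_warns(self):
        with pytest.warns(UserWarning, match="3 samples"):
            folds = stratified_folds(["a"] * 3 + ["b"] * 10, n_folds=5, seed=0)
        sizes = [(folds[:3] == f).sum() for f in range(5)]
        assert sorted(sizes) == [0, 0, 1, 1, 1]

    def test_too_few_samples_error(self):
        with pytest.raises(ValueError, match="folds"):
            stratified_folds(["a", "b"], n_folds=5)


# ---------------------------------------------------------------------------
# 1-D LDA


class TestLda1D:
    def test_symmetric_classes_boundary_at_midpoint(self):
        model = fit_lda_1d([1, 2, 3, 7, 8, 9], [False, False, False, True, True, True])
        assert model.boundary == pytest.approx(5.0)

    def test_pooled_variance_and_boundary(self):
        # {0,0,1} vs {2,3,4}: pooled SS = 2/3 + 2, df = 4 -> var 2/3; boundary 5/3
        model = fit_lda_1d([0, 0, 1, 2, 3, 4], [False, False, False, True, True, True])
        assert model.var == pytest.approx(2 / 3)
        assert model.boundary == pytest.approx(5 / 3)

    def test_translation_equivariance(self):
        x = np.array([0.1, 0.3, 0.2, 0.9, 1.1, 0.8])
        y = [False, False, False, True, True, True]
        m1 = fit_lda_1d(x, y)
        m2 = fit_lda_1d(x + 10.0, y)
        assert m2.mu_tumor == pytest.approx(m1.mu_tumor + 10)
        assert m2.boundary == pytest.approx(m1.boundary + 10)
        assert m2.var == pytest.approx(m1.var)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            fit_lda_1d([1, 2, 3], [True, True, True])

    def test_degenerate_zero_variance_scores_by_side(self):
        model = fit_lda_1d([1, 1, 3, 3], [False, False, True, True])
        assert model.degenerate
        assert model.score([4.0])[0] == np.inf
        assert model.score([0.0])[0] == -np.inf
        assert model.score([2.0])[0] == 0.0

    def test_matches_sklearn_lda_decisions(self):
        """Independent oracle: predictions at the decision boundary agree
        with sklearn's LDA on random unequal-prior data."""
        rng = np.random.default_rng(3)
        for _ in range(20):
            n1, n2 = rng.integers(3, 15, size=2)
            x = np.concatenate([rng.normal(0, 1, n1), rng.normal(1.5, 1, n2)])
            y = np.array([False] * n1 + [True] * n2)
            model = fit_lda_1d(x, y)
            sk = LinearDiscriminantAnalysis().fit(x.reshape(-1, 1), y)
            grid = np.linspace(x.min() - 1, x.max() + 1, 40)
            ours = model.score(grid) >= 0
            theirs = sk.predict(grid.reshape(-1, 1)).astype(bool)
            assert (ours == theirs).all()


# ---------------------------------------------------------------------------
# AUC


def brute_force_auc(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    pos, neg = s[y], s[~y]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_known_example(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.7, 0.3, 0.2], [1, 1, 1, 0, 0, 0]) == pytest.approx(8 / 9)

    def test_all_ties_half(self):
        assert roc_auc([5, 5, 5, 5], [1, 1, 0, 0]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [1, 1])

    @given(st.integers(0, 2**32 - 1))
    def test_equals_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 50))
        n_pos = int(rng.integers(1, n))
        scores = rng.choice(np.round(rng.normal(size=n), 1), size=n)  # induce ties
        labels = np.zeros(n, bool)
        labels[rng.permutation(n)[:n_pos]] = True
        auc = roc_auc(scores, labels)
        assert auc == pytest.approx(brute_force_auc(scores, labels))
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_equals_mann_whitney_u_statistic(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(1, 1, 12), rng.normal(0, 1, 15)
        u = mannwhitneyu(x, y, alternative="two-sided").statistic
        scores = np.concatenate([x, y])
        labels = [True] * 12 + [False] * 15
        assert roc_auc(scores, labels) == pytest.approx(u / (12 * 15))


class TestCvAuc:
    def test_separable_data_every_fold_perfect(self):
        x = np.concatenate([np.arange(10), np.arange(100, 110)])
        y = [False] * 10 + [True] * 10
        folds = stratified_folds(y, 5, seed=0)
        ev = cv_auc(x, y, folds)
        assert ev.fold_aucs == [1.0] * 5 and ev.cvauc == 1.0

    def test_permuted_labels_near_half(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=400)
        y = rng.permutation([True] * 200 + [False] * 200)
        folds = stratified_folds(y.astype(int), 5, seed=0)
        assert abs(cv_auc(x, y, folds).cvauc - 0.5) < 0.08

    def test_cvauc_is_mean_of_folds(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=40) + np.r_[np.zeros(20), np.ones(20)]
        y = [False] * 20 + [True] * 20
        ev = cv_auc(x, y, stratified_folds(y, 5, seed=1))
        assert ev.cvauc == pytest.approx(np.mean(ev.fold_aucs))

    def test_single_class_fold_skipped(self):
        x = np.arange(10.0)
        y = [False] * 5 + [True] * 5
        folds = np.array([0] * 5 + [1] * 5)  # each fold holds out one class
        with pytest.raises(ValueError, match="degenerate"):
            cv_auc(x, y, folds)


# ---------------------------------------------------------------------------
# Selection and cutoffs


class TestFilterAndTiles:
    def test_efficiency_and_discrimination_thresholds(self):
        evals = {
            "a": ModelEval([0.95]),  # cumulative 999 -> fails efficiency
            "b": ModelEval([0.80]),  # exactly at both cutoffs -> kept
            "c": ModelEval([0.79]),  # fails discrimination
        }
        cum = pd.Series({"a": 999, "b": 1000, "c": 5000})
        assert filter_smmips(evals, cum) == ["b"]

    def test_best_tile_by_cvauc(self):
        evals = {"t1_p": ModelEval([0.91]), "t1_m": ModelEval([0.88]), "t2_p": ModelEval([0.85])}
        groups = {"t1_p": "t1", "t1_m": "t1", "t2_p": "t2"}
        cum = pd.Series({"t1_p": 1000, "t1_m": 1000, "t2_p": 1000})
        assert pick_best_tile(list(evals), groups, evals, cum) == ["t1_p", "t2_p"]

    def test_tie_broken_by_undigested_counts_then_id(self):
        evals = {"t1_p": ModelEval([0.9]), "t1_m": ModelEval([0.9])}
        groups = {"t1_p": "t1", "t1_m": "t1"}
        assert pick_best_tile(
            list(evals), groups, evals, pd.Series({"t1_p": 2000, "t1_m": 4000})
        ) == ["t1_m"]
        assert pick_best_tile(
            list(evals), groups, evals, pd.Series({"t1_p": 2000, "t1_m": 2000})
        ) == ["t1_m"]  # lexicographic: t1_m < t1_p


def exhaustive_cutoff_errors(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    best = len(y) + 1
    for c in np.concatenate([s - 1e-9, s + 1e-9, [s.min() - 1, s.max() + 1]]):
        pred = s >= c
        best = min(best, int((pred & ~y).sum() + (~pred & y).sum()))
    return best


class TestSingleModelCutoff:
    def test_tie_returns_larger_cutoff(self):
        scores = [0.9, 0.8, 0.4, 0.7, 0.3, 0.2]
        labels = [1, 1, 1, 0, 0, 0]
        cut = single_model_cutoff(scores, labels)
        assert cut == pytest.approx(0.75)  # FP+FN = 1 at 0.35 and 0.75; specificity wins

    def test_separable_gap_midpoint_zero_errors(self):
        cut = single_model_cutoff([1, 2, 3, 7, 8, 9], [0, 0, 0, 1, 1, 1])
        assert cut == pytest.approx(5.0)
        s = np.array([1, 2, 3, 7, 8, 9])
        y = np.array([0, 0, 0, 1, 1, 1], bool)
        assert (((s >= cut) != y).sum()) == 0

    def test_identical_scores_majority_rules(self):
        # normals outnumber tumors: cutoff lands above the shared score
        cut = single_model_cutoff([2.0, 2.0, 2.0], [1, 0, 0])
        assert cut > 2.0
        cut = single_model_cutoff([2.0, 2.0, 2.0], [1, 1, 0])
        assert cut < 2.0

    @given(st.integers(0, 2**32 - 1))
    def test_achieves_exhaustive_minimum(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        scores = np.round(rng.normal(size=n), 1)
        labels = rng.integers(0, 2, size=n).astype(bool)
        if labels.all() or not labels.any():
            labels[0] = not labels[0]
        cut = single_model_cutoff(scores, labels)
        pred = scores >= cut
        errors = int((pred & ~labels).sum() + (~pred & labels).sum())
        assert errors == exhaustive_cutoff_errors(scores, labels)


class TestEnsembleVoteCutoff:
    def test_known_votes(self):
        votes = np.array([[1, 1, 1], [1, 1, 0], [1, 0, 0], [0, 0, 0]], bool)
        assert ensemble_vote_cutoff(votes, [1, 1, 0, 0]) == 2

    def test_unanimous_voters_threshold_one(self):
        votes = np.ones((4, 5), bool)
        assert ensemble_vote_cutoff(votes, [1, 1, 1, 1]) == 1

    def test_tie_prefers_smallest_k(self):
        votes = np.array([[1, 1], [0, 0]], bool)  # k=1 and k=2 both perfect
        assert ensemble_vote_cutoff(votes, [1, 0]) == 1

    @given(st.integers(0, 2**32 - 1))
    def test_achieves_exhaustive_maximum_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(2, 20)), int(rng.integers(1, 8))
        votes = rng.integers(0, 2, size=(n, m)).astype(bool)
        labels = rng.integers(0, 2, size=n).astype(bool)
        k = ensemble_vote_cutoff(votes, labels)
        acc_at_k = ((votes.sum(axis=1) >= k) == labels).mean()
        best = max(
            ((votes.sum(axis=1) >= kk) == labels).mean() for kk in range(1, m + 1)
        )
        assert acc_at_k == best


# ---------------------------------------------------------------------------
# Confusion metrics


class TestConfusionMetrics:
    def test_multi_cancer_metrics(self):
        m = confusion_metrics(ConfusionTable(tp=104, tn=135, fp=14, fn=6))
        assert round(m["sensitivity"], 3) == 0.945
        assert round(m["specificity"], 3) == 0.906
        assert round(m["accuracy"], 3) == 0.923
        assert round(m["balanced_accuracy"], 3) == 0.926

    def test_perfect_tiny_table(self):
        m = confusion_metrics(ConfusionTable(tp=1, tn=1, fp=0, fn=0))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_is_nan_not_zero(self):
        m = confusion_metrics(ConfusionTable(tp=0, tn=5, fp=0, fn=0))
        assert np.isnan(m["sensitivity"]) and np.isnan(m["balanced_accuracy"])
        assert m["specificity"] == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionTable(tp=-1, tn=0, fp=0, fn=0)


# ---------------------------------------------------------------------------
# Ensemble end to end


@pytest.fixture(scope="module")
def trained(tiny_panel):
    samples = default_sample_sheet(31, n_tumor=30, n_normal=24, n_blood=6, n_undigested=3)
    config = SimConfig(seed=31, samples=samples, n_molecules_per_target=2000)
    counts, _ = simulate_counts(tiny_panel, config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = train_ensemble(counts, seed=31)
    return model, counts


class TestEnsembleClassifier:
    def test_vote_threshold_is_inclusive(self, trained):
        model, counts = trained
        clf = model.classifier
        X = model._features(counts.subset(samples=counts.digested_samples))
        votes = clf.vote_counts(X)
        pred = clf.predict(X)
        at_k = votes >= clf.vote_threshold_
        assert (pred.astype(bool) == at_k.to_numpy()).all()

    def test_training_predictions_reproduce_stored_confusion(self, trained):
        model, counts = trained
        clf = model.classifier
        sub = counts.subset(samples=counts.digested_samples)
        X = model._features(sub)
        pred = clf.predict(X).astype(bool)
        actual = (sub.sample_meta["condition"] == "tumor").to_numpy()
        stored = clf.training_confusion_
        assert int((pred & actual).sum()) == stored.tp
        assert int((~pred & ~actual).sum()) == stored.tn

    def test_missing_columns_listed(self, trained):
        model, counts = trained
        clf = model.classifier
        X = model._features(counts).drop(columns=clf.included_smmips_[:1])
        with pytest.raises(ValueError, match=clf.included_smmips_[0]):
            clf.predict(X)

    def test_model_json_roundtrip(self, trained, tmp_path):
        model, counts = trained
        model.to_json(tmp_path / "model.json")
        back = TrainedModel.from_json(tmp_path / "model.json")
        sub = counts.subset(samples=counts.digested_samples)
        pd.testing.assert_frame_equal(back.predict(sub), model.predict(sub))

    def test_sklearn_get_set_params_roundtrip(self):
        clf = EnsembleLdaClassifier(min_cvauc=0.85)
        params = clf.get_params()
        assert params["min_cvauc"] == 0.85
        clf.set_params(n_folds=4)
        assert clf.n_folds == 4

    def test_undigested_counts_required(self, trained):
        model, counts = trained
        X = model._features(counts.subset(samples=counts.digested_samples))
        y = (counts.sample_meta.loc[X.index, "condition"] == "tumor").to_numpy()
        with pytest.raises(ValueError, match="cum_undigested"):
            EnsembleLdaClassifier().fit(X, y)

    def test_cumulative_undigested_requires_controls(self, tiny_panel):
        samples = default_sample_sheet(5, n_tumor=3, n_normal=3, n_blood=0, n_undigested=0)
        config = SimConfig(seed=5, samples=samples, n_molecules_per_target=100)
        counts, _ = simulate_counts(tiny_panel, config)
        with pytest.raises(ValueError, match="undigested"):
            cumulative_undigested_counts(counts)
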