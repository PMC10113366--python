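"""Nested LOOCV orchestration: leakage guard, performance arithmetic,
cumulative-weight formula, permutation inference, Wilcoxon oracle,
final-model identification and external generalisation."""

import itertools

import numpy as np
import pytest
from scipy import stats

from fcbiomarker import (
    CohortSpec,
    CVConfig,
    FCDataset,
    SCCAParams,
    TrainOptions,
    cumulative_weights,
    final_model,
    generate_fc_dataset,
    generalize,
    loocv_run,
    performance,
    permutation_test,
    select_features,
    slr_predict,
    wilcoxon_weights,
)
from fcbiomarker.crossval import CVError, CVResult


def small_config(seed=0):
    """Light selection geometry for fast nested runs on tiny cohorts."""
    return CVConfig(
        scca=SCCAParams(c_u_grid=(1.2, 1.8), n_folds=2),
        slr=TrainOptions(max_iter=100),
        seed=seed,
    )


@pytest.fixture(scope="module")
def small_separable():
    spec = CohortSpec(n_std=8, n_hc=8, n_regions=8, seed=5,
                      discriminative_edges=[(0, 1, -0.8), (2, 5, 0.8)])
    ds, _, truth = generate_fc_dataset(spec)
    return ds, truth


@pytest.fixture(scope="module")
def small_cv(small_separable):
    ds, truth = small_separable
    return loocv_run(ds, small_config())


class TestPerformance:
    def test_perfect_predictions(self):
        y = np.array([1, 1, 0, 0])
        assert performance(y.astype(float), y) == (1.0, 1.0, 1.0, 1.0)

    def test_all_predicted_hc_on_unbalanced_mix(self):
        # 30 StD / 61 HC, every prediction below threshold
        y = np.array([1] * 30 + [0] * 61)
        p = np.full(91, 0.2)
        acc, sens, spec, _ = performance(p, y)
        assert acc == pytest.approx(61 / 91)
        assert sens == 0.0
        assert spec == 1.0

    def test_rank_auc_matches_trapezoidal_roc_oracle(self, rng):
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        scores = rng.uniform(size=60)
        _, _, _, auc = performance(scores, y)
        # oracle: trapezoidal integration of the empirical ROC curve
        thresholds = np.unique(np.concatenate([[-np.inf], scores, [np.inf]]))[::-1]
        tpr = [np.mean(scores[y == 1] >= t) for t in thresholds]
        fpr = [np.mean(scores[y == 0] >= t) for t in thresholds]
        assert auc == pytest.approx(np.trapezoid(tpr, fpr), abs=1e-12)

    def test_rank_auc_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        scores = rng.uniform(size=80)
        scores[10:20] = scores[0]   # ties
        _, _, _, auc = performance(scores, y)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(CVError, match="AUC undefined"):
            performance(np.array([0.2, 0.8]), np.array([1, 1]))


class TestLOOCV:
    def test_high_auc_on_separable_cohort(self, small_cv):
        assert small_cv.auc >= 0.85

    def test_determinism(self, small_separable):
        ds, _ = small_separable
        a = loocv_run(ds, small_config())
        b = loocv_run(ds, small_config())
        np.testing.assert_array_equal(a.predictions, b.predictions)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_no_leakage_selection_ignores_held_out_subject(self, small_separable):
        # replacing the held-out subject's features by wild values must not
        # change that fold's candidate set or weights
        ds, _ = small_separable
        cfg = small_config()
        cv = loocv_run(ds, cfg)
        X2 = ds.X.copy()
        X2[0] = 1e3   # corrupt the first (held-out in fold 0) subject
        ds2 = FCDataset(X=X2, y=ds.y, age=ds.age, sex=ds.sex,
                        subject_ids=ds.subject_ids, n_regions=ds.n_regions)
        cv2 = loocv_run(ds2, cfg)
        np.testing.assert_array_equal(cv.selected[0], cv2.selected[0])
        np.testing.assert_array_equal(cv.weights[0], cv2.weights[0])
        m1, s1 = cv.fold_standardization[0]
        m2, s2 = cv2.fold_standardization[0]
        np.testing.assert_array_equal(m1, m2)
        np.testing.assert_array_equal(s1, s2)

    def test_fold_selection_reproducible_from_training_subset(self, small_separable):
        # fold i's candidate set equals an independent select_features call on
        # the same training subset with the same derived seed
        ds, _ = small_separable
        cfg = small_config()
        cv = loocv_run(ds, cfg)
        fold_seeds = np.random.SeedSequence([cfg.seed, 911]).generate_state(
            ds.n_subjects) % (2**31 - 1)
        i = 3
        tr = np.ones(ds.n_subjects, bool)
        tr[i] = False
        cand = select_features(ds.X[tr], ds.y[tr], np.asarray(ds.age)[tr],
                               np.asarray(ds.sex)[tr], cfg.scca,
                               seed=int(fold_seeds[i]))
        np.testing.assert_array_equal(cv.selected[i], cand)

    def test_class_minimum_enforced(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((5, 6))
        ds = FCDataset(X=X, y=np.array([1, 0, 0, 0, 0]), age=np.zeros(5),
                       sex=np.zeros(5), subject_ids=[str(k) for k in range(5)],
                       n_regions=4)
        with pytest.raises(CVError, match="per class"):
            loocv_run(ds, small_config())


class TestCumulativeWeights:
    def test_zero_weights_all_zero(self, small_cv):
        cv = CVResult(n_subjects=3, n_features=4, selected=[np.array([0])] * 3,
                      weights=np.zeros((3, 4)), predictions=np.zeros(3),
                      labels=np.array([1, 0, 1]), fold_standardization=[])
        assert all(c == 0.0 for _, c in cumulative_weights(cv))

    def test_hand_formula(self):
        # three folds with weights (1, -2, 0.5) on edge 2: c = 3.5
        W = np.zeros((3, 4))
        W[:, 2] = [1.0, -2.0, 0.5]
        cv = CVResult(n_subjects=3, n_features=4, selected=[np.array([2])] * 3,
                      weights=W, predictions=np.zeros(3),
                      labels=np.array([1, 0, 1]), fold_standardization=[])
        ranked = cumulative_weights(cv)
        assert ranked[0] == (2, 3.5)
        assert all(c == 0.0 for _, c in ranked[1:])

    def test_formula_fidelity_against_stored_folds(self, small_cv):
        # independent recomputation from the stored per-fold weights
        expected = np.abs(small_cv.weights).sum(axis=0)
        for k, c in cumulative_weights(small_cv):
            assert c == expected[k]

    def test_never_selected_edges_have_zero_weight(self, small_cv):
        ever = set(small_cv.ever_selected.tolist())
        for k in range(small_cv.n_features):
            if k not in ever:
                assert small_cv.cumulative[k] == 0.0

    def test_ties_broken_by_edge_id(self):
        W = np.zeros((2, 5))
        W[0, [1, 3]] = 2.0
        cv = CVResult(n_subjects=2, n_features=5, selected=[np.array([1, 3])] * 2,
                      weights=W, predictions=np.zeros(2), labels=np.array([1, 0]),
                      fold_standardization=[])
        ranked = cumulative_weights(cv)
        assert [k for k, _ in ranked[:2]] == [1, 3]


class TestPermutationTest:
    def test_p_value_formula_extreme(self):
        # observed above every permuted value with n_perm = 99: p = 0.01
        from fcbiomarker.crossval import PermutationResult
        permuted = np.linspace(0.3, 0.6, 99)
        p = (1 + np.sum(permuted >= 0.95)) / (99 + 1)
        assert p == 0.01

    def test_determinism_and_validity(self, small_separable):
        ds, _ = small_separable
        cfg = small_config(seed=3)
        a = permutation_test(ds, cfg, n_perm=19, statistic="accuracy")
        b = permutation_test(ds, cfg, n_perm=19, statistic="accuracy")
        np.testing.assert_array_equal(a.permuted, b.permuted)
        assert a.p_value == b.p_value
        assert a.p_value >= 1 / 20
        # separable cohort: observed accuracy should beat most permutations
        assert a.observed > np.median(a.permuted)

    def test_n_perm_minimum(self, small_separable):
        ds, _ = small_separable
        with pytest.raises(CVError, match="n_perm"):
            permutation_test(ds, small_config(), n_perm=5)


class TestWilcoxon:
    def test_matches_exact_enumeration_oracle_n10(self):
        # brute force over all 2^10 sign assignments
        w = np.array([0.8, 1.2, 0.9, 1.5, 0.7, 1.1, 1.3, 0.6, 1.0, 1.4])
        W = np.zeros((10, 3))
        W[:, 1] = w
        cv = CVResult(n_subjects=10, n_features=3, selected=[np.array([1])] * 10,
                      weights=W, predictions=np.zeros(10),
                      labels=np.array([1, 0] * 5), fold_standardization=[])
        p_pkg = wilcoxon_weights(cv, [1])[1]["p"]
        ranks = stats.rankdata(np.abs(w))
        observed = np.sum(ranks[w > 0])
        count = 0
        for signs in itertools.product([0, 1], repeat=10):
            wplus = np.sum(ranks[np.array(signs, bool)])
            # two-sided: as extreme in either direction
            if min(wplus, 55 - wplus) <= min(observed, 55 - observed):
                count += 1
        p_oracle = count / 2**10
        assert p_pkg == pytest.approx(p_oracle, abs=1e-12)

    def test_all_identical_positive_minimal_p(self):
        W = np.zeros((12, 2))
        W[:, 0] = 2.5
        cv = CVResult(n_subjects=12, n_features=2, selected=[np.array([0])] * 12,
                      weights=W, predictions=np.zeros(12),
                      labels=np.array([1, 0] * 6), fold_standardization=[])
        res = wilcoxon_weights(cv, [0])[0]
        # identical values are one big tie: normal approximation, still tiny
        assert res["p"] < 0.01

    def test_all_zero_weights_flagged(self):
        cv = CVResult(n_subjects=8, n_features=2, selected=[np.array([])] * 8,
                      weights=np.zeros((8, 2)), predictions=np.zeros(8),
                      labels=np.array([1, 0] * 4), fold_standardization=[])
        res = wilcoxon_weights(cv, [0])[0]
        assert res["p"] == 1.0 and res["flagged"]

    def test_symmetric_null_p_typically_large(self):
        # weights symmetric about zero: small p should be rare
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            w = rng.standard_normal(15)
            W = np.zeros((15, 1))
            W[:, 0] = w
            cv = CVResult(n_subjects=15, n_features=1, selected=[np.array([0])] * 15,
                          weights=W, predictions=np.zeros(15),
                          labels=np.array([1, 0] * 7 + [1]),
                          fold_standardization=[])
            ps.append(wilcoxon_weights(cv, [0])[0]["p"])
        assert np.median(ps) > 0.3
        assert np.mean(np.array(ps) < 0.05) < 0.2


class TestFinalModelAndGeneralize:
    def test_identified_subset_of_ever_selected(self, small_separable, small_cv):
        ds, _ = small_separable
        model, identified = final_model(ds, small_cv, small_config())
        assert set(identified.tolist()) <= set(small_cv.ever_selected.tolist())

    def test_identified_edges_are_discriminative(self, small_separable, small_cv):
        # at n=16 one strong edge can make the second redundant under ARD, and
        # shrinkage keeps some weakly-associated edges with small weights, so
        # require the identified set to be nonempty and led (largest absolute
        # weight) by an injected edge
        ds, truth = small_separable
        model, identified = final_model(ds, small_cv, small_config())
        inj = set(truth.discriminative_edge_ids.tolist())
        assert identified.size > 0
        assert inj & set(identified.tolist())
        lead = identified[int(np.argmax(np.abs(model.weights)))]
        assert int(lead) in inj

    def test_frequency_identification_rule(self, small_separable, small_cv):
        # edges selected in >= half the folds; injected edges qualify and the
        # set is a subset of the union
        ds, truth = small_separable
        _, identified = final_model(ds, small_cv, small_config(),
                                    identify="frequency",
                                    min_selection_fraction=0.5)
        assert set(identified.tolist()) <= set(small_cv.ever_selected.tolist())
        assert set(truth.discriminative_edge_ids.tolist()) <= set(identified.tolist())
        counts = np.zeros(small_cv.n_features)
        for sel in small_cv.selected:
            counts[np.asarray(sel, dtype=int)] += 1
        for k in identified:
            assert counts[k] >= 0.5 * len(small_cv.selected)

    def test_training_set_predictions_reproducible(self, small_separable, small_cv):
        ds, _ = small_separable
        model, _ = final_model(ds, small_cv, small_config())
        p1 = slr_predict(model, ds.X[:, model.edge_ids])
        p2 = slr_predict(model, ds.X[:, model.edge_ids])
        np.testing.assert_array_equal(p1, p2)

    def test_generalizes_to_cohort_from_same_spec(self, small_separable, small_cv):
        ds, truth = small_separable
        model, _ = final_model(ds, small_cv, small_config())
        ext_spec = CohortSpec(n_std=16, n_hc=27, n_regions=8, seed=99,
                              discriminative_edges=[(0, 1, -0.8), (2, 5, 0.8)])
        ext, _, _ = generate_fc_dataset(ext_spec, cohort="test")
        acc, sens, spec, auc = generalize(model, ext)
        assert auc >= small_cv.auc - 0.15

    def test_shuffled_external_labels_near_chance(self, small_separable, small_cv):
        ds, _ = small_separable
        model, _ = final_model(ds, small_cv, small_config())
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ext = FCDataset(X=ds.X, y=rng.permutation(ds.y), age=ds.age,
                            sex=ds.sex, subject_ids=ds.subject_ids,
                            n_regions=ds.n_regions)
            aucs.append(generalize(model, ext)[3])
        assert 0.3 < np.mean(aucs) < 0.7

    def test_edge_index_mismatch_rejected(self, small_separable, small_cv):
        ds, _ = small_separable
        model, _ = final_model(ds, small_cv, small_config())
        tiny = FCDataset(X=np.zeros((4, 3)), y=np.array([1, 0, 1, 0]),
                         age=np.zeros(4), sex=np.zeros(4),
                         subject_ids=list("abcd"), n_regions=3)
        with pytest.raises(CVError, match="edge-index"):
            generalize(model, tiny)
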