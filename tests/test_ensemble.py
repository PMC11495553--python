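"""The undersampling-bagging SVM ensemble: splits, subsets, fusion, metrics."""

import dataclasses

import numpy as np
import pytest

from rsbagging.ensemble import (
    ABSTAIN,
    Dataset,
    EnsembleConfig,
    PredictionResult,
    build_task_dataset,
    evaluate,
    fit_single_svm,
    make_balanced_subsets,
    predict,
    run_task,
    stratified_split,
    train_ensemble,
)
from rsbagging.synthetic import CohortSpec, gen_cohort, gen_imbalanced_gaussians


@pytest.fixture(scope="module")
def imbalanced():
    return gen_imbalanced_gaussians(91, 909, n_features=10, separation=2.0, seed=5)


@pytest.fixture(scope="module")
def table1_cohort():
    return gen_cohort(CohortSpec(seed=0))


class TestStratifiedSplit:
    def test_table1_class_counts_round_to_nearest(self):
        X = np.zeros((241, 2))
        y = np.concatenate([np.ones(97, int), np.zeros(144, int)])
        tr, te = stratified_split(Dataset(X, y), 0.3, seed=1)
        assert te.n_positive == 29 and te.n_negative == 43
        assert tr.n_positive == 68 and tr.n_negative == 101

    def test_balanced_even_split(self):
        X = np.zeros((100, 2))
        y = np.repeat([0, 1], 50)
        tr, te = stratified_split(Dataset(X, y), 0.2, seed=0)
        assert te.n_positive == 10 and te.n_negative == 10

    def test_same_seed_same_split(self, imbalanced):
        a = stratified_split(imbalanced, 0.3, seed=9)
        b = stratified_split(imbalanced, 0.3, seed=9)
        np.testing.assert_array_equal(a[1].X, b[1].X)
        np.testing.assert_array_equal(a[1].y, b[1].y)

    def test_singleton_class_rejected(self):
        data = Dataset(np.zeros((5, 2)), np.array([0, 0, 0, 0, 1]))
        with pytest.raises(ValueError):
            stratified_split(data, 0.3, seed=0)


class TestBalancedSubsets:
    def test_subsets_exactly_balanced(self):
        y = np.concatenate([np.ones(5, int), np.zeros(50, int)])
        data = Dataset(np.zeros((55, 2)), y)
        subsets = make_balanced_subsets(data, N=10, seed=0)
        minority = set(np.flatnonzero(y == 1))
        assert len(subsets) == 10
        for idx in subsets:
            assert len(idx) == 10
            assert minority <= set(idx)           # every minority sample kept
            maj = [i for i in idx if y[i] == 0]
            assert len(maj) == 5 == len(set(maj))  # distinct majority draws

    def test_majority_coverage_with_many_subsets(self):
        """Coupon-collector: 200 subsets cover nearly all majority samples."""
        y = np.concatenate([np.ones(5, int), np.zeros(50, int)])
        data = Dataset(np.zeros((55, 2)), y)
        subsets = make_balanced_subsets(data, N=200, seed=1)
        union = set().union(*(set(i for i in s if y[i] == 0) for s in subsets))
        assert len(union) > 0.95 * 50

    def test_minority_larger_than_majority_rejected(self):
        y = np.concatenate([np.ones(10, int), np.zeros(3, int)])
        with pytest.raises(ValueError):
            make_balanced_subsets(Dataset(np.zeros((13, 2)), y), 3, 0)


class TestTrainPredict:
    def test_separable_data_perfect_base_models(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-10, 0.1, (40, 3)),
                       rng.normal(10, 0.1, (8, 3))])
        y = np.concatenate([np.zeros(40, int), np.ones(8, int)])
        data = Dataset(X, y)
        ens = train_ensemble(data, EnsembleConfig(N=5, seed=0))
        Xz = ens.transform(X)
        for m, idx in zip(ens.base_models, ens.subset_indices):
            assert (m.predict(Xz[idx]) == y[idx]).all()

    def test_single_model_ensemble_equals_undersampled_svm(self, imbalanced):
        tr, te = stratified_split(imbalanced, 0.3, seed=2)
        cfg = EnsembleConfig(N=1, alpha=0.5, seed=2)
        ens = train_ensemble(tr, cfg)
        pred = predict(ens, te.X)
        # fusing one model is exactly that model's calibrated decision
        single = ens.base_models[0]
        p = single.predict_proba(ens.transform(te.X))[:, list(single.classes_).index(1)]
        direct = (p >= 0.5).astype(int)
        np.testing.assert_array_equal(pred.labels, direct)

    def test_alpha_half_never_abstains(self, imbalanced):
        tr, te = stratified_split(imbalanced, 0.3, seed=3)
        ens = train_ensemble(tr, EnsembleConfig(N=5, alpha=0.5, seed=3))
        rep = evaluate(predict(ens, te.X), te.y)
        assert rep.predict_rate == 100.0

    def test_threshold_arithmetic_abstains(self):
        pred_labels = np.array([ABSTAIN])
        p = 0.55
        alpha = 0.6
        lab = 1 if p >= alpha else (0 if 1 - p >= alpha else ABSTAIN)
        assert lab == ABSTAIN == pred_labels[0]

    def test_predict_rate_nonincreasing_in_alpha(self, imbalanced):
        tr, te = stratified_split(imbalanced, 0.3, seed=4)
        ens = train_ensemble(tr, EnsembleConfig(N=7, seed=4))
        rates = []
        for a in np.arange(0.5, 0.91, 0.1):
            ens.config = dataclasses.replace(ens.config, alpha=float(a))
            rates.append(evaluate(predict(ens, te.X), te.y).predict_rate)
        assert all(b <= a + 1e-12 for a, b in zip(rates, rates[1:]))

    def test_determinism(self, imbalanced):
        tr, te = stratified_split(imbalanced, 0.3, seed=5)
        p1 = predict(train_ensemble(tr, EnsembleConfig(N=3, seed=5)), te.X)
        p2 = predict(train_ensemble(tr, EnsembleConfig(N=3, seed=5)), te.X)
        np.testing.assert_array_equal(p1.labels, p2.labels)
        np.testing.assert_array_equal(p1.p_positive, p2.p_positive)

    def test_vote_variance_decreases_with_n(self, imbalanced):
        """Mean-vote variance across reseeded ensembles shrinks from N=5 to 51."""
        tr, _ = stratified_split(imbalanced, 0.3, seed=6)
        small = Dataset(tr.X[:200], tr.y[:200]).ensure_positive_minority()
        x0 = tr.X[:1]
        variances = {}
        for n in (5, 51):
            votes = [predict(train_ensemble(
                small, EnsembleConfig(N=n, seed=s)), x0).p_positive[0]
                for s in range(15)]
            variances[n] = np.var(votes)
        assert variances[51] < variances[5]


class TestEvaluate:
    def test_worked_confusion_example(self):
        y_true = np.array([1, 1, 0, 0, 0, 1, 0])
        y_pred = np.array([1, 1, 0, 0, 0, 0, 1])
        rep = evaluate(PredictionResult(y_pred, y_pred.astype(float)), y_true)
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (2, 3, 1, 1)
        assert rep.accuracy == pytest.approx(71.43, abs=0.01)
        assert rep.sensitivity == pytest.approx(66.67, abs=0.01)
        assert rep.specificity == pytest.approx(75.00, abs=0.01)
        assert rep.f1 == pytest.approx(66.67, abs=0.01)
        assert rep.predict_rate == 100.0

    def test_predict_rate_with_abstentions(self):
        labels = np.array([1, 0, 1, ABSTAIN, ABSTAIN, ABSTAIN, 0, 1, 0, 1])
        rep = evaluate(PredictionResult(labels, np.zeros(10)), np.ones(10, int))
        assert rep.predict_rate == 70.0

    def test_matches_brute_force_on_random_cases(self, rng):
        """evaluate() equals an explicit loop on 1000 random prediction pairs."""
        labels = rng.choice([0, 1, ABSTAIN], size=1000, p=[0.4, 0.4, 0.2])
        truth = rng.integers(0, 2, size=1000)
        rep = evaluate(PredictionResult(labels, np.zeros(1000)), truth)
        tp = tn = fp = fn = 0
        for p, t in zip(labels, truth):
            if p == ABSTAIN:
                continue
            if p == 1 and t == 1:
                tp += 1
            elif p == 0 and t == 0:
                tn += 1
            elif p == 1 and t == 0:
                fp += 1
            else:
                fn += 1
        assert (rep.tp, rep.tn, rep.fp, rep.fn) == (tp, tn, fp, fn)
        assert rep.accuracy == pytest.approx(100 * (tp + tn) / (tp + tn + fp + fn))
        assert rep.predict_rate == pytest.approx(100 * (tp + tn + fp + fn) / 1000)

    def test_random_predictor_near_half_accuracy(self, rng):
        n = 1000
        labels = rng.integers(0, 2, size=n)
        truth = rng.integers(0, 2, size=n)
        rep = evaluate(PredictionResult(labels, np.zeros(n)), truth)
        se = 100 * 0.5 / np.sqrt(n)
        assert abs(rep.accuracy - 50.0) < 3 * se

    def test_all_abstained_flagged(self):
        labels = np.full(5, ABSTAIN)
        rep = evaluate(PredictionResult(labels, np.zeros(5)), np.ones(5, int))
        assert rep.all_abstained and np.isnan(rep.accuracy)


class TestImbalanceBenefit:
    def test_sensitivity_gain_over_single_svm(self):
        """10:1 Gaussians: the balanced ensemble recovers minority sensitivity
        that a single SVM on the imbalanced training set misses."""
        gains, spec_losses = [], []
        for rep_i in range(5):
            data = gen_imbalanced_gaussians(91, 909, 10, 2.0, seed=100 + rep_i)
            tr, te = stratified_split(data, 0.3, seed=rep_i)
            cfg = EnsembleConfig(N=11, alpha=0.5, seed=rep_i)
            ens_rep = evaluate(predict(train_ensemble(tr, cfg), te.X), te.y)
            svm, tf = fit_single_svm(tr, cfg)
            yp = svm.predict(tf(te.X))
            svm_rep = evaluate(PredictionResult(yp, yp.astype(float)), te.y)
            gains.append(ens_rep.sensitivity - svm_rep.sensitivity)
            spec_losses.append(svm_rep.specificity - ens_rep.specificity)
        assert np.mean(gains) >= 15.0
        assert np.mean(spec_losses) < np.mean(gains)


class TestRunTask:
    def test_doc_task_class_sizes(self, table1_cohort):
        features, labels = table1_cohort
        data = build_task_dataset(features, labels, "doc")
        assert data.n_positive == 97 and data.n_negative == 144

    def test_motor_lr_class_sizes(self, table1_cohort):
        features, labels = table1_cohort
        data = build_task_dataset(features, labels, "motor_LR")
        # DoC excluded: 37 left vs 46 right; minority (left) is positive
        assert data.n_positive == 37 and data.n_negative == 46

    def test_location_tasks_class_sizes(self, table1_cohort):
        features, labels = table1_cohort
        lr = build_task_dataset(features, labels, "location_LR")
        assert {lr.n_positive, lr.n_negative} == {52, 47}
        sb = build_task_dataset(features, labels, "location_single_bilateral")
        assert sb.n_positive == 36 and sb.n_negative == 99

    def test_single_repeat_reproducible(self, table1_cohort):
        features, labels = table1_cohort
        cfg = EnsembleConfig(N=3, repeats=1, seed=11)
        r1 = run_task(features, labels, "doc", cfg)
        r2 = run_task(features, labels, "doc", cfg)
        assert r1.to_dict() == r2.to_dict()

    def test_unknown_task_rejected(self, table1_cohort):
        features, labels = table1_cohort
        with pytest.raises(ValueError):
            run_task(features, labels, "aphasia", EnsembleConfig())
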