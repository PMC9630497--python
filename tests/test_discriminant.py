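"""PCA, Gaussian discriminant flavors, exhaustive search, CV, ROC."""

import itertools

import numpy as np
import pytest

from ramanfuse.discriminant import (
    FLAVORS,
    CandidateSpec,
    ConfusionTable,
    _folds,
    confusion_from_predictions,
    enumerate_candidates,
    evaluate_candidate,
    fit_discriminant,
    fit_pca,
    roc_auc,
    search_candidates,
    select_best,
)


class TestPCA:
    def test_forced_geometry_diagonal_cloud(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        X = np.column_stack([t, t]) + rng.normal(0, 1e-6, (200, 2))
        m = fit_pca(X)
        np.testing.assert_allclose(np.abs(m.loadings[0]), [2**-0.5] * 2, atol=1e-4)
        assert m.explained_variance_ratio[0] > 0.999999

    def test_reconstruction_complete(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 20))
        m = fit_pca(X)
        np.testing.assert_allclose(m.inverse_transform(m.scores), X, atol=1e-8)

    def test_explained_variance_matches_eig_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.normal(size=(10, 20))
            m = fit_pca(X)
            evals = np.sort(np.linalg.eigvalsh(np.cov(X, rowvar=False)))[::-1]
            ratios = evals[: len(m.explained_variance_ratio)] / evals.sum()
            np.testing.assert_allclose(m.explained_variance_ratio, ratios, atol=1e-8)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(3)
        m = fit_pca(rng.normal(size=(15, 30)))
        G = m.loadings @ m.loadings.T
        np.testing.assert_allclose(G, np.eye(G.shape[0]), atol=1e-8)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_pca(np.ones((5, 4)))


class TestEnumerate:
    def test_counts(self):
        assert len(enumerate_candidates(5)) == 6 * 31
        assert len(enumerate_candidates(1, ["linear"])) == 1

    def test_no_duplicates_and_deterministic(self):
        c1 = enumerate_candidates(4)
        c2 = enumerate_candidates(4)
        assert c1 == c2
        assert len(set(c1)) == len(c1)


class TestFitDiscriminant:
    def _planted(self, rng, sep=5.0, n=50, d=1):
        X = np.vstack([rng.normal(-sep, 1, (n, d)), rng.normal(sep, 1, (n, d))])
        y = np.array(["control"] * n + ["cancer"] * n, dtype=object)
        return X, y

    @pytest.mark.parametrize("flavor", FLAVORS)
    def test_separated_classes_perfect_training_accuracy(self, flavor):
        rng = np.random.default_rng(4)
        X, y = self._planted(rng, d=2)
        m = fit_discriminant(X, y, flavor)
        assert (m.predict(X) == y).all()

    def test_identical_distributions_chance_level(self):
        rng = np.random.default_rng(5)
        accs = []
        for _ in range(50):
            X = rng.normal(size=(60, 2))
            y = np.array(["cancer"] * 36 + ["control"] * 24, dtype=object)
            m = fit_discriminant(X, y, "linear")
            accs.append((m.predict(X) == y).mean())
        assert abs(np.mean(accs) - 0.6) < 0.1

    def test_linear_boundary_shift_invariant(self):
        rng = np.random.default_rng(6)
        X, y = self._planted(rng, sep=1.0, d=3)
        m1 = fit_discriminant(X, y, "linear")
        m2 = fit_discriminant(X + 100.0, y, "linear")
        assert (m1.predict(X) == m2.predict(X + 100.0)).all()

    def test_singular_covariance_directs_to_pseudo(self):
        rng = np.random.default_rng(20)
        X = np.zeros((10, 3))
        X[:, 0] = rng.normal(size=10)
        X[:5, 0] += 4.0
        # third coordinate constant: per-class covariance is singular
        y = np.array(["cancer"] * 5 + ["control"] * 5, dtype=object)
        with pytest.raises(np.linalg.LinAlgError, match="pseudo"):
            fit_discriminant(X, y, "quadratic")
        m = fit_discriminant(X, y, "pseudoquadratic")  # succeeds
        assert (m.predict(X) == y).all()

    def test_matches_sklearn_lda_predictions(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(7)
        X = rng.normal(size=(40, 3))
        X[:20] += 0.8
        y = np.array(["cancer"] * 20 + ["control"] * 20, dtype=object)
        ours = fit_discriminant(X, y, "linear").predict(X)
        sk = LinearDiscriminantAnalysis(solver="svd").fit(X, y).predict(X)
        assert (ours == sk).mean() == 1.0

    def test_matches_sklearn_qda_predictions(self):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 3))
        X[:30] *= 2.0
        X[:30] += 0.5
        y = np.array(["cancer"] * 30 + ["control"] * 30, dtype=object)
        ours = fit_discriminant(X, y, "quadratic").predict(X)
        sk = QuadraticDiscriminantAnalysis(store_covariance=True).fit(X, y).predict(X)
        assert (ours == sk).mean() == 1.0


class TestConfusion:
    def test_arithmetic_from_definition(self):
        ct = ConfusionTable(tp=26, fn=1, tn=18, fp=3)
        assert ct.sensitivity == pytest.approx(26 / 27)
        assert ct.specificity == pytest.approx(18 / 21)
        assert ct.accuracy == pytest.approx(44 / 48)
        assert ct.total == 48


class TestEvaluate:
    def test_perfect_classifier_lopo_no_errors(self):
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(-3, 0.3, (12, 30)), rng.normal(3, 0.3, (12, 30))])
        y = ["control"] * 12 + ["cancer"] * 12
        ct, _, _ = evaluate_candidate(
            X, y, CandidateSpec("linear", (1,)), "leave_one_patient_out", 3
        )
        assert ct.fp == 0 and ct.fn == 0

    def test_each_sample_validated_once(self):
        y = ["cancer"] * 6 + ["control"] * 6
        seen = []
        for tr, te in _folds(y, None, "leave_one_patient_out"):
            seen.extend(te.tolist())
        assert sorted(seen) == list(range(12))

    def test_permuted_labels_near_majority_rate(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(24, 30))
        labels = np.array(["cancer"] * 14 + ["control"] * 10, dtype=object)
        accs = []
        for _ in range(50):
            perm = rng.permutation(labels)
            ct, _, _ = evaluate_candidate(
                X, perm, CandidateSpec("linear", (1, 2)), "leave_one_patient_out", 2
            )
            accs.append(ct.accuracy)
        assert abs(np.mean(accs) - 14 / 24) < 0.1

    def test_cv_invariant_to_sample_order(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(20, 15))
        X[:10] += 1.0
        y = np.array(["cancer"] * 10 + ["control"] * 10, dtype=object)
        ct1, _, _ = evaluate_candidate(X, y, CandidateSpec("linear", (1, 2)),
                                       "leave_one_patient_out", 3)
        perm = rng.permutation(20)
        ct2, _, _ = evaluate_candidate(X[perm], y[perm], CandidateSpec("linear", (1, 2)),
                                       "leave_one_patient_out", 3)
        assert (ct1.tp, ct1.fp, ct1.tn, ct1.fn) == (ct2.tp, ct2.fp, ct2.tn, ct2.fn)


class TestSelectBest:
    def test_argmin_errors(self, tiny_results=None):
        import pandas as pd

        df = pd.DataFrame([
            dict(flavor="linear", pc_subset="1", n_pcs=1, tp=1, fp=2, tn=1, fn=1,
                 errors=3, sensitivity=0.5, specificity=0.3, accuracy=0.4),
            dict(flavor="quadratic", pc_subset="1,2", n_pcs=2, tp=2, fp=0, tn=1, fn=1,
                 errors=1, sensitivity=0.7, specificity=1.0, accuracy=0.75),
            dict(flavor="linear", pc_subset="2", n_pcs=1, tp=2, fp=1, tn=1, fn=1,
                 errors=2, sensitivity=0.7, specificity=0.5, accuracy=0.6),
        ])
        assert select_best(df)["errors"] == 1

    def test_tie_breaks_toward_fewer_pcs(self):
        import pandas as pd

        rows = [
            dict(flavor="linear", pc_subset="1,2,3", n_pcs=3, tp=2, fp=1, tn=2, fn=0,
                 errors=1, sensitivity=1, specificity=0.7, accuracy=0.8),
            dict(flavor="linear", pc_subset="1,2", n_pcs=2, tp=2, fp=1, tn=2, fn=0,
                 errors=1, sensitivity=1, specificity=0.7, accuracy=0.8),
        ]
        best = select_best(pd.DataFrame(rows))
        assert best["pc_subset"] == "1,2"

    def test_planted_signal_subset_recovered(self):
        # class signal only along the top-variance directions mapping to PCs 1-2
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.array(["cancer"] * 24 + ["control"] * 16, dtype=object)
            cls = (y == "cancer").astype(float)
            X = rng.normal(0, 0.3, (n, 30))
            X[:, 0] += 4 * rng.normal(size=n) + 2.2 * cls  # PC1: big variance + signal
            X[:, 1] += 2.5 * rng.normal(size=n) + 1.6 * cls  # PC2
            table = search_candidates(X, y, K=3, scheme="stratified_kfold")
            best = select_best(table)
            subset = {int(i) for i in best["pc_subset"].split(",")}
            if subset <= {1, 2}:
                hits += 1
        assert hits >= 14

    def test_exhaustive_search_equals_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(3):
            X = rng.normal(size=(16, 12))
            X[:8] += 0.7
            y = np.array(["cancer"] * 8 + ["control"] * 8, dtype=object)
            table = search_candidates(X, y, K=3, scheme="resubstitution")
            # naive: refit every candidate from scratch
            best_naive, best_err = None, None
            p = fit_pca(X, 3)
            for flavor in FLAVORS:
                for r in range(1, 4):
                    for subset in itertools.combinations(range(1, 4), r):
                        cols = np.array(subset) - 1
                        m = fit_discriminant(p.scores[:, cols], y, flavor)
                        err = int((m.predict(p.scores[:, cols]) != y).sum())
                        key = (err, len(subset), FLAVORS.index(flavor), subset)
                        if best_err is None or key < best_err:
                            best_err, best_naive = key, (flavor, subset)
            best = select_best(table)
            assert best["flavor"] == best_naive[0]
            assert tuple(int(i) for i in best["pc_subset"].split(",")) == best_naive[1]


class TestROC:
    def test_perfect_order_auc_one(self):
        roc = roc_auc([0.9, 0.8, 0.2, 0.1], ["cancer", "cancer", "control", "control"])
        assert roc.auc == pytest.approx(1.0)

    def test_pair_counting_example(self):
        roc = roc_auc([0.9, 0.4, 0.6, 0.2], ["cancer", "cancer", "control", "control"])
        assert roc.auc == pytest.approx(0.75)

    def test_label_inversion_complements_auc(self):
        rng = np.random.default_rng(13)
        scores = rng.normal(size=30)
        labels = np.array(["cancer"] * 15 + ["control"] * 15, dtype=object)
        a = roc_auc(scores, labels).auc
        b = roc_auc(scores, np.where(labels == "cancer", "control", "cancer")).auc
        assert a + b == pytest.approx(1.0)

    def test_trapezoid_equals_pair_statistic(self):
        rng = np.random.default_rng(14)
        for _ in range(100):
            n1, n0 = rng.integers(3, 15), rng.integers(3, 15)
            scores = np.round(rng.normal(size=n1 + n0), 1)  # force ties
            labels = np.array(["cancer"] * n1 + ["control"] * n0, dtype=object)
            auc = roc_auc(scores, labels).auc
            pos, neg = scores[:n1], scores[n1:]
            gt = (pos[:, None] > neg[None]).sum()
            eq = (pos[:, None] == neg[None]).sum()
            mw = (gt + 0.5 * eq) / (n1 * n0)
            assert auc == pytest.approx(mw, abs=1e-12)

    def test_one_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], ["cancer", "cancer"])

    def test_curve_monotone_from_origin_to_one(self):
        rng = np.random.default_rng(15)
        scores = rng.normal(size=40)
        labels = np.array(["cancer"] * 22 + ["control"] * 18, dtype=object)
        roc = roc_auc(scores, labels)
        assert roc.fpr[0] == 0 and roc.tpr[0] == 0
        assert roc.fpr[-1] == 1 and roc.tpr[-1] == 1
        assert np.all(np.diff(roc.fpr) >= 0) and np.all(np.diff(roc.tpr) >= 0)
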