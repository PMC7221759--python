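"""PLS-DA: dummy coding, the NIPALS core against least-squares and reference
oracles, the argmax decision rule, VIP identities, accuracy bookkeeping and
cross-validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from numpy.testing import assert_allclose
from sklearn.cross_decomposition import PLSRegression

from gamenir import ConfusionMatrix, PLSDAClassifier, cross_validate, dummy_code, loocv
from gamenir.plsda import accuracy_percent, nipals_pls2


def two_class_toy(n=30, gap=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, 8))
    y = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
    X[y == "b", 0] += gap
    return X, y


class TestDummyCode:
    def test_indicator_rows(self):
        Y = dummy_code(["A", "B", "A"], ["A", "B"])
        assert_allclose(Y, [[1, 0], [0, 1], [1, 0]])

    @given(st.lists(st.sampled_from(["a", "b", "c"]), min_size=1, max_size=30))
    def test_row_and_column_sums(self, labels):
        Y = dummy_code(labels, ["a", "b", "c"])
        assert_allclose(Y.sum(axis=1), 1.0)
        for c, cls in enumerate(["a", "b", "c"]):
            assert Y[:, c].sum() == labels.count(cls)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="z"):
            dummy_code(["a", "z"], ["a", "b"])


class TestNipalsCore:
    def test_full_rank_equals_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        xm, ym, W, P, Q, T = nipals_pls2(X, y[:, None], 6)
        B = W @ np.linalg.inv(P.T @ W) @ Q.T
        bls, *_ = np.linalg.lstsq(X - X.mean(0), y - y.mean(), rcond=None)
        assert_allclose(B.ravel(), bls, atol=1e-8)

    def test_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(25, 10))
        Y = dummy_code(rng.choice(list("ab"), 25), ["a", "b"])
        *_, T = nipals_pls2(X, Y, 5)
        G = T.T @ T
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8

    def test_informative_channel_dominates_first_weight(self):
        X, y = two_class_toy(gap=10.0)
        model = PLSDAClassifier(n_components=2).fit(X, y)
        assert np.argmax(np.abs(model.x_weights_[:, 0])) == 0

    def test_coefficients_reproduce_deflation_fit(self):
        # two-way assembly: scores*loadings route == B route
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 7))
        y = rng.choice(list("abc"), 20)
        model = PLSDAClassifier(n_components=4).fit(X, y)
        via_scores = model.x_scores_ @ model.y_loadings_.T + model.y_mean_
        via_B = model.decision_function(X)
        assert np.abs(via_scores - via_B).max() < 1e-8

    @pytest.mark.parametrize("lv", [1, 2, 3, 5])
    def test_matches_reference_pls_predictions(self, lv):
        # sklearn's NIPALS is the independent oracle; its inner tolerance is
        # on the squared step, so it must be tightened for the comparison
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 20))
        y = rng.choice(list("abc"), 40)
        Y = dummy_code(y, ["a", "b", "c"])
        mine = PLSDAClassifier(n_components=lv).fit(X, y)
        ref = PLSRegression(n_components=lv, scale=False,
                            tol=1e-24, max_iter=20000).fit(X, Y)
        assert np.abs(mine.decision_function(X) - ref.predict(X)).max() < 1e-6

    def test_zero_variance_x_rejected(self):
        with pytest.raises(ValueError):
            nipals_pls2(np.ones((10, 4)), np.arange(10.0)[:, None], 1)

    def test_nonconvergence_raises(self):
        # late LVs on structureless data have a vanishing eigen-gap
        rng = np.random.default_rng(0)
        X = rng.normal(size=(40, 20))
        Y = dummy_code(rng.choice(list("abc"), 40), ["a", "b", "c"])
        with pytest.raises(RuntimeError, match="converge"):
            nipals_pls2(X, Y, 8)


class TestPredict:
    def test_separable_toy_is_perfect_on_training_data(self):
        X, y = two_class_toy()
        model = PLSDAClassifier(n_components=2).fit(X, y)
        assert (model.predict(X) == y).all()

    def test_centroid_sample_predicts_class_priors(self):
        X, y = two_class_toy()
        model = PLSDAClassifier(n_components=2).fit(X, y)
        yhat = model.decision_function(X.mean(0, keepdims=True))
        assert_allclose(yhat[0], model.y_mean_, atol=1e-12)

    def test_prediction_is_deterministic(self, small_dataset):
        X = small_dataset.X
        y = small_dataset.meta["species"].to_numpy()
        a = PLSDAClassifier(n_components=3).fit(X, y).predict(X)
        b = PLSDAClassifier(n_components=3).fit(X, y).predict(X)
        assert (a == b).all()

    def test_channel_mismatch_rejected(self):
        X, y = two_class_toy()
        model = PLSDAClassifier(n_components=2).fit(X, y)
        with pytest.raises(ValueError, match="channel"):
            model.predict(X[:, :5])

    def test_threshold_rule_two_classes(self):
        X, y = two_class_toy()
        model = PLSDAClassifier(n_components=2, decision_rule="threshold").fit(X, y)
        assert (model.predict(X) == y).all()

    def test_threshold_rule_needs_two_classes(self, small_dataset):
        model = PLSDAClassifier(n_components=2, decision_rule="threshold")
        model.fit(small_dataset.X, small_dataset.meta["species"].to_numpy())
        with pytest.raises(ValueError):
            model.predict(small_dataset.X)


class TestVip:
    def test_mean_squared_vip_is_one(self, small_dataset):
        model = PLSDAClassifier(n_components=5).fit(
            small_dataset.X, small_dataset.meta["species"].to_numpy())
        assert (model.vip() ** 2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_lv_closed_form(self):
        X, y = two_class_toy()
        model = PLSDAClassifier(n_components=1).fit(X, y)
        w = model.x_weights_[:, 0]
        expected = np.sqrt(len(w)) * np.abs(w) / np.linalg.norm(w)
        assert_allclose(model.vip(), expected, atol=1e-10)

    def test_discriminating_channel_scores_above_one(self):
        X, y = two_class_toy(gap=8.0)
        model = PLSDAClassifier(n_components=2).fit(X, y)
        vip = model.vip()
        assert vip[0] > 1.0
        assert vip[0] == vip.max()


class TestConfusionAndAccuracy:
    def test_counts_and_one_vs_rest_bookkeeping(self):
        cm = ConfusionMatrix.from_labels(
            ["a", "a", "b", "b", "c"], ["a", "b", "b", "b", "a"], ["a", "b", "c"])
        assert cm.n_total == 5 and cm.n_correct == 3
        for cls in "abc":
            c = cm.one_vs_rest(cls)
            assert c["TP"] + c["TN"] + c["FP"] + c["FN"] == 5

    def test_all_correct_matrix_is_100_percent(self):
        cm = ConfusionMatrix.from_labels(["a", "b"], ["a", "b"], ["a", "b"])
        assert cm.accuracy() == 100.0
        assert cm.accuracy("a") == 100.0

    def test_overall_accuracy_complements_misclassification(self):
        rng = np.random.default_rng(3)
        y = rng.choice(list("abc"), 60)
        p = rng.choice(list("abc"), 60)
        cm = ConfusionMatrix.from_labels(y, p, list("abc"))
        assert cm.accuracy() == pytest.approx(100.0 * (1 - np.mean(y != p)))

    def test_empty_matrix_rejected(self):
        cm = ConfusionMatrix(np.zeros((2, 2), dtype=int), ["a", "b"])
        with pytest.raises(ValueError):
            cm.accuracy()

    def test_count_pair_accuracy(self):
        assert accuracy_percent(219, 235) == pytest.approx(93.19148936, abs=1e-6)
        with pytest.raises(ValueError):
            accuracy_percent(1, 0)


class TestCrossValidation:
    def test_separable_toy_is_perfect_under_loocv(self):
        X, y = two_class_toy(gap=8.0)
        cm, pred = loocv(X, y, n_lv=2)
        assert cm.accuracy() == 100.0
        assert (pred == y).all()

    def test_loocv_not_better_than_calibration_on_average(self):
        # statistical ordering over 20 seeds at a moderate signal level
        diffs = []
        for seed in range(20):
            X, y = two_class_toy(n=40, gap=1.5, seed=seed)
            model = PLSDAClassifier(n_components=3).fit(X, y)
            cal = 100.0 * (model.predict(X) == y).mean()
            cv = loocv(X, y, n_lv=3)[0].accuracy()
            diffs.append(cal - cv)
        assert np.mean(diffs) >= 0.0

    def test_venetian_blinds_scheme_runs(self):
        X, y = two_class_toy(gap=8.0)
        cm, _ = cross_validate(X, y, n_lv=2, scheme="venetian:5")
        assert cm.accuracy() == 100.0

    def test_leave_one_animal_out_grouping(self, small_dataset):
        sub = small_dataset.select(
            small_dataset.meta["species"].to_numpy() == "ostrich")
        cm, _ = cross_validate(sub.X, sub.meta["muscle"].to_numpy(), n_lv=2,
                               groups=sub.meta["animal_id"].to_numpy())
        assert cm.n_total == sub.n_samples

    def test_unknown_scheme_rejected(self):
        X, y = two_class_toy()
        with pytest.raises(ValueError):
            cross_validate(X, y, n_lv=2, scheme="bootstrap")

    def test_too_few_samples_rejected(self):
        X, y = two_class_toy(n=3)
        with pytest.raises(ValueError):
            loocv(X, y, n_lv=1)
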