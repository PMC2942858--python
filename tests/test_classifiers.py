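import numpy as np
import pytest

from classpower import (
    CASE,
    CONTROL,
    ClassifierSpec,
    LabeledDataset,
    fit_predict_score,
    nsc_fit,
    nsc_threshold_grid,
    rf_permutation_importance,
)
from conftest import SEED, toy_dataset

ALL_KINDS = ["knn", "nsc", "rf", "svm"]
SMALL_RF = dict(rf_trees=60)


def spec_for(kind, **kw):
    if kind == "rf":
        kw = {**SMALL_RF, **kw}
    return ClassifierSpec(kind=kind, **kw)


class TestCommonContract:
    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_separable_data_classified_perfectly(self, kind, separable):
        train = LabeledDataset(separable.X[::2], separable.y[::2])
        labels, _ = fit_predict_score(spec_for(kind), train,
                                      separable.X[1::2], seed=SEED)
        assert np.mean(labels == separable.y[1::2]) == 1.0

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_permuted_labels_give_chance_accuracy(self, kind):
        rng = np.random.default_rng(SEED)
        X = rng.normal(0, 1, (120, 20))
        y01 = rng.permutation(np.repeat([0, 1], 60))
        train = toy_dataset(X[:80], y01[:80])
        labels, scores = fit_predict_score(spec_for(kind), train, X[80:], seed=SEED)
        acc = np.mean(labels == np.where(y01[80:] == 1, CASE, CONTROL))
        assert 0.25 <= acc <= 0.75
        assert np.all(np.isfinite(scores))

    @pytest.mark.parametrize("kind", ALL_KINDS)
    def test_scores_reproduce_labels(self, kind, small_gaussian):
        train = LabeledDataset(small_gaussian.X[:40], small_gaussian.y[:40])
        labels, scores = fit_predict_score(spec_for(kind), train,
                                           small_gaussian.X[40:], seed=SEED)
        boundary = 0.5 if kind in ("knn", "rf") else 0.0
        np.testing.assert_array_equal(
            labels, np.where(scores >= boundary, CASE, CONTROL)
        )

    def test_feature_mismatch_rejected(self, small_gaussian):
        with pytest.raises(ValueError, match="features"):
            fit_predict_score(spec_for("knn"), small_gaussian,
                              small_gaussian.X[:, :5])

    def test_single_class_train_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(ValueError, match="class"):
            fit_predict_score(spec_for("knn"), toy_dataset(X, np.ones(10)), X)


class TestKnn:
    def test_five_neighbor_vote_on_toy_line(self):
        # neighbors of 1.05 by distance: 1.0, 1.1, 1.2 (case), 0.2, 0.1
        # -> exhaustive enumeration gives a 3/5 case fraction
        train = toy_dataset([[0.0], [0.1], [0.2], [1.0], [1.1], [1.2]],
                            [0, 0, 0, 1, 1, 1])
        labels, scores = fit_predict_score(spec_for("knn"), train, [[1.05]])
        assert labels[0] == CASE
        assert scores[0] == pytest.approx(3 / 5)


class TestShrunkenCentroid:
    def test_zero_threshold_equals_plain_nearest_centroid(self, small_gaussian):
        model = nsc_fit(small_gaussian, 0.0)
        np.testing.assert_array_equal(model.d_shrunk, model.d)
        # oracle: plain diagonal nearest-centroid discriminant by hand
        X, y01 = small_gaussian.X, (small_gaussian.y == CASE).astype(int)
        cent = np.vstack([X[y01 == 0].mean(0), X[y01 == 1].mean(0)])
        np.testing.assert_allclose(model.shrunken_centroids, cent, atol=1e-10)
        sw = model.pooled_sd + model.s0
        pri = np.array([(y01 == 0).mean(), (y01 == 1).mean()])
        disc = np.stack(
            [(((X - cent[k]) / sw) ** 2).sum(1) - 2 * np.log(pri[k])
             for k in range(2)], axis=1,
        )
        expected = np.where(disc[:, 1] < disc[:, 0], CASE, CONTROL)
        np.testing.assert_array_equal(model.predict(X), expected)

    def test_full_shrinkage_leaves_priors_only(self):
        rng = np.random.default_rng(SEED)
        X = rng.normal(size=(30, 8))
        train = toy_dataset(X, np.r_[np.ones(10), np.zeros(20)])
        model = nsc_fit(train, delta_threshold=np.abs(
            nsc_fit(train, 0.0).d).max() + 1.0)
        assert np.all(model.d_shrunk == 0.0)
        assert len(model.active_features()) == 0
        # every prediction goes to the majority (higher-prior) class
        assert np.all(model.predict(rng.normal(size=(15, 8))) == CONTROL)

    def test_two_feature_toy_centroid_differences(self):
        # feature 1 separates the classes, feature 2 has identical centroids
        train = toy_dataset([[0, 0], [0, 2], [2, 0], [2, 2]], [0, 0, 1, 1])
        model = nsc_fit(train, 0.0)
        assert np.all(model.d[:, 0] != 0.0)
        np.testing.assert_array_equal(model.d[:, 1], 0.0)
        assert 1 not in nsc_fit(train, 1e-9).active_features()

    def test_shrinkage_invariants(self, small_gaussian):
        d0 = nsc_fit(small_gaussian, 0.0).d
        grid = nsc_threshold_grid(small_gaussian, 12)
        counts = []
        for t in grid:
            m = nsc_fit(small_gaussian, t)
            assert np.all(np.abs(m.d_shrunk) <= np.abs(d0) + 1e-12)
            assert np.all(m.d_shrunk[np.abs(d0) <= t] == 0.0)
            counts.append(len(m.active_features()))
        assert counts == sorted(counts, reverse=True)  # monotone in threshold
        assert counts[-1] == 0

    def test_zero_variance_feature_handled(self):
        X = np.random.default_rng(SEED).normal(size=(20, 4))
        X[:, 2] = 3.14
        train = toy_dataset(X, np.repeat([0, 1], 10))
        model = nsc_fit(train, 0.0)
        assert np.all(np.isfinite(model.d))
        assert np.all(np.isfinite(model.decision_scores(X)))


class TestPriorPolicy:
    @pytest.mark.parametrize("kind", ["nsc", "rf"])
    def test_balanced_classes_prior_neutral(self, kind, small_gaussian):
        test_X = small_gaussian.X + 0.1
        out = {}
        for policy in ("empirical", "equal"):
            labels, scores = fit_predict_score(
                spec_for(kind, prior_policy=policy), small_gaussian,
                test_X, seed=SEED,
            )
            out[policy] = (labels, scores)
        np.testing.assert_array_equal(out["empirical"][0], out["equal"][0])
        np.testing.assert_allclose(out["empirical"][1], out["equal"][1])

    def test_equal_priors_shift_nsc_decision_on_unbalanced_data(self):
        rng = np.random.default_rng(SEED)
        X = rng.normal(size=(90, 5))
        train = toy_dataset(X, np.r_[np.ones(30), np.zeros(60)])
        emp = nsc_fit(train, 0.0, "empirical")
        eq = nsc_fit(train, 0.0, "equal")
        np.testing.assert_array_equal(eq.priors, [0.5, 0.5])
        # equal priors remove the majority-class pull
        assert np.mean(eq.decision_scores(X)) > np.mean(emp.decision_scores(X))


class TestForestImportance:
    def test_deterministic_given_seed(self, small_gaussian):
        spec = spec_for("rf")
        a = rf_permutation_importance(small_gaussian, spec, seed=SEED)
        b = rf_permutation_importance(small_gaussian, spec, seed=SEED)
        np.testing.assert_array_equal(a, b)
        c = rf_permutation_importance(small_gaussian, spec, seed=SEED + 1)
        assert not np.array_equal(a, c)

    def test_decisive_feature_ranks_first(self):
        # one perfectly class-determining feature among 99 noise features
        rng = np.random.default_rng(SEED)
        wins = 0
        for trial in range(20):
            X = rng.normal(size=(60, 100))
            y01 = np.repeat([0, 1], 30)
            X[:, 37] = y01 * 2.0 - 1.0
            imp = rf_permutation_importance(
                toy_dataset(X, y01), spec_for("rf", rf_trees=100),
                seed=SEED + trial,
            )
            wins += int(np.argmax(imp) == 37)
        assert wins >= 19

    def test_matches_reference_r_implementation(self, tmp_path):
        """OOB permutation importance agrees with R's randomForest.

        Same data, independent implementations: the importance rankings
        should be strongly correlated and agree on the decisive features.
        """
        import subprocess

        rng = np.random.default_rng(SEED)
        X = rng.normal(size=(80, 15))
        y01 = np.repeat([0, 1], 40)
        X[:, 3] += y01 * 1.5
        X[:, 11] += y01 * 1.0
        data = toy_dataset(X, y01)
        imp = rf_permutation_importance(data, spec_for("rf", rf_trees=500),
                                        seed=SEED)

        csv = tmp_path / "data.csv"
        out = tmp_path / "imp.csv"
        np.savetxt(csv, np.column_stack([X, y01]), delimiter=",")
        script = tmp_path / "imp.R"
        script.write_text(
            "suppressMessages(library(randomForest))\n"
            f"d <- read.csv('{csv}', header=FALSE)\n"
            "x <- d[, 1:15]; y <- factor(d[[16]])\n"
            "set.seed(1)\n"
            "fit <- randomForest(x, y, ntree=1000, importance=TRUE)\n"
            "imp <- importance(fit, type=1, scale=FALSE)\n"
            f"write.csv(data.frame(imp=imp[,1]), '{out}', row.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True,
                       capture_output=True, timeout=300)
        r_imp = np.loadtxt(out, skiprows=1)
        from scipy.stats import spearmanr

        assert set(np.argsort(-imp)[:2]) == set(np.argsort(-r_imp)[:2]) == {3, 11}
        assert spearmanr(imp, r_imp).statistic > 0.6

    def test_noise_importances_center_at_zero(self, noise_only):
        imp = rf_permutation_importance(noise_only, spec_for("rf", rf_trees=200),
                                        seed=SEED)
        assert np.any(imp < 0) and np.any(imp > 0)
        assert abs(np.mean(imp)) < 0.02
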