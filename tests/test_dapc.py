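"""PCA, stepwise PC selection, QDA posteriors, metrics, splits and fusion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from ramancharm.dapc import (
    DAPC,
    FusedDAPC,
    comparator_fit_predict,
    evaluate,
    fit_pca,
    fit_qda,
    holdback_split,
    predict_qda,
    select_pcs,
)


class TestPCA:
    def test_rank_one_data_has_single_component(self, rng):
        direction = rng.standard_normal(5)
        X = np.outer(rng.standard_normal(20), direction)
        pca = fit_pca(X)
        assert pca.explained_variance[0] > 1e-6
        assert np.all(pca.explained_variance[1:] <= 1e-10)

    def test_loadings_orthonormal(self, rng):
        pca = fit_pca(rng.standard_normal((50, 20)))
        gram = pca.loadings.T @ pca.loadings
        np.testing.assert_allclose(gram, np.eye(pca.n_components), atol=1e-8)

    def test_full_rank_reconstruction(self, rng):
        X = rng.standard_normal((15, 8))
        pca = fit_pca(X)
        scores = pca.transform(X)
        back = scores @ pca.loadings.T + pca.mean
        np.testing.assert_allclose(back, X, atol=1e-8)

    def test_variances_non_increasing_and_sign_fixed(self, rng):
        X = rng.standard_normal((40, 10))
        pca = fit_pca(X)
        assert np.all(np.diff(pca.explained_variance) <= 1e-12)
        for j in range(pca.n_components):
            col = pca.loadings[:, j]
            assert col[np.abs(col).argmax()] > 0

    def test_nonfinite_rejected(self):
        X = np.ones((5, 3))
        X[0, 0] = np.inf
        with pytest.raises(ValueError):
            fit_pca(X)


class TestSelectPCs:
    def test_alpha_one_selects_all(self, rng):
        S = rng.standard_normal((30, 4))
        y = np.repeat(["a", "b", "c"], 10)
        assert sorted(select_pcs(S, y, alpha=1.0)) == [0, 1, 2, 3]

    def test_planted_pc_selected_first(self, rng):
        S = rng.standard_normal((72, 6))
        y = np.repeat(["a", "b", "c"], 24)
        shift = {"a": -3.0, "b": 0.0, "c": 3.0}
        S[:, 4] += np.array([shift[l] for l in y])
        selected = select_pcs(S, y, alpha=0.001)
        assert selected[0] == 4

    def test_null_selection_rate_controlled(self):
        # permuted labels: expected selections per run well below 0.1
        count = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            S = r.standard_normal((36, 8))
            y = r.permutation(np.repeat(["a", "b", "c"], 12))
            count += len(select_pcs(S, y, alpha=0.001))
        assert count / 20 <= 0.1

    def test_duplicate_pc_never_joins_its_copy(self, rng):
        S = rng.standard_normal((36, 2))
        y = np.repeat(["a", "b", "c"], 12)
        S[:, 0] += np.array([{"a": -3.0, "b": 0.0, "c": 3.0}[l] for l in y])
        S = np.hstack([S[:, :1], S[:, :1]])  # exact duplicate column
        selected = select_pcs(S, y, alpha=0.5)
        assert len(selected) == 1

    def test_anova_criterion_marginal(self, rng):
        S = rng.standard_normal((36, 3))
        y = np.repeat(["a", "b", "c"], 12)
        S[:, 1] += np.array([{"a": -4.0, "b": 0.0, "c": 4.0}[l] for l in y])
        assert select_pcs(S, y, alpha=0.001, criterion="anova") == [1]


class TestQDA:
    def test_two_gaussians_boundary_at_midpoint(self, rng):
        X = np.vstack([
            rng.standard_normal((40, 2)),
            rng.standard_normal((40, 2)) + np.array([4.0, 0.0]),
        ])
        y = np.array(["a"] * 40 + ["b"] * 40)
        qda = fit_qda(X, y, reg_gamma=0.0)
        labels, _ = predict_qda(qda, np.array([[0.5, 0.0], [3.5, 0.0]]))
        assert list(labels) == ["a", "b"]

    def test_gamma_one_gives_diagonal_covariances(self, rng):
        X = rng.standard_normal((30, 3)) @ rng.standard_normal((3, 3))
        y = np.repeat(["a", "b"], 15)
        qda = fit_qda(X, y, reg_gamma=1.0)
        for S in qda.covariances:
            np.testing.assert_allclose(S, np.diag(np.diag(S)))

    def test_posteriors_match_bruteforce_densities(self, rng):
        X = np.vstack([
            rng.standard_normal((25, 3)),
            rng.standard_normal((25, 3)) * 1.5 + 2.0,
            rng.standard_normal((25, 3)) * 0.7 - 2.0,
        ])
        y = np.repeat(["a", "b", "c"], 25)
        qda = fit_qda(X, y, reg_gamma=0.1)
        pts = rng.standard_normal((10, 3)) * 2.0
        _, probs = predict_qda(qda, pts)
        dens = np.stack(
            [
                qda.priors[ci]
                * multivariate_normal(qda.means[ci], qda.covariances[ci]).pdf(pts)
                for ci in range(3)
            ],
            axis=1,
        )
        oracle = dens / dens.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs, oracle, atol=1e-10)

    def test_equidistant_point_fifty_fifty(self):
        X = np.vstack([
            np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]]),
            np.array([[4.0, 0.0], [4.0, 1.0], [5.0, 0.0], [5.0, 1.0]]),
        ])
        y = np.array(["a"] * 4 + ["b"] * 4)
        qda = fit_qda(X, y, reg_gamma=0.0)
        _, probs = predict_qda(qda, np.array([[2.5, 0.5]]))
        np.testing.assert_allclose(probs[0], [0.5, 0.5], atol=1e-12)

    def test_identity_covariance_mahalanobis_is_euclidean(self, rng):
        mean = np.array([1.0, -2.0])
        qda = fit_qda(
            np.vstack([rng.standard_normal((50, 2)) + mean,
                       rng.standard_normal((50, 2)) - mean]),
            np.repeat(["a", "b"], 50),
            reg_gamma=0.0,
        )
        x = rng.standard_normal((5, 2))
        diff = x - qda.means[0]
        d_euclid = np.einsum("ni,ij,nj->n", diff, np.linalg.inv(qda.covariances[0]), diff)
        manual = np.einsum(
            "ni,nj,ij->n", diff, diff, np.linalg.inv(qda.covariances[0])
        )
        np.testing.assert_allclose(d_euclid, manual)

    def test_probabilities_sum_to_one(self, rng):
        X = rng.standard_normal((40, 4))
        y = np.repeat(["a", "b"], 20)
        qda = fit_qda(X, y)
        _, probs = predict_qda(qda, rng.standard_normal((20, 4)) * 10)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_dimension_mismatch_rejected(self, rng):
        qda = fit_qda(rng.standard_normal((20, 3)), np.repeat(["a", "b"], 10))
        with pytest.raises(ValueError, match="dimension"):
            predict_qda(qda, np.zeros((2, 5)))


class TestEvaluate:
    def test_perfect_model_closed_form(self):
        classes = np.array(["a", "b", "c"])
        y = np.array(["a", "b", "c", "a"])
        probs = np.array([
            [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0], [1.0, 0.0, 0.0],
        ])
        m = evaluate(y, probs, classes, np.array([1 / 3] * 3))
        assert m.minus2_loglik == pytest.approx(0.0, abs=1e-9)
        assert m.r2_entropy == pytest.approx(1.0)
        assert m.accuracy == 1.0

    def test_null_model_r2_zero(self):
        classes = np.array(["a", "b", "c"])
        y = np.repeat(classes, 4)
        probs = np.tile([1 / 3, 1 / 3, 1 / 3], (12, 1))
        m = evaluate(y, probs, classes, np.array([1 / 3] * 3))
        assert m.r2_entropy == pytest.approx(0.0, abs=1e-12)

    def test_priors_only_minus2_loglik_is_2n_ln3(self):
        n = 12
        classes = np.array(["a", "b", "c"])
        y = np.repeat(classes, n // 3)
        probs = np.tile([1 / 3, 1 / 3, 1 / 3], (n, 1))
        m = evaluate(y, probs, classes, np.array([1 / 3] * 3))
        assert m.minus2_loglik == pytest.approx(2 * n * np.log(3.0), rel=1e-12)

    def test_confusion_trace_equals_accuracy(self, rng):
        classes = np.array(["a", "b"])
        y = rng.choice(classes, 30)
        probs = rng.dirichlet([1, 1], size=30)
        m = evaluate(y, probs, classes, np.array([0.5, 0.5]))
        assert m.accuracy == pytest.approx(
            np.trace(m.confusion.to_numpy()) / 30
        )

    def test_invalid_probability_rows_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            evaluate(
                np.array(["a"]), np.array([[0.7, 0.7]]),
                np.array(["a", "b"]), np.array([0.5, 0.5]),
            )


class TestHoldbackSplit:
    def test_24_per_class_gives_6_test_each(self):
        labels = np.repeat(["hepa", "n2a", "msc"], 24)
        train, test = holdback_split(labels, fraction=0.25, seed=3)
        assert test.size == 18
        for c in ("hepa", "n2a", "msc"):
            assert (labels[test] == c).sum() == 6
        assert np.intersect1d(train, test).size == 0

    def test_fraction_half_on_four_rows(self):
        labels = np.repeat(["a", "b"], 4)
        _, test = holdback_split(labels, fraction=0.5, seed=0)
        assert (labels[test] == "a").sum() == 2
        assert (labels[test] == "b").sum() == 2

    def test_same_seed_identical_split(self):
        labels = np.repeat(["a", "b", "c"], 24)
        s1 = holdback_split(labels, seed=11)
        s2 = holdback_split(labels, seed=11)
        np.testing.assert_array_equal(s1[1], s2[1])

    def test_day_tag_holds_out_whole_batches(self):
        labels = np.repeat(["a", "b"], 8)
        days = np.tile(np.repeat(["d1", "d2", "d3", "d4"], 2), 2)
        _, test = holdback_split(
            labels, fraction=0.25, by="day_tag", seed=0, day_tags=days
        )
        held_days = set(days[test])
        assert all(np.isin(np.nonzero(np.isin(days, list(held_days)))[0], test).all()
                   for _ in [0])

    def test_too_small_class_rejected(self):
        labels = np.array(["a", "a", "b", "b", "b", "b"])
        with pytest.raises(ValueError, match="too few"):
            holdback_split(labels, fraction=0.25)


class TestFusion:
    @staticmethod
    def _blocks(rng, spectral_signal=True, image_signal=True):
        labels = pd.Series(np.repeat(["a", "b", "c"], 12))
        shift = np.array([{"a": -3.0, "b": 0.0, "c": 3.0}[l] for l in labels])
        spec = rng.standard_normal((36, 12))
        img = rng.standard_normal((36, 12))
        if spectral_signal:
            spec[:, 0] += shift
            spec[:, 1] -= shift
        if image_signal:
            img[:, 0] += shift
            img[:, 1] += 0.5 * shift
        idx = pd.Index([f"cell{i}" for i in range(36)], name="cell_id")
        return (
            pd.DataFrame(spec, index=idx),
            pd.DataFrame(img, index=idx),
            pd.Series(labels.values, index=idx),
        )

    def test_signal_only_in_spectral_block(self, rng):
        spec, img, labels = self._blocks(rng, image_signal=False)
        res = FusedDAPC(spec, img, labels).fit(seed=0)
        assert set(res.block_of_selected) == {"spectral"}

    def test_duplicate_block_adds_no_redundant_pcs(self, rng):
        spec, _, labels = self._blocks(rng, image_signal=False)
        res = FusedDAPC(spec, spec.copy(), labels).fit(seed=0)
        # the duplicated block's PCs are collinear with the originals:
        # each selected direction can enter only once
        tags = res.block_of_selected
        assert len(tags) == len(set(zip(tags, res.selected_pc_indices)))
        pooled_dim = len(tags)
        assert pooled_dim <= 3

    def test_row_mismatch_rejected(self, rng):
        spec, img, labels = self._blocks(rng)
        with pytest.raises(ValueError, match="row identity"):
            FusedDAPC(spec, img.iloc[:-1], labels)

    def test_reports_block_counts(self, rng):
        spec, img, labels = self._blocks(rng)
        res = FusedDAPC(spec, img, labels).fit(seed=0)
        per = res.selected_per_block
        assert per["spectral"] + per["image"] == len(res.selected_pc_indices)
        assert "spectral" in res.summary()


class TestDAPCModel:
    def test_summary_contains_metrics(self, rng):
        labels = pd.Series(np.repeat(["a", "b"], 12))
        X = rng.standard_normal((24, 6))
        X[:, 0] += np.array([{"a": -3.0, "b": 3.0}[l] for l in labels])
        res = DAPC(pd.DataFrame(X), labels).fit(seed=0)
        text = res.summary()
        assert "accuracy" in text and "train" in text and "test" in text

    def test_results_predict_matches_fit_predictions(self, rng):
        labels = pd.Series(np.repeat(["a", "b"], 12))
        X = pd.DataFrame(rng.standard_normal((24, 6)))
        X[0] += np.array([{"a": -3.0, "b": 3.0}[l] for l in labels])
        res = DAPC(X, labels).fit(seed=0)
        pred, probs = res.predict(X)
        np.testing.assert_array_equal(pred, res.predictions["predicted"].values)

    def test_no_significant_pc_raises(self, rng):
        labels = pd.Series(np.repeat(["a", "b"], 12))
        X = pd.DataFrame(rng.standard_normal((24, 6)))
        with pytest.raises(ValueError, match="no PC"):
            DAPC(X, labels, alpha=1e-9).fit(seed=0)


class TestComparators:
    @pytest.fixture()
    def separable(self, rng):
        # equilateral blob arrangement: no class sits "between" the others,
        # so even the linear-response argmax of PLS-DA is unambiguous
        labels = pd.Series(np.repeat(["a", "b", "c"], 10))
        X = rng.standard_normal((30, 5)) * 0.05
        centers = {"a": (0, 0), "b": (6, 0), "c": (3, 5.196)}
        for i, l in enumerate(labels):
            X[i, 0] += centers[l][0]
            X[i, 1] += centers[l][1]
        return pd.DataFrame(X), labels

    @pytest.mark.parametrize("method", ["plsda", "kmeans", "svm"])
    def test_separable_data_classified_perfectly(self, separable, method):
        data, labels = separable
        m = comparator_fit_predict(data, labels, method)
        assert m.accuracy == 1.0

    def test_unknown_method_rejected(self, separable):
        data, labels = separable
        with pytest.raises(ValueError, match="unknown"):
            comparator_fit_predict(data, labels, "forest")
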