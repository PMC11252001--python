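import numpy as np
import pandas as pd
import pytest

import farmbiome as fb
from farmbiome.plsda import (
    _mahalanobis_predict,
    _nipals,
    encode_labels,
    project_scores,
)


def _random_problem(seed, n=16, p=6, informative=True):
    rng = np.random.default_rng(seed)
    y = np.array(["HHS"] * (n // 2) + ["LHS"] * (n // 2))
    X = rng.normal(size=(n, p))
    if informative:
        X[:, 0] += np.where(y == "HHS", 1.5, -1.5)
    return X, y


class TestFit:
    def test_single_informative_column_gets_unit_weight(self):
        # Column 0 equals the class encoding; column 1 is exactly
        # orthogonal to it (sums to zero within each class).
        y = np.array(["HHS", "HHS", "HHS", "HHS", "LHS", "LHS", "LHS", "LHS"])
        X = np.column_stack(
            [
                np.where(y == "HHS", 1.0, -1.0),
                np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 3.0, -3.0]),
            ]
        )
        model = fb.fit_plsda(X, y, 1)
        np.testing.assert_allclose(np.abs(model.x_weights[:, 0]), [1.0, 0.0], atol=1e-10)
        scores = model.scores[:, 0]
        assert scores[y == "HHS"].min() > scores[y == "LHS"].max()

    def test_score_orthogonality(self):
        X, y = _random_problem(0)
        model = fb.fit_plsda(X, y, 3)
        gram = model.scores.T @ model.scores
        off_diag = gram - np.diag(np.diag(gram))
        assert np.abs(off_diag).max() < 1e-8

    def test_matches_eigen_oracle_per_deflation_step(self):
        """Weights/scores equal the dominant eigenvector of X'yy'X at each step."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 3))
        y = np.array(["HHS"] * 4 + ["LHS"] * 4)
        model = fb.fit_plsda(X, y, 2)
        encoded, _ = encode_labels(y)
        Xd = X - X.mean(axis=0)
        yd = encoded - encoded.mean()
        for a in range(2):
            M = np.outer(Xd.T @ yd, yd @ Xd)  # X'y y'X, rank one
            evals, evecs = np.linalg.eigh(M)
            w_oracle = evecs[:, np.argmax(evals)]
            w = model.x_weights[:, a]
            sign = np.sign(w_oracle @ w)
            np.testing.assert_allclose(w, sign * w_oracle, atol=1e-8)
            t = Xd @ w
            np.testing.assert_allclose(model.scores[:, a], t, atol=1e-8)
            p_load = Xd.T @ t / (t @ t)
            q = yd @ t / (t @ t)
            Xd = Xd - np.outer(t, p_load)
            yd = yd - q * t

    def test_first_weight_proportional_to_xty(self):
        for seed in range(5):
            X, y = _random_problem(seed)
            encoded, _ = encode_labels(y)
            model = fb.fit_plsda(X, y, 1)
            direction = (X - X.mean(axis=0)).T @ (encoded - encoded.mean())
            direction /= np.linalg.norm(direction)
            w = model.x_weights[:, 0]
            np.testing.assert_allclose(w, np.sign(w @ direction) * direction, atol=1e-8)

    def test_agrees_with_sklearn_nipals(self):
        from sklearn.cross_decomposition import PLSRegression

        X, y = _random_problem(3, n=20, p=8)
        encoded, _ = encode_labels(y)
        model = fb.fit_plsda(X, y, 3)
        ref = PLSRegression(n_components=3, scale=False).fit(X, encoded)
        for a in range(3):
            w, w_ref = model.x_weights[:, a], ref.x_weights_[:, a]
            sign = np.sign(w @ w_ref)
            np.testing.assert_allclose(w, sign * w_ref, atol=1e-8)
            np.testing.assert_allclose(
                model.scores[:, a], sign * ref.x_scores_[:, a], atol=1e-8
            )

    def test_rejects_single_class_and_excess_components(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError):
            fb.fit_plsda(X, np.array(["HHS"] * 6), 1)
        y = np.array(["HHS"] * 3 + ["LHS"] * 3)
        with pytest.raises(ValueError):
            fb.fit_plsda(X, y, 6)


class TestMahalanobis:
    def test_training_centroid_member_classified_home(self):
        X, y = _random_problem(1)
        model = fb.fit_plsda(X, y, 2)
        preds = fb.classify_mahalanobis(model, X)
        centroid_scores = model.centroids
        # a synthetic sample projecting exactly onto the HHS centroid
        assert (preds[y == "HHS"] == "HHS").mean() > 0.9

    def test_equidistant_tie_breaks_lexicographically(self):
        centroids = np.array([[-1.0, 0.0], [1.0, 0.0]])
        cov = np.eye(2)
        pred = _mahalanobis_predict(
            np.array([[0.0, 0.0]]), centroids, cov, ("HHS", "LHS")
        )
        assert pred[0] == "HHS"

    def test_anisotropic_covariance_overrules_euclidean(self):
        """Hand-computed case where Euclidean and Mahalanobis disagree.

        Centroids at (0,0) and (4,0); covariance diag(8, 0.5). Point
        (2.4, 1): Euclidean prefers the first centroid (d^2 5.76+1 vs
        2.56+1), but Mahalanobis distances are 0.72+2=2.72 vs 0.32+2=2.32,
        so the second centroid wins.
        """
        centroids = np.array([[0.0, 0.0], [4.0, 0.0]])
        cov = np.diag([8.0, 0.5])
        point = np.array([[2.4, 1.0]])
        d1 = point[0] @ np.linalg.inv(cov) @ point[0]
        delta2 = point[0] - centroids[1]
        d2 = delta2 @ np.linalg.inv(cov) @ delta2
        assert d1 == pytest.approx(2.72) and d2 == pytest.approx(2.32)
        pred = _mahalanobis_predict(point, centroids, cov, ("HHS", "LHS"))
        assert pred[0] == "LHS"


class TestCvBer:
    def test_perfect_separation_near_zero_ber(self):
        X, y = _random_problem(2, n=24, p=5)
        X[:, 0] = np.where(y == "HHS", 5.0, -5.0) + 0.01 * X[:, 1]
        mean_ber, chosen = fb.cv_ber(X, y, repetitions=20, seed=0)
        assert mean_ber[0] < 0.05

    def test_uninformative_labels_ber_near_half(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(24, 8))
        y = np.array(["HHS", "LHS"] * 12)
        mean_ber, _ = fb.cv_ber(X, y, repetitions=50, seed=1)
        assert 0.4 <= mean_ber.min() <= 0.6

    def test_ber_equals_mean_of_per_class_errors(self):
        """Recompute BER by hand from pooled CV predictions on one toy run."""
        from farmbiome.plsda import _cv_errors_per_a, _stratified_folds

        X, y = _random_problem(4, n=12, p=4)
        encoded, labels = encode_labels(y)
        rng = np.random.default_rng(0)
        ber = _cv_errors_per_a(X, y, encoded, labels, 4, 1, rng)[0]
        # replay with the same fold stream
        rng = np.random.default_rng(0)
        assignment = _stratified_folds(y, 4, rng)
        errs = {lbl: 0 for lbl in labels}
        counts = {lbl: 0 for lbl in labels}
        for f in range(4):
            test, train = assignment == f, assignment != f
            model = fb.fit_plsda(X[train], y[train], 1)
            pred = fb.classify_mahalanobis(model, X[test])
            for lbl in labels:
                mask = y[test] == lbl
                errs[lbl] += (pred[mask] != lbl).sum()
                counts[lbl] += mask.sum()
        expected = np.mean([errs[lbl] / counts[lbl] for lbl in labels])
        assert ber == pytest.approx(expected, abs=1e-12)

    def test_class_smaller_than_folds_rejected(self):
        X = np.random.default_rng(0).normal(size=(5, 3))
        y = np.array(["HHS"] * 3 + ["LHS"] * 2)
        with pytest.raises(ValueError, match="fewer"):
            fb.cv_ber(X, y, folds=4, repetitions=2, seed=0)

    def test_deterministic_for_fixed_seed(self):
        X, y = _random_problem(6, n=16, p=5)
        b1, a1 = fb.cv_ber(X, y, repetitions=10, seed=42)
        b2, a2 = fb.cv_ber(X, y, repetitions=10, seed=42)
        np.testing.assert_array_equal(b1, b2)
        assert a1 == a2


class TestVip:
    def test_normalisation_identity(self):
        for seed in range(5):
            X, y = _random_problem(seed, p=7)
            model = fb.fit_plsda(X, y, 3)
            vip = fb.vip_scores(model)
            assert np.sum(np.asarray(vip) ** 2) == pytest.approx(7, abs=1e-8)

    def test_single_component_single_weight_closed_form(self):
        y = np.array(["HHS"] * 4 + ["LHS"] * 4)
        X = np.column_stack(
            [
                np.where(y == "HHS", 1.0, -1.0),
                np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5, 3.0, -3.0]),
                np.array([-1.0, 1.0, -2.0, 2.0, -0.5, 0.5, -3.0, 3.0]),
            ]
        )
        model = fb.fit_plsda(X, y, 1)
        vip = np.asarray(fb.vip_scores(model))
        np.testing.assert_allclose(vip, [np.sqrt(3), 0.0, 0.0], atol=1e-8)

    def test_matches_direct_formula_evaluation(self):
        X, y = _random_problem(8, p=3)
        model = fb.fit_plsda(X, y, 2)
        W, ss = model.x_weights, model.y_ss
        expected = np.sqrt(
            3 * ((W**2 / (W**2).sum(axis=0)) @ ss) / ss.sum()
        )
        np.testing.assert_allclose(np.asarray(fb.vip_scores(model)), expected, atol=1e-10)


class TestIterativeSelection:
    def test_symmetric_equal_vips_stop_immediately(self):
        """All variables identical copies -> every VIP is exactly 1."""
        rng = np.random.default_rng(0)
        base = np.where(np.arange(12) < 6, 1.0, -1.0) + 0.1 * rng.normal(size=12)
        X = pd.DataFrame({f"g{i}": base for i in range(4)})
        y = np.array(["HHS"] * 6 + ["LHS"] * 6)
        trace = fb.iterative_vip_selection(X, y, repetitions=5, seed=0)
        assert len(trace.iterations) == 1
        assert trace.stop_reason == "no_variable_below_threshold"
        assert trace.final_selected == list(X.columns)

    def test_retained_sets_strictly_shrink_and_final_is_min_ber(self, scaled_wall):
        scaled, labels, _ = scaled_wall
        trace = fb.iterative_vip_selection(
            scaled, labels, repetitions=20, seed=1
        )
        sizes = [len(it["retained"]) for it in trace.iterations]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert trace.final_ber == pytest.approx(
            min(it["ber"] for it in trace.iterations)
        )

    def test_recovers_injected_signal(self, scaled_wall):
        scaled, labels, truth = scaled_wall
        trace = fb.iterative_vip_selection(scaled, labels, repetitions=20, seed=0)
        recovered = set(trace.final_selected) & truth.differential_genus_ids
        observable = truth.differential_genus_ids & set(scaled.columns)
        assert len(recovered) >= len(observable) - 3


class TestConfusion:
    def test_rows_sum_to_hundred_and_separable_is_high(self):
        X, y = _random_problem(9, n=16, p=4)
        X[:, 0] = np.where(y == "HHS", 5.0, -5.0)
        obs, perm = fb.confusion_matrices(
            X, y, n_components=1, repetitions=50, seed=0
        )
        np.testing.assert_allclose(obs.matrix.sum(axis=1), 100.0, atol=1e-9)
        np.testing.assert_allclose(perm.matrix.sum(axis=1), 100.0, atol=1e-9)
        assert obs.true_positive_pct.min() > 95.0

    def test_permuted_near_chance(self):
        X, y = _random_problem(10, n=24, p=6)
        _, perm = fb.confusion_matrices(
            X, y, n_components=2, repetitions=200, seed=3
        )
        assert np.abs(perm.true_positive_pct - 50.0).max() < 5.0

    def test_observed_dominates_permuted_with_signal(self):
        for seed in (0, 1, 2):
            X, y = _random_problem(seed, n=16, p=5)
            obs, perm = fb.confusion_matrices(
                X, y, n_components=2, repetitions=60, seed=seed
            )
            assert (
                obs.true_positive_pct.mean() >= perm.true_positive_pct.mean()
            )

    def test_deterministic_for_fixed_seed(self):
        X, y = _random_problem(11, n=12, p=4)
        r1 = fb.confusion_matrices(X, y, n_components=1, repetitions=20, seed=7)
        r2 = fb.confusion_matrices(X, y, n_components=1, repetitions=20, seed=7)
        pd.testing.assert_frame_equal(r1[0].matrix, r2[0].matrix)
        pd.testing.assert_frame_equal(r1[1].matrix, r2[1].matrix)


def test_projection_reproduces_training_scores():
    X, y = _random_problem(12, n=14, p=5)
    model = fb.fit_plsda(X, y, 2)
    np.testing.assert_allclose(project_scores(model, X), model.scores, atol=1e-8)
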