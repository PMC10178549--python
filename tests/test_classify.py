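import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.ensemble import RandomForestClassifier
from sklearn.svm import SVC

import ovotrace as ot
from ovotrace.classify import RFConfig, SVMConfig
from ovotrace.cnn import CNNSpec, OuterProductCNN, TrainConfig
from ovotrace.errors import ParameterError, ValidationError


def _table(X, y=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return ot.SpectraTable(np.arange(X.shape[1], dtype=float) + 500.0, X, y=y)


class TestOuterProduct:
    def test_hand_examples(self):
        assert np.array_equal(ot.outer_product([1.0, 2.0]), [[1, 2], [2, 4]])
        assert np.array_equal(ot.outer_product([0.0, 0.0, 0.0]), np.zeros((3, 3)))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_one_gram_invariants(self, seed):
        """S = x x^T is symmetric, PSD, rank <= 1, with trace = sum x_i^2."""
        x = np.random.default_rng(seed).standard_normal(8)
        S = ot.outer_product(x)
        assert np.array_equal(S, S.T)
        eig = np.sort(np.linalg.eigvalsh(S))
        assert eig[0] >= -1e-10  # PSD
        assert np.allclose(eig[:-1], 0.0, atol=1e-10)  # rank <= 1
        assert abs(eig[-1] - np.sum(x**2)) < 1e-10
        assert abs(np.trace(S) - np.sum(x**2)) < 1e-12

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            ot.outer_product([1.0])


class TestRandomForest:
    def test_perfect_split_feature(self):
        X = np.column_stack([np.repeat([0.0, 5.0, 10.0], 10), np.zeros(30)])
        y = np.repeat([0, 1, 2], 10)
        clf = ot.train_rf(_table(X, y), seed=0)
        assert np.mean(clf.predict(X) == y) == 1.0

    def test_single_stump(self):
        X = np.repeat([[0.0, 1.0]], 10, axis=0) + np.arange(10)[:, None]
        y = np.array([0] * 5 + [1] * 5)
        clf = ot.train_rf(
            _table(X, y), RFConfig(n_trees=1, max_depth=1), seed=0
        )
        assert len(clf.trees) == 1
        assert clf.trees[0].get_depth() == 1

    def test_single_class_gives_constant_predictor(self):
        X = np.random.default_rng(0).standard_normal((6, 3))
        with pytest.warns(UserWarning, match="single-class"):
            clf = ot.train_rf(_table(X, [2] * 6), seed=0)
        assert np.all(clf.predict(X) == 2)

    def test_accuracy_tracks_reference_ensemble(self, labelled_blobs):
        """Mean held-out accuracy within 5 points of an independent bagged
        forest implementation on the same splits."""
        rng = np.random.default_rng(123)
        X, y = labelled_blobs.X, labelled_blobs.y
        X = X + 0.8 * rng.standard_normal(X.shape)  # make the task non-trivial
        ours, ref = [], []
        for seed in range(10):
            order = np.random.default_rng(seed).permutation(len(y))
            tr, te = order[:24], order[24:]
            clf = ot.train_rf(_table(X[tr], y[tr]), seed=seed)
            ours.append(np.mean(clf.predict(X[te]) == y[te]))
            skl = RandomForestClassifier(
                n_estimators=10, max_depth=2, max_features="sqrt",
                random_state=seed,
            ).fit(X[tr], y[tr])
            ref.append(np.mean(skl.predict(X[te]) == y[te]))
        assert abs(np.mean(ours) - np.mean(ref)) <= 0.05


class TestSVM:
    def test_separated_blobs_classified_perfectly(self, labelled_blobs):
        clf = ot.train_svm(labelled_blobs)
        assert np.mean(clf.predict(labelled_blobs.X) == labelled_blobs.y) == 1.0

    def test_decision_function_matches_kernel_expansion(self):
        """The fitted decision value equals the explicit support-vector sum
        sum_i a_i* exp(-||x - z_i||^2 / sigma^2) + b*."""
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(0, 1, (15, 3)), rng.normal(4, 1, (15, 3))])
        y = np.array([0] * 15 + [1] * 15)
        clf = ot.train_svm(_table(X, y), SVMConfig(sigma=2.0, C=1.0))
        svc = clf.svc
        Z = clf.scaler.transform(X[:3])
        manual = []
        for z in Z:
            k = np.exp(-np.sum((svc.support_vectors_ - z) ** 2, axis=1) / 2.0**2)
            manual.append(svc.dual_coef_[0] @ k + svc.intercept_[0])
        assert np.allclose(manual, svc.decision_function(Z), atol=1e-8)

    def test_rbf_separates_xor_where_linear_cannot(self):
        X = np.array([[0, 0], [1, 1], [0, 1], [1, 0]] * 8, dtype=float)
        X += 0.05 * np.random.default_rng(3).standard_normal(X.shape)
        y = np.array([0, 0, 1, 1] * 8)
        rbf = ot.train_svm(_table(X, y), SVMConfig(sigma=0.5, C=10.0))
        assert np.mean(rbf.predict(X) == y) == 1.0
        linear = SVC(kernel="linear", C=10.0).fit(X, y)
        assert np.mean(linear.predict(X) == y) < 1.0

    def test_bad_hyperparameters_rejected(self):
        with pytest.raises(ParameterError):
            SVMConfig(sigma=-1.0)
        with pytest.raises(ParameterError):
            SVMConfig(C=0.0)


class TestCNN:
    def test_untrained_network_outputs_three_scores(self):
        net = OuterProductCNN(side=6, spec=CNNSpec(), seed=0)
        scores = net.predict_scores(np.random.default_rng(0).standard_normal((4, 6, 6)))
        assert scores.shape == (4, 3)

    def test_separable_samples_fit_perfectly(self, labelled_blobs):
        sub = labelled_blobs.subset_rows(
            [0, 1, 2, 3, 12, 13, 14, 15, 24, 25, 26, 27]
        )
        clf = ot.train_cnn(sub, cfg=TrainConfig(max_epochs=50, seed=0))
        assert np.mean(clf.predict(sub.X) == sub.y) == 1.0
        assert np.all(np.isfinite(clf.loss_history))

    def test_identical_seeds_give_identical_loss_traces(self, labelled_blobs):
        sub = labelled_blobs.subset_rows(list(range(0, 36, 3)))
        cfg = TrainConfig(max_epochs=5, seed=42)
        a = ot.train_cnn(sub, cfg=cfg)
        b = ot.train_cnn(sub, cfg=cfg)
        assert a.loss_history == b.loss_history

    def test_input_side_below_minimum_rejected(self):
        with pytest.raises(ParameterError, match=">= 2"):
            OuterProductCNN(side=1, spec=CNNSpec(), seed=0)


@pytest.fixture(scope="module")
def fitted(labelled_blobs):
    return ot.train_svm(labelled_blobs)


class TestPredictContract:

    def test_training_set_recovered_by_perfect_fit(self, labelled_blobs, fitted):
        assert np.array_equal(
            ot.predict(fitted, labelled_blobs), labelled_blobs.y
        )

    def test_permutation_equivariance(self, labelled_blobs, fitted):
        perm = np.random.default_rng(5).permutation(labelled_blobs.n_samples)
        direct = ot.predict(fitted, labelled_blobs)[perm]
        shuffled = ot.predict(fitted, labelled_blobs.subset_rows(perm))
        assert np.array_equal(direct, shuffled)

    def test_feature_count_mismatch_rejected(self, labelled_blobs, fitted):
        narrower = labelled_blobs.subset_columns([0, 1, 2])
        with pytest.raises(ValidationError):
            ot.predict(fitted, narrower)

    def test_serialization_round_trip(self, labelled_blobs, fitted, tmp_path):
        path = ot.save_classifier(fitted, tmp_path / "model.pkl")
        loaded = ot.load_classifier(path)
        assert np.array_equal(
            ot.predict(loaded, labelled_blobs), ot.predict(fitted, labelled_blobs)
        )
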