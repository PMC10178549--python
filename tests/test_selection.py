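import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovotrace as ot
from ovotrace.errors import DegenerateDataError, ParameterError, ValidationError
from ovotrace.selection import cars_schedule, spa_chain


def _table(X, y=None):
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return ot.SpectraTable(np.arange(X.shape[1], dtype=float) + 400.0, X, y=y)


class TestPLS:
    def test_exact_linear_recovery(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((25, 2))
        y = 3 * X[:, 0] - 2 * X[:, 1] + 0.5
        model = ot.pls_fit(X, y, n_components=2)
        assert np.sqrt(np.mean((model.predict(X) - y) ** 2)) <= 1e-8

    def test_constant_response(self):
        X = np.random.default_rng(1).standard_normal((10, 4))
        model = ot.pls_fit(X, np.full(10, 5.0), n_components=2)
        assert np.allclose(model.coefficients, 0.0, atol=1e-10)
        assert model.bias == pytest.approx(5.0)

    def test_full_components_match_ordinary_least_squares(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        model = ot.pls_fit(X, y, n_components=5)
        Xc = np.hstack([X, np.ones((30, 1))])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        ols_pred = Xc @ beta
        assert np.allclose(model.predict(X), ols_pred, atol=1e-8)

    def test_coefficients_track_true_sparse_signal(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 10))
        beta = np.zeros(10)
        beta[[1, 4, 7]] = [2.0, -1.5, 1.0]
        signal = X @ beta
        noise = rng.standard_normal(30) * signal.std() / np.sqrt(10)
        model = ot.pls_fit(X, signal + noise, n_components=5)
        r = np.corrcoef(model.coefficients, beta)[0, 1]
        assert r > 0.9

    def test_too_many_components_rejected(self):
        X = np.zeros((5, 3))
        with pytest.raises(ParameterError):
            ot.pls_fit(X, np.arange(5.0), n_components=4)


class TestSPAProject:
    def test_orthogonal_candidate_unchanged(self):
        out = ot.spa_project(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert np.allclose(out, [0.0, 1.0])

    def test_parallel_candidate_zeroed(self):
        out = ot.spa_project(np.array([2.0, 4.0]), np.array([1.0, 2.0]))
        assert np.allclose(out, 0.0)

    def test_hand_computed_projection(self):
        out = ot.spa_project(np.array([1.0, 1.0]), np.array([1.0, 0.0]))
        assert np.allclose(out, [0.0, 1.0])

    def test_zero_anchor_rejected(self):
        with pytest.raises(ValidationError):
            ot.spa_project(np.ones(3), np.zeros(3))


def _oracle_chain(X, start, max_vars):
    """Brute-force SPA: residual via explicit least-squares at every step."""
    scale = np.linalg.norm(X, axis=0).max()
    chain = [start]
    for _ in range(max_vars - 1):
        A = X[:, chain]
        best, best_norm = None, -1.0
        for j in range(X.shape[1]):
            if j in chain:
                continue
            beta, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
            norm = np.linalg.norm(X[:, j] - A @beta)
            if norm < 1e-10 * scale:
                continue
            if norm > best_norm:
                best_norm, best = norm, j
        if best is None:
            break
        chain.append(best)
    return chain


class TestSPASelect:
    @given(seed=st.integers(0, 10_000), p=st.integers(2, 8))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_chain_matches_brute_force_oracle(self, seed, p):
        """Gram-Schmidt chain construction equals explicit lstsq projections."""
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((12, p))
        for start in range(p):
            assert spa_chain(X, start, p) == _oracle_chain(X, start, p)

    def test_duplicate_columns_never_co_selected(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((20, 3))
        X = np.hstack([base, base[:, [0]], base[:, [2]]])  # cols 3,4 duplicate 0,2
        for start in range(5):
            chain = spa_chain(X, start, 5)
            assert not ({0, 3} <= set(chain) or {2, 4} <= set(chain))

    def test_chosen_size_minimizes_rmse_curve(self, small_table):
        s = ot.snv(small_table)
        res = ot.spa_select(s, max_vars=5, cv_folds=3)
        best = min(res.rmse_by_size, key=lambda k: (res.rmse_by_size[k], k))
        assert res.chosen_size == best
        assert len(res.selected_indices) == res.chosen_size
        assert len(set(res.selected_indices)) == res.chosen_size

    def test_selects_planted_absorption_bands(self):
        """With the class signature confined to the 700/800 nm dips, at least
        half the selected wavelengths land within 30 nm of a dip center."""
        from ovotrace.synthetic import GeneratorConfig

        cfg = GeneratorConfig(
            class_levels=(0.9999, 1.0001, 1.0),
            n_per_class=(30, 30, 30),
            seed=5,
        )
        table = ot.snv(ot.generate(cfg))
        res = ot.spa_select(table, max_vars=10, cv_folds=10)
        wl = res.selected_wavelengths_nm
        near = np.minimum(np.abs(wl - 700.0), np.abs(wl - 800.0)) <= 30.0
        assert near.mean() >= 0.5

    def test_bad_max_vars_rejected(self, small_table):
        with pytest.raises(ParameterError):
            ot.spa_select(small_table, max_vars=0)


class TestCARSWeights:
    def test_hand_examples(self):
        assert np.allclose(ot.cars_weights([1.0, 1.0, 2.0]), [0.25, 0.25, 0.5])
        assert np.allclose(ot.cars_weights([0.0, 3.0]), [0.0, 1.0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_probability_vector(self, seed):
        k = np.random.default_rng(seed).standard_normal(100)
        w = ot.cars_weights(k)
        assert np.all(w >= 0)
        assert abs(w.sum() - 1.0) < 1e-12

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            ot.cars_weights(np.zeros(5))


class TestCARSSchedule:
    def test_decay_endpoints_and_monotonicity(self):
        counts = cars_schedule(200, 50)
        assert counts[0] == 200
        assert counts[-1] == 2
        assert np.all(np.diff(counts) <= 0)


@pytest.fixture(scope="module")
def run(small_table):
    s = ot.snv(small_table)
    return ot.cars_select(s, n_runs=20, cv_folds=3, seed=4), s


class TestCARSSelect:

    def test_best_run_is_argmin(self, run):
        res, _ = run
        assert res.best_run == int(np.argmin(res.rmsecv_by_run))

    def test_retained_counts_span_schedule(self, run):
        res, table = run
        assert res.retained_counts[0] == table.n_wavelengths
        assert res.retained_counts[-1] <= 2
        assert len(res.selected_indices) == res.retained_counts[res.best_run]

    def test_weights_are_probability_vectors(self, run):
        res, _ = run
        for w in res.weights_history:
            assert np.all(w >= 0)
            assert abs(w.sum() - 1.0) < 1e-9

    def test_seeded_reproducibility(self, small_table):
        s = ot.snv(small_table)
        a = ot.cars_select(s, n_runs=10, cv_folds=3, seed=9)
        b = ot.cars_select(s, n_runs=10, cv_folds=3, seed=9)
        assert a.selected_indices == b.selected_indices
        assert np.array_equal(a.rmsecv_by_run, b.rmsecv_by_run)

    def test_too_few_runs_rejected(self, small_table):
        with pytest.raises(ParameterError):
            ot.cars_select(small_table, n_runs=1)
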