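import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import plp
from plp.exceptions import AlignmentError, ValidationError
from plp.pls import _as_frame


def _scaled(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


class TestAutoscale:
    def test_closed_form_column(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        scaled, mean, scale = plp.autoscale(frame)
        assert np.allclose(scaled["a"], [-1.0, 0.0, 1.0])
        assert mean["a"] == 2.0 and scale["a"] == 1.0

    def test_constant_column_warns_and_centers(self):
        frame = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.warns(UserWarning, match="flat"):
            scaled, _, scale = plp.autoscale(frame)
        assert np.allclose(scaled["flat"], 0.0)
        assert scale["flat"] == 1.0

    def test_random_table_means_and_variances(self, rng):
        frame = pd.DataFrame(rng.normal(2.0, 3.0, size=(50, 8)))
        scaled, _, _ = plp.autoscale(frame)
        assert np.abs(scaled.mean(0)).max() < 1e-12
        assert np.abs(scaled.var(0, ddof=1) - 1.0).max() < 1e-12

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            plp.autoscale(pd.DataFrame())


class TestNipalsComponent:
    def test_univariate_shortcut_no_iterations_q_exactly_one(self, rng):
        X = _scaled(rng.normal(size=(30, 5)))
        y = rng.normal(size=30)
        comp = plp.nipals_component(X, y - y.mean())
        assert comp.n_iter == 0
        assert comp.q.shape == (1,) and comp.q[0] == 1.0

    def test_univariate_iterative_path_identical(self, rng):
        X = _scaled(rng.normal(size=(30, 5)))
        y = rng.normal(size=(30, 1))
        a = plp.nipals_component(X, y - y.mean())
        b = plp.nipals_component(X, y - y.mean(), _force_iterative=True)
        assert np.abs(a.t - b.t).max() < 1e-12
        assert np.abs(a.w - b.w).max() < 1e-12
        assert a.q[0] == b.q[0] == 1.0
        assert abs(a.b - b.b) < 1e-12

    def test_rank_one_noiseless_recovery(self, rng):
        # orthogonal predictors: the weight vector isolates the active
        # column exactly and the inner slope recovers the proportionality
        X = np.linalg.qr(rng.normal(size=(25, 4)))[0]
        y = 3.0 * X[:, [1]]
        comp = plp.nipals_component(X, y)
        corr = np.corrcoef(comp.t, X[:, 1])[0, 1]
        assert abs(abs(corr) - 1.0) < 1e-10
        # inner slope maps scores back onto y exactly
        assert np.abs(comp.b * comp.t * comp.q[0] - y[:, 0]).max() < 1e-8

    def test_first_component_matches_svd_oracle(self, rng):
        X = _scaled(rng.normal(size=(30, 5)))
        Y = rng.normal(size=(30, 2))
        Yc = Y - Y.mean(0)
        comp = plp.nipals_component(X, Yc)
        w_svd = np.linalg.svd(X.T @ Yc)[0][:, 0]
        t_svd = X @ w_svd
        cos = abs(comp.t @ t_svd) / (np.linalg.norm(comp.t) * np.linalg.norm(t_svd))
        assert abs(cos - 1.0) < 1e-6

    def test_loading_rescaling_leaves_unit_p(self, rng):
        X = _scaled(rng.normal(size=(30, 5)))
        Y = rng.normal(size=(30, 3))
        comp = plp.nipals_component(X, Y - Y.mean(0))
        assert abs(np.linalg.norm(comp.p) - 1.0) < 1e-12

    def test_degenerate_data_raises(self):
        X = np.zeros((10, 3))
        y = np.ones(10)
        with pytest.raises(ValidationError, match="degenerate"):
            plp.nipals_component(X, y)


class TestFitPLS:
    def test_full_components_match_ols(self, rng):
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 3))
        model = plp.fit_pls(X, Y, n_components=6)
        pred = model.predict(_as_frame(X, "x")).to_numpy()
        A = np.column_stack([np.ones(40), X])
        beta, *_ = np.linalg.lstsq(A, Y, rcond=None)
        assert np.abs(pred - A @ beta).max() < 1e-6

    def test_scores_mutually_orthogonal(self, rng):
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 3))
        model = plp.fit_pls(X, Y, n_components=6)
        T = model.T
        G = T.T @ T
        norm = np.sqrt(np.outer(np.diag(G), np.diag(G)))
        off = np.abs(G / norm - np.eye(6)).max()
        assert off < 1e-8

    def test_noiseless_linear_system_fully_explained(self, rng):
        X = rng.normal(size=(30, 3))
        C = rng.normal(size=(3, 2))
        Y = X @ C
        model = plp.fit_pls(X, Y, n_components=3)
        assert abs(model.r2y_cum[-1] - 100.0) < 1e-6

    def test_r2y_trajectory_non_decreasing(self, rng):
        X = rng.normal(size=(50, 8))
        Y = rng.normal(size=(50, 4))
        model = plp.fit_pls(X, Y, n_components=8)
        assert (np.diff(model.r2y_cum) >= -1e-10).all()

    def test_zero_components_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValidationError):
            plp.fit_pls(X, rng.normal(size=(10, 1)), n_components=0)

    def test_components_beyond_rank_rejected(self, rng):
        X = rng.normal(size=(10, 3))
        X = np.column_stack([X, X[:, 0] + X[:, 1]])  # rank 3, 4 columns
        with pytest.raises(ValidationError, match="rank"):
            plp.fit_pls(X, rng.normal(size=(10, 2)), n_components=4)

    def test_row_label_mismatch_names_first(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=list("abcde"))
        Y = pd.DataFrame(rng.normal(size=(5, 1)), index=list("abxde"))
        with pytest.raises(AlignmentError, match="'c' vs 'x'"):
            plp.fit_pls(X, Y, n_components=1)

    def test_predict_is_idempotent_on_training_rows(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 4)),
                         index=[f"o{i}" for i in range(20)],
                         columns=list("abcd"))
        Y = pd.DataFrame(rng.normal(size=(20, 2)), index=X.index)
        model = plp.fit_pls(X, Y, n_components=3)
        full = model.predict(X)
        one = model.predict(X.iloc[[7]])
        assert np.abs(one.to_numpy() - full.iloc[[7]].to_numpy()).max() < 1e-12

    def test_predict_column_mismatch_lists_names(self, rng):
        X = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
        model = plp.fit_pls(X, rng.normal(size=(20, 1)), n_components=2)
        bad = X.rename(columns={"c": "z"})
        with pytest.raises(AlignmentError, match=r"missing \['c'\], unexpected \['z'\]"):
            model.predict(bad)

    def test_held_out_noiseless_rows_recovered(self, rng):
        X = rng.normal(size=(40, 5))
        C = rng.normal(size=(5, 2))
        Y = X @ C
        model = plp.fit_pls(X[:30], Y[:30], n_components=5)
        pred = model.predict(_as_frame(X[30:], "x")).to_numpy()
        assert np.abs(pred - Y[30:]).max() < 1e-6

    def test_agrees_with_sklearn_reference(self, rng):
        # sklearn's scale=True also autoscales Y, so feed it pre-scaled Y
        # and compare on that common footing
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(35, 6))
        Y = rng.normal(size=(35, 2))
        y_sd = Y.std(axis=0, ddof=1)
        for k in (1, 3):
            ours = plp.fit_pls(X, Y / y_sd, n_components=k)
            ref = sklearn.PLSRegression(n_components=k, scale=True,
                                        tol=1e-12, max_iter=5000).fit(X, Y)
            pred_ours = ours.predict(_as_frame(X, "x")).to_numpy() * y_sd
            assert np.abs(pred_ours - ref.predict(X)).max() < 1e-6


class TestExplainedVariance:
    @pytest.mark.parametrize("factor,expected", [(1.0, 100.0), (0.0, 0.0), (0.5, 75.0)])
    def test_scaled_predictions(self, rng, factor, expected):
        Y = rng.normal(size=(20, 3))
        assert abs(plp.explained_variance_pct(Y, factor * Y) - expected) < 1e-9

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            plp.explained_variance_pct(np.zeros((3, 2)), np.zeros((3, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            plp.explained_variance_pct(np.zeros((3, 2)), np.zeros((2, 3)))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_obs=st.integers(8, 30), nx=st.integers(2, 6))
def test_property_scores_orthogonal_and_r2_monotone(seed, n_obs, nx):
    """On arbitrary random data, NIPALS scores stay mutually orthogonal and
    the cumulative explained response variance never decreases."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_obs, nx))
    Y = rng.normal(size=(n_obs, 2))
    k = min(nx, n_obs - 1, int(np.linalg.matrix_rank((X - X.mean(0)) / X.std(0, ddof=1))))
    model = plp.fit_pls(X, Y, n_components=k)
    T = model.T
    G = T.T @ T
    norm = np.sqrt(np.outer(np.diag(G), np.diag(G)))
    assert np.abs(G / norm - np.eye(model.n_components)).max() < 1e-8
    assert (np.diff(model.r2y_cum) >= -1e-10).all()
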