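"""PLS core: NIPALS fits, variance accounting, VIP, LOO-CV, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from rumiprox import pls


@pytest.fixture
def random_problem(rng):
    X = rng.standard_normal((12, 5))
    y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0]) + 0.1 * rng.standard_normal(12)
    return X, y


class TestFitPls:
    def test_single_predictor_equals_ols(self, rng):
        x = rng.standard_normal((15, 1))
        y = 2.5 * x.ravel() + rng.standard_normal(15)
        fit = pls.fit_pls(x, y, 1)
        slope = np.polyfit(x.ravel(), y, 1)[0]
        assert fit.coef[0] == pytest.approx(slope, abs=1e-10)

    def test_exact_linear_reaches_full_variance(self, rng):
        X = rng.standard_normal((12, 5))
        y = X @ np.array([1.0, 2, 3, 4, 5])
        fit = pls.fit_pls(X, y, 5)
        assert fit.y_variance_total[-1] == pytest.approx(100.0, abs=1e-6)

    def test_matches_independent_implementation(self, random_problem):
        """Fitted values agree with an established PLS implementation
        using the same autoscaling and deflation definitions."""
        from sklearn.cross_decomposition import PLSRegression
        X, y = random_problem
        for A in (1, 2, 3, 4):
            fit = pls.fit_pls(X, y, A)
            other = PLSRegression(n_components=A, scale=True).fit(X, y.reshape(-1, 1))
            np.testing.assert_allclose(fit.predict(X), other.predict(X).ravel(),
                                       atol=1e-8)

    def test_score_orthogonality(self, random_problem):
        X, y = random_problem
        fit = pls.fit_pls(X, y, 4)
        G = fit.scores.T @ fit.scores
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_cumulative_variance_monotone_and_bounded(self, random_problem):
        X, y = random_problem
        fit = pls.fit_pls(X, y, 4)
        for total in (fit.x_variance_total, fit.y_variance_total):
            assert (np.diff(total) >= -1e-10).all()
            assert total[-1] <= 100 + 1e-8

    def test_pls_at_full_rank_reproduces_ols(self, random_problem):
        X, y = random_problem
        fit = pls.fit_pls(X, y, 5)
        beta = np.linalg.lstsq(np.column_stack([np.ones(12), X]), y, rcond=None)[0]
        yhat_ols = np.column_stack([np.ones(12), X]) @ beta
        np.testing.assert_allclose(fit.predict(X), yhat_ols, atol=1e-6)

    def test_sign_flip_of_response(self, random_problem):
        X, y = random_problem
        a, b = pls.fit_pls(X, y, 3), pls.fit_pls(X, -y, 3)
        np.testing.assert_allclose(a.coef_scaled, -b.coef_scaled, atol=1e-10)
        np.testing.assert_allclose(pls.compute_vip(a), pls.compute_vip(b),
                                   atol=1e-10)

    def test_zero_variance_column_rejected(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 2.0
        with pytest.raises(ValueError, match="zero-variance"):
            pls.fit_pls(X, rng.standard_normal(10), 2, columns=["a", "b", "c"])

    def test_factor_count_out_of_range(self, random_problem):
        X, y = random_problem
        with pytest.raises(ValueError, match="out of range"):
            pls.fit_pls(X, y, 12)


class TestVip:
    def test_single_predictor_is_one(self, rng):
        x = rng.standard_normal((10, 1))
        fit = pls.fit_pls(x, x.ravel() * 2 + rng.standard_normal(10), 1)
        assert pls.compute_vip(fit).iloc[0] == pytest.approx(1.0)

    def test_symmetric_weights_all_one(self, rng):
        z = rng.standard_normal(40)
        X = np.column_stack([z + 0.01 * rng.standard_normal(40) for _ in range(4)])
        fit = pls.fit_pls(X, z, 1)
        np.testing.assert_allclose(pls.compute_vip(fit), 1.0, atol=0.01)

    @given(st.integers(0, 1000))
    def test_sum_of_squares_identity(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(5, 15), rng.integers(2, 8)
        A = int(min(n - 1, p, rng.integers(1, 5)))
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        fit = pls.fit_pls(X, y, A)
        vip = pls.compute_vip(fit)
        assert (vip**2).sum() == pytest.approx(p, abs=1e-8)


class TestLooSelectFactors:
    def test_press_matches_fold_enumeration(self, rng):
        X = rng.standard_normal((5, 3))
        y = rng.standard_normal(5)
        rep = pls.loo_select_factors(X, y, max_factors=2)
        for A in (1, 2):
            press = 0.0
            for i in range(5):
                m = np.ones(5, bool)
                m[i] = False
                f = pls.fit_pls(X[m], y[m], A)
                press += (f.predict(X[i:i + 1])[0] - y[i]) ** 2
            assert rep.press[A] == pytest.approx(press, rel=1e-10)

    def test_clean_signal_predicted_with_two_factors(self, rng):
        # orthonormal predictors: two factors carry the exact signal
        X, _ = np.linalg.qr(rng.standard_normal((20, 6)))
        y = X[:, 0] - X[:, 1]
        rep = pls.loo_select_factors(X, y, max_factors=5)
        assert rep.q2[2] > 0.99
        assert rep.q2[rep.chosen] > 0.99

    def test_pure_noise_has_nonpositive_q2(self):
        q2 = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.standard_normal((15, 8))
            y = rng.standard_normal(15)
            rep = pls.loo_select_factors(X, y, max_factors=4)
            q2.append(rep.q2.max())
        assert np.median(q2) <= 0


class TestVarianceTable:
    @pytest.mark.parametrize("currents,totals", [
        ((35.46, 21.19, 6.72), (35.46, 56.65, 63.37)),
        ((28.98, 21.25, 7.86), (28.98, 50.23, 58.09)),
    ])
    def test_cumulative_totals(self, currents, totals):
        np.testing.assert_allclose(pls.cumulative_totals(currents), totals,
                                   atol=1e-9)

    def test_single_factor_total_equals_current(self, rng):
        X = rng.standard_normal((10, 4))
        y = X[:, 0] + rng.standard_normal(10)
        fit = pls.fit_pls(X, y, 1)
        tab = pls.variance_table(fit)
        assert tab["model_effects_total"].iloc[0] == tab["model_effects_current"].iloc[0]
        assert len(tab) == 1


class TestSequentialSelect:
    @pytest.fixture
    def selection_inputs(self, rng):
        n, p_signal, p_noise = 40, 4, 12
        signal = rng.standard_normal((n, p_signal))
        y = signal @ np.array([1.0, -1.0, 0.8, -0.8]) + 0.5 * rng.standard_normal(n)
        X = np.column_stack([signal, rng.standard_normal((n, p_noise))])
        cols = [f"K{j:05d}" for j in range(p_signal + p_noise)]
        gm = pd.DataFrame(X, columns=cols)
        class6 = pd.Series(np.repeat(["c1", "c2"], n // 2))
        return gm, y, class6, cols[:p_signal]

    def test_zero_threshold_is_noop(self, selection_inputs):
        gm, y, class6, _ = selection_inputs
        sel = pls.sequential_select(gm, y, "ADG", class6=class6,
                                    vip_threshold=0.0)
        assert sorted(sel.genes) == sorted(gm.columns)
        assert sel.candidate_sizes == [len(gm.columns)]

    def test_candidate_sizes_strictly_decrease(self, selection_inputs):
        gm, y, class6, _ = selection_inputs
        sel = pls.sequential_select(gm, y, "ADG", class6=class6)
        sizes = sel.candidate_sizes
        assert all(a > b for a, b in zip(sizes, sizes[1:]))

    def test_signal_recovered(self, selection_inputs):
        gm, y, class6, signal_cols = selection_inputs
        # pure-response criterion keeps every informative column; the
        # elimination trajectory ranks the signal columns above the noise
        sel = pls.sequential_select(gm, y, "ADG", class6=class6,
                                    rsq_tolerance=0.0, criterion="dependent")
        assert set(signal_cols) <= set(sel.genes)
        top4 = sel.table["ko"].head(4).tolist()
        assert set(top4) == set(signal_cols)

    def test_without_class_variance_reported(self, selection_inputs):
        gm, y, class6, _ = selection_inputs
        sel = pls.sequential_select(gm, y, "ADG", class6=class6)
        assert 0 <= sel.explained_y_without_class <= 100
        assert 0 <= sel.explained_y_with_class <= 100

    def test_table_ordered_by_vip(self, selection_inputs):
        gm, y, class6, _ = selection_inputs
        sel = pls.sequential_select(gm, y, "ADG", class6=class6)
        vips = sel.table["vip"].to_numpy()
        assert (np.diff(vips) <= 1e-12).all()
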