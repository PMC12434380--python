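import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cpmkit.cpm import (NetworkMask, cohort_strengths, fit_strength_model,
                        network_strength, partial_spearman, predict,
                        rank_transform, screen_edges)
from cpmkit.connectome import EdgeIndexMap
from cpmkit.simulate import null_benchmark, simulate_cohort
from conftest import make_cohort


def oracle_partial_spearman(x, y, cov):
    """Independent path: rank, residualize by explicit normal equations,
    correlate."""
    n = len(x)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    design = np.column_stack([np.ones(n)] +
                             [stats.rankdata(c) for c in np.atleast_2d(cov.T)]) \
        if cov is not None and cov.size else np.ones((n, 1))
    beta_x = np.linalg.solve(design.T @ design, design.T @ xr)
    beta_y = np.linalg.solve(design.T @ design, design.T @ yr)
    rx, ry = xr - design @ beta_x, yr - design @ beta_y
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestRankTransform:
    def test_simple_and_tied_examples(self):
        np.testing.assert_array_equal(rank_transform([3, 1, 2]), [3, 1, 2])
        np.testing.assert_array_equal(rank_transform([5, 5, 1]), [2.5, 2.5, 1])

    def test_agrees_with_sort_based_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 10, size=50).astype(float)  # plenty of ties
        ranks = rank_transform(x)
        order = np.argsort(x, kind="stable")
        expect = np.empty(50)
        expect[order] = np.arange(1, 51)
        for val in np.unique(x):
            sel = x == val
            expect[sel] = expect[sel].mean()
        np.testing.assert_allclose(ranks, expect)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            rank_transform(np.array([]))


class TestPartialSpearman:
    def test_reduces_to_classic_spearman_without_covariates(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x, y = rng.normal(size=30), rng.normal(size=30)
            rho, p = partial_spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert rho == pytest.approx(ref.statistic, abs=1e-12)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_monotone_transform_of_x_gives_rho_one(self):
        x = np.linspace(-2, 3, 25)
        rho, p = partial_spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        assert p < 1e-20

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(30)
        for _ in range(25):
            x, y = rng.normal(size=30), rng.normal(size=30)
            cov = rng.normal(size=(30, 2))
            rho, _ = partial_spearman(x, y, cov)
            assert rho == pytest.approx(oracle_partial_spearman(x, y, cov),
                                        abs=1e-10)

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=40), rng.normal(size=40)
        cov = rng.normal(size=(40, 2))
        rho, p = partial_spearman(x, y, cov)
        df = pd.DataFrame(dict(x=x, y=y, c1=cov[:, 0], c2=cov[:, 1]))
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"],
                              method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_partialling_removes_shared_signal(self):
        rng = np.random.default_rng(6)
        cov = rng.normal(size=(50, 1))
        y = cov[:, 0]                      # y IS the covariate
        x = rng.normal(size=50)
        rho, _ = partial_spearman(x, y + 1e-9 * rng.normal(size=50), cov)
        assert abs(rho) < 0.3

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_spearman(np.ones(20), np.arange(20.0))

    def test_rank_deficient_covariates_rejected(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=20), rng.normal(size=20)
        c = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank-deficient"):
            partial_spearman(x, y, np.column_stack([c, c]))

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_maps(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=25), rng.normal(size=25)
        cov = rng.normal(size=(25, 2))
        rho1, _ = partial_spearman(x, y, cov)
        rho2, _ = partial_spearman(np.exp(x), y ** 3, cov)
        assert rho1 == pytest.approx(rho2, abs=1e-10)


class TestScreenEdges:
    def test_perfect_edge_is_selected(self):
        rng = np.random.default_rng(10)
        n, E = 200, 45
        y = rng.normal(size=n)
        X = rng.normal(size=(n, E))
        X[:, 7] = y
        cohort = make_cohort(X, y, rng=rng)
        res = screen_edges(cohort, alpha=1e-3, adjust=False)
        assert res.mask[7]
        assert res.rho[7] == pytest.approx(1.0)
        assert res.sign[7] == 1

    def test_null_selection_rate_within_binomial_bound(self):
        sim = simulate_cohort(null_benchmark(seed=21))
        res = screen_edges(sim.cohort, alpha=1e-3, adjust=False)
        # E=1035, alpha=1e-3: mean ~1 selected; 8 is > 6 SDs out
        assert res.n_selected <= 8

    def test_screen_matches_per_edge_partial_spearman(self):
        rng = np.random.default_rng(11)
        n, E = 60, 21
        X, y = rng.normal(size=(n, E)), rng.normal(size=n)
        cohort = make_cohort(X, y, rng=rng)
        res = screen_edges(cohort, alpha=0.05, adjust=True)
        cov = cohort.covariates()
        for k in range(0, E, 5):
            rho, p = partial_spearman(X[:, k], y, cov)
            assert res.rho[k] == pytest.approx(rho, abs=1e-10)
            assert res.p[k] == pytest.approx(p, abs=1e-10)

    def test_degenerate_outcome_rejected(self):
        rng = np.random.default_rng(12)
        cohort = make_cohort(rng.normal(size=(40, 10)), np.ones(40), rng=rng)
        with pytest.raises(ValueError, match="constant"):
            screen_edges(cohort)


class TestStrength:
    def test_examples(self):
        assert network_strength(np.array([1.0, 2.0]),
                                np.array([False, False])) == 0.0
        v = np.array([0.5, -0.5, 1.0, 9.9])
        m = np.array([True, True, True, False])
        assert network_strength(v, m) == pytest.approx(2.0)

    def test_matches_bruteforce_loop_and_is_sign_invariant(self):
        rng = np.random.default_rng(13)
        v = rng.normal(size=30)
        m = rng.random(30) < 0.4
        expect = sum(abs(v[i]) for i in range(30) if m[i])
        assert network_strength(v, m) == pytest.approx(expect)
        assert network_strength(-v, m) == pytest.approx(expect)
        X = rng.normal(size=(8, 30))
        np.testing.assert_allclose(
            cohort_strengths(X, m),
            [network_strength(row, m) for row in X])

    def test_nonfinite_masked_value_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            network_strength(np.array([1.0, np.inf]), np.array([True, True]))


class TestStrengthModel:
    def test_exact_line(self):
        m = fit_strength_model(np.array([0.0, 1.0, 2.0]),
                               np.array([10.0, 12.0, 14.0]))
        assert m.slope == pytest.approx(2.0)
        assert m.intercept == pytest.approx(10.0)
        assert predict(m, 0) == pytest.approx(10.0)
        assert predict(m, 3) == pytest.approx(16.0)

    def test_constant_outcome_gives_flat_line(self):
        m = fit_strength_model(np.array([0.0, 1.0, 2.0]), np.full(3, 7.0))
        assert m.slope == pytest.approx(0.0)
        assert m.intercept == pytest.approx(7.0)

    def test_matches_covariance_closed_form(self):
        rng = np.random.default_rng(14)
        s, y = rng.normal(size=100), rng.normal(size=100)
        m = fit_strength_model(s, y)
        assert m.slope == pytest.approx(np.cov(s, y)[0, 1] / np.var(s, ddof=1))

    def test_vector_predict_is_elementwise(self):
        m = fit_strength_model(np.arange(5.0), 2 * np.arange(5.0) + 1)
        s = np.array([0.5, 1.5])
        np.testing.assert_allclose(predict(m, s),
                                   [predict(m, x) for x in s])

    def test_constant_strengths_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_strength_model(np.ones(5), np.arange(5.0))


class TestNetworkMask:
    def test_csv_roundtrip_uses_one_based_ids(self, tmp_path):
        rng = np.random.default_rng(15)
        n, E = 50, 45
        X, y = rng.normal(size=(n, E)), rng.normal(size=n)
        cohort = make_cohort(X, y, rng=rng)
        res = screen_edges(cohort, alpha=0.3, adjust=False)
        mask = NetworkMask.from_screen(res, cohort.edges.edge_map)
        path = tmp_path / "mask.csv"
        mask.to_csv(path)
        raw = pd.read_csv(path, comment="#")
        assert raw["region_i"].min() >= 1
        back = NetworkMask.from_csv(path)
        pd.testing.assert_frame_equal(
            back.table[["region_i", "region_j"]],
            mask.table[["region_i", "region_j"]])
        assert back.n_regions == 10
        assert back.provenance["alpha"] == 0.3
        np.testing.assert_array_equal(
            back.boolean_mask(EdgeIndexMap(10)), res.mask)
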