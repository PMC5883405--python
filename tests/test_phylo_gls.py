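"""GLS/PGLS fitting, Pagel's lambda, model comparison, ANOVA, t-test, ASR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import squamet as sq
from squamet.phylo_gls import GLSError


def three_taxon_tree():
    return sq.read_newick("((A:1,B:1):1,C:2);")


class TestVCV:
    def test_hand_computed_three_taxon(self):
        v = sq.vcv_from_tree(three_taxon_tree())
        order = [v.species.index(s) for s in ["A", "B", "C"]]
        m = v.matrix[np.ix_(order, order)]
        np.testing.assert_allclose(m, [[2, 1, 0], [1, 2, 0], [0, 0, 2]])

    def test_star_tree_is_scaled_identity(self):
        v = sq.vcv_from_tree(sq.simulate_tree(8, seed=0, model="star"))
        np.testing.assert_allclose(v.matrix, np.eye(8))

    def test_matches_path_enumeration_oracle(self):
        tree = sq.simulate_tree(30, seed=13)
        v = sq.vcv_from_tree(tree)
        # oracle: shared path length = sum of edges common to both
        # root-to-tip node paths
        paths = {}
        for leaf in tree.tree.leaf_node_iter():
            nodes, node = [], leaf
            while node is not None:
                nodes.append(node)
                node = node.parent_node
            paths[leaf.taxon.label] = nodes
        for i, a in enumerate(v.species):
            for j, b in enumerate(v.species):
                shared = set(map(id, paths[a])) & set(map(id, paths[b]))
                expect = sum(
                    float(n.edge.length or 0.0)
                    for n in paths[a]
                    if id(n) in shared and n.parent_node is not None
                )
                assert v.matrix[i, j] == pytest.approx(expect, abs=1e-9)


class TestLambdaTransform:
    def test_lambda_one_identity(self):
        V = sq.vcv_from_tree(three_taxon_tree()).matrix
        np.testing.assert_allclose(sq.lambda_transform(V, 1.0), V)

    def test_lambda_zero_diagonal(self):
        V = sq.vcv_from_tree(three_taxon_tree()).matrix
        np.testing.assert_allclose(sq.lambda_transform(V, 0.0), np.diag(np.diag(V)))

    def test_half_lambda_elementwise(self):
        v = sq.vcv_from_tree(three_taxon_tree())
        order = [v.species.index(s) for s in ["A", "B", "C"]]
        m = sq.lambda_transform(v.matrix, 0.5)[np.ix_(order, order)]
        np.testing.assert_allclose(m, [[2, 0.5, 0], [0.5, 2, 0], [0, 0, 2]])

    def test_out_of_range_rejected(self):
        with pytest.raises(GLSError):
            sq.lambda_transform(np.eye(3), 1.2)


class TestGLSFit:
    def test_identity_V_reproduces_ols_exactly(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(25), rng.normal(size=(25, 2))])
        y = X @ [1.0, 2.0, -0.5] + rng.normal(0, 0.5, 25)
        fit = sq.gls_fit(y, X, np.eye(25))
        ols = sm.OLS(y, X).fit()
        np.testing.assert_allclose(fit.coef, ols.params, atol=1e-10)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-10)
        assert fit.r2 == pytest.approx(ols.rsquared, abs=1e-10)

    def test_exact_linear_response(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        y = X @ [3.0, 2.0]
        fit = sq.gls_fit(y, X)
        assert fit.r2 == pytest.approx(1.0) and np.allclose(fit.residuals, 0)

    def test_matches_whitening_oracle(self):
        rng = np.random.default_rng(7)
        tree = sq.simulate_tree(20, seed=77)
        V = sq.vcv_from_tree(tree).matrix
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = rng.normal(size=20)
        fit = sq.gls_fit(y, X, V)
        L = np.linalg.cholesky(V)
        ols = sm.OLS(np.linalg.solve(L, y), np.linalg.solve(L, X)).fit()
        np.testing.assert_allclose(fit.coef, ols.params, atol=1e-9)
        np.testing.assert_allclose(fit.se, ols.bse, atol=1e-9)

    def test_rank_deficient_design_rejected(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(GLSError):
            sq.gls_fit(np.arange(10.0), X)

    def test_lnL_invariant_to_consistent_permutation(self):
        rng = np.random.default_rng(8)
        V = sq.vcv_from_tree(sq.simulate_tree(15, seed=5)).matrix
        X = np.column_stack([np.ones(15), rng.normal(size=15)])
        y = rng.normal(size=15)
        perm = rng.permutation(15)
        f1 = sq.gls_fit(y, X, V)
        f2 = sq.gls_fit(y[perm], X[perm], V[np.ix_(perm, perm)])
        assert f1.lnL == pytest.approx(f2.lnL, abs=1e-9)

    def test_aic_recomputed_from_lnL(self):
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        fit = sq.gls_fit(rng.normal(size=20), X)
        # p coefficients + 1 scale
        assert fit.aic == pytest.approx(-2 * fit.lnL + 2 * (fit.p + 1))


class TestFitLambdaML:
    def test_refined_optimum_dominates_grid(self):
        tree = sq.simulate_tree(60, seed=21)
        pc = sq.vcv_from_tree(tree)
        y = sq.simulate_bm(tree, 1.0, 0.5, 0.0, seed=22)
        X = np.ones((60, 1))
        fit = sq.fit_lambda_ml(y, X, pc)
        grid_best = max(
            sq.gls_fit(y, X, sq.lambda_transform(pc.matrix, g)).lnL
            for g in np.linspace(0, 1, 101)
        )
        assert fit.lnL >= grid_best - 1e-12

    def test_ci_is_ordered_and_contains_estimate(self):
        tree = sq.simulate_tree(80, seed=31)
        y = sq.simulate_bm(tree, 1.0, 0.7, 0.0, seed=32)
        fit = sq.fit_lambda_ml(y, np.ones((80, 1)), sq.vcv_from_tree(tree))
        lo, hi = fit.lambda_ci
        assert lo <= fit.lambda_ <= hi

    def test_independent_noise_gives_small_lambda(self):
        hits = 0
        for s in range(20):
            tree = sq.simulate_tree(100, seed=500 + s)
            rng = np.random.default_rng(600 + s)
            y = rng.normal(size=100)  # no phylogenetic signal
            fit = sq.fit_lambda_ml(y, np.ones((100, 1)), sq.vcv_from_tree(tree))
            hits += fit.lambda_ < 0.15
        assert hits >= 18  # >= 90%

    def test_aic_counts_lambda_as_one_parameter(self):
        tree = sq.simulate_tree(40, seed=41)
        y = sq.simulate_bm(tree, 1.0, 0.5, 0.0, seed=42)
        fit = sq.fit_lambda_ml(y, np.ones((40, 1)), sq.vcv_from_tree(tree))
        assert fit.aic == pytest.approx(-2 * fit.lnL + 2 * (fit.p + 1 + 1))


class TestModelComparison:
    def _two_fits(self):
        tree = sq.simulate_tree(50, seed=51)
        pc = sq.vcv_from_tree(tree)
        y = sq.simulate_bm(tree, 1.0, 0.8, 0.0, seed=52)
        X = np.ones((50, 1))
        ols = sq.gls_fit(y, X)
        pgls = sq.fit_lambda_ml(y, X, pc)
        return ols, pgls

    def test_single_fit_delta_zero(self):
        ols, _ = self._two_fits()
        ranked = sq.aic_compare([ols])
        assert ranked[0][1] == 0.0

    def test_mismatched_response_rejected(self):
        rng = np.random.default_rng(0)
        f1 = sq.gls_fit(rng.normal(size=10), np.ones((10, 1)))
        f2 = sq.gls_fit(rng.normal(size=10), np.ones((10, 1)))
        with pytest.raises(GLSError):
            sq.aic_compare([f1, f2])

    def test_small_lnL_gain_prefers_smaller_model(self):
        # larger model pays 2 AIC for <1 lnL gain
        rng = np.random.default_rng(3)
        X1 = np.ones((40, 1))
        X2 = np.column_stack([np.ones(40), rng.normal(size=40)])
        y = rng.normal(size=40)
        f1, f2 = sq.gls_fit(y, X1), sq.gls_fit(y, X2)
        if f2.lnL - f1.lnL < 1:
            assert sq.aic_compare([f1, f2])[0][0] is f1

    def test_lrt_chi2_quantile(self):
        # inverse check of the chi2_1 5% critical value
        assert stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=0.001)
        ols, pgls = self._two_fits()
        res = sq.likelihood_ratio_test(ols, pgls)
        assert res.statistic == pytest.approx(max(0.0, 2 * (pgls.lnL - ols.lnL)))
        assert res.df == 1
        assert res.p_value == pytest.approx(stats.chi2.sf(res.statistic, 1), abs=1e-10)

    def test_identical_likelihood_gives_p_one(self):
        y = np.random.default_rng(5).normal(size=20)
        f = sq.gls_fit(y, np.ones((20, 1)))
        f_lam = sq.gls_fit(y, np.ones((20, 1)), lambda_estimated=True)
        res = sq.likelihood_ratio_test(f, f_lam)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_non_nested_rejected(self):
        y = np.random.default_rng(6).normal(size=20)
        f = sq.gls_fit(y, np.ones((20, 1)))
        with pytest.raises(GLSError):
            sq.likelihood_ratio_test(f, f)


TERMS = ["R", "G", "ln_mass", "R:G", "R:ln_mass", "G:ln_mass", "R:G:ln_mass"]


class TestSequentialAnova:
    def test_full_factorial_residual_df(self, study_like):
        ds, fit, corr, frame = study_like
        pc = sq.vcv_from_tree(ds.phylogeny)
        at = sq.sequential_anova("t_smr", TERMS, frame, pc, "ml")
        assert at.residual["df"] == 188
        assert sum(r["df"] for r in at.rows) + at.residual["df"] == len(frame) - 1

    def test_rows_match_nested_rss_oracle(self, small_dataset, vcv30):
        ds = small_dataset
        fit = sq.fit_mte(ds.table)
        corr = sq.correct(ds.table, fit)
        frame = pd.DataFrame(
            {
                "R": [1 if r.reproductive_mode == "viviparous" else 0 for r in ds.table],
                "G": [1 if r.clade == "snake" else 0 for r in ds.table],
                "ln_mass": corr.ln_mass,
                "t_smr": corr.t_smr,
            }
        )
        lam = 0.5
        at = sq.sequential_anova("t_smr", TERMS, frame, vcv30, lam)
        # oracle: brute-force refit of the nested whitened models
        V = sq.lambda_transform(vcv30.matrix, lam)
        L = np.linalg.cholesky(V)
        cols = {
            "R": frame["R"].to_numpy(float),
            "G": frame["G"].to_numpy(float),
            "ln_mass": frame["ln_mass"].to_numpy(float),
        }

        def col(term):
            out = np.ones(len(frame))
            for p in term.split(":"):
                out = out * cols[p]
            return out

        y = np.linalg.solve(L, frame["t_smr"].to_numpy())
        design = [np.linalg.solve(L, np.ones(len(frame)))]
        rss_prev = float(
            (y - design[0] * (design[0] @ y) / (design[0] @ design[0])) @
            (y - design[0] * (design[0] @ y) / (design[0] @ design[0]))
        )
        for row, term in zip(at.rows, TERMS):
            design.append(np.linalg.solve(L, col(term)))
            Xw = np.column_stack(design)
            beta, *_ = np.linalg.lstsq(Xw, y, rcond=None)
            rss = float((y - Xw @ beta) @ (y - Xw @ beta))
            assert row["SS"] == pytest.approx(rss_prev - rss, abs=1e-8)
            rss_prev = rss

    def test_ss_conservation(self, small_dataset, vcv30):
        ds = small_dataset
        fit = sq.fit_mte(ds.table)
        corr = sq.correct(ds.table, fit)
        frame = pd.DataFrame(
            {
                "R": [1 if r.reproductive_mode == "viviparous" else 0 for r in ds.table],
                "G": [1 if r.clade == "snake" else 0 for r in ds.table],
                "ln_mass": corr.ln_mass,
                "t_smr": corr.t_smr,
            }
        )
        at = sq.sequential_anova("t_smr", TERMS, frame, vcv30, 0.7)
        V = sq.lambda_transform(vcv30.matrix, 0.7)
        L = np.linalg.cholesky(V)
        y = np.linalg.solve(L, frame["t_smr"].to_numpy())
        ones = np.linalg.solve(L, np.ones(len(frame)))
        mu = (ones @ y) / (ones @ ones)
        total = float((y - mu * ones) @ (y - mu * ones))
        assert sum(r["SS"] for r in at.rows) + at.residual["SS"] == pytest.approx(
            total, abs=1e-8
        )

    def test_orthogonal_term_order_invariant(self):
        # balanced 2x2 design with V = I: factor SS identical first or last
        n = 40
        A = np.tile([0, 0, 1, 1], n // 4).astype(float)
        B = np.tile([0, 1, 0, 1], n // 4).astype(float)
        rng = np.random.default_rng(11)
        y = 1.0 + 0.5 * A - 0.3 * B + rng.normal(0, 0.4, n)
        frame = pd.DataFrame({"A": A - A.mean(), "B": B - B.mean(), "y": y})
        first = sq.sequential_anova("y", ["A", "B"], frame, None, 0.0)
        last = sq.sequential_anova("y", ["B", "A"], frame, None, 0.0)
        assert first.rows[0]["SS"] == pytest.approx(last.rows[1]["SS"], abs=1e-8)

    def test_single_level_factor_rejected(self):
        frame = pd.DataFrame({"R": np.zeros(10), "y": np.arange(10.0)})
        with pytest.raises(GLSError):
            sq.sequential_anova("y", ["R"], frame, None, 0.0)


class TestPooledT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = sq.pooled_t_test(a, a)
        assert res.statistic == pytest.approx(0.0) and res.p_value == pytest.approx(1.0)

    def test_study_group_sizes_give_df_194(self):
        rng = np.random.default_rng(12)
        res = sq.pooled_t_test(rng.normal(size=128), rng.normal(size=68))
        assert res.df == 194

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(0, 1, 17), rng.normal(0.3, 1.2, 23)
        res = sq.pooled_t_test(a, b)
        sp2 = ((16 * a.var(ddof=1)) + (22 * b.var(ddof=1))) / 38
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 17 + 1 / 23))
        assert res.statistic == pytest.approx(t, abs=1e-12)
        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 38), abs=1e-12)

    def test_zero_pooled_variance_rejected(self):
        with pytest.raises(GLSError):
            sq.pooled_t_test([1.0, 1.0], [2.0, 2.0])


class TestASR:
    def test_constant_trait(self):
        tree = sq.simulate_tree(10, seed=61)
        vals = {s: 3.14 for s in tree.tip_labels}
        anc = sq.asr_brownian(tree, vals)
        assert all(v == pytest.approx(3.14) for v in anc.values())

    def test_symmetric_cherry_root_is_midpoint(self):
        tree = sq.read_newick("(A:1,B:1);")
        anc = sq.asr_brownian(tree, {"A": 0.0, "B": 4.0})
        assert list(anc.values())[0] == pytest.approx(2.0)

    def test_root_matches_gls_closed_form(self):
        tree = sq.simulate_tree(10, seed=62)
        y = sq.simulate_bm(tree, 1.0, 1.0, 1.5, seed=63)
        vals = dict(zip(tree.tip_labels, y))
        anc = sq.asr_brownian(tree, vals)
        V = sq.vcv_from_tree(tree).matrix
        ones = np.ones(10)
        mu = (ones @ np.linalg.solve(V, y)) / (ones @ np.linalg.solve(V, ones))
        root_label = next(iter(anc))
        assert anc[root_label] == pytest.approx(mu, abs=1e-9)

    def test_missing_tip_value_rejected(self):
        tree = sq.read_newick("(A:1,B:1);")
        with pytest.raises(GLSError):
            sq.asr_brownian(tree, {"A": 1.0})
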