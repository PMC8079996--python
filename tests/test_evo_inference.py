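"""Likelihood engine, model fitting, PGLS, ancestral states and ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from lifecube import (
    asr_bm,
    bm_loglik,
    class_anova,
    fit_model,
    model_covariance,
    mv_pgls,
    parse_newick,
    pgls,
    phylo_signal_lambda,
    select_model,
    simulate_trait,
    vcv_matrix,
)
from lifecube.evo_inference import _model_tree, _profile_loglik, _align


def dense_loglik(tree, model, shape, x, sigma2, z0, dense_vcv):
    """Independent oracle: dense multivariate-normal density with the model
    covariance built from dendropy path sums."""
    if model in ("BM", "kappa"):
        C = dense_vcv(_model_tree(tree, model, shape) if model == "kappa" else tree)
    elif model == "lambda":
        C = dense_vcv(tree)
        d = np.diag(C).copy()
        C = C * shape
        np.fill_diagonal(C, d)
    else:  # OU from the closed-form covariance on shared paths
        S = dense_vcv(tree)
        T = np.diag(S).max()
        C = np.exp(-2 * shape * (T - S)) * (1 - np.exp(-2 * shape * S)) / (2 * shape)
        np.fill_diagonal(C, (1 - np.exp(-2 * shape * T)) / (2 * shape))
    n = tree.n_tips
    return multivariate_normal.logpdf(x, mean=np.full(n, z0), cov=sigma2 * C)


class TestLikelihoodEngine:
    def test_pruning_matches_dense_all_models(self, yule, dense_vcv_oracle):
        rng = np.random.default_rng(0)
        for seed in range(10):
            t = yule(int(rng.integers(4, 13)), 100 + seed)
            x = rng.normal(size=t.n_tips)
            s2, z0 = float(rng.uniform(0.5, 2)), float(rng.normal())
            for model, shape in [("BM", None), ("lambda", 0.4),
                                 ("kappa", 0.7), ("OU", 1.1)]:
                ll = bm_loglik(_model_tree(t, model, shape),
                               dict(zip(t.tip_names, x)), s2, z0)
                ref = dense_loglik(t, model, shape, x, s2, z0, dense_vcv_oracle)
                assert ll == pytest.approx(ref, abs=1e-8)

    def test_two_tip_star_hand_value(self):
        """Two independent N(1, 1) tips at (0, 2): logL = -(log 2pi + 1)."""
        t = parse_newick("(A:1,B:1);")
        ll = bm_loglik(t, {"A": 0.0, "B": 2.0}, 1.0, 1.0)
        assert ll == pytest.approx(-(math.log(2 * math.pi) + 1.0))

    def test_rate_doubling_identity_at_mean(self, star5):
        """With x == z0, doubling sigma2 lowers logL by (n/2) log 2."""
        x = {nm: 1.0 for nm in star5.tip_names}
        d = bm_loglik(star5, x, 1.0, 1.0) - bm_loglik(star5, x, 2.0, 1.0)
        assert d == pytest.approx(2.5 * math.log(2.0))

    def test_name_mismatch_lists_offenders(self, star5):
        with pytest.raises(ValueError, match="E"):
            bm_loglik(star5, {"A": 1, "B": 2, "C": 3, "D": 4, "X": 5}, 1.0, 0.0)


class TestFitModel:
    def test_star_tree_closed_form(self, star5):
        x = {"A": 1.0, "B": 3.0, "C": 2.0, "D": 5.0, "E": 4.0}
        f = fit_model(star5, x, "BM")
        arr = np.array(list(x.values()))
        assert f.z0 == pytest.approx(arr.mean())
        assert f.sigma2 == pytest.approx(((arr - arr.mean()) ** 2).mean())
        assert f.aic == pytest.approx(2 * 2 - 2 * f.loglik)

    def test_kappa_unidentifiable_on_unit_branches_flagged(self):
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        x = {"A": 0.1, "B": 0.5, "C": -0.2, "D": 0.9}
        fk = fit_model(t, x, "kappa")
        fb = fit_model(t, x, "BM")
        assert fk.loglik >= fb.loglik - 1e-9
        assert fk.note is not None and "unidentifiable" in fk.note

    def test_lambda_recovery_under_bm(self, yule):
        """BM data should fit lambda near 1."""
        t = yule(150, 42)
        x = simulate_trait(t, {"model": "BM", "z0": 0.0, "sigma2": 1.0},
                           np.random.default_rng(1))
        f = fit_model(t, x, "lambda")
        assert f.shape > 0.85

    def test_min_tips_enforced(self):
        t = parse_newick("(A:1,B:1,C:1);")
        with pytest.raises(ValueError, match="4 tips"):
            fit_model(t, {"A": 1.0, "B": 2.0, "C": 3.0}, "BM")


class TestSelectModel:
    def _fit(self, star5, model):
        x = {"A": 1.0, "B": 3.0, "C": 2.0, "D": 5.0, "E": 4.0}
        return fit_model(star5, x, model)

    def test_min_aic_wins_and_ties_prefer_simpler(self, star5):
        fits = [self._fit(star5, m) for m in ("BM", "lambda", "kappa", "OU")]
        best = select_model(fits)
        assert best.aic == min(f.aic for f in fits)
        # on a star tree BM and the shape models coincide; BM has 2 params
        assert best.model == "BM"

    def test_permutation_invariance(self, star5):
        fits = [self._fit(star5, m) for m in ("BM", "lambda", "kappa", "OU")]
        assert select_model(fits).model == select_model(fits[::-1]).model

    def test_fits_on_different_data_rejected(self, star5):
        a = self._fit(star5, "BM")
        b = fit_model(star5, {"A": 9.0, "B": 3.0, "C": 2.0, "D": 5.0, "E": 4.0}, "BM")
        with pytest.raises(ValueError, match="different data"):
            select_model([a, b])


class TestSignal:
    def test_strong_bm_signal_hits_permutation_floor(self, yule):
        t = yule(150, 7)
        x = simulate_trait(t, {"model": "BM", "z0": 0.0, "sigma2": 1.0},
                           np.random.default_rng(2))
        r = phylo_signal_lambda(t, x, n_permutations=999, seed=5)
        assert r.p_value == pytest.approx(1.0 / 1000.0)
        assert r.lambda_hat > 0.8
        assert r.p_value >= 1.0 / (r.n_permutations + 1)

    def test_constant_trait_degenerate_flag(self, star5):
        r = phylo_signal_lambda(star5, {nm: 2.0 for nm in star5.tip_names},
                                n_permutations=19, seed=0)
        assert r.degenerate

    def test_seeded_reproducibility(self, yule):
        t = yule(40, 8)
        x = simulate_trait(t, {"model": "BM", "z0": 0.0, "sigma2": 1.0},
                           np.random.default_rng(3))
        a = phylo_signal_lambda(t, x, n_permutations=99, seed=11)
        b = phylo_signal_lambda(t, x, n_permutations=99, seed=11)
        assert a.p_value == b.p_value and a.lambda_hat == b.lambda_hat


def _pic_slope(tree, y, x):
    """Independent-contrasts regression through the origin (oracle)."""
    yv = _align(tree, y)
    xv = _align(tree, x)
    m = {i: (xv[i], yv[i]) for i in range(tree.n_tips)}
    v = {i: 0.0 for i in range(tree.n_tips)}
    cx, cy = [], []
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            continue
        k0 = kids[0]
        mx, my = m[k0]
        vv = v[k0] + tree.blen[k0]
        for k in kids[1:]:
            nx, ny = m[k]
            vk = v[k] + tree.blen[k]
            V = vv + vk
            cx.append((mx - nx) / math.sqrt(V))
            cy.append((my - ny) / math.sqrt(V))
            mx = (mx * vk + nx * vv) / V
            my = (my * vk + ny * vv) / V
            vv = vv * vk / V
        m[node] = (mx, my)
        v[node] = vv
    cx, cy = np.array(cx), np.array(cy)
    return float((cx * cy).sum() / (cx * cx).sum())


class TestPgls:
    def test_star_tree_equals_ols(self, star5):
        y = {"A": 2.1, "B": 4.0, "C": 5.9, "D": 8.2, "E": 9.8}
        x = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0, "E": 5.0}
        fit = pgls(star5, y, x)
        xv = np.array(list(x.values()))
        yv = np.array(list(y.values()))
        b, a = np.polyfit(xv, yv, 1)
        assert fit.slope == pytest.approx(b, abs=1e-10)
        assert fit.intercept == pytest.approx(a, abs=1e-10)

    def test_exact_linear_star_case(self, cherry_plus_one):
        t = parse_newick("(A:1,B:1,C:1);")
        fit = pgls(t, {"A": 2.0, "B": 4.0, "C": 6.0}, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)
        assert fit.sigma2_resid == pytest.approx(0.0, abs=1e-12)

    def test_bm_pgls_slope_matches_contrasts(self, yule):
        rng = np.random.default_rng(4)
        for seed in range(5):
            t = yule(10, 200 + seed)
            x = pd.Series(rng.normal(size=10), index=t.tip_names)
            y = pd.Series(rng.normal(size=10), index=t.tip_names)
            fit = pgls(t, y, x)  # BM covariance
            assert fit.slope == pytest.approx(_pic_slope(t, y, x), abs=1e-8)

    def test_slope_invariant_to_response_shift(self, yule):
        t = yule(12, 9)
        rng = np.random.default_rng(5)
        x = pd.Series(rng.normal(size=12), index=t.tip_names)
        y = pd.Series(rng.normal(size=12), index=t.tip_names)
        f1 = pgls(t, y, x)
        f2 = pgls(t, y + 10.0, x)
        assert f2.slope == pytest.approx(f1.slope, abs=1e-10)
        assert f2.intercept == pytest.approx(f1.intercept + 10.0, abs=1e-8)

    def test_singular_design_rejected(self, star5):
        with pytest.raises(ValueError, match="singular"):
            pgls(star5, {nm: 1.0 * i for i, nm in enumerate(star5.tip_names)},
                 {nm: 3.0 for nm in star5.tip_names})


class TestMvPgls:
    def test_star_tree_reduces_to_ols(self):
        t = parse_newick("(A:1,B:1,C:1,D:1,E:1,F:1,G:1,H:1);")
        rng = np.random.default_rng(6)
        x = pd.Series(rng.normal(size=8), index=t.tip_names)
        Y = pd.DataFrame(rng.normal(size=(8, 3)), index=t.tip_names,
                         columns=["u", "v", "w"])
        fit = mv_pgls(t, Y, x, estimate_error=False)
        X = np.column_stack([np.ones(8), x.values])
        B_ols, *_ = np.linalg.lstsq(X, Y.values, rcond=None)
        np.testing.assert_allclose(fit.B.values, B_ols, atol=1e-5)
        res = Y.values - X @ B_ols
        np.testing.assert_allclose(fit.R.values * 1.0, res.T @ res / 8, atol=1e-5)

    def test_loglik_matches_dense_evaluation(self, yule):
        t = yule(6, 11)
        rng = np.random.default_rng(7)
        x = pd.Series(rng.normal(size=6), index=t.tip_names)
        Y = pd.DataFrame(rng.normal(size=(6, 3)), index=t.tip_names,
                         columns=["u", "v", "w"])
        fit = mv_pgls(t, Y, x, estimate_error=True)
        C = vcv_matrix(t).matrix
        lam = fit.lambda_hat
        Cl = lam * C + (1 - lam) * np.diag(np.diag(C))
        Sig = np.kron(Cl, fit.R.values) + np.kron(np.eye(6), np.diag(fit.meas_error.values))
        X = np.column_stack([np.ones(6), x.values])
        mean = (X @ fit.B.values).ravel()
        ref = multivariate_normal.logpdf(Y.values.ravel(), mean=mean, cov=Sig)
        assert fit.loglik == pytest.approx(ref, abs=1e-8)

    def test_optimum_beats_dense_grid(self, yule):
        """Returned optimum dominates a (lambda, e) grid scored by dense
        likelihood with plug-in GLS coefficients and residual covariance."""
        t = yule(5, 17)
        rng = np.random.default_rng(3)
        x = pd.Series(rng.normal(size=5), index=t.tip_names)
        Y = pd.DataFrame(rng.normal(size=(5, 3)), index=t.tip_names,
                         columns=["a", "b", "c"])
        fit = mv_pgls(t, Y, x, estimate_error=True)
        C = vcv_matrix(t).matrix
        X = np.column_stack([np.ones(5), x.values])
        best = -np.inf
        for lam in np.linspace(0, 1, 21):
            for le in np.linspace(-6, 1, 21):
                e = np.full(3, np.exp(le))
                Bc, *_ = np.linalg.lstsq(X, Y.values, rcond=None)
                R = np.cov((Y.values - X @ Bc).T) / np.diag(C).mean() + 1e-6 * np.eye(3)
                for _ in range(25):
                    Cl = lam * C + (1 - lam) * np.diag(np.diag(C))
                    Sig = np.kron(Cl, R) + np.kron(np.eye(5), np.diag(e))
                    Si = np.linalg.inv(Sig)
                    Xf = np.kron(X, np.eye(3))
                    beta = np.linalg.solve(Xf.T @ Si @ Xf, Xf.T @ Si @ Y.values.ravel())
                    Bc = beta.reshape(2, 3)
                    res = Y.values - X @ Bc
                    R_new = res.T @ np.linalg.inv(Cl) @ res / 5
                    if np.allclose(R_new, R, atol=1e-12):
                        R = R_new
                        break
                    R = R_new
                ll = multivariate_normal.logpdf(
                    Y.values.ravel(), mean=(X @ Bc).ravel(),
                    cov=np.kron(Cl, R) + np.kron(np.eye(5), np.diag(e)),
                    allow_singular=True,
                )
                best = max(best, ll)
        assert fit.loglik >= best - 1e-6

    def test_correlations_bounded_and_unit_diagonal(self, yule):
        t = yule(30, 13)
        rng = np.random.default_rng(8)
        x = pd.Series(rng.normal(size=30), index=t.tip_names)
        Y = pd.DataFrame(rng.normal(size=(30, 3)), index=t.tip_names,
                         columns=["u", "v", "w"])
        fit = mv_pgls(t, Y, x)
        np.testing.assert_allclose(np.diag(fit.corr.values), 1.0)
        assert np.abs(fit.corr.values).max() <= 1.0 + 1e-9
        assert np.linalg.eigvalsh(fit.R.values).min() >= -1e-9


class TestAsr:
    def test_star_root_is_mean(self):
        t = parse_newick("(A:1,B:1,C:1);")
        a = asr_bm(t, {"A": 1.0, "B": 2.0, "C": 3.0})
        assert a.root_estimate == pytest.approx(2.0)

    def test_two_tip_precision_weighted_mean(self):
        t = parse_newick("(A:1,B:3);")
        a = asr_bm(t, {"A": 0.0, "B": 4.0})
        assert a.root_estimate == pytest.approx(1.0)

    def test_matches_dense_conditional_mean(self, yule):
        for seed in range(3):
            t = yule(9, 300 + seed)
            rng = np.random.default_rng(seed)
            x = rng.normal(size=9)
            a = asr_bm(t, dict(zip(t.tip_names, x)))
            # dense oracle: E[anc | tips] = z0 + S C^-1 (x - z0)
            depth = t.depths()
            C = vcv_matrix(t).matrix

            def path(i):
                p = [i]
                while t.parent[p[-1]] >= 0:
                    p.append(t.parent[p[-1]])
                return p

            S = np.zeros((t.n_nodes, t.n_tips))
            for nd in range(t.n_nodes):
                anc = set(path(nd))
                for tip in range(t.n_tips):
                    mrca = next(q for q in path(tip) if q in anc)
                    S[nd, tip] = depth[mrca]
            z0 = fit_model(t, dict(zip(t.tip_names, x)), "BM").z0
            ref = z0 + S @ np.linalg.solve(C, x - z0)
            np.testing.assert_allclose(a.estimates, ref, atol=1e-8)

    def test_root_within_tip_range_on_ultrametric(self, yule):
        for seed in range(5):
            t = yule(15, 400 + seed)
            x = np.random.default_rng(seed).normal(size=15)
            a = asr_bm(t, dict(zip(t.tip_names, x)))
            assert x.min() - 1e-12 <= a.root_estimate <= x.max() + 1e-12


class TestAnova:
    def test_hand_computed_two_groups(self):
        r = class_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert r.F == pytest.approx(1.5)
        assert (r.df_between, r.df_within) == (1, 4)

    def test_identical_groups_give_zero_f(self):
        r = class_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert r.F == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(9)
        vals = np.concatenate([rng.normal(m, 1, 12) for m in (0.0, 0.6, 1.4)])
        labs = np.repeat(["x", "y", "z"], 12)
        r = class_anova(vals, labs)
        grand = vals.mean()
        ssb = sum(12 * (vals[labs == g].mean() - grand) ** 2 for g in "xyz")
        ssw = sum(((vals[labs == g] - vals[labs == g].mean()) ** 2).sum() for g in "xyz")
        F = (ssb / 2) / (ssw / (36 - 3))
        assert r.F == pytest.approx(F, abs=1e-10)
        assert len(r.tukey) == 3  # three pairwise comparisons

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            class_anova([1, 2, 3], ["a", "a", "b"])
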