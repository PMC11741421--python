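import numpy as np
import pytest

from strainepi.io import read_newick
from strainepi.pglmm import (
    PGLMM,
    PglmmFit,
    PhyloCorrelation,
    _BasePosterior,
    _BernoulliPglmmPosterior,
    _GaussianPglmmPosterior,
    _chol_psd,
    _integrated_loglik,
    _psis_elpd,
    compare_models,
    loo_elpd,
    phylo_r2,
    ratio_regularizer_prior_mass,
    tree_to_correlation,
)
from strainepi.simulate import PhyloSimConfig, simulate_phylo_dataset


def finite_difference(post, th, eps=1e-6):
    g = np.zeros_like(th)
    for i in range(th.size):
        tp, tm = th.copy(), th.copy()
        tp[i] += eps
        tm[i] -= eps
        g[i] = (post.logp_and_grad(tp)[0] - post.logp_and_grad(tm)[0]) / (2 * eps)
    return g


class TestTreeToCorrelation:
    def test_star_tree_gives_identity(self):
        t = read_newick("(A:1,B:1,C:1,D:1);")
        c = tree_to_correlation(t)
        np.testing.assert_allclose(c.omega, np.eye(4), atol=1e-12)

    def test_shared_path_worked_example(self):
        t = read_newick("((A:1,B:1):1,C:2);")
        c = tree_to_correlation(t)
        i = {n: k for k, n in enumerate(c.leaf_order)}
        assert c.omega[i["A"], i["B"]] == pytest.approx(0.5)
        assert c.omega[i["A"], i["C"]] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(c.omega), 1.0)

    def test_ultrametric_identity(self):
        # for an ultrametric tree, omega_ij = 1 - d_ij / (2 * depth)
        t = read_newick("((A:1,B:1):2,(C:2,D:2):1);")
        c = tree_to_correlation(t)
        dm = t.tip_tip_distances()
        order = [list(dm.ids).index(n) for n in c.leaf_order]
        d = dm.data[np.ix_(order, order)]
        np.testing.assert_allclose(c.omega, 1.0 - d / (2 * 3.0), atol=1e-12)

    def test_zero_root_to_tip_rejected(self):
        with pytest.raises(ValueError):
            tree_to_correlation(read_newick("((A:0,B:1):0,C:1);"))


def test_ratio_regularizer_prior_mass_closed_form_and_sampling(rng):
    analytic = ratio_regularizer_prior_mass()
    assert analytic == pytest.approx(1 - np.exp(-2))
    draws = rng.gamma(shape=1.0, scale=1 / 2.0, size=200_000)
    assert np.mean(draws < 1.0) == pytest.approx(analytic, abs=5e-3)


class TestGradients:
    def test_all_posteriors_match_finite_differences(self, rng):
        n, p = 10, 2
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        A = rng.normal(size=(n, n))
        om = A @ A.T
        s = 1 / np.sqrt(np.diag(om))
        om = s[:, None] * om * s[None, :]
        L = _chol_psd(om)
        y = rng.normal(size=n)
        yb = (rng.random(n) < 0.5).astype(float)
        posts = [
            _GaussianPglmmPosterior(y, X, L, True, 5.0, 3.0, 2.5),
            _GaussianPglmmPosterior(y, X, L, False, 5.0, 3.0, 2.5),
            _BernoulliPglmmPosterior(yb, X, L, 5.0, 1.0),
            _BasePosterior(y, X, "gaussian"),
            _BasePosterior(yb, X, "bernoulli"),
        ]
        for post in posts:
            th = 0.3 * rng.standard_normal(post.dim)
            _, g = post.logp_and_grad(th)
            np.testing.assert_allclose(g, finite_difference(post, th), atol=1e-5)


class TestPhyloR2:
    def _fit(self, sp, sr):
        S = len(sp)
        return PglmmFit(
            family="gaussian",
            regularized=True,
            leaf_order=["a", "b"],
            beta=np.zeros((S, 1)),
            sigma_p=np.asarray(sp, dtype=float),
            sigma_r=np.asarray(sr, dtype=float),
            leaf_effects=np.zeros((S, 2)),
            rhat=np.ones(1),
            divergences=0,
            converged=True,
        )

    def test_equal_scales_give_half(self):
        r2 = phylo_r2(self._fit([1.0, 2.0, 0.5], [1.0, 2.0, 0.5]))
        np.testing.assert_allclose(r2["draws"], 0.5)

    def test_vanishing_phylo_noise_gives_zero(self):
        r2 = phylo_r2(self._fit([1e-8, 1e-9], [1.0, 1.0]))
        assert r2["mean"] < 1e-10

    def test_matches_per_draw_brute_force(self, rng):
        sp = rng.random(50) + 0.1
        sr = rng.random(50) + 0.1
        r2 = phylo_r2(self._fit(sp, sr))
        np.testing.assert_allclose(r2["draws"], sp**2 / (sp**2 + sr**2))

    def test_bernoulli_family_rejected(self):
        fit = self._fit([1.0], [1.0])
        fit.family = "bernoulli"
        fit.sigma_r = None
        with pytest.raises(ValueError):
            phylo_r2(fit)


class TestIntegratedLoglik:
    def _fit(self, family, S, n, rng, sigma_p=1.0):
        return PglmmFit(
            family=family,
            regularized=True,
            leaf_order=[f"s{i}" for i in range(n)],
            beta=rng.normal(size=(S, 1)) * 0.1,
            sigma_p=np.full(S, sigma_p),
            sigma_r=np.full(S, 0.7) if family == "gaussian" else None,
            leaf_effects=rng.normal(size=(S, n)),
            rhat=np.ones(1),
            divergences=0,
            converged=True,
        )

    def test_identity_omega_gaussian_marginal_variance(self, rng):
        # with omega = I the conditional reduces to the marginal:
        # predictive variance sigma_r^2 + sigma_p^2 for every sample
        n, S = 5, 40
        fit = self._fit("gaussian", S, n, rng, sigma_p=1.3)
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        ll = _integrated_loglik(fit, y, X, np.eye(n))
        var = 0.7**2 + 1.3**2
        mean = fit.beta[:, [0]] * np.ones((1, n))
        expected = -0.5 * np.log(2 * np.pi * var) - 0.5 * (y[None, :] - mean) ** 2 / var
        np.testing.assert_allclose(ll, expected, atol=1e-10)

    def test_bernoulli_quadrature_degenerates_to_plugin(self, rng):
        # sigma_p -> 0: the integral collapses onto the fixed-effect part
        n, S = 6, 30
        fit = self._fit("bernoulli", S, n, rng, sigma_p=1e-12)
        fit.leaf_effects = np.zeros((S, n))
        y = (rng.random(n) < 0.5).astype(float)
        X = np.ones((n, 1))
        ll = _integrated_loglik(fit, y, X, np.eye(n))
        eta = fit.beta @ X.T
        sgn = np.where(y > 0, 1.0, -1.0)
        expected = -np.logaddexp(0.0, -sgn[None, :] * eta)
        np.testing.assert_allclose(ll, expected, atol=1e-8)


@pytest.mark.filterwarnings("ignore")
class TestFitting:
    def test_null_data_yields_near_zero_r2(self):
        _, corr, y, _ = simulate_phylo_dataset(
            PhyloSimConfig(n_tips=100, sigma_p=0.0, sigma_r=1.0, seed=11)
        )
        fit = PGLMM(chains=2, warmup=400, draws=400, seed=1).fit(None, y, corr).fit_
        assert phylo_r2(fit)["mean"] < 0.1

    def test_strong_signal_recovered(self):
        _, corr, y, true_r2 = simulate_phylo_dataset(
            PhyloSimConfig(n_tips=150, sigma_p=2.09, sigma_r=0.418, seed=12)
        )
        fit = PGLMM(chains=2, warmup=400, draws=400, seed=2).fit(None, y, corr).fit_
        r2 = phylo_r2(fit)
        assert abs(r2["mean"] - true_r2) < 0.12

    def test_bernoulli_family_runs_and_aligns(self, rng):
        _, corr, lat, _ = simulate_phylo_dataset(
            PhyloSimConfig(n_tips=60, sigma_p=1.0, sigma_r=1.0, seed=13)
        )
        y = (rng.random(60) < 1 / (1 + np.exp(-lat))).astype(float)
        fit = PGLMM(family="bernoulli", chains=2, warmup=300, draws=300, seed=3).fit(
            None, y, corr
        ).fit_
        assert fit.sigma_r is None
        assert fit.leaf_effects.shape[1] == 60

    def test_self_comparison_elpd_diff_within_noise(self, rng):
        # scoring the same base model from two independent posterior runs:
        # the ELPD difference is Monte-Carlo noise around zero
        n = 40
        y = rng.normal(size=n)
        X = np.ones((n, 1))
        post = _BasePosterior(y, X, "gaussian")
        from strainepi.nuts import run_chains

        pw = []
        for seed in (1, 2):
            res = run_chains(
                post.logp_and_grad, post.initial_position, 2, 400, 400, seed=seed
            )
            elpd, _ = _psis_elpd(post.pointwise_loglik(res.flat))
            pw.append(elpd)
        diff = pw[0] - pw[1]
        se = np.sqrt(n * diff.var(ddof=1))
        assert abs(diff.sum()) < max(2 * se, 0.5)

    def test_loo_matches_exact_refit_small_n(self):
        _, corr, y, _ = simulate_phylo_dataset(
            PhyloSimConfig(n_tips=6, sigma_p=1.0, sigma_r=1.0, seed=2)
        )
        fit = PGLMM(chains=4, warmup=500, draws=500, seed=3).fit(None, y, corr).fit_
        loo = loo_elpd(fit, y, None, corr)
        om = corr.omega
        from scipy.special import logsumexp

        exact = np.zeros(len(y))
        for i in range(len(y)):
            keep = [j for j in range(len(y)) if j != i]
            sub = PhyloCorrelation(
                [corr.leaf_order[j] for j in keep], om[np.ix_(keep, keep)]
            )
            f2 = (
                PGLMM(chains=4, warmup=500, draws=500, seed=100 + i)
                .fit(None, y[keep], sub)
                .fit_
            )
            w = np.linalg.solve(om[np.ix_(keep, keep)], om[np.ix_(keep, [i])]).ravel()
            m = f2.leaf_effects @ w
            v = f2.sigma_p**2 * (1.0 - om[i, keep] @ np.linalg.solve(
                om[np.ix_(keep, keep)], om[keep, i]
            ))
            var = f2.sigma_r**2 + v
            ll = -0.5 * np.log(2 * np.pi * var) - 0.5 * (y[i] - f2.beta[:, 0] - m) ** 2 / var
            exact[i] = logsumexp(ll) - np.log(ll.size)
        np.testing.assert_allclose(loo["pointwise"], exact, atol=0.35)

    def test_null_comparison_makes_no_positive_call(self):
        _, corr, y, _ = simulate_phylo_dataset(
            PhyloSimConfig(n_tips=80, sigma_p=0.0, sigma_r=1.0, seed=21)
        )
        c = compare_models(
            y, None, corr, family="gaussian", chains=2, warmup=400, draws=400, seed=4
        )
        assert not c.positive_call
        assert abs(c.elpd_diff) < max(4 * c.se_diff, 2.0)
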