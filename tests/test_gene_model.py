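import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strainepi.containers import GeneMatrix, SampleMetadata
from strainepi.genes import (
    GeneGLMAssociator,
    GeneHorseshoeAssociator,
    HorseshoeConfig,
    bh_adjust,
    call_gene_hits,
    GeneAssociation,
)


def _dataset(presence, y, covariates=None, family="bernoulli"):
    n = presence.shape[1]
    samples = [f"s{i}" for i in range(n)]
    gm = GeneMatrix("sp", [f"g{i}" for i in range(presence.shape[0])], samples, presence)
    meta = SampleMetadata(samples, np.asarray(y, dtype=float), covariates, family)
    return gm, meta


class TestGeneGlm:
    def test_two_by_two_closed_form_log_odds_ratio(self):
        # control/case x absent/present table [[30,10],[10,30]]
        y = np.r_[np.zeros(40), np.ones(40)]
        g = np.r_[np.zeros(30), np.ones(10), np.zeros(10), np.ones(30)]
        gm, meta = _dataset(g[None, :], y)
        (a,) = GeneGLMAssociator().fit(gm, meta).associations_
        assert a.coefficient == pytest.approx(np.log(9.0), abs=1e-4)

    def test_presence_independent_of_outcome_gives_zero(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        g = np.r_[np.tile([0.0, 1.0], 10), np.tile([0.0, 1.0], 10)]
        gm, meta = _dataset(g[None, :], y)
        (a,) = GeneGLMAssociator().fit(gm, meta).associations_
        assert a.coefficient == pytest.approx(0.0, abs=1e-8)

    def test_constant_covariate_leaves_coefficient_unchanged(self, rng):
        n = 80
        g = (rng.random(n) < 0.5).astype(float)
        y = (rng.random(n) < 1 / (1 + np.exp(-(g - 0.5)))).astype(float)
        gm, meta = _dataset(g[None, :], y)
        (a1,) = GeneGLMAssociator().fit(gm, meta).associations_
        cov = pd.DataFrame({"c": np.ones(n)})
        gm2, meta2 = _dataset(g[None, :], y, covariates=cov)
        (a2,) = GeneGLMAssociator().fit(gm2, meta2).associations_
        assert a1.coefficient == pytest.approx(a2.coefficient, abs=1e-6)

    def test_constant_gene_skipped_with_warning(self, rng):
        pres = np.vstack([np.ones(30), (rng.random(30) < 0.5).astype(float)])
        y = (rng.random(30) < 0.5).astype(float)
        gm, meta = _dataset(pres, y)
        with pytest.warns(UserWarning, match="constant"):
            est = GeneGLMAssociator().fit(gm, meta)
        assert len(est.associations_) == 1

    def test_complete_separation_flagged_and_excluded_from_bh(self):
        y = np.r_[np.zeros(20), np.ones(20)]
        g_sep = y.copy()  # perfectly separates
        g_ok = np.tile([0.0, 1.0], 20)
        gm, meta = _dataset(np.vstack([g_sep, g_ok]), y)
        est = GeneGLMAssociator().fit(gm, meta)
        sep = est.associations_[0]
        assert sep.note == "separated"
        assert not np.isfinite(sep.coefficient)
        assert np.isfinite(est.associations_[1].q_value)

    def test_gaussian_family_recovers_linear_effect(self, rng):
        n = 200
        g = (rng.random(n) < 0.5).astype(float)
        y = 1.0 + 2.0 * g + rng.normal(0, 0.5, n)
        gm, meta = _dataset(g[None, :], y, family="gaussian")
        (a,) = GeneGLMAssociator().fit(gm, meta).associations_
        assert a.coefficient == pytest.approx(2.0, abs=0.3)


class TestBhAdjust:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_and_all_ones(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200))
    def test_matches_brute_force_and_statsmodels(self, ps):
        p = np.asarray(ps)
        # brute force: q_i = min over p_(j) >= p_i of m * p_(j) / rank_j
        m = p.size
        order = np.argsort(p, kind="mergesort")
        sp = p[order]
        brute_sorted = np.empty(m)
        for i in range(m):
            brute_sorted[i] = min(min(sp[j] * m / (j + 1) for j in range(i, m)), 1.0)
        brute = np.empty(m)
        brute[order] = brute_sorted
        np.testing.assert_allclose(bh_adjust(p), brute, atol=1e-12)
        from statsmodels.stats.multitest import multipletests

        np.testing.assert_allclose(
            bh_adjust(p), multipletests(p, method="fdr_bh")[1], atol=1e-12
        )


class TestHitCalling:
    def test_strict_threshold_boundary(self):
        a = GeneAssociation("g", 1.0, 0.1, 0.01, 0.049)
        b = GeneAssociation("h", 1.0, 0.1, 0.01, 0.05)
        out = call_gene_hits([a, b], q_threshold=0.05)
        assert out[0].is_hit and not out[1].is_hit

    def test_empty_list(self):
        assert call_gene_hits([]) == []

    def test_horseshoe_rule_requires_interval_and_magnitude(self):
        a = GeneAssociation("g", 1.0, posterior_interval=(0.2, 1.8))
        b = GeneAssociation("h", 0.3, posterior_interval=(0.1, 0.5))
        c = GeneAssociation("i", 1.0, posterior_interval=(-0.1, 2.0))
        out = call_gene_hits([a, b, c], effect_threshold=0.5)
        assert [x.is_hit for x in out] == [True, False, False]


class TestHorseshoe:
    def test_default_expected_nonzero_fraction(self):
        assert HorseshoeConfig().expected_nonzero_fraction == 0.01

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            HorseshoeConfig(expected_nonzero_fraction=0.0)
        with pytest.raises(ValueError):
            HorseshoeConfig(interval_level=0.4)

    def test_planted_gene_detected_null_genes_not(self, rng):
        n, G = 300, 25
        pres = (rng.random((G, n)) < 0.5).astype(float)
        eta = -1.5 + 3.0 * pres[4]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        gm, meta = _dataset(pres, y)
        est = GeneHorseshoeAssociator(chains=2, warmup=400, draws=400, seed=0).fit(gm, meta)
        hit_genes = {a.gene_id for a in est.associations_ if a.is_hit}
        assert hit_genes == {"g4"}
        lo, hi = dict((a.gene_id, a.posterior_interval) for a in est.associations_)["g4"]
        assert lo > 0

    def test_null_simulation_no_hits(self, rng):
        n, G = 200, 25
        pres = (rng.random((G, n)) < 0.5).astype(float)
        for seed in (0, 1):
            y = (rng.random(n) < 0.5).astype(float)
            gm, meta = _dataset(pres, y)
            est = GeneHorseshoeAssociator(chains=2, warmup=300, draws=300, seed=seed).fit(
                gm, meta
            )
            assert not any(a.is_hit for a in est.associations_)

    def test_duplicate_presence_patterns_share_coefficient(self, rng):
        n = 150
        g = (rng.random(n) < 0.5).astype(float)
        other = (rng.random(n) < 0.5).astype(float)
        pres = np.vstack([g, g, other])  # two identical genes
        y = (rng.random(n) < 1 / (1 + np.exp(-(2 * g - 1)))).astype(float)
        gm, meta = _dataset(pres, y)
        est = GeneHorseshoeAssociator(chains=2, warmup=300, draws=300, seed=2).fit(gm, meta)
        a0, a1, a2 = est.associations_
        assert a0.coefficient == a1.coefficient
        assert a0.note == a1.note == "collinear_group"
        assert a2.note == ""
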