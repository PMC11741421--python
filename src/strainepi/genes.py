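"""Associating strain gene carriage with outcomes.

Two alternative multiplicity strategies over a species' binarized gene
presence matrix:

* per-gene GLMs ``outcome ~ covariates + gene_presence`` (identity link for
  continuous outcomes, logit link for binary), Wald p-values for the
  presence term, Benjamini-Hochberg correction across the species' genes and
  a Q-threshold hit call; or
* one joint model ``outcome ~ covariates + sum_g gamma_g presence_g`` with a
  regularized horseshoe prior on the gene coefficients, calibrated so the
  prior expects a configurable fraction (1% by default) of nonzero
  coefficients; hits are genes whose central posterior interval excludes
  zero with posterior mean magnitude above a threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy.special import expit
from sklearn.base import BaseEstimator

from ._priors import half_cauchy_logscale, half_t_logscale, normal_iid
from .containers import GeneMatrix, SampleMetadata
from .nuts import run_chains

__all__ = [
    "GeneAssociation",
    "HorseshoeConfig",
    "GeneGLMAssociator",
    "GeneHorseshoeAssociator",
    "fit_gene_glms",
    "fit_gene_horseshoe",
    "bh_adjust",
    "call_gene_hits",
]


@dataclass
class GeneAssociation:
    """Association record for one gene's presence term."""

    gene_id: str
    coefficient: float
    std_error: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    posterior_interval: tuple[float, float] | None = None
    is_hit: bool = False
    note: str = ""


@dataclass
class HorseshoeConfig:
    """Regularized-horseshoe hyperparameters.

    ``expected_nonzero_fraction`` (p0) calibrates the global scale so the
    prior expects p0 * n_genes nonzero coefficients.  The slab is a
    Student-t(slab_df) envelope of scale ``slab_scale`` bounding how large a
    "selected" coefficient may get.  Hits require the central
    ``interval_level`` posterior interval to exclude zero and the posterior
    mean magnitude to exceed ``effect_threshold`` (link scale).
    """

    expected_nonzero_fraction: float = 0.01
    slab_scale: float = 2.5
    slab_df: float = 4.0
    effect_threshold: float = 0.5
    interval_level: float = 0.99

    def __post_init__(self) -> None:
        if not 0 < self.expected_nonzero_fraction < 1:
            raise ValueError("expected_nonzero_fraction must be in (0, 1)")
        if not 0.5 < self.interval_level < 1:
            raise ValueError("interval_level must be in (0.5, 1)")
        if min(self.slab_scale, self.slab_df, self.effect_threshold) <= 0:
            raise ValueError("slab_scale, slab_df and effect_threshold must be positive")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (running-minimum convention)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _design(meta: SampleMetadata) -> np.ndarray:
    cov, _ = meta.design_matrix()
    return np.column_stack([np.ones(len(meta.sample_ids)), cov])


class GeneGLMAssociator(BaseEstimator):
    """Per-gene GLM association with BH correction.

    Parameters
    ----------
    q_threshold : float
        Strict BH hit threshold (Q < q_threshold).

    Attributes
    ----------
    associations_ : list of GeneAssociation (one per non-constant gene).
    results_ : pandas DataFrame view of the associations.
    """

    def __init__(self, q_threshold: float = 0.05):
        self.q_threshold = q_threshold

    def fit(self, presence: GeneMatrix, meta: SampleMetadata):
        import pandas as pd

        if set(presence.sample_ids) - set(meta.sample_ids):
            raise ValueError("presence sample set must be contained in metadata")
        meta = meta.select_samples(presence.sample_ids)
        y = meta.outcome
        X0 = _design(meta)
        fam = sm.families.Binomial() if meta.outcome_family == "bernoulli" else sm.families.Gaussian()
        assocs: list[GeneAssociation] = []
        n_const = 0
        for gi, gene in enumerate(presence.gene_ids):
            g = presence.abundance[gi]
            if g.min() == g.max():
                n_const += 1
                continue
            X = np.column_stack([X0, g])
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = sm.GLM(y, X, family=fam).fit()
                coef = float(res.params[-1])
                se = float(res.bse[-1])
                pval = float(res.pvalues[-1])
            except Exception:
                coef, se, pval = float("nan"), float("nan"), float("nan")
            if not np.isfinite(coef) or not np.isfinite(se) or se > 1e3:
                assocs.append(
                    GeneAssociation(gene, float("nan"), float("nan"), note="separated")
                )
            else:
                assocs.append(GeneAssociation(gene, coef, se, pval))
        if n_const:
            warnings.warn(f"skipped {n_const} constant-presence genes")
        ok = [a for a in assocs if np.isfinite(a.p_value)]
        if ok:
            q = bh_adjust([a.p_value for a in ok])
            for a, qv in zip(ok, q):
                a.q_value = float(qv)
                a.is_hit = bool(qv < self.q_threshold)
        self.associations_ = assocs
        self.results_ = pd.DataFrame(
            [
                (a.gene_id, a.coefficient, a.std_error, a.p_value, a.q_value, a.is_hit, a.note)
                for a in assocs
            ],
            columns=["gene", "coefficient", "std_error", "p", "q", "hit", "note"],
        )
        return self


class _HorseshoePosterior:
    """Regularized-horseshoe GLM.

    theta = [b (p), log lambda (G), log tau, log c^2, z (G)] (+ log sigma for
    the gaussian family).  gamma_g = tau * lambda_tilde_g * z_g with
    lambda_tilde^2 = c^2 lambda^2 / (c^2 + tau^2 lambda^2).
    """

    def __init__(self, y, X, P, family, cfg: HorseshoeConfig, beta_sd=5.0):
        self.y, self.X, self.P, self.family = y, X, P, family
        self.n, self.p = X.shape
        self.G = P.shape[1]
        self.cfg = cfg
        self.beta_sd = beta_sd
        p0 = cfg.expected_nonzero_fraction
        sigma_pseudo = 2.0 if family == "bernoulli" else 1.0
        self.tau0 = p0 / (1 - p0) * sigma_pseudo / np.sqrt(self.n)
        self.dim = self.p + 2 * self.G + 2 + (1 if family == "gaussian" else 0)

    def unpack(self, th):
        p, G = self.p, self.G
        b = th[:p]
        llam = th[p : p + G]
        ltau = th[p + G]
        lc2 = th[p + G + 1]
        z = th[p + G + 2 : p + 2 * G + 2]
        lsr = th[-1] if self.family == "gaussian" else None
        return b, llam, ltau, lc2, z, lsr

    def gamma(self, th):
        b, llam, ltau, lc2, z, _ = self.unpack(th)
        lam2 = np.exp(2 * llam)
        tau = np.exp(ltau)
        c2 = np.exp(lc2)
        t2l2 = tau**2 * lam2
        m = np.sqrt(c2 * lam2 / (c2 + t2l2))
        return tau * m * z

    def logp_and_grad(self, th):
        b, llam, ltau, lc2, z, lsr = self.unpack(th)
        lam2 = np.exp(2 * llam)
        tau = np.exp(ltau)
        c2 = np.exp(lc2)
        t2l2 = tau**2 * lam2
        q = t2l2 / (c2 + t2l2)  # in (0, 1)
        m = np.sqrt(lam2 * (1.0 - q))  # = lambda_tilde / 1; m^2 = c2 lam2/(c2+t2l2)
        gam = tau * m * z
        eta = self.X @ b + self.P @ gam
        g = np.empty(self.dim)
        if self.family == "gaussian":
            sr = np.exp(lsr)
            r = self.y - eta
            inv_var = 1.0 / sr**2
            lp = -self.n * lsr - 0.5 * inv_var * float(r @ r)
            resid = r * inv_var
            lp_s, g_s = half_t_logscale(lsr, 3.0, 2.5)
            lp += lp_s
            g[-1] = -self.n + inv_var * float(r @ r) + g_s
        else:
            lp = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
            resid = self.y - expit(eta)
        g_gam = self.P.T @ resid

        lp_b, g_b = normal_iid(b, self.beta_sd)
        lp_z, g_z0 = normal_iid(z, 1.0)
        lp += lp_b + lp_z
        # local scales: half-Cauchy(1) each
        lp += float(np.sum(-np.log1p(lam2) + llam))
        d_llam_prior = -2.0 * lam2 / (1.0 + lam2) + 1.0
        # global scale: half-Cauchy(tau0)
        lp_t, g_t = half_cauchy_logscale(ltau, self.tau0)
        lp += lp_t
        # slab: c^2 ~ Inv-Gamma(df/2, df * scale^2 / 2)
        a_ig = self.cfg.slab_df / 2.0
        b_ig = self.cfg.slab_df * self.cfg.slab_scale**2 / 2.0
        lp += -(a_ig + 1.0) * lc2 - b_ig / c2 + lc2
        d_lc2_prior = -a_ig + b_ig / c2

        gg = g_gam * gam  # elementwise d lp / d log(scale factors of gamma)
        g[: self.p] = self.X.T @ resid + g_b
        g[self.p : self.p + self.G] = gg * (1.0 - q) + d_llam_prior
        g[self.p + self.G] = float(np.sum(gg * (1.0 - q))) + g_t
        g[self.p + self.G + 1] = float(np.sum(gg * q * 0.5)) + d_lc2_prior
        g[self.p + self.G + 2 : self.p + 2 * self.G + 2] = g_gam * tau * m + g_z0
        return lp, g

    def initial_position(self, rng):
        th = 0.1 * rng.standard_normal(self.dim)
        p, G = self.p, self.G
        th[p : p + G] = 0.0 + 0.1 * rng.standard_normal(G)
        th[p + G] = np.log(self.tau0)
        th[p + G + 1] = np.log(self.cfg.slab_scale**2)
        if self.family == "gaussian":
            th[-1] = np.log(max(np.std(self.y), 0.1))
        return th


class GeneHorseshoeAssociator(BaseEstimator):
    """Joint gene model with a regularized horseshoe prior.

    Genes with identical presence patterns are collapsed to one
    representative before sampling (exact collinearity) and expanded
    afterwards with a shared coefficient, flagged in the output notes.

    Attributes
    ----------
    associations_ : list of GeneAssociation with posterior mean coefficients
        and central credible intervals.
    converged_ : bool; False when any gene coefficient has split-R-hat > 1.01.
    """

    def __init__(
        self,
        config: HorseshoeConfig | None = None,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        target_accept: float = 0.9,
    ):
        self.config = config
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept

    def fit(self, presence: GeneMatrix, meta: SampleMetadata):
        import pandas as pd

        cfg = self.config or HorseshoeConfig()
        meta = meta.select_samples(presence.sample_ids)
        y = meta.outcome
        X = _design(meta)
        M = presence.abundance  # (G, n), 0/1
        variable = M.min(axis=1) != M.max(axis=1)
        if (~variable).any():
            warnings.warn(f"skipped {int((~variable).sum())} constant-presence genes")
        genes = [g for g, v in zip(presence.gene_ids, variable) if v]
        Mv = M[variable]
        # collapse identical presence patterns
        _, rep_idx, inverse = np.unique(Mv, axis=0, return_index=True, return_inverse=True)
        P = Mv[np.sort(rep_idx)].T  # (n, Gu) keep first-occurrence order
        order = np.argsort(rep_idx)
        remap = np.empty_like(order)
        remap[order] = np.arange(order.size)
        inverse = remap[inverse]
        group_sizes = np.bincount(inverse)

        family = meta.outcome_family
        post = _HorseshoePosterior(y, X, P.astype(float), family, cfg)
        res = run_chains(
            post.logp_and_grad,
            post.initial_position,
            n_chains=self.chains,
            n_warmup=self.warmup,
            n_draws=self.draws,
            seed=self.seed,
            target_accept=self.target_accept,
        )
        gam_draws = np.stack([post.gamma(th) for th in res.flat])  # (S, Gu)
        alpha = 1.0 - cfg.interval_level
        lo, hi = np.quantile(gam_draws, [alpha / 2, 1 - alpha / 2], axis=0)
        mean = gam_draws.mean(axis=0)
        # R-hat on the gamma scale
        S_c = res.draws.shape[1]
        gam_chains = gam_draws.reshape(res.draws.shape[0], S_c, -1)
        from .nuts import split_rhat

        rhat_g = split_rhat(gam_chains)
        self.converged_ = res.converged and bool(np.nanmax(rhat_g) <= 1.01)
        self.warnings_ = list(res.warnings)
        if np.nanmax(rhat_g) > 1.01:
            msg = f"NON-CONVERGENCE: max gene-coefficient split R-hat {np.nanmax(rhat_g):.3f}"
            self.warnings_.append(msg)
            warnings.warn(msg)

        assocs = []
        for gi, gene in enumerate(genes):
            k = inverse[gi]
            note = "collinear_group" if group_sizes[k] > 1 else ""
            a = GeneAssociation(
                gene_id=gene,
                coefficient=float(mean[k]),
                std_error=float(gam_draws[:, k].std(ddof=1)),
                posterior_interval=(float(lo[k]), float(hi[k])),
                is_hit=bool((lo[k] > 0 or hi[k] < 0) and abs(mean[k]) > cfg.effect_threshold),
                note=note,
            )
            assocs.append(a)
        self.associations_ = assocs
        self.gamma_draws_ = gam_draws
        self.gene_group_ = inverse
        self.results_ = pd.DataFrame(
            [
                (a.gene_id, a.coefficient, a.std_error, *a.posterior_interval, a.is_hit, a.note)
                for a in assocs
            ],
            columns=["gene", "coefficient", "std_error", "lower", "upper", "hit", "note"],
        )
        return self


def fit_gene_glms(presence: GeneMatrix, meta: SampleMetadata, q_threshold: float = 0.05):
    """Functional wrapper over :class:`GeneGLMAssociator`."""
    return GeneGLMAssociator(q_threshold=q_threshold).fit(presence, meta).associations_


def fit_gene_horseshoe(
    presence: GeneMatrix, meta: SampleMetadata, cfg: HorseshoeConfig | None = None, **kw
):
    """Functional wrapper over :class:`GeneHorseshoeAssociator`."""
    return GeneHorseshoeAssociator(config=cfg, **kw).fit(presence, meta).associations_


def call_gene_hits(
    assocs: list[GeneAssociation],
    q_threshold: float = 0.05,
    effect_threshold: float = 0.5,
):
    """Set hit flags: strict Q < threshold (GLM path), or interval excludes
    zero with |posterior mean| above the effect threshold (horseshoe path)."""
    for a in assocs:
        if a.posterior_interval is not None:
            lo, hi = a.posterior_interval
            a.is_hit = bool(
                (lo > 0 or hi < 0)
                and np.isfinite(a.coefficient)
                and abs(a.coefficient) > effect_threshold
            )
        else:
            a.is_hit = bool(np.isfinite(a.q_value) and a.q_value < q_threshold)
    return assocs
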