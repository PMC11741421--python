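"""Random-effects model of within-species pathway carriage.

Species-stratified pathway abundance tracks overall species abundance; a
pathway preferentially lost (or retained) by the strains of one phenotype
group shows up as a vertical shift between groups on the log-log scale.  The
model:

    log10(pwy_abd) ~ log10(species_abd) + (1 | pwy) + (0 + group | pwy) + intercept

with partial pooling of the per-pathway intercepts (Normal(0, sigma_int),
sigma_int ~ half-t(5, 0, 2.5)) and of the per-pathway group effects
(Normal(0, sigma_effects), sigma_effects ~ Exponential(3), an aggressive
shrinkage encoding that few pathways differ between groups).  The global
intercept has a t(5, EM, 2.5) prior (EM = empirical mean of the retained
log10 pathway abundances), the species slope a Normal(1, 1) prior, and the
residual scale a half-t(3, 0, 2.5) prior.  Zeros are discarded (the model
works with log abundances).

A pathway is a hit when all three criteria hold: its 98% posterior group
effect interval excludes zero, the absolute posterior mean exceeds 0.25
(i.e. a 10^0.25 ~ 1.78-fold change), and the posterior mean species slope is
positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from ._priors import exponential_logscale, half_t_logscale, student_t
from .containers import PathwayMatrix, SampleMetadata
from .nuts import run_chains, split_rhat

__all__ = [
    "PathwayFitInput",
    "PathwayFit",
    "prepare_pathway_input",
    "PathwayCarriageModel",
    "fit_pathway_model",
    "call_pathway_hits",
]


@dataclass
class PathwayFitInput:
    """Long-format observations with zeros removed (base-10 logs)."""

    pathway_ids: list[str]
    pathway_index: np.ndarray  # (N,) int, index into pathway_ids
    log10_pathway: np.ndarray  # (N,)
    log10_species: np.ndarray  # (N,)
    group: np.ndarray  # (N,) in {0, 1}
    empirical_mean: float  # EM: mean of retained log10 pathway abundances

    def __post_init__(self) -> None:
        for arr in (self.log10_pathway, self.log10_species, self.group):
            if not np.all(np.isfinite(arr)):
                raise ValueError("non-finite values in pathway fit input")


def prepare_pathway_input(
    pm: PathwayMatrix, meta: SampleMetadata, min_obs: int = 3
) -> PathwayFitInput:
    """Drop zero observations, take base-10 logs, compute EM.

    Observations where the pathway or the species abundance is zero are
    discarded; pathways left with fewer than ``min_obs`` observations are
    dropped entirely (warning).
    """
    meta = meta.select_samples([s for s in pm.sample_ids if s in set(meta.sample_ids)])
    pm_cols = {s: j for j, s in enumerate(pm.sample_ids)}
    cols = [pm_cols[s] for s in meta.sample_ids]
    abd = pm.abundance[:, cols]
    sp = pm.species_abundance[cols]
    group = meta.outcome
    if not np.isin(group, (0.0, 1.0)).all():
        raise ValueError("pathway model requires a binary group variable")
    ok_sample = np.isfinite(sp) & (sp > 0)
    rows, pidx, lp, ls, gv = [], [], [], [], []
    kept_ids = []
    for i, pid in enumerate(pm.pathway_ids):
        mask = ok_sample & (abd[i] > 0)
        if mask.sum() < min_obs:
            warnings.warn(f"pathway {pid}: fewer than {min_obs} nonzero observations; dropped")
            continue
        k = len(kept_ids)
        kept_ids.append(pid)
        pidx.append(np.full(int(mask.sum()), k))
        lp.append(np.log10(abd[i, mask]))
        ls.append(np.log10(sp[mask]))
        gv.append(group[mask])
    if not kept_ids:
        raise ValueError("all pathways dropped; nothing to fit")
    lp = np.concatenate(lp)
    return PathwayFitInput(
        pathway_ids=kept_ids,
        pathway_index=np.concatenate(pidx),
        log10_pathway=lp,
        log10_species=np.concatenate(ls),
        group=np.concatenate(gv),
        empirical_mean=float(lp.mean()),
    )


@dataclass
class PathwayFit:
    """Posterior draws for the pathway carriage model."""

    pathway_ids: list[str]
    global_intercept: np.ndarray  # (S,)
    species_slope: np.ndarray  # (S,)
    pathway_intercepts: np.ndarray  # (S, P)
    group_effects: np.ndarray  # (S, P)
    sigma_int: np.ndarray
    sigma_effects: np.ndarray
    residual_scale: np.ndarray
    rhat: np.ndarray
    divergences: int
    converged: bool
    warnings: list[str] = field(default_factory=list)


class _PathwayPosterior:
    """theta = [b0, b1, lsi, lse, lsr, za (P), zg (P)] (non-centered)."""

    def __init__(self, inp: PathwayFitInput):
        self.inp = inp
        self.P = len(inp.pathway_ids)
        self.N = inp.log10_pathway.size
        self.dim = 5 + 2 * self.P

    def unpack(self, th):
        P = self.P
        return th[0], th[1], th[2], th[3], th[4], th[5 : 5 + P], th[5 + P : 5 + 2 * P]

    def logp_and_grad(self, th):
        b0, b1, lsi, lse, lsr, za, zg = self.unpack(th)
        si, se, sr = np.exp(lsi), np.exp(lse), np.exp(lsr)
        inp = self.inp
        a = si * za
        gp = se * zg
        mu = b0 + b1 * inp.log10_species + a[inp.pathway_index] + gp[inp.pathway_index] * inp.group
        r = inp.log10_pathway - mu
        inv_var = 1.0 / sr**2
        lp = -self.N * lsr - 0.5 * inv_var * float(r @ r)

        lp_b0, g_b0 = student_t(b0, 5.0, inp.empirical_mean, 2.5)
        lp_si, g_si = half_t_logscale(lsi, 5.0, 2.5)
        lp_se, g_se = exponential_logscale(lse, 3.0)
        lp_sr, g_sr = half_t_logscale(lsr, 3.0, 2.5)
        lp += lp_b0 - 0.5 * (b1 - 1.0) ** 2 + lp_si + lp_se + lp_sr
        lp += -0.5 * float(za @ za) - 0.5 * float(zg @ zg)

        rw = r * inv_var
        sum_r_by_p = np.bincount(inp.pathway_index, weights=rw, minlength=self.P)
        sum_rg_by_p = np.bincount(inp.pathway_index, weights=rw * inp.group, minlength=self.P)
        g = np.empty(self.dim)
        g[0] = float(rw.sum()) + g_b0
        g[1] = float(rw @ inp.log10_species) - (b1 - 1.0)
        g[2] = float(a @ sum_r_by_p) + g_si
        g[3] = float(gp @ sum_rg_by_p) + g_se
        g[4] = -self.N + inv_var * float(r @ r) + g_sr
        g[5 : 5 + self.P] = si * sum_r_by_p - za
        g[5 + self.P :] = se * sum_rg_by_p - zg
        return lp, g

    def initial_position(self, rng):
        th = 0.1 * rng.standard_normal(self.dim)
        th[0] = self.inp.empirical_mean
        th[1] = 1.0
        th[2] = np.log(1.0)
        th[3] = np.log(0.2)
        th[4] = np.log(max(np.std(self.inp.log10_pathway), 0.1))
        return th


class PathwayCarriageModel(BaseEstimator):
    """Hierarchical Bayesian model of pathway carriage vs species abundance.

    Attributes
    ----------
    fit_ : PathwayFit with posterior draws for the global terms, per-pathway
        intercepts and group effects, and convergence diagnostics.
    """

    def __init__(
        self,
        chains: int = 4,
        warmup: int = 1000,
        draws: int = 1000,
        seed: int = 0,
        target_accept: float = 0.8,
    ):
        self.chains = chains
        self.warmup = warmup
        self.draws = draws
        self.seed = seed
        self.target_accept = target_accept

    def fit(self, inp: PathwayFitInput):
        if len(inp.pathway_ids) < 2:
            raise ValueError("need at least 2 pathways")
        if len(np.unique(inp.group)) < 2:
            raise ValueError("both groups must be present")
        post = _PathwayPosterior(inp)
        res = run_chains(
            post.logp_and_grad,
            post.initial_position,
            n_chains=self.chains,
            n_warmup=self.warmup,
            n_draws=self.draws,
            seed=self.seed,
            target_accept=self.target_accept,
        )
        flat = res.flat
        P = len(inp.pathway_ids)
        si = np.exp(flat[:, 2])
        se = np.exp(flat[:, 3])
        self.fit_ = PathwayFit(
            pathway_ids=list(inp.pathway_ids),
            global_intercept=flat[:, 0],
            species_slope=flat[:, 1],
            pathway_intercepts=si[:, None] * flat[:, 5 : 5 + P],
            group_effects=se[:, None] * flat[:, 5 + P : 5 + 2 * P],
            sigma_int=si,
            sigma_effects=se,
            residual_scale=np.exp(flat[:, 4]),
            rhat=res.rhat,
            divergences=res.divergences,
            converged=res.converged,
            warnings=list(res.warnings),
        )
        return self


def fit_pathway_model(inp: PathwayFitInput, **kw) -> PathwayFit:
    """Functional wrapper over :class:`PathwayCarriageModel`."""
    return PathwayCarriageModel(**kw).fit(inp).fit_


def call_pathway_hits(
    fit: PathwayFit, interval_level: float = 0.98, effect_threshold: float = 0.25
) -> pd.DataFrame:
    """Hit table under the three-criterion rule.

    hit = (central interval excludes 0) and (|posterior mean| >
    effect_threshold) and (posterior mean species slope > 0).  The fold
    change column reports 10^|effect|.
    """
    alpha = 1.0 - interval_level
    lo, hi = np.quantile(fit.group_effects, [alpha / 2, 1 - alpha / 2], axis=0)
    mean = fit.group_effects.mean(axis=0)
    slope_positive = bool(fit.species_slope.mean() > 0)
    hits = (np.sign(lo) == np.sign(hi)) & (np.abs(mean) > effect_threshold) & slope_positive
    return pd.DataFrame(
        {
            "pathway": fit.pathway_ids,
            "effect_mean": mean,
            "effect_lower": lo,
            "effect_upper": hi,
            "fold_change": 10.0 ** np.abs(mean),
            "species_slope_mean": float(fit.species_slope.mean()),
            "hit": hits,
        }
    )
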