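"""Synthetic-data generators for validating the three model families.

Three generators mirror the generative structure of stool metagenomes at the
strain level:

* ``simulate_gene_dataset`` — species abundances drawn log-normally (a
  configurable stand-in for fitted stool-survey presets), per-subject gene
  carriage, skew-normal gene-level measurement noise, logistic zero-inflation
  centered on each gene's median log abundance, a planted subset of risk
  genes that raise disease log-odds, and a planted subset of subjects whose
  gene abundances are shifted down to emulate insufficient coverage.
* ``simulate_phylo_dataset`` — a random phylogeny whose tree-structured
  covariance drives the outcome: y = MVN(0, sigma_p^2 Omega) + MVN(0,
  sigma_r^2 I).
* ``simulate_pathway_dataset`` — runs the pathway carriage model's generative
  structure in reverse: per-pathway intercepts, a unit slope on log10 species
  abundance, and a group effect spiked into a few pathways.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skbio import TreeNode

from .containers import GeneMatrix, PathwayMatrix, SampleMetadata

__all__ = [
    "GeneSimConfig",
    "PhyloSimConfig",
    "PathwaySimConfig",
    "simulate_gene_dataset",
    "simulate_phylo_dataset",
    "simulate_pathway_dataset",
    "random_phylogeny",
    "phylo_parameter_grid",
    "zero_inflation_prob",
    "classification_metrics",
]


@dataclass
class GeneSimConfig:
    """Study conditions for the gene-profile simulator.

    Defaults reproduce the validation conditions: 200 cases and 200 controls,
    1000 genes of which a handful raise disease log-odds by 1, 25% of
    subjects poorly covered with average log gene abundance reduced by 4,
    skew-normal(0, 1, -1) gene noise, and logistic zero-inflation with growth
    rate -1 centered on each gene's median log abundance.
    """

    n_per_group: int = 200
    n_genes: int = 1000
    n_risk_genes: int = 5
    risk_gene_logodds: float = 1.0
    species_effect_logodds: float = 0.0
    poor_coverage_fraction: float = 0.25
    poor_coverage_shift: float = -4.0
    skew_noise: tuple[float, float, float] = (0.0, 1.0, -1.0)  # location, scale, shape
    species_lognormal: tuple[float, float] = (0.0, 2.0)  # (mu, sigma), natural log
    carriage_prob: float = 0.5
    max_batches: int = 50
    seed: int = 0


@dataclass
class PhyloSimConfig:
    """Study conditions for the phylogenetic simulator."""

    n_tips: int = 100
    sigma_p: float = 1.0
    sigma_r: float = 1.0
    seed: int = 0


@dataclass
class PathwaySimConfig:
    """Study conditions for the pathway-carriage simulator."""

    n_pathways: int = 30
    n_spiked: int = 3
    spiked_effect: float = 0.5
    residual_sd: float = 1.0
    n_samples: int = 400
    species_lognormal: tuple[float, float] = (0.0, 2.0)
    seed: int = 0


def zero_inflation_prob(log_abundance, median):
    """P(observation is zeroed | log abundance a) = 1 / (1 + exp(a - m)).

    A logistic function of the log abundance centered on the per-gene median
    ``m`` with growth rate -1: an observation exactly at the median is zeroed
    with probability 1/2, and the probability decreases with abundance.
    """
    return 1.0 / (1.0 + np.exp(np.asarray(log_abundance) - median))


def simulate_gene_dataset(cfg: GeneSimConfig) -> tuple[GeneMatrix, SampleMetadata, dict]:
    """Generate a species' gene profile, binary outcomes, and truth labels.

    Subjects are generated until the case and control quotas are both met
    (disease intercept centers baseline prevalence near 50%).  Returns the
    gene abundance matrix (linear scale, zeros included), per-sample
    metadata, and a truth dict with keys ``risk_genes``, ``poorly_covered``,
    ``species_log_abundance`` and ``carriage``.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = cfg.species_lognormal
    n_target = 2 * cfg.n_per_group
    # intercept centers the expected risk-gene contribution -> ~50% prevalence
    intercept = -cfg.risk_gene_logodds * cfg.n_risk_genes * cfg.carriage_prob

    risk_idx = rng.choice(cfg.n_genes, size=cfg.n_risk_genes, replace=False)
    s_list, risk_carriage_list, y_list = [], [], []
    n_cases = n_controls = 0
    for _ in range(cfg.max_batches):
        b = n_target
        s = rng.normal(mu, sigma, size=b)
        risk_car = rng.random((b, cfg.n_risk_genes)) < cfg.carriage_prob
        eta = (
            intercept
            + cfg.risk_gene_logodds * risk_car.sum(axis=1)
            + cfg.species_effect_logodds * (s - mu) / sigma
        )
        y = (rng.random(b) < 1.0 / (1.0 + np.exp(-eta))).astype(float)
        s_list.append(s)
        risk_carriage_list.append(risk_car)
        y_list.append(y)
        n_cases += int(y.sum())
        n_controls += int(b - y.sum())
        if n_cases >= cfg.n_per_group and n_controls >= cfg.n_per_group:
            break
    else:
        raise RuntimeError("group quotas unreachable within the batch cap")

    s_all = np.concatenate(s_list)
    y_all = np.concatenate(y_list)
    risk_car_all = np.vstack(risk_carriage_list)
    keep_case = np.flatnonzero(y_all == 1)[: cfg.n_per_group]
    keep_ctrl = np.flatnonzero(y_all == 0)[: cfg.n_per_group]
    keep = np.sort(np.concatenate([keep_case, keep_ctrl]))
    s = s_all[keep]
    y = y_all[keep]
    n = keep.size

    carriage = rng.random((cfg.n_genes, n)) < cfg.carriage_prob
    carriage[risk_idx, :] = risk_car_all[keep].T

    a, scale, shape = cfg.skew_noise
    noise = stats.skewnorm.rvs(shape, loc=a, scale=scale, size=(cfg.n_genes, n), random_state=rng)
    log_abd = s[None, :] + noise

    n_poor = int(round(cfg.poor_coverage_fraction * n))
    poor_idx = rng.choice(n, size=n_poor, replace=False)
    log_abd[:, poor_idx] += cfg.poor_coverage_shift

    # logistic zero-inflation: P(zero | a) = 1 / (1 + exp(a - per-gene median))
    carried_log = np.where(carriage, log_abd, np.nan)
    med = np.nanmedian(carried_log, axis=1)
    med = np.where(np.isnan(med), np.nanmedian(log_abd, axis=1), med)
    p_zero = zero_inflation_prob(log_abd, med[:, None])
    observed = rng.random((cfg.n_genes, n)) >= p_zero

    abundance = np.where(carriage & observed, np.exp(log_abd), 0.0)

    sample_ids = [f"s{i:04d}" for i in range(n)]
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    gm = GeneMatrix("sim_species", gene_ids, sample_ids, abundance)
    meta = SampleMetadata(
        sample_ids=sample_ids,
        outcome=y,
        covariates=None,
        outcome_family="bernoulli",
    )
    truth = {
        "risk_genes": [gene_ids[i] for i in sorted(risk_idx)],
        "poorly_covered": [sample_ids[i] for i in sorted(poor_idx)],
        "species_log_abundance": s,
        "carriage": carriage,
    }
    return gm, meta, truth


def random_phylogeny(n_tips: int, rng: np.random.Generator) -> TreeNode:
    """Random binary topology by sequential random splitting, branch lengths
    Uniform(0, 1); tips named t1..tn."""
    counter = [0]

    def build(k: int) -> TreeNode:
        if k == 1:
            counter[0] += 1
            node = TreeNode(name=f"t{counter[0]}")
        else:
            left = int(rng.integers(1, k))
            node = TreeNode(children=[build(left), build(k - left)])
        node.length = float(rng.uniform())
        return node

    tree = build(int(n_tips))
    tree.length = None  # root has no branch
    return tree


def simulate_phylo_dataset(cfg: PhyloSimConfig):
    """Generate (tree, correlation, outcome, true R^2).

    outcome = MVN(0, sigma_p^2 Omega) + MVN(0, sigma_r^2 I); the true
    phylogenetic R^2 is sigma_p^2 / (sigma_p^2 + sigma_r^2).
    """
    from .pglmm import tree_to_correlation

    if cfg.sigma_p == 0 and cfg.sigma_r == 0:
        raise ValueError("sigma_p and sigma_r cannot both be zero")
    if cfg.n_tips < 4:
        raise ValueError("need at least 4 tips")
    rng = np.random.default_rng(cfg.seed)
    tree = random_phylogeny(cfg.n_tips, rng)
    corr = tree_to_correlation(tree)
    n = cfg.n_tips
    L = np.linalg.cholesky(corr.omega + 1e-10 * np.eye(n))
    y = cfg.sigma_p * (L @ rng.standard_normal(n)) + cfg.sigma_r * rng.standard_normal(n)
    true_r2 = cfg.sigma_p**2 / (cfg.sigma_p**2 + cfg.sigma_r**2)
    return tree, corr, y, true_r2


def phylo_parameter_grid(
    n_values: tuple = (10, 98, 186, 274, 362, 450),
    sigma_values: tuple = (0.0, 0.418, 0.836, 1.254, 1.672, 2.09),
) -> list[tuple[int, float, float]]:
    """Simulation grid of (n_tips, sigma_p, sigma_r); points with both noise
    scales zero are dropped."""
    return [
        (n, sp, sr)
        for n in n_values
        for sp in sigma_values
        for sr in sigma_values
        if not (sp == 0.0 and sr == 0.0)
    ]


def simulate_pathway_dataset(cfg: PathwaySimConfig) -> tuple[PathwayMatrix, SampleMetadata, dict]:
    """Generate pathway abundances by running the carriage model in reverse.

    log10 pathway abundance = intercept_p + 1 * log10 species + effect_p *
    group + Normal(0, residual_sd); effect_p equals ``spiked_effect`` for the
    first ``n_spiked`` pathways and 0 otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    mu, sigma = cfg.species_lognormal
    n = cfg.n_samples
    s_nat = rng.normal(mu, sigma, size=n)  # natural-log species abundance
    log10_species = s_nat / np.log(10.0)
    group = (rng.random(n) < 0.5).astype(float)
    intercepts = rng.normal(0.0, 1.0, size=cfg.n_pathways)
    effects = np.zeros(cfg.n_pathways)
    spiked = rng.choice(cfg.n_pathways, size=cfg.n_spiked, replace=False)
    effects[spiked] = cfg.spiked_effect
    eps = rng.normal(0.0, cfg.residual_sd, size=(cfg.n_pathways, n))
    log10_pwy = intercepts[:, None] + log10_species[None, :] + effects[:, None] * group[None, :] + eps
    pathway_ids = [f"pwy{i:03d}" for i in range(cfg.n_pathways)]
    sample_ids = [f"s{i:04d}" for i in range(n)]
    pm = PathwayMatrix(
        "sim_species",
        pathway_ids,
        sample_ids,
        10.0**log10_pwy,
        species_abundance=np.exp(s_nat),
    )
    meta = SampleMetadata(sample_ids, group, None, outcome_family="bernoulli")
    truth = {
        "spiked_pathways": [pathway_ids[i] for i in sorted(spiked)],
        "effects": effects,
        "intercepts": intercepts,
    }
    return pm, meta, truth


@dataclass
class ClassificationMetrics:
    tpr: float
    fpr: float
    ppv: float
    auc: float


def classification_metrics(
    truth, calls=None, scores=None
) -> ClassificationMetrics:
    """TPR/FPR/PPV from binary calls and rank-statistic AUC from scores.

    Undefined-denominator cases (no positives, no negatives, no calls) are
    returned as NaN.
    """
    truth = np.asarray(truth, dtype=bool)
    tpr = fpr = ppv = auc = float("nan")
    if calls is not None:
        calls = np.asarray(calls, dtype=bool)
        tp = int((calls & truth).sum())
        fp = int((calls & ~truth).sum())
        fn = int((~calls & truth).sum())
        tn = int((~calls & ~truth).sum())
        if tp + fn:
            tpr = tp / (tp + fn)
        if fp + tn:
            fpr = fp / (fp + tn)
        if tp + fp:
            ppv = tp / (tp + fp)
    if scores is not None and truth.any() and (~truth).any():
        from sklearn.metrics import roc_auc_score

        auc = float(roc_auc_score(truth, np.asarray(scores, dtype=float)))
    return ClassificationMetrics(tpr=tpr, fpr=fpr, ppv=ppv, auc=auc)
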