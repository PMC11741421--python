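"""Adaptive coverage filtering of species-sample pairs.

Shotgun metagenomes only support strain-level analysis of a species when the
combination of species abundance and sequencing depth saturates detection of
the genes a typical strain carries (collector's-curve logic).  For each
species-sample pair two statistics are computed — the number of nonzero gene
observations and the median natural-log abundance of the nonzero observations
— and a k-means clustering with k=2 on the standardized statistics separates
"well covered" from "poorly covered" samples.  The full gene-table filter is:
prevalence filter, drop poorly covered samples, prevalence filter again with
the new sample count, then binarize to presence/absence.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from .containers import GeneMatrix

__all__ = [
    "SampleCoverageStats",
    "CoverageLabels",
    "KMeansCoverageClassifier",
    "sample_stats",
    "kmeans_coverage_label",
    "prevalence_filter",
    "binarize_presence",
    "filter_pipeline",
    "rank_abundance_table",
]

logger = logging.getLogger(__name__)

WELL = "well_covered"
POOR = "poorly_covered"


@dataclass
class SampleCoverageStats:
    """Coverage statistics for one species-sample pair.

    ``median_log_nonzero`` is the median of natural-log abundances over the
    nonzero genes; it is NaN when the sample has no nonzero gene.
    """

    sample_id: str
    n_nonzero: int
    median_log_nonzero: float


@dataclass
class CoverageLabels:
    """Binary well/poorly-covered labels plus the fitted cluster centroids."""

    labels: dict[str, str]
    cluster_centroids: np.ndarray | None  # (2, 2) in standardized space, or None

    def well_covered_ids(self) -> list[str]:
        return [s for s, lab in self.labels.items() if lab == WELL]


def sample_stats(m: GeneMatrix) -> list[SampleCoverageStats]:
    """Compute the two per-sample coverage statistics for a gene matrix."""
    out = []
    for j, sid in enumerate(m.sample_ids):
        col = m.abundance[:, j]
        nz = col[col > 0]
        med = float(np.median(np.log(nz))) if nz.size else float("nan")
        out.append(SampleCoverageStats(sid, int(nz.size), med))
    return out


class KMeansCoverageClassifier(BaseEstimator):
    """k=2 clustering of coverage statistics into well/poorly covered.

    Both statistics are standardized to zero mean and unit variance before
    clustering (counts and log abundances are on incommensurate scales).  The
    cluster whose centroid has the larger sum of standardized coordinates is
    labeled well covered; ties go to the cluster with the larger n_nonzero
    centroid.  Samples with no nonzero observation never enter the clustering
    and are labeled poorly covered directly.

    Parameters
    ----------
    n_init : int
        Seeded k-means restarts; the best-inertia solution is kept.
    random_state : int
        Seed for the k-means initialization.

    Attributes
    ----------
    labels_ : dict of sample id -> {"well_covered", "poorly_covered"}
    cluster_centers_ : ndarray of shape (2, 2) or None
        Centroids in standardized (n_nonzero, median_log_nonzero) space.
    """

    def __init__(self, n_init: int = 10, random_state: int = 0):
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, stats: list[SampleCoverageStats]):
        eligible = [s for s in stats if s.n_nonzero > 0]
        labels: dict[str, str] = {s.sample_id: POOR for s in stats}
        if len(eligible) < 2:
            warnings.warn(
                "fewer than 2 samples with nonzero observations; labeling all poorly covered"
            )
            self.labels_ = labels
            self.cluster_centers_ = None
            return self
        pts = np.array([[s.n_nonzero, s.median_log_nonzero] for s in eligible], dtype=float)
        mu = pts.mean(axis=0)
        sd = pts.std(axis=0)
        sd[sd == 0] = 1.0
        z = (pts - mu) / sd
        km = KMeans(n_clusters=2, n_init=self.n_init, random_state=self.random_state)
        assign = km.fit_predict(z)
        sums = km.cluster_centers_.sum(axis=1)
        if sums[0] != sums[1]:
            well = int(np.argmax(sums))
        else:  # tie: breadth of coverage decides
            well = int(np.argmax(km.cluster_centers_[:, 0]))
        for s, a in zip(eligible, assign):
            labels[s.sample_id] = WELL if a == well else POOR
        self.labels_ = labels
        self.cluster_centers_ = km.cluster_centers_
        return self


def kmeans_coverage_label(stats: list[SampleCoverageStats], seed: int = 0) -> CoverageLabels:
    """Label samples well/poorly covered by k-means on the coverage statistics."""
    clf = KMeansCoverageClassifier(random_state=seed).fit(stats)
    return CoverageLabels(labels=clf.labels_, cluster_centroids=clf.cluster_centers_)


def prevalence_filter(m: GeneMatrix, fraction: float = 0.005) -> GeneMatrix:
    """Drop genes observed in fewer than floor(fraction*N) samples or in more
    than N - floor(fraction*N) samples.

    Counts exactly equal to either bound are kept ("fewer than" / "more
    than").  Gene order is preserved.
    """
    if not 0 <= fraction < 0.5:
        raise ValueError("fraction must be in [0, 0.5)")
    n = m.n_samples
    t = int(np.floor(fraction * n))
    counts = (m.abundance > 0).sum(axis=1)
    keep = (counts >= t) & (counts <= n - t)
    return replace(
        m,
        gene_ids=[g for g, k in zip(m.gene_ids, keep) if k],
        abundance=m.abundance[keep, :].copy(),
    )


def binarize_presence(m: GeneMatrix) -> GeneMatrix:
    """Replace abundances with 0/1 presence indicators (entry 1 iff > 0)."""
    return replace(m, abundance=(m.abundance > 0).astype(float))


def filter_pipeline(
    m: GeneMatrix, fraction: float = 0.005, seed: int = 0
) -> tuple[GeneMatrix, CoverageLabels]:
    """Three-step adaptive filter: prevalence, drop poorly covered samples,
    prevalence with the post-dropping sample count; then binarize.

    Returns the binarized surviving matrix and the coverage labels for all
    original samples.
    """
    m1 = prevalence_filter(m, fraction)
    labels = kmeans_coverage_label(sample_stats(m1), seed=seed)
    keep = [s for s in m1.sample_ids if labels.labels[s] == WELL]
    if not keep:
        warnings.warn(f"{m.species_name}: no well-covered samples survive filtering")
        empty = replace(m1, sample_ids=[], abundance=m1.abundance[:, :0].copy())
        return binarize_presence(empty), labels
    m2 = m1.select_samples(keep)
    m3 = prevalence_filter(m2, fraction)  # threshold recomputed at the new N
    return binarize_presence(m3), labels


def rank_abundance_table(m: GeneMatrix, labels: CoverageLabels | None = None):
    """Rank-ordered per-sample log gene abundances (diagnostic table).

    One row per (sample, rank) with the natural-log abundance of the rank-th
    most abundant nonzero gene — the tabular analogue of the saturation
    curves used to visually confirm well/poor separation.
    """
    import pandas as pd

    rows = []
    for j, sid in enumerate(m.sample_ids):
        col = m.abundance[:, j]
        nz = np.sort(col[col > 0])[::-1]
        lab = labels.labels.get(sid) if labels is not None else None
        for r, v in enumerate(nz, start=1):
            rows.append((sid, r, float(np.log(v)), lab))
    return pd.DataFrame(rows, columns=["sample_id", "rank", "log_abundance", "label"])
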