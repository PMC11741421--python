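"""Core in-memory containers for species-stratified strain data.

Abundance tables are stored as dense numpy arrays (features x samples) with
explicit feature and sample identifier lists, mirroring the HUMAnN convention
of one stratified table per community with ``Species|Feature`` row labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneMatrix",
    "PathwayMatrix",
    "SampleMetadata",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when a container invariant is violated."""


def _check_ids(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class GeneMatrix:
    """Per-species gene-family abundance matrix (genes x samples).

    Parameters
    ----------
    species_name : str
        The species (or other basal clade, e.g. an SGB) the genes belong to.
    gene_ids : list of str
        Row identifiers, unique.
    sample_ids : list of str
        Column identifiers, unique.
    abundance : ndarray of shape (n_genes, n_samples)
        Nonnegative abundances (relative abundance or copy-number units;
        values are used as given).
    """

    species_name: str
    gene_ids: list[str]
    sample_ids: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene ids")
        self.sample_ids = _check_ids(self.sample_ids, "sample ids")
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"abundance shape {self.abundance.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.abundance)):
            raise ValidationError("abundance contains non-finite values")
        if (self.abundance < 0).any():
            raise ValidationError("abundance contains negative values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select_samples(self, sample_ids: Sequence[str]) -> "GeneMatrix":
        """Return a copy restricted to ``sample_ids`` in the given order."""
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in idx]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        cols = [idx[s] for s in sample_ids]
        return replace(
            self,
            sample_ids=list(sample_ids),
            abundance=self.abundance[:, cols].copy(),
        )

    def select_genes(self, gene_ids: Sequence[str]) -> "GeneMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in gene_ids]
        return replace(
            self, gene_ids=list(gene_ids), abundance=self.abundance[rows, :].copy()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.abundance, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class PathwayMatrix:
    """Per-species pathway abundance matrix plus the species' own abundance.

    ``species_abundance`` holds the overall abundance of the species in each
    sample (aligned to ``sample_ids``); the pathway model regresses log10
    pathway abundance on log10 species abundance.
    """

    species_name: str
    pathway_ids: list[str]
    sample_ids: list[str]
    abundance: np.ndarray
    species_abundance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.pathway_ids = _check_ids(self.pathway_ids, "pathway ids")
        self.sample_ids = _check_ids(self.sample_ids, "sample ids")
        self.abundance = np.asarray(self.abundance, dtype=float)
        if self.abundance.shape != (len(self.pathway_ids), len(self.sample_ids)):
            raise ValidationError("abundance shape does not match id lists")
        if (self.abundance < 0).any():
            raise ValidationError("abundance contains negative values")
        if self.species_abundance is None:
            self.species_abundance = np.full(len(self.sample_ids), np.nan)
        else:
            self.species_abundance = np.asarray(self.species_abundance, dtype=float)
            if self.species_abundance.shape != (len(self.sample_ids),):
                raise ValidationError("species_abundance not aligned to sample_ids")
            if np.nanmin(self.species_abundance, initial=0.0) < 0:
                raise ValidationError("species_abundance contains negative values")

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class SampleMetadata:
    """Outcome and covariates per sample.

    ``outcome_family`` is ``"bernoulli"`` when the outcome takes values only
    in {0, 1}, otherwise ``"gaussian"``; auto-detection may be overridden.
    """

    sample_ids: list[str]
    outcome: np.ndarray
    covariates: pd.DataFrame
    outcome_family: str = "gaussian"

    def __post_init__(self) -> None:
        self.sample_ids = _check_ids(self.sample_ids, "sample ids")
        self.outcome = np.asarray(self.outcome, dtype=float)
        if self.outcome.shape != (len(self.sample_ids),):
            raise ValidationError("outcome not aligned to sample_ids")
        if np.isnan(self.outcome).any():
            raise ValidationError("outcome contains missing values")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.sample_ids)
        if len(self.covariates) != len(self.sample_ids):
            raise ValidationError("covariates not aligned to sample_ids")
        self.covariates = self.covariates.set_axis(self.sample_ids, axis=0)
        if self.outcome_family not in ("gaussian", "bernoulli"):
            raise ValidationError(f"unknown outcome family {self.outcome_family!r}")
        if self.outcome_family == "bernoulli" and not np.isin(self.outcome, (0.0, 1.0)).all():
            raise ValidationError("bernoulli outcome must contain only 0/1")

    @staticmethod
    def detect_family(outcome: np.ndarray) -> str:
        outcome = np.asarray(outcome, dtype=float)
        return "bernoulli" if np.isin(outcome, (0.0, 1.0)).all() else "gaussian"

    def select_samples(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        rows = [idx[s] for s in sample_ids]
        return SampleMetadata(
            sample_ids=list(sample_ids),
            outcome=self.outcome[rows].copy(),
            covariates=self.covariates.iloc[rows].copy(),
            outcome_family=self.outcome_family,
        )

    def design_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Covariate design (no intercept), categoricals dummy-encoded."""
        if self.covariates.shape[1] == 0:
            return np.empty((len(self.sample_ids), 0)), []
        enc = pd.get_dummies(self.covariates, drop_first=True, dtype=float)
        return enc.to_numpy(dtype=float), list(enc.columns)
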