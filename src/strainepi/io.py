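"""Readers and writers for the toolkit's file formats.

Stratified abundance tables follow the HUMAnN convention: tab-separated,
header row of sample ids (the first header cell is ignored), feature ids in
the first column, optionally stratified as ``Species|Feature``. ``#`` comment
lines are permitted. Gzip-compressed inputs are accepted transparently.
Trees are Newick files handled through scikit-bio.
"""

from __future__ import annotations

import gzip
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import GeneMatrix, PathwayMatrix, SampleMetadata, ValidationError

__all__ = [
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "read_newick",
    "write_newick",
    "align_samples",
    "ParseError",
]

logger = logging.getLogger(__name__)

STRATIFICATION_DELIMITER = "|"


class ParseError(ValueError):
    """Raised when an input file cannot be parsed."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _read_tsv_matrix(path) -> pd.DataFrame:
    with _open_text(path) as fh:
        raw = [ln for ln in fh if ln.strip()]
    if not raw:
        raise ParseError(f"{path}: empty table")
    # header row may itself carry a leading "#" (HUMAnN convention); the
    # header is the last line of the leading comment block, if any
    n_lead = 0
    while n_lead < len(raw) and raw[n_lead].startswith("#"):
        n_lead += 1
    header_line = raw[n_lead - 1] if n_lead else raw[0]
    lines = [header_line] + [ln for ln in raw[n_lead or 1 :] if not ln.startswith("#")]
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header (need >= 2 tab-separated columns)")
    sample_ids = header[1:]  # first header cell ignored
    if len(set(sample_ids)) != len(sample_ids):
        raise ParseError(f"{path}: duplicate sample ids in header")
    feats, rows = [], []
    for k, ln in enumerate(lines[1:], start=2):
        parts = ln.rstrip("\n").split("\t")
        if len(parts) != len(header):
            raise ParseError(f"{path}: line {k} has {len(parts)} fields, expected {len(header)}")
        feats.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as e:
            raise ParseError(f"{path}: line {k}: {e}") from None
    df = pd.DataFrame(rows, index=feats, columns=sample_ids, dtype=float)
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate feature ids: {dupes[:5]}")
    if (df.to_numpy() < 0).any():
        raise ValidationError(f"{path}: negative abundance values")
    return df


def read_abundance_table(
    path,
    stratified: bool = True,
    kind: str = "gene",
    species_abundance: dict[str, np.ndarray] | None = None,
) -> dict[str, GeneMatrix | PathwayMatrix]:
    """Read a (possibly stratified) abundance TSV into one matrix per species.

    Parameters
    ----------
    path : path-like
        TSV (optionally gzipped); rows = features, columns = samples.
    stratified : bool
        When True, rows are ``Species|Feature`` and unstratified rows are
        ignored; when False the whole table becomes a single matrix under the
        species name ``"all"``.
    kind : {"gene", "pathway"}
        Container type to build.
    species_abundance : dict, optional
        Species name -> per-sample abundance vector (pathway tables only).

    Returns
    -------
    dict mapping species name to :class:`GeneMatrix` or :class:`PathwayMatrix`.
    """
    df = _read_tsv_matrix(path)
    cls = GeneMatrix if kind == "gene" else PathwayMatrix
    out: dict[str, GeneMatrix | PathwayMatrix] = {}
    if not stratified:
        groups = {"all": df}
    else:
        keep = df.index.str.contains(STRATIFICATION_DELIMITER, regex=False)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.warning("%s: ignoring %d unstratified rows", path, n_drop)
        df = df.loc[keep]
        species = df.index.str.split(STRATIFICATION_DELIMITER, n=1).str[0]
        groups = {sp: sub for sp, sub in df.groupby(species, sort=False)}
    for sp, sub in groups.items():
        feats = (
            list(sub.index)
            if not stratified
            else [f.split(STRATIFICATION_DELIMITER, 1)[1] for f in sub.index]
        )
        kwargs = {}
        if kind == "pathway" and species_abundance is not None:
            kwargs["species_abundance"] = species_abundance.get(sp)
        if kind == "gene":
            out[sp] = GeneMatrix(sp, feats, list(sub.columns), sub.to_numpy())
        else:
            out[sp] = PathwayMatrix(sp, feats, list(sub.columns), sub.to_numpy(), **kwargs)
    return out


def write_abundance_table(matrices, path, feature_header: str = "# feature") -> None:
    """Write one or more matrices back to a stratified TSV."""
    if isinstance(matrices, (GeneMatrix, PathwayMatrix)):
        matrices = [matrices]
    samples = matrices[0].sample_ids
    for m in matrices:
        if m.sample_ids != samples:
            raise ValidationError("all matrices must share the same sample columns")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(feature_header + "\t" + "\t".join(samples) + "\n")
        for m in matrices:
            feats = m.gene_ids if isinstance(m, GeneMatrix) else m.pathway_ids
            for i, f in enumerate(feats):
                vals = "\t".join(repr(float(v)) for v in m.abundance[i])
                fh.write(f"{m.species_name}{STRATIFICATION_DELIMITER}{f}\t{vals}\n")


def read_metadata(
    path,
    outcome_col: str,
    covariate_cols: Sequence[str] = (),
    sample_col: str | None = None,
    outcome_family: str | None = None,
) -> SampleMetadata:
    """Read a per-sample metadata TSV.

    The sample-id column defaults to the first column. ``outcome_family`` is
    auto-detected (bernoulli iff the outcome is entirely 0/1) unless given.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str} if sample_col is None else None)
    if sample_col is None:
        sample_col = df.columns[0]
    for col in [sample_col, outcome_col, *covariate_cols]:
        if col not in df.columns:
            raise KeyError(f"{path}: column {col!r} not found")
    if df[outcome_col].isna().any():
        raise ValidationError(f"{path}: missing values in outcome column {outcome_col!r}")
    outcome = df[outcome_col].to_numpy(dtype=float)
    family = outcome_family or SampleMetadata.detect_family(outcome)
    return SampleMetadata(
        sample_ids=[str(s) for s in df[sample_col]],
        outcome=outcome,
        covariates=df[list(covariate_cols)].copy(),
        outcome_family=family,
    )


def read_newick(path_or_str) -> TreeNode:
    """Parse a Newick tree; validates unique leaves and nonnegative lengths."""
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        tree = TreeNode.read([path_or_str])
    else:
        tree = TreeNode.read(str(path_or_str))
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValidationError("duplicate leaf names in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise ValidationError(f"negative branch length on {node.name!r}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def align_samples(matrix, meta: SampleMetadata):
    """Intersect matrix and metadata samples, in metadata order.

    Samples on one side only are dropped with a logged warning; returns the
    restricted (matrix, metadata) pair.
    """
    have = set(matrix.sample_ids)
    shared = [s for s in meta.sample_ids if s in have]
    drop_m = have - set(shared)
    drop_meta = [s for s in meta.sample_ids if s not in have]
    if drop_m:
        logger.warning("dropping %d samples absent from metadata", len(drop_m))
    if drop_meta:
        logger.warning("dropping %d metadata rows absent from abundance table", len(drop_meta))
    return matrix.select_samples(shared), meta.select_samples(shared)
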