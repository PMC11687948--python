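"""Taxa similarity inputs for the 2D embedding.

Four interchangeable views of "which taxa resemble each other": metabolic
annotation vectors used as-is, per-taxon abundance profiles, a combined
z-scored block of both, and pairwise distances (1 - correlation across
samples, or cophenetic distance on a phylogeny).
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .containers import AnnotationTable, DistanceMatrix, TaxaFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "correlation_distance",
    "cophenetic_distance",
    "build_feature_matrix",
]


def correlation_distance(
    abund: pd.DataFrame, method: str = "pearson"
) -> DistanceMatrix:
    """d(i, j) = 1 - r(i, j) of taxa abundance profiles across samples.

    Zero-variance taxa are assigned the uninformative r = 0 (distance 1 to
    everything) so downstream embeddings never see missing values.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"method must be 'pearson' or 'spearman', got {method!r}")
    values = abund.to_numpy(dtype=float)
    n_taxa, n_samples = values.shape
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples, got {n_samples}")
    constant = values.std(axis=1) == 0
    if constant.any():
        logger.info("%d zero-variance taxa assigned r=0", int(constant.sum()))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if method == "pearson":
            r = np.corrcoef(values)
        else:
            r = stats.spearmanr(values.T).statistic
            r = np.atleast_2d(r)
    r = np.nan_to_num(r, nan=0.0)
    d = np.clip(1.0 - r, 0.0, 2.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa_ids=list(abund.index.astype(str)), values=d)


def cophenetic_distance(tree: str | dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs of a tree.

    Missing branch lengths are treated as 1 (logged); duplicate leaf labels
    are an error because taxa must map uniquely to pixels later.
    """
    if isinstance(tree, dendropy.Tree):
        t = tree
    else:
        try:
            t = dendropy.Tree.get(data=tree, schema="newick")
        except Exception as exc:  # dendropy raises several parse error types
            raise ValueError(f"unparseable newick tree: {exc}") from exc
    leaves = list(t.leaf_node_iter())
    labels = [lf.taxon.label if lf.taxon is not None else None for lf in leaves]
    if any(lb is None for lb in labels):
        raise ValueError("tree contains unlabeled leaves")
    if len(set(labels)) != len(labels):
        dupes = sorted({lb for lb in labels if labels.count(lb) > 1})
        raise ValueError(f"duplicate leaf labels: {dupes}")

    missing = 0
    for edge in t.preorder_edge_iter():
        if edge.head_node is t.seed_node:
            continue
        if edge.length is None:
            edge.length = 1.0
            missing += 1
    if missing:
        logger.info("%d edges had no branch length; treated as 1", missing)

    pdm = t.phylogenetic_distance_matrix()
    taxa = {lf.taxon.label: lf.taxon for lf in leaves}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(taxa_ids=labels, values=d)


def _zscore_rows(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=1, keepdims=True)
    std = values.std(axis=1, keepdims=True)
    std[std == 0] = 1.0  # constant rows become all-zero, not NaN
    return (values - mean) / std


def _zscore_cols(values: np.ndarray) -> np.ndarray:
    mean = values.mean(axis=0, keepdims=True)
    std = values.std(axis=0, keepdims=True)
    std[std == 0] = 1.0
    return (values - mean) / std


def build_feature_matrix(
    abund: pd.DataFrame | None = None,
    annot: AnnotationTable | None = None,
    mode: str = "metabolic",
    taxa_ids: Sequence[str] | None = None,
) -> TaxaFeatureMatrix:
    """Assemble the per-taxon feature rows fed to the embedder.

    metabolic: raw annotation vectors (no further computation); abundance:
    per-taxon standardized profile across samples; combined: column-z-scored
    concatenation of both blocks.  Taxa missing from the annotation table are
    retained with all-zero metabolite vectors so the image layout covers
    every observed taxon.
    """
    if mode not in ("metabolic", "abundance", "combined"):
        raise ValueError(f"unknown mode {mode!r}")

    if mode in ("abundance", "combined"):
        if abund is None:
            raise ValueError(f"mode {mode!r} requires an abundance table")
        taxa = list(abund.index.astype(str))
    else:
        if annot is None:
            raise ValueError("metabolic mode requires an annotation table")
        taxa = list(taxa_ids) if taxa_ids is not None else list(annot.taxa_ids)

    def annotation_block(for_taxa: list[str]) -> np.ndarray:
        frame = annot.to_frame()
        present = [t for t in for_taxa if t in frame.index]
        if not present:
            raise ValueError("no overlap between requested taxa and annotation table")
        block = frame.reindex(for_taxa).fillna(0.0).to_numpy(dtype=float)
        n_missing = len(for_taxa) - len(present)
        if n_missing:
            logger.info("%d taxa missing annotations; zero vectors used", n_missing)
        return block

    if mode == "metabolic":
        values = annotation_block(taxa)
    elif mode == "abundance":
        values = _zscore_rows(abund.to_numpy(dtype=float))
    else:
        if annot is None:
            raise ValueError("combined mode requires an annotation table")
        abund_block = _zscore_rows(abund.to_numpy(dtype=float))
        met_block = annotation_block(taxa)
        values = _zscore_cols(np.hstack([abund_block, met_block]))
    return TaxaFeatureMatrix(taxa_ids=taxa, values=values, kind=mode)
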