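"""Readers and writers for the plain-text interchange formats.

Abundance: TSV/CSV, first column taxon id, header = sample ids.  Labels:
two- or three-column TSV (sample_id, phenotype[, cohort]).  Annotations and
traits: TSV with a header row.  Trees: newick.  Delimiters are sniffed.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AnnotationTable, CountMatrix, TraitTable

logger = logging.getLogger(__name__)

__all__ = [
    "read_abundance",
    "read_labels",
    "read_annotations",
    "read_traits",
    "read_tree",
    "write_counts",
    "write_labels",
    "write_annotations",
    "write_traits",
]


def _read_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep=None, engine="python", index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def read_abundance(path) -> CountMatrix:
    """Read a taxa x samples table; detect counts vs relative abundance.

    All-integer tables are treated as counts; tables whose columns sum to ~1
    as relative abundances.  Either way a CountMatrix is returned (counts are
    converted downstream by :meth:`CountMatrix.relative_abundance`).
    """
    frame = _read_table(path)
    if frame.index.duplicated().any():
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        raise ValueError(f"duplicate taxon ids in {path}: {dupes[:5]}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(~np.isfinite(numeric.to_numpy(dtype=float)))
    if bad.size:
        r, c = bad[0]
        raise ValueError(
            f"non-numeric cell at taxon {frame.index[r]!r}, sample "
            f"{frame.columns[c]!r} in {path}"
        )
    values = numeric.to_numpy(dtype=float)
    is_counts = np.allclose(values, np.round(values)) and values.max() > 1.0
    kind = "counts" if is_counts else "relative"
    logger.info("read %s as %s (%d taxa x %d samples)", path, kind, *values.shape)
    return CountMatrix(
        counts=values,
        taxa_ids=list(frame.index),
        sample_ids=list(frame.columns.astype(str)),
        metadata={"source": str(path), "kind": kind},
    )


def read_labels(path, sample_ids: list[str]) -> pd.Series:
    """Read per-sample labels; every label must match a known sample and
    every sample must be labeled.  A cohort column, if present, is folded
    into ``"phenotype|cohort"`` composite labels."""
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"label file {path} needs at least two columns")
    frame = frame.set_index(frame.columns[0])
    unknown = sorted(set(frame.index) - set(sample_ids))
    if unknown:
        raise ValueError(f"labels for unknown samples in {path}: {unknown[:5]}")
    missing = sorted(set(sample_ids) - set(frame.index))
    if missing:
        raise ValueError(f"samples without labels in {path}: {missing[:5]}")
    if frame.shape[1] >= 2:
        labels = frame.iloc[:, 0] + "|" + frame.iloc[:, 1]
    else:
        labels = frame.iloc[:, 0]
    return labels.reindex(sample_ids).rename("label")


def read_annotations(path, taxa_ids: list[str] | None = None) -> AnnotationTable:
    """Read a taxa x metabolite table; optionally subset to known taxa
    (extra annotation rows are dropped silently with a logged count)."""
    frame = _read_table(path).astype(float)
    if taxa_ids is not None:
        extra = len(set(frame.index) - set(taxa_ids))
        if extra:
            logger.info("dropping %d annotation rows for unobserved taxa", extra)
        frame = frame.loc[frame.index.intersection(taxa_ids)]
    return AnnotationTable.from_frame(frame)


def read_traits(path) -> TraitTable:
    frame = _read_table(path)
    frame["gene_count"] = pd.to_numeric(frame["gene_count"], errors="coerce")
    return TraitTable(frame=frame)


def read_tree(path) -> str:
    """Return newick text (parsing/validation happens in cophenetic_distance)."""
    return Path(path).read_text()


def write_counts(cm: CountMatrix, path) -> None:
    frame = cm.to_frame()
    frame.index.name = "taxon_id"
    frame.to_csv(path, sep="\t")


def write_labels(cm: CountMatrix, path) -> None:
    if cm.labels is None:
        raise ValueError("count matrix has no labels")
    rows = []
    for sample, label in zip(cm.sample_ids, cm.labels):
        parts = str(label).split("|")
        rows.append(
            {"sample_id": sample, "phenotype": parts[0]}
            | ({"cohort": parts[1]} if len(parts) > 1 else {})
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_annotations(annot: AnnotationTable, path) -> None:
    frame = annot.to_frame()
    frame.index.name = "taxon_id"
    frame.to_csv(path, sep="\t")


def write_traits(traits: TraitTable, path) -> None:
    frame = traits.frame.copy()
    frame.index.name = "taxon_id"
    frame.to_csv(path, sep="\t")
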