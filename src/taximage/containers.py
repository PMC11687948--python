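"""Shared in-memory containers passed between pipeline stages.

Conventions: abundance tables are taxa x samples; annotation tables are
taxa x metabolites; all identifier lists are plain Python strings and must
be unique within a table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

GRAM_CATEGORIES = ("positive", "negative", "unknown")
MOTILITY_CATEGORIES = ("motile", "non-motile", "unknown")
OXYGEN_CATEGORIES = ("aerobic", "anaerobic", "facultative", "unknown")


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate {what}: {dupes[:5]}")
    return ids


@dataclass
class CountMatrix:
    """Taxa x samples count (or relative-abundance) matrix with labels.

    ``labels`` holds one phenotype label per sample; for crossed designs each
    label is a ``"phenotype|cohort"`` string.
    """

    counts: np.ndarray
    taxa_ids: list[str]
    sample_ids: list[str]
    labels: list[str] | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.taxa_ids = _check_unique(self.taxa_ids, "taxa ids")
        self.sample_ids = _check_unique(self.sample_ids, "sample ids")
        if self.counts.shape != (len(self.taxa_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} inconsistent with "
                f"{len(self.taxa_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if self.labels is not None and len(self.labels) != len(self.sample_ids):
            raise ValueError("one label required per sample")
        if np.any(self.counts < 0):
            raise ValueError("negative abundance values")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxa_ids, columns=self.sample_ids)

    def relative_abundance(self) -> pd.DataFrame:
        """Column-normalize to per-sample relative abundances (sum 1)."""
        frame = self.to_frame().astype(float)
        sums = frame.sum(axis=0)
        sums = sums.replace(0, 1.0)  # all-zero sample stays all-zero
        return frame / sums

    def label_series(self) -> pd.Series:
        if self.labels is None:
            raise ValueError("no labels attached")
        return pd.Series(list(self.labels), index=self.sample_ids, name="label")


@dataclass
class AnnotationTable:
    """Taxa x metabolite production/transformation indicators or weights."""

    taxa_ids: list[str]
    metabolite_ids: list[str]
    values: np.ndarray
    signal_metabolites: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa_ids = _check_unique(self.taxa_ids, "taxa ids")
        self.metabolite_ids = _check_unique(self.metabolite_ids, "metabolite ids")
        if self.values.shape != (len(self.taxa_ids), len(self.metabolite_ids)):
            raise ValueError("annotation matrix shape inconsistent with id lists")
        if np.any(self.values < 0):
            raise ValueError("negative annotation weights")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.taxa_ids, columns=self.metabolite_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AnnotationTable":
        return cls(
            taxa_ids=list(frame.index.astype(str)),
            metabolite_ids=list(frame.columns.astype(str)),
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class TraitTable:
    """Per-taxon categorical traits plus an integer gene count.

    Columns: gram_status, motility, oxygen_tolerance (vocabulary-restricted)
    and gene_count (nullable integer).
    """

    frame: pd.DataFrame

    COLUMNS = ("gram_status", "motility", "oxygen_tolerance", "gene_count")
    VOCAB = {
        "gram_status": GRAM_CATEGORIES,
        "motility": MOTILITY_CATEGORIES,
        "oxygen_tolerance": OXYGEN_CATEGORIES,
    }

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"trait table missing columns {missing}")
        _check_unique(self.frame.index, "taxa ids")
        for col, vocab in self.VOCAB.items():
            bad = set(self.frame[col].dropna()) - set(vocab)
            if bad:
                raise ValueError(f"{col} contains values outside vocabulary: {bad}")

    @property
    def taxa_ids(self) -> list[str]:
        return list(self.frame.index.astype(str))


@dataclass
class DistanceMatrix:
    """Symmetric pairwise taxa distances with zero diagonal."""

    taxa_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa_ids = _check_unique(self.taxa_ids, "taxa ids")
        n = len(self.taxa_ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square over taxa ids")
        if np.any(self.values < -1e-12):
            raise ValueError("negative distances")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal must be zero")
        # enforce exactly after tolerance check
        self.values = np.maximum((self.values + self.values.T) / 2.0, 0.0)
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxa_ids, columns=self.taxa_ids)


@dataclass
class TaxaFeatureMatrix:
    """Per-taxon feature vectors driving the 2D embedding."""

    taxa_ids: list[str]
    values: np.ndarray
    kind: str = "metabolic"  # {metabolic, abundance, combined}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.taxa_ids = _check_unique(self.taxa_ids, "taxa ids")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.taxa_ids):
            raise ValueError("feature matrix must have one row per taxon")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite feature values")
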