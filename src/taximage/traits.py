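"""Downstream interpretation of important-taxa sets.

Three views: per-group metabolite "producer sums" filtered at a percentile,
differential metabolite statistics between important and unimportant taxa
(rank-sum test, Benjamini-Hochberg adjustment, volcano/MA-ready columns),
and categorical trait summaries with median gene counts.
"""

from __future__ import annotations

import logging
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import AnnotationTable, TraitTable

logger = logging.getLogger(__name__)

__all__ = ["metabolite_sums", "differential_metabolites", "trait_summary"]


def metabolite_sums(
    important_sets: Mapping[Any, Iterable[str]],
    annot: AnnotationTable,
    percentile: float = 99.0,
) -> dict[str, Any]:
    """Per-group metabolite sums over important taxa, percentile-filtered.

    For each group, annotation weights of that group's important taxa are
    summed per metabolite and metabolites at or above the within-group
    percentile of nonzero sums are retained.  Also reports the metabolites
    retained in every group (the cross-group intersection).
    """
    if not (0 <= percentile < 100):
        raise ValueError("percentile must lie in [0, 100)")
    frame = annot.to_frame()
    per_group: dict[Any, pd.Series] = {}
    retained: dict[Any, set] = {}
    for group, taxa in important_sets.items():
        taxa = [str(t) for t in taxa]
        present = [t for t in taxa if t in frame.index]
        dropped = len(taxa) - len(present)
        if dropped:
            logger.info("group %s: %d taxa missing from annotations", group, dropped)
        if not present:
            logger.warning("group %s has no annotated important taxa", group)
            per_group[group] = pd.Series(dtype=float)
            retained[group] = set()
            continue
        sums = frame.loc[present].sum(axis=0)
        nonzero = sums[sums > 0]
        if nonzero.empty:
            per_group[group] = pd.Series(dtype=float)
            retained[group] = set()
            continue
        threshold = np.percentile(nonzero.to_numpy(), percentile)
        kept = nonzero[nonzero >= threshold].sort_values(ascending=False)
        per_group[group] = kept
        retained[group] = set(kept.index)
    common = set.intersection(*retained.values()) if retained else set()
    return {"per_group": per_group, "common": sorted(common)}


def differential_metabolites(
    important: Iterable[str],
    unimportant: Iterable[str],
    annot: AnnotationTable,
    eps: float = 1e-3,
    test: str = "ranksum",
) -> pd.DataFrame:
    """Per-metabolite differential statistics between two taxa sets.

    log2 fold change of pseudocounted group means, a rank-sum (or Welch t)
    test of annotation weights between the sets, and BH-adjusted p-values.
    Columns cover both volcano (log2_fc vs -log10 p) and MA (mean_expression
    vs log2_fc) views.
    """
    if test not in ("ranksum", "ttest"):
        raise ValueError("test must be 'ranksum' or 'ttest'")
    frame = annot.to_frame()
    imp = [t for t in (str(x) for x in important) if t in frame.index]
    unimp = [t for t in (str(x) for x in unimportant) if t in frame.index]
    if not imp or not unimp:
        raise ValueError("both taxa sets must be nonempty (after annotation join)")
    low_power = min(len(imp), len(unimp)) < 2
    if low_power:
        logger.warning("a taxa set has fewer than 2 annotated members; low power")

    a = frame.loc[imp].to_numpy(dtype=float)
    b = frame.loc[unimp].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    log2_fc = np.log2((mean_a + eps) / (mean_b + eps))

    pvals = np.ones(frame.shape[1])
    statistic = np.zeros(frame.shape[1])
    for j in range(frame.shape[1]):
        x, y = a[:, j], b[:, j]
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            continue  # identical constant columns: no evidence
        if test == "ranksum":
            res = stats.mannwhitneyu(x, y, alternative="two-sided")
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
        statistic[j] = float(res.statistic)
        pvals[j] = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    qvals = multipletests(pvals, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "metabolite_id": annot.metabolite_ids,
            "mean_important": mean_a,
            "mean_unimportant": mean_b,
            "mean_expression": (a.sum(axis=0) + b.sum(axis=0)) / (len(imp) + len(unimp)),
            "log2_fc": log2_fc,
            "statistic": statistic,
            "pvalue": pvals,
            "qvalue": qvals,
            "low_power": low_power,
        }
    )


def trait_summary(
    taxa_sets: Mapping[Any, Iterable[str]], traits: TraitTable
) -> pd.DataFrame:
    """Category counts and median gene count per taxa set.

    Taxa absent from the trait table count as "unknown" in every categorical
    trait (set sizes are conserved); the median gene count is over taxa with
    a known count and is NaN for empty sets.
    """
    frame = traits.frame
    rows = []
    for name, taxa in taxa_sets.items():
        taxa = [str(t) for t in taxa]
        row: dict[str, Any] = {"set": name, "n_taxa": len(taxa)}
        present = [t for t in taxa if t in frame.index]
        absent = len(taxa) - len(present)
        sub = frame.loc[present] if present else frame.iloc[:0]
        for col, vocab in TraitTable.VOCAB.items():
            counts = sub[col].value_counts()
            for cat in vocab:
                row[f"{col}_{cat}"] = int(counts.get(cat, 0))
            row[f"{col}_unknown"] += absent
        gene_counts = pd.to_numeric(sub["gene_count"], errors="coerce").dropna()
        row["median_gene_count"] = (
            float(gene_counts.median()) if len(gene_counts) else float("nan")
        )
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
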