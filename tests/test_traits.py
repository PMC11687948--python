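"""Metabolite aggregation, differential statistics, trait summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

import taximage as tx


@pytest.fixture(scope="module")
def annot_4groups():
    rng = np.random.default_rng(0)
    taxa = [f"t{i}" for i in range(80)]
    annot = tx.AnnotationTable(
        taxa_ids=taxa,
        metabolite_ids=[f"m{j}" for j in range(25)],
        values=(rng.random((80, 25)) < 0.4).astype(float),
    )
    groups = {
        g: set(rng.choice(taxa, size=15, replace=False)) for g in "ABCD"
    }
    return annot, groups


class TestMetaboliteSums:
    def test_single_producer_sum_is_weight(self):
        annot = tx.AnnotationTable(
            taxa_ids=["t0"], metabolite_ids=["m0"], values=[[2.5]]
        )
        res = tx.metabolite_sums({"g": {"t0"}}, annot, percentile=0)
        assert res["per_group"]["g"]["m0"] == 2.5

    def test_percentile_zero_keeps_all_nonzero(self, annot_4groups):
        annot, groups = annot_4groups
        res = tx.metabolite_sums(groups, annot, percentile=0)
        frame = annot.to_frame()
        for g, taxa in groups.items():
            sums = frame.loc[sorted(taxa)].sum(axis=0)
            assert set(res["per_group"][g].index) == set(sums[sums > 0].index)

    def test_sort_and_threshold_oracle(self, annot_4groups):
        annot, groups = annot_4groups
        res = tx.metabolite_sums(groups, annot, percentile=80)
        frame = annot.to_frame()
        for g, taxa in groups.items():
            sums = frame.loc[sorted(taxa)].sum(axis=0)
            nonzero = sums[sums > 0]
            thr = np.percentile(nonzero.to_numpy(), 80)
            expected = set(nonzero[nonzero >= thr].index)
            assert set(res["per_group"][g].index) == expected
        # common = intersection of retained sets
        retained = [set(res["per_group"][g].index) for g in groups]
        assert set(res["common"]) == set.intersection(*retained)

    def test_retained_set_shrinks_with_percentile(self, annot_4groups):
        annot, groups = annot_4groups
        sizes = [
            len(tx.metabolite_sums(groups, annot, percentile=p)["per_group"]["A"])
            for p in (0, 50, 90, 99)
        ]
        assert sizes == sorted(sizes, reverse=True)

    def test_empty_group_yields_empty_table(self, annot_4groups):
        annot, _ = annot_4groups
        res = tx.metabolite_sums({"empty": set(), "full": {"t0"}}, annot)
        assert len(res["per_group"]["empty"]) == 0


class TestDifferentialMetabolites:
    def test_identical_groups_zero_fold_change(self):
        rng = np.random.default_rng(1)
        taxa = [f"t{i}" for i in range(20)]
        annot = tx.AnnotationTable(
            taxa_ids=taxa,
            metabolite_ids=["m0", "m1", "m2"],
            values=(rng.random((20, 3)) < 0.5).astype(float),
        )
        # two disjoint sets with identical annotation rows
        annot.values[10:] = annot.values[:10]
        stats_frame = tx.differential_metabolites(taxa[:10], taxa[10:], annot)
        np.testing.assert_allclose(stats_frame["log2_fc"], 0.0, atol=1e-12)

    def test_exclusive_signal_metabolite_ranks_first(self):
        taxa = [f"t{i}" for i in range(30)]
        values = np.zeros((30, 5))
        values[:10, 0] = 1.0          # produced only by "important" taxa
        values[:, 1:] = 0.5           # constant elsewhere
        annot = tx.AnnotationTable(
            taxa_ids=taxa, metabolite_ids=[f"m{j}" for j in range(5)], values=values
        )
        res = tx.differential_metabolites(taxa[:10], taxa[10:], annot, eps=1e-3)
        assert res.loc[0, "log2_fc"] == pytest.approx(np.log2((1 + 1e-3) / 1e-3))
        assert res["pvalue"].idxmin() == 0

    def test_per_column_oracle(self):
        """Matches an independent rank-sum + BH recomputation per metabolite."""
        da = list(range(45))
        taxa = [f"t{i}" for i in range(200)]
        annot = tx.simulate_annotations(taxa, 30, da, 0.9, 0.2, seed=9, n_signal=10)
        important = set(taxa[:45])
        unimportant = set(taxa[45:])
        res = tx.differential_metabolites(important, unimportant, annot)
        frame = annot.to_frame()
        a = frame.loc[sorted(important)].to_numpy()
        b = frame.loc[sorted(unimportant)].to_numpy()
        pvals = []
        for j in range(30):
            if np.all(a[:, j] == a[0, j]) and np.all(b[:, j] == b[0, j]) and a[0, j] == b[0, j]:
                pvals.append(1.0)
            else:
                pvals.append(
                    stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided").pvalue
                )
        np.testing.assert_allclose(res["pvalue"], pvals, atol=1e-12)
        np.testing.assert_allclose(
            res["qvalue"], multipletests(pvals, method="fdr_bh")[1], atol=1e-12
        )
        # enriched signal metabolites dominate the ranking
        top10 = set(res.nsmallest(10, "qvalue")["metabolite_id"])
        assert len(top10 & set(annot.signal_metabolites)) >= 5

    def test_adjusted_never_below_raw(self, annot_4groups):
        annot, groups = annot_4groups
        res = tx.differential_metabolites(groups["A"], groups["B"], annot)
        assert (res["qvalue"] >= res["pvalue"] - 1e-12).all()

    def test_empty_set_rejected(self, annot_4groups):
        annot, groups = annot_4groups
        with pytest.raises(ValueError, match="nonempty"):
            tx.differential_metabolites(set(), groups["A"], annot)


class TestTraitSummary:
    def test_counts_sum_to_set_size(self, small_sim):
        traits = small_sim["traits"]
        taxa = traits.taxa_ids
        sets = {"s1": set(taxa[:10]), "s2": set(taxa[5:20]) | {"missing_taxon"}}
        report = tx.trait_summary(sets, traits)
        for name, members in sets.items():
            for trait in ("gram_status", "motility", "oxygen_tolerance"):
                cols = [c for c in report.columns if c.startswith(trait)]
                assert report.loc[name, cols].sum() == len(members)

    def test_median_gene_count(self):
        frame = pd.DataFrame(
            {
                "gram_status": ["positive"] * 3,
                "motility": ["motile"] * 3,
                "oxygen_tolerance": ["aerobic"] * 3,
                "gene_count": [100, 200, 900],
            },
            index=["a", "b", "c"],
        )
        report = tx.trait_summary({"s": {"a", "b", "c"}}, tx.TraitTable(frame))
        assert report.loc["s", "median_gene_count"] == 200

    def test_empty_set_missing_median(self, small_sim):
        report = tx.trait_summary({"none": set()}, small_sim["traits"])
        assert report.loc["none", "n_taxa"] == 0
        assert np.isnan(report.loc["none", "median_gene_count"])

    def test_hand_tabulated_recount(self, small_sim):
        rng = np.random.default_rng(2)
        traits = small_sim["traits"]
        members = set(rng.choice(traits.taxa_ids, size=20, replace=False))
        report = tx.trait_summary({"s": members}, traits)
        sub = traits.frame.loc[sorted(members)]
        for cat in ("positive", "negative", "unknown"):
            assert report.loc["s", f"gram_status_{cat}"] == (
                (sub["gram_status"] == cat).sum()
            )
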