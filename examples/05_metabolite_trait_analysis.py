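"""Downstream interpretation: metabolites and traits of important taxa.

Takes an important/unimportant taxa split (here, the true DA taxa stand in
for a saliency-derived selection so the example is fast), sums annotation
columns per group at a percentile filter, tests each metabolite between the
two sets (rank-sum + Benjamini-Hochberg), and tabulates functional traits.
"""

import taximage as tx

taxa = [f"taxon_{i:04d}" for i in range(200)]
annot = tx.simulate_annotations(taxa, 60, range(45), 0.9, 0.2, seed=2)
traits = tx.simulate_traits(taxa, seed=3)

important = set(taxa[:45])
unimportant = set(taxa[45:])

sums = tx.metabolite_sums({"region_A": important}, annot, percentile=99)
print("99th-percentile metabolite producer sums (region_A):")
print(sums["per_group"]["region_A"].to_string())

diff = tx.differential_metabolites(important, unimportant, annot)
top = diff.nsmallest(8, "qvalue")[["metabolite_id", "log2_fc", "pvalue", "qvalue"]]
print("\ntop differential metabolites (signal block is met_0000..met_0009):")
print(top.round(4).to_string(index=False))

common, unique = tx.common_unique_partition(
    {"A": important, "B": set(taxa[30:80])}
)
report = tx.trait_summary(
    {"common": common, "unique_A": unique["A"], "unique_B": unique["B"]}, traits
)
print("\ntrait summary (category counts + median gene count per set):")
print(report.to_string())
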