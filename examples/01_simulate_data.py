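"""Simulate a sparse 16S-like count matrix with a known disease signal.

Generates 200 taxa x 120 samples (60 control / 60 case) at ~80% sparsity,
with 45 differentially abundant (DA) taxa spiked by a 2x fold change in the
case class, plus matching annotation and trait tables.
"""

import numpy as np

import taximage as tx

params = tx.SimParams(
    n_taxa=200,
    n_per_class=60,
    library_size=10_000,
    da_indices=range(45),
    fold_change=2.0,
    target_sparsity=0.8,
    seed=1,
)
cm = tx.simulate_counts(params)
annot = tx.simulate_annotations(
    cm.taxa_ids, n_metabolites=60, da_indices=params.da_indices,
    enrichment=0.9, background_rate=0.2, seed=2,
)
traits = tx.simulate_traits(cm.taxa_ids, seed=3)

print(f"counts: {cm.n_taxa} taxa x {cm.n_samples} samples")
print(f"library size per sample: {cm.counts.sum(axis=0).min()}"
      f" (exact for every sample: {bool((cm.counts.sum(axis=0) == params.library_size).all())})")
print(f"realized sparsity: {cm.metadata['realized_sparsity']:.3f}"
      f" (target {params.target_sparsity})")

rel = cm.relative_abundance().to_numpy()
labels = np.array(cm.labels)
case = rel[:, labels == "case"].mean(axis=1)
ctrl = rel[:, labels == "control"].mean(axis=1)
ratio = (case[:45] + 1e-9) / (ctrl[:45] + 1e-9)
print(f"mean case/control abundance ratio of DA taxa: {ratio.mean():.2f}"
      " (the injected fold change, shrunk by compositional renormalization)")
print(f"annotations: {annot.values.shape[1]} metabolites,"
      f" signal block = {annot.signal_metabolites}")
print(traits.frame.head())
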