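"""Turn the taxa table into fixed-layout sample images.

Taxa are embedded in 2D from their metabolite-annotation vectors, enclosed
by the minimum-area rotated rectangle, and rasterized onto a 24x24 grid.
Every sample image places the same taxon at the same pixel; pixel intensity
is the summed relative abundance of its taxa.
"""

import numpy as np

import taximage as tx

cm = tx.simulate_counts(
    tx.SimParams(n_taxa=200, n_per_class=60, da_indices=range(45),
                 fold_change=2.0, target_sparsity=0.8, seed=1)
)
annot = tx.simulate_annotations(cm.taxa_ids, 60, range(45), 0.9, 0.2, seed=2)
abund = cm.relative_abundance()

features = tx.build_feature_matrix(abund=abund, annot=annot, mode="metabolic")
embedding = tx.embed_taxa(features, method="tsne", perplexity=30, seed=0)
rect = tx.min_area_rectangle(embedding.coords)
print(f"minimum-area rectangle: area {rect.area:.1f}, "
      f"rotation {np.rad2deg(rect.angle):.1f} degrees")

pmap = tx.assign_pixels(embedding, height=24, width=24)
print(f"pixel map: {pmap.n_taxa} taxa on {pmap.n_occupied_pixels} pixels; "
      f"{pmap.n_collisions} taxa share a pixel "
      f"(max {pmap.max_taxa_per_pixel} per pixel)")

stack = tx.render_images(abund, pmap)
mass = stack.denormalized().sum(axis=(1, 2))
print(f"per-image compositional mass (should be exactly 1): "
      f"min {mass.min():.12f}, max {mass.max():.12f}")
print(f"normalization constant stored for held-out data: {stack.norm_max:.4f}")
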