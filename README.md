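# taximage

**Interpretable microbiome phenotype classification by turning taxa tables
into images.**

Microbiome association studies usually hand a taxa × sample
relative-abundance table to a black-box classifier and stop at an accuracy
number.  `taximage` is for researchers who also want to know *which* taxa —
and which of their metabolites and functional traits — drive a predicted
phenotype.  It does this by re-expressing every sample as a small
single-channel image in which functionally similar taxa are neighboring
pixels, classifying the images with a residual CNN that carries a spatial
attention gate in every block, and then projecting the network's class
saliency back through the fixed taxon→pixel map into per-taxon importance
scores and downstream metabolite/trait statistics.

## The method in brief

1. **Taxa similarity** — each taxon *i* gets a feature vector: its
   metabolite-annotation row (Agora2-style table, used as loaded), its
   standardized abundance profile, a combination of both, or a pairwise
   distance (1 − r Pearson/Spearman, or cophenetic distance on a phylogeny).
2. **Embedding + rasterization** — t-SNE/UMAP embeds taxa in ℝ²; the
   minimum-area rotated rectangle of the cloud (rotating calipers on the
   convex hull) is mapped affinely onto an H × W grid.  The resulting
   PixelMap is fixed for the whole dataset: sample *s* becomes the image
   X⁽ˢ⁾ with X⁽ˢ⁾ᵣ𝒸 = Σ_{i ∈ pixel(r,c)} aᵢₛ, where aᵢₛ is relative
   abundance, so each raw image sums to exactly 1.
3. **Classification** — a stem convolution, residual blocks
   (conv → BN → ReLU → conv → BN → spatial attention → shortcut → ReLU,
   attention = σ(conv₇ₓ₇[channel-mean; channel-max])), global average
   pooling and a softmax head; trained with Adam, early stopping, and
   leakage-safe cross-validation (embedding, pixel map and normalization
   refit per fold).  The network is pure NumPy with analytic gradients.
4. **Interpretation** — Grad-CAM: channel weights αₖ = mean spatial
   gradient of the class logit w.r.t. feature map Aₖ; saliency =
   max-normalized ReLU(Σₖ αₖAₖ), averaged over all samples of a class and
   assigned to each taxon via its pixel.  Taxa above a saliency percentile
   are "important"; metabolite producer-sums, rank-sum/BH differential
   metabolite statistics and trait summaries characterize them.

A multivariate-hypergeometric count simulator (gamma intensity noise,
abundance-weighted dropout calibrated to a target sparsity, exact library
sizes) generates sparse compositional 16S-like data with a planted
differential-abundance signal, so the entire chain is testable offline.
See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

`examples/` contains one short script per capability.  The core loop:

```python
import taximage as tx
from taximage.nn import CVSettings, TrainConfig, cross_validate

cm = tx.simulate_counts(tx.SimParams(
    n_taxa=200, n_per_class=60, da_indices=range(45),
    fold_change=4.0, target_sparsity=0.8, seed=1))
annot = tx.simulate_annotations(cm.taxa_ids, 60, range(45), 0.9, 0.2, seed=2)

cv = cross_validate(cm.relative_abundance(), cm.label_series(),
                    settings=CVSettings(similarity_mode="metabolic",
                                        image_height=16, image_width=16,
                                        blocks=((8,3,1),(16,3,2)),
                                        train=TrainConfig(epochs=50, patience=12)),
                    k=5, seed=0, annot=annot)
print(cv["aggregate"])
```

Running `python examples/03_train_and_evaluate.py` prints:

```
 repeat  fold  accuracy  macro_f1  auc
      0     0     0.958     0.958  1.0
      0     1     1.000     1.000  1.0
      0     2     1.000     1.000  1.0
      0     3     1.000     1.000  1.0
      0     4     1.000     1.000  1.0
mean accuracy 0.992, macro-F1 0.992, AUC 1.000
```

— a 4× fold change across 45 of 200 taxa at 80% sparsity is nearly
perfectly separable, while the same pipeline on a no-signal simulation
stays at chance (~0.5).  `examples/04_saliency_importance.py` then shows
the interpretability half — on its seed the Grad-CAM-derived taxa ranking
recovers the truly spiked taxa with AUROC 0.997 and every taxon selected at
the 90th saliency percentile is a true positive (the median across five
independent simulations in the acceptance battery is ≈ 0.86) — and
`examples/05_...` pushes the selected taxa through metabolite and trait
statistics.

## Command line

A thin CLI wraps the library for shell use:

```bash
taximage simulate --out sim_out --seed 1
taximage build-images --counts sim_out/counts.tsv \
    --annotations sim_out/annotations.tsv --size 32 --seed 1 --out img_out
taximage run --config pipeline.yaml --seed 1   # full pipeline from YAML
taximage cv  --config pipeline.yaml --k 5
```

All inputs are plain TSV/CSV (taxa × samples counts, sample labels,
taxa × metabolite annotations, taxa × trait tables) plus newick trees.

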