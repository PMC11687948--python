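"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import taximage as tx
from taximage.nn import CVSettings, TrainConfig


@pytest.fixture(scope="session")
def small_sim():
    """Tiny strongly-separable dataset: 60 taxa, 30/class, fold 3, 12 DA."""
    params = tx.SimParams(
        n_taxa=60,
        n_per_class=30,
        library_size=5000,
        da_indices=range(12),
        fold_change=3.0,
        target_sparsity=0.7,
        seed=11,
    )
    cm = tx.simulate_counts(params)
    annot = tx.simulate_annotations(
        cm.taxa_ids, 30, params.da_indices, 0.9, 0.2, seed=12, n_signal=6
    )
    traits = tx.simulate_traits(cm.taxa_ids, seed=13)
    return {"params": params, "counts": cm, "annot": annot, "traits": traits}


@pytest.fixture(scope="session")
def small_images(small_sim):
    """Images rendered from the small dataset with a fixed t-SNE layout."""
    cm = small_sim["counts"]
    abund = cm.relative_abundance()
    fm = tx.build_feature_matrix(abund=abund, annot=small_sim["annot"], mode="combined")
    emb = tx.embed_taxa(fm, method="tsne", perplexity=10, seed=5, max_iter=300)
    pmap = tx.assign_pixels(emb, 12, 12)
    stack = tx.render_images(abund, pmap)
    return {"pmap": pmap, "stack": stack, "labels": np.array(cm.labels)}


@pytest.fixture(scope="session")
def small_fitted(small_images):
    """A trained model on the small dataset (shared; treat as read-only)."""
    model = tx.build_model([(8, 3, 1), (16, 3, 2)], 2, 12, 12, seed=0)
    fitted = tx.train(
        model,
        small_images["stack"].images,
        small_images["labels"],
        TrainConfig(epochs=30, patience=30, seed=0),
    )
    return fitted


@pytest.fixture
def fast_cv_settings():
    return CVSettings(
        similarity_mode="combined",
        image_height=12,
        image_width=12,
        blocks=((8, 3, 1), (16, 3, 2)),
        tsne_max_iter=300,
        perplexity=10,
        train=TrainConfig(epochs=15, patience=5),
    )
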