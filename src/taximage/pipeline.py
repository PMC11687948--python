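"""End-to-end pipeline: data -> similarity -> images -> model -> importance.

A :class:`PipelineConfig` captures every stage's settings plus a single root
seed; each stage derives its own seed by a fixed offset, so one (config,
seed) pair reproduces every artifact.  ``run_pipeline`` writes a manifest
alongside its outputs with the config hash and derived seeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .containers import AnnotationTable, CountMatrix, TraitTable
from .imaging import assign_pixels, embed_taxa, render_images
from .nn.network import BlockSpec, build_model
from .nn.training import CVSettings, TrainConfig, cross_validate, evaluate, train
from .saliency import (
    class_saliency,
    common_unique_partition,
    select_important,
    taxa_importance,
)
from .sim import SimParams, simulate_annotations, simulate_counts, simulate_traits
from .similarity import build_feature_matrix, correlation_distance, cophenetic_distance
from .traits import differential_metabolites, metabolite_sums, trait_summary

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_model_bundle", "child_seed"]

# fixed per-stage seed offsets: all randomness flows from one root seed
STAGE_OFFSETS = {"simulate": 1, "embedding": 2, "model": 3, "cv": 4}


def child_seed(root: int, stage: str) -> int:
    return (root * 1000003 + STAGE_OFFSETS[stage]) % (2**31 - 1)


@dataclass
class PipelineConfig:
    # inputs (either paths, or simulate=True)
    counts_path: str | None = None
    labels_path: str | None = None
    annotations_path: str | None = None
    traits_path: str | None = None
    tree_path: str | None = None
    simulate: bool = False
    sim: dict = field(default_factory=dict)  # SimParams overrides
    sim_annotations: dict = field(default_factory=dict)
    # representation
    similarity_mode: str = "metabolic"
    embedding_method: str = "tsne"
    perplexity: float = 30.0
    n_neighbors: int = 15
    min_dist: float = 0.1
    tsne_max_iter: int = 500
    image_height: int = 32
    image_width: int = 32
    # model
    blocks: list = field(default_factory=lambda: [[16, 3, 1], [32, 3, 2]])
    train: dict = field(default_factory=dict)  # TrainConfig overrides
    # evaluation / interpretation
    cross_validation: bool = False
    cv_folds: int = 5
    cv_repeats: int = 1
    saliency_layer: int = -1
    importance_percentile: float = 90.0
    metabolite_percentile: float = 99.0
    # bookkeeping
    seed: int = 0
    out_dir: str = "taximage_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate_paths(self) -> None:
        if self.simulate:
            return
        if self.counts_path is None or self.labels_path is None:
            raise ValueError("counts_path and labels_path required unless simulate=true")
        for name in ("counts_path", "labels_path", "annotations_path",
                     "traits_path", "tree_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]

    def cv_settings(self) -> CVSettings:
        return CVSettings(
            similarity_mode=self.similarity_mode,
            embedding_method=self.embedding_method,
            perplexity=self.perplexity,
            n_neighbors=self.n_neighbors,
            min_dist=self.min_dist,
            tsne_max_iter=self.tsne_max_iter,
            image_height=self.image_height,
            image_width=self.image_width,
            blocks=tuple(tuple(b) for b in self.blocks),
            train=TrainConfig(**self.train),
        )


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulate:
        params = SimParams(**{**cfg.sim, "seed": child_seed(cfg.seed, "simulate")})
        cm = simulate_counts(params)
        annot = simulate_annotations(
            cm.taxa_ids,
            n_metabolites=cfg.sim_annotations.get("n_metabolites", 60),
            da_indices=params.da_indices,
            enrichment=cfg.sim_annotations.get("enrichment", 0.9),
            background_rate=cfg.sim_annotations.get("background_rate", 0.2),
            seed=child_seed(cfg.seed, "simulate") + 1,
            n_signal=cfg.sim_annotations.get("n_signal", 10),
        )
        traits = simulate_traits(cm.taxa_ids, seed=child_seed(cfg.seed, "simulate") + 2)
        return cm, cm.label_series(), annot, traits, None
    cfg.validate_paths()
    cm = tio.read_abundance(cfg.counts_path)
    labels = tio.read_labels(cfg.labels_path, cm.sample_ids)
    annot = (
        tio.read_annotations(cfg.annotations_path, cm.taxa_ids)
        if cfg.annotations_path
        else None
    )
    traits = tio.read_traits(cfg.traits_path) if cfg.traits_path else None
    tree = tio.read_tree(cfg.tree_path) if cfg.tree_path else None
    return cm, labels, annot, traits, tree


def _embedding_input(cfg, abund, annot, tree):
    mode = cfg.similarity_mode
    if mode in ("pearson", "spearman"):
        return correlation_distance(abund, method=mode)
    if mode == "cophenetic":
        if tree is None:
            raise ValueError("cophenetic similarity requires tree_path")
        return cophenetic_distance(tree)
    return build_feature_matrix(abund=abund, annot=annot, mode=mode)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute every stage and write artifacts under ``cfg.out_dir``.

    Returns the result bundle (pixel map, fitted model, metrics, per-class
    saliency and importance, trait report, manifest) as a dict.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(cfg),
        "config_hash": cfg.config_hash(),
        "stage_seeds": {s: child_seed(cfg.seed, s) for s in STAGE_OFFSETS},
    }

    def stage(name):
        logger.info("pipeline stage: %s", name)

    stage("load")
    try:
        cm, labels, annot, traits, tree = _load_inputs(cfg)
    except Exception as exc:
        raise RuntimeError(f"[load] {exc}; check input paths/config") from exc
    abund = cm.relative_abundance()
    if cfg.simulate:
        tio.write_counts(cm, out / "counts.tsv")
        tio.write_labels(cm, out / "labels.tsv")
        if annot is not None:
            tio.write_annotations(annot, out / "annotations.tsv")
        if traits is not None:
            tio.write_traits(traits, out / "traits.tsv")

    stage("similarity+embedding")
    emb_input = _embedding_input(cfg, abund, annot, tree)
    emb = embed_taxa(
        emb_input,
        method=cfg.embedding_method,
        perplexity=cfg.perplexity,
        n_neighbors=cfg.n_neighbors,
        min_dist=cfg.min_dist,
        seed=child_seed(cfg.seed, "embedding"),
        max_iter=cfg.tsne_max_iter,
    )
    pmap = assign_pixels(emb, cfg.image_height, cfg.image_width)
    pmap.to_tsv(out / "pixel_map.tsv")

    stage("render")
    stack = render_images(abund, pmap)
    np.savez(out / "images.npz", images=stack.images, sample_ids=stack.sample_ids)

    results: dict = {"pixel_map": pmap, "manifest": manifest}
    metrics_out: dict = {}

    if cfg.cross_validation:
        stage("cross-validation")
        cv = cross_validate(
            abund,
            labels,
            settings=cfg.cv_settings(),
            k=cfg.cv_folds,
            repeats=cfg.cv_repeats,
            seed=child_seed(cfg.seed, "cv"),
            annot=annot,
            tree=tree,
        )
        cv["fold_metrics"].to_csv(out / "cv_metrics.tsv", sep="\t", index=False)
        metrics_out["cv"] = cv["aggregate"]
        results["cv"] = cv

    stage("train")
    classes = np.unique(labels.to_numpy())
    model = build_model(
        [BlockSpec(*b) for b in cfg.blocks],
        n_classes=len(classes),
        height=cfg.image_height,
        width=cfg.image_width,
        seed=child_seed(cfg.seed, "model"),
    )
    fitted = train(
        model,
        stack.images,
        labels.to_numpy(),
        TrainConfig(**{**cfg.train, "seed": child_seed(cfg.seed, "model")}),
    )
    fitted.norm_max = stack.norm_max
    train_metrics = evaluate(fitted, stack.images, labels.to_numpy())
    metrics_out["training_set"] = {
        k: v for k, v in train_metrics.items() if k != "confusion_matrix"
    }
    np.savez(
        out / "model.npz",
        **{k.replace(".", "__"): v for k, v in model.state().items()},
    )
    with open(out / "model_manifest.json", "w") as fh:
        json.dump(
            {
                "blocks": [list(dataclasses.astuple(b)) for b in model.block_specs],
                "classes": [str(c) for c in fitted.classes],
                "norm_max": stack.norm_max,
                "input_shape": list(model.input_shape),
                "config_hash": cfg.config_hash(),
            },
            fh,
            indent=2,
        )

    stage("saliency")
    importance_frames = []
    important_sets: dict[str, set] = {}
    for class_value in classes:
        sal = class_saliency(
            fitted, stack.images, labels.to_numpy(), class_value,
            layer=cfg.saliency_layer,
        )
        np.save(out / f"saliency_{class_value}.npy".replace("|", "_"), sal.values)
        _save_heatmap(sal.values, out / f"saliency_{class_value}.png".replace("|", "_"))
        imp = taxa_importance(sal, pmap)
        selected, _ = select_important(imp, percentile=cfg.importance_percentile)
        important_sets[str(class_value)] = selected
        frame = imp.to_frame()
        frame["selected"] = frame["taxon_id"].isin(selected)
        importance_frames.append(frame)
    importance = pd.concat(importance_frames, ignore_index=True)
    importance.to_csv(out / "taxa_importance.tsv", sep="\t", index=False)
    results["importance"] = importance
    results["important_sets"] = important_sets

    stage("analyze")
    if annot is not None:
        sums = metabolite_sums(
            important_sets, annot, percentile=cfg.metabolite_percentile
        )
        pd.concat(
            {str(g): s for g, s in sums["per_group"].items()}, names=["group"]
        ).rename("producer_sum").to_frame().to_csv(out / "metabolite_sums.tsv", sep="\t")
        union_selected = set.union(*important_sets.values()) if important_sets else set()
        all_taxa = set(cm.taxa_ids)
        if union_selected and (all_taxa - union_selected):
            diff = differential_metabolites(
                union_selected, all_taxa - union_selected, annot
            )
            diff.to_csv(out / "differential_metabolites.tsv", sep="\t", index=False)
            results["differential_metabolites"] = diff
        results["metabolite_sums"] = sums
    if traits is not None and len(important_sets) >= 2:
        common, unique = common_unique_partition(important_sets)
        sets = {"common": common} | {f"unique_{g}": s for g, s in unique.items()}
        report = trait_summary(sets, traits)
        report.to_csv(out / "trait_summary.tsv", sep="\t")
        results["trait_summary"] = report

    manifest["metrics"] = metrics_out
    manifest["pixel_map"] = {
        "collisions": pmap.n_collisions,
        "max_taxa_per_pixel": pmap.max_taxa_per_pixel,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    results["metrics"] = metrics_out
    results["model"] = fitted
    return results


def load_model_bundle(out_dir):
    """Rebuild a trained model + pixel map from a pipeline output directory.

    Returns (FittedModel, PixelMap); the stored normalization constant and
    input view are restored, so held-out data evaluates exactly as at
    training time.
    """
    from .imaging import PixelMap
    from .nn.training import FittedModel

    out = Path(out_dir)
    with open(out / "model_manifest.json") as fh:
        manifest = json.load(fh)
    with np.load(out / "model.npz") as archive:
        state = {k.replace("__", "."): archive[k] for k in archive.files}
    height, width = manifest["input_shape"]
    model = build_model(
        [BlockSpec(*b) for b in manifest["blocks"]],
        n_classes=len(manifest["classes"]),
        height=height,
        width=width,
    )
    model.load_state(state)
    model.is_trained = True
    fitted = FittedModel(
        network=model,
        classes=np.array(manifest["classes"]),
        history=pd.DataFrame(),
        config=TrainConfig(),
        norm_max=manifest["norm_max"],
    )
    frame = pd.read_csv(out / "pixel_map.tsv", sep="\t")
    pmap = PixelMap(
        height=height,
        width=width,
        taxa_ids=list(frame["taxon_id"].astype(str)),
        rows=frame["row"].to_numpy(),
        cols=frame["col"].to_numpy(),
        angle=0.0,
        corners=np.zeros((4, 2)),
    )
    return fitted, pmap


def _save_heatmap(values: np.ndarray, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(values, cmap="inferno", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
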