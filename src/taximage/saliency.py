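"""Grad-CAM class saliency back-projected to per-taxon importance.

The class score's gradient with respect to a residual block's feature maps
is spatially averaged into channel weights; the weighted, rectified channel
sum is upsampled to image resolution and max-normalized.  Per-class maps
average the (individually normalized) per-sample maps of every sample with
that label.  Each taxon then inherits the saliency of its pixel, so taxa
sharing a pixel necessarily tie — the shared-pixel count is reported
because it bounds the interpretability resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
from skimage.transform import resize

from .imaging import PixelMap
from .nn.training import FittedModel

logger = logging.getLogger(__name__)

__all__ = [
    "SaliencyMap",
    "TaxaImportance",
    "gradcam",
    "class_saliency",
    "occlusion_scores",
    "taxa_importance",
    "select_important",
    "common_unique_partition",
]


@dataclass
class SaliencyMap:
    values: np.ndarray  # H x W in [0, 1]
    class_label: Any
    n_samples: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("saliency map must be 2D")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-9:
            raise ValueError("saliency values must lie in [0, 1]")


@dataclass
class TaxaImportance:
    taxa_ids: list[str]
    scores: np.ndarray
    class_label: Any
    shared_pixel_counts: np.ndarray | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"taxon_id": self.taxa_ids, "score": self.scores})
        frame["class"] = self.class_label
        if self.shared_pixel_counts is not None:
            frame["shared_pixel_count"] = self.shared_pixel_counts
        return frame


def _max_normalize(values: np.ndarray) -> np.ndarray:
    peak = values.max()
    return values / peak if peak > 0 else values


def _cam(fitted: FittedModel, image: np.ndarray, class_index: int, layer: int):
    net = fitted.network
    logits = net.forward(image[None], train=False)
    dlogits = np.zeros_like(logits)
    dlogits[0, class_index] = 1.0
    net.backward(dlogits)
    activations = net.block_outputs[layer][0]  # C x h x w
    gradients = net.block_output_grads[layer][0]
    channel_weights = gradients.mean(axis=(1, 2))
    return np.maximum((channel_weights[:, None, None] * activations).sum(axis=0), 0.0)


def gradcam(
    fitted: FittedModel,
    image: np.ndarray,
    class_index: int,
    layer: int = -1,
    upsample: str = "bilinear",
) -> SaliencyMap:
    """Grad-CAM map for one sample image, upsampled to image size, max 1."""
    if not fitted.network.is_trained:
        raise ValueError("model must be trained before computing saliency")
    if not (0 <= class_index < len(fitted.classes)):
        raise ValueError(f"class_index {class_index} out of range")
    n_blocks = len(fitted.network.blocks)
    if not (-n_blocks <= layer < n_blocks):
        raise ValueError(f"layer {layer} out of range for {n_blocks} blocks")
    image = np.asarray(image, dtype=float)
    cam = _cam(fitted, image, class_index, layer)
    target = image.shape[-2:]
    if cam.shape != target:
        order = 1 if upsample == "bilinear" else 0
        cam = resize(cam, target, order=order, mode="edge", anti_aliasing=False)
    return SaliencyMap(
        values=_max_normalize(cam), class_label=fitted.classes[class_index]
    )


def class_saliency(
    fitted: FittedModel, images: np.ndarray, labels, class_value, layer: int = -1
) -> SaliencyMap:
    """Mean of per-sample Grad-CAM maps over all samples of a class.

    Per-sample maps are max-normalized before averaging, and the mean map is
    renormalized, so every sample contributes on the same scale.
    """
    labels = np.asarray(labels)
    members = np.flatnonzero(labels == class_value)
    if members.size == 0:
        raise ValueError(f"no samples with class {class_value!r}")
    class_index = int(np.flatnonzero(fitted.classes == class_value)[0])
    total = None
    for i in members:
        sal = gradcam(fitted, images[i], class_index, layer=layer)
        total = sal.values if total is None else total + sal.values
    mean_map = _max_normalize(total / members.size)
    return SaliencyMap(values=mean_map, class_label=class_value, n_samples=members.size)


def occlusion_scores(
    fitted: FittedModel, image: np.ndarray, class_index: int, batch_size: int = 128
) -> np.ndarray:
    """Drop in class probability when each pixel is zeroed (occlusion map).

    An independent, gradient-free importance signal used to sanity-check
    Grad-CAM maps.
    """
    image = np.asarray(image, dtype=float)
    h, w = image.shape[-2:]
    base = fitted.predict_proba(image[None])[0, class_index]
    occluded = np.repeat(image.reshape(1, h, w), h * w, axis=0)
    idx = np.arange(h * w)
    occluded[idx, idx // w, idx % w] = 0.0
    probs = fitted.predict_proba(occluded)[:, class_index]
    return (base - probs).reshape(h, w)


def taxa_importance(sal: SaliencyMap, pmap: PixelMap) -> TaxaImportance:
    """Back-project pixel saliency to taxa via the fixed pixel map."""
    if sal.values.shape != (pmap.height, pmap.width):
        raise ValueError(
            f"saliency {sal.values.shape} does not match pixel map "
            f"({pmap.height}, {pmap.width})"
        )
    scores = sal.values[pmap.rows, pmap.cols]
    pixel_counts = pd.Series(list(zip(pmap.rows, pmap.cols))).value_counts()
    shared = np.array(
        [pixel_counts[(r, c)] for r, c in zip(pmap.rows, pmap.cols)], dtype=int
    )
    n_ambiguous = int((shared > 1).sum())
    if n_ambiguous:
        logger.info("%d taxa share a pixel with another taxon", n_ambiguous)
    return TaxaImportance(
        taxa_ids=list(pmap.taxa_ids),
        scores=scores,
        class_label=sal.class_label,
        shared_pixel_counts=shared,
        metadata={"n_shared_pixel_taxa": n_ambiguous, "n_samples": sal.n_samples},
    )


def select_important(imp: TaxaImportance, percentile: float = 90.0):
    """Split taxa into {important, unimportant} at a percentile of the
    nonzero scores (ties kept: threshold comparison is >=)."""
    if len(imp.taxa_ids) == 0:
        raise ValueError("empty importance vector")
    if not (0 <= percentile < 100):
        raise ValueError("percentile must lie in [0, 100)")
    nonzero = imp.scores[imp.scores > 0]
    if nonzero.size == 0:
        return set(), set(imp.taxa_ids)
    threshold = np.percentile(nonzero, percentile)
    selected = {
        t
        for t, s in zip(imp.taxa_ids, imp.scores)
        if s > 0 and s >= threshold
    }
    return selected, set(imp.taxa_ids) - selected


def common_unique_partition(groups: Mapping[Any, Iterable[str]]):
    """Intersection across all groups + per-group exclusive sets."""
    sets = {g: set(v) for g, v in groups.items()}
    if len(sets) < 2:
        raise ValueError("need at least two groups")
    names = list(sets)
    common = set.intersection(*sets.values())
    unique = {
        g: sets[g] - set.union(*(sets[o] for o in names if o != g)) for g in names
    }
    return common, unique
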