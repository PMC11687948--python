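"""Fixed-layout taxa-to-image transformation.

Taxa are embedded into the plane (t-SNE or UMAP), enclosed by the
minimum-area rotated rectangle of the point cloud (rotating calipers on the
convex hull), and the rectangle is rasterized onto an H x W grid.  The
resulting taxon -> pixel assignment (PixelMap) is fixed for the whole
dataset: every sample image places the same taxon at the same pixel, with
pixel intensity equal to the summed relative abundance of its taxa.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import ConvexHull, QhullError

from .containers import DistanceMatrix, TaxaFeatureMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Embedding2D",
    "Rectangle",
    "PixelMap",
    "ImageStack",
    "embed_taxa",
    "min_area_rectangle",
    "assign_pixels",
    "render_images",
]


@dataclass
class Embedding2D:
    taxa_ids: list[str]
    coords: np.ndarray  # n_taxa x 2
    method: str
    params: dict[str, Any]
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.taxa_ids), 2):
            raise ValueError("embedding must be n_taxa x 2")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite embedding coordinates")


@dataclass
class Rectangle:
    """Minimum-area enclosing rectangle: rotation angle, corners, area."""

    angle: float  # radians in [0, pi/2)
    corners: np.ndarray  # 4 x 2, in rectangle order
    area: float


@dataclass
class PixelMap:
    """Dataset-wide taxon -> (row, col) pixel assignment."""

    height: int
    width: int
    taxa_ids: list[str]
    rows: np.ndarray
    cols: np.ndarray
    angle: float
    corners: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=int)
        self.cols = np.asarray(self.cols, dtype=int)
        n = len(self.taxa_ids)
        if self.rows.shape != (n,) or self.cols.shape != (n,):
            raise ValueError("one pixel per taxon required")
        if (
            self.rows.min(initial=0) < 0
            or self.cols.min(initial=0) < 0
            or (n and (self.rows.max() >= self.height or self.cols.max() >= self.width))
        ):
            raise ValueError("pixel indices out of bounds")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa_ids)

    def inverse_index(self) -> dict[tuple[int, int], list[str]]:
        inv: dict[tuple[int, int], list[str]] = {}
        for taxon, r, c in zip(self.taxa_ids, self.rows, self.cols):
            inv.setdefault((int(r), int(c)), []).append(taxon)
        return inv

    @property
    def n_occupied_pixels(self) -> int:
        return len(set(zip(self.rows.tolist(), self.cols.tolist())))

    @property
    def n_collisions(self) -> int:
        """Number of taxa sharing a pixel with at least one other taxon."""
        return self.n_taxa - self.n_occupied_pixels

    @property
    def max_taxa_per_pixel(self) -> int:
        return max((len(v) for v in self.inverse_index().values()), default=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"taxon_id": self.taxa_ids, "row": self.rows, "col": self.cols}
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def sidecar(self) -> dict[str, Any]:
        return {
            "height": self.height,
            "width": self.width,
            "angle": self.angle,
            "corners": np.asarray(self.corners).tolist(),
            **self.metadata,
        }

    def write_sidecar(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.sidecar(), fh, indent=2)


@dataclass
class ImageStack:
    """Per-sample single-channel rasters plus the normalization constant."""

    sample_ids: list[str]
    images: np.ndarray  # n_samples x H x W, normalized
    norm_max: float

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 3 or self.images.shape[0] != len(self.sample_ids):
            raise ValueError("images must be n_samples x H x W")

    def denormalized(self) -> np.ndarray:
        return self.images * self.norm_max


def embed_taxa(
    data: TaxaFeatureMatrix | DistanceMatrix,
    method: str = "tsne",
    perplexity: float = 30.0,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
    max_iter: int = 500,
) -> Embedding2D:
    """Embed taxa into 2D with t-SNE or UMAP (deterministic given seed).

    A DistanceMatrix input goes through the precomputed-distance pathway; a
    TaxaFeatureMatrix through the euclidean feature pathway.
    """
    if method not in ("tsne", "umap"):
        raise ValueError(f"method must be 'tsne' or 'umap', got {method!r}")
    precomputed = isinstance(data, DistanceMatrix)
    values = data.values
    n_taxa = len(data.taxa_ids)
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa to embed")

    if method == "tsne":
        if perplexity >= n_taxa:
            raise ValueError(
                f"perplexity ({perplexity}) must be smaller than the number of "
                f"taxa ({n_taxa}); lower --perplexity"
            )
        from sklearn.manifold import TSNE

        tsne = TSNE(
            n_components=2,
            perplexity=perplexity,
            metric="precomputed" if precomputed else "euclidean",
            init="random",
            random_state=seed,
            max_iter=max_iter,
        )
        coords = tsne.fit_transform(values)
        params = {"perplexity": perplexity, "max_iter": max_iter}
    else:
        import umap  # deferred: numba compilation cost at first import

        nn = min(n_neighbors, n_taxa - 1)
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=nn,
            min_dist=min_dist,
            metric="precomputed" if precomputed else "euclidean",
            random_state=seed,
        )
        coords = reducer.fit_transform(values)
        params = {"n_neighbors": nn, "min_dist": min_dist}
    params["input"] = "distance" if precomputed else data.kind
    return Embedding2D(
        taxa_ids=list(data.taxa_ids),
        coords=np.asarray(coords, dtype=float),
        method=method,
        params=params,
        seed=seed,
    )


def _rotation(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def _degenerate_rectangle(pts: np.ndarray) -> Rectangle:
    """Rectangle for collinear / duplicate / tiny point sets (zero area)."""
    center = pts.mean(axis=0)
    centered = pts - center
    if len(pts) == 1 or np.allclose(centered, 0.0):
        corners = np.repeat(pts[:1], 4, axis=0).astype(float)
        return Rectangle(angle=0.0, corners=corners, area=0.0)
    # principal direction of the (collinear) cloud
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    angle = float(np.arctan2(direction[1], direction[0])) % (np.pi / 2)
    rot = _rotation(-angle)
    q = pts @ rot.T
    lo, hi = q.min(axis=0), q.max(axis=0)
    box = np.array([[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]])
    corners = box @ _rotation(angle).T
    area = float((hi[0] - lo[0]) * (hi[1] - lo[1]))
    return Rectangle(angle=angle, corners=corners, area=area)


def min_area_rectangle(points: np.ndarray) -> Rectangle:
    """Minimum-area rectangle enclosing a 2D point set (rotating calipers).

    One rectangle edge is collinear with a convex-hull edge, so it suffices
    to test the axis-aligned bounding box at each hull-edge angle.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be n x 2")
    if len(pts) < 1:
        raise ValueError("need at least one point")
    if len(pts) < 3:
        return _degenerate_rectangle(pts)
    try:
        hull = pts[ConvexHull(pts).vertices]
    except QhullError:
        return _degenerate_rectangle(pts)

    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 1], edges[:, 0]), np.pi / 2))
    best: Rectangle | None = None
    for angle in angles:
        rot = _rotation(-angle)
        q = hull @ rot.T
        lo, hi = q.min(axis=0), q.max(axis=0)
        area = float((hi[0] - lo[0]) * (hi[1] - lo[1]))
        if best is None or area < best.area:
            box = np.array(
                [[lo[0], lo[1]], [hi[0], lo[1]], [hi[0], hi[1]], [lo[0], hi[1]]]
            )
            best = Rectangle(
                angle=float(angle), corners=box @ _rotation(angle).T, area=area
            )
    assert best is not None
    return best


def assign_pixels(emb: Embedding2D, height: int = 32, width: int = 32) -> PixelMap:
    """Rasterize the embedding onto an H x W grid via the minimum rectangle.

    Coordinates are rotated by -angle, the rectangle is affinely mapped to
    [0, W) x [0, H), and pixels are floors of the mapped coordinates with the
    top/right edge clamped into the last bin (half-open bins except the last).
    """
    if height < 2 or width < 2:
        raise ValueError("image size must be at least 2 x 2")
    rect = min_area_rectangle(emb.coords)
    rot = _rotation(-rect.angle)
    q = emb.coords @ rot.T
    lo, hi = q.min(axis=0), q.max(axis=0)
    span = hi - lo
    # degenerate axes: pad to a sliver of the longer axis so the map is defined
    pad = max(span.max(), 1.0) * 1e-6
    span = np.where(span <= 0, pad, span)

    cols = np.floor((q[:, 0] - lo[0]) / span[0] * width).astype(int)
    rows = np.floor((q[:, 1] - lo[1]) / span[1] * height).astype(int)
    cols = np.clip(cols, 0, width - 1)
    rows = np.clip(rows, 0, height - 1)

    pmap = PixelMap(
        height=height,
        width=width,
        taxa_ids=list(emb.taxa_ids),
        rows=rows,
        cols=cols,
        angle=rect.angle,
        corners=rect.corners,
        metadata={
            "embedding_method": emb.method,
            "embedding_params": emb.params,
            "seed": emb.seed,
        },
    )
    logger.info(
        "pixel map %dx%d: %d taxa on %d pixels (%d collisions, max %d per pixel)",
        height,
        width,
        pmap.n_taxa,
        pmap.n_occupied_pixels,
        pmap.n_collisions,
        pmap.max_taxa_per_pixel,
    )
    return pmap


def render_images(
    abund: pd.DataFrame,
    pmap: PixelMap,
    norm_max: float | None = None,
) -> ImageStack:
    """Render each sample column as an image over the fixed pixel layout.

    Pixel value = sum of the relative abundances of the taxa mapped there
    (compositional mass is conserved before normalization).  The stack is
    divided by the global maximum pixel value; pass ``norm_max`` to reuse a
    training-set constant on held-out data.
    """
    taxa = list(abund.index.astype(str))
    known = set(pmap.taxa_ids)
    missing = [t for t in taxa if t not in known]
    if missing:
        raise ValueError(
            f"{len(missing)} taxa absent from the pixel map, e.g. {missing[:5]}"
        )
    values = abund.to_numpy(dtype=float)
    col_sums = values.sum(axis=0)
    if not np.allclose(col_sums[col_sums > 0], 1.0, atol=1e-6):
        raise ValueError(
            "abundance columns must be relative (sum to 1); normalize counts first"
        )

    index = {t: k for k, t in enumerate(pmap.taxa_ids)}
    order = np.array([index[t] for t in taxa])
    pix = pmap.rows[order] * pmap.width + pmap.cols[order]
    scatter = sparse.csr_matrix(
        (np.ones(len(taxa)), (pix, np.arange(len(taxa)))),
        shape=(pmap.height * pmap.width, len(taxa)),
    )
    flat = scatter @ values  # (H*W) x n_samples
    raw = flat.T.reshape(values.shape[1], pmap.height, pmap.width)
    if norm_max is None:
        norm_max = float(raw.max())
    if norm_max <= 0:
        norm_max = 1.0
    return ImageStack(
        sample_ids=list(abund.columns.astype(str)),
        images=raw / norm_max,
        norm_max=float(norm_max),
    )
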