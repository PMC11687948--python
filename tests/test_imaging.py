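"""Embedding, minimum-area rectangle, pixel assignment, and rendering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import taximage as tx
from taximage.imaging import min_area_rectangle


def rotation_grid_area(points, step_deg=0.01):
    """Brute-force oracle: min axis-aligned bbox area over rotations 0-90."""
    angles = np.deg2rad(np.arange(0.0, 90.0, step_deg))
    cos, sin = np.cos(angles), np.sin(angles)
    x, y = points[:, 0], points[:, 1]
    xr = np.outer(cos, x) + np.outer(sin, y)
    yr = -np.outer(sin, x) + np.outer(cos, y)
    return float(
        np.min((xr.max(1) - xr.min(1)) * (yr.max(1) - yr.min(1)))
    )


class TestMinAreaRectangle:
    def test_unit_square(self):
        rect = min_area_rectangle(
            np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        )
        assert rect.area == pytest.approx(1.0, abs=1e-9)
        assert np.rad2deg(rect.angle) % 90 == pytest.approx(0.0, abs=1e-6)

    def test_rotated_square_area_invariance(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        theta = np.deg2rad(45)
        rot = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        rect = min_area_rectangle(square @ rot.T)
        assert rect.area == pytest.approx(1.0, abs=1e-9)
        assert np.rad2deg(rect.angle) % 90 == pytest.approx(45.0, abs=1e-6)

    def test_rotation_grid_oracle(self):
        rng = np.random.default_rng(5)
        points = rng.normal(size=(200, 2)) @ np.array([[2.0, 0.7], [0.0, 1.0]])
        rect = min_area_rectangle(points)
        oracle = rotation_grid_area(points)
        assert rect.area == pytest.approx(oracle, rel=1e-3)

    def test_all_points_inside(self):
        rng = np.random.default_rng(9)
        points = rng.random((60, 2)) * 10
        rect = min_area_rectangle(points)
        rot = np.array(
            [
                [np.cos(-rect.angle), -np.sin(-rect.angle)],
                [np.sin(-rect.angle), np.cos(-rect.angle)],
            ]
        )
        q = points @ rot.T
        corners = rect.corners @ rot.T
        lo, hi = corners.min(0), corners.max(0)
        assert (q >= lo - 1e-9).all() and (q <= hi + 1e-9).all()

    def test_never_exceeds_axis_aligned_bbox(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            points = rng.normal(size=(30, 2))
            rect = min_area_rectangle(points)
            aabb = np.prod(points.max(0) - points.min(0))
            assert rect.area <= aabb + 1e-9

    def test_degenerate_sets(self):
        single = min_area_rectangle(np.array([[3.0, 4.0]]))
        assert single.area == 0.0
        collinear = min_area_rectangle(
            np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        )
        assert collinear.area == pytest.approx(0.0, abs=1e-12)


class TestAssignPixels:
    def _emb(self, coords, seed=0):
        coords = np.asarray(coords, dtype=float)
        return tx.Embedding2D(
            taxa_ids=[f"t{i}" for i in range(len(coords))],
            coords=coords,
            method="tsne",
            params={},
            seed=seed,
        )

    def test_corners_occupy_quadrants(self):
        emb = self._emb([[0, 0], [1, 0], [0, 1], [1, 1]])
        pmap = tx.assign_pixels(emb, 2, 2)
        pixels = set(zip(pmap.rows.tolist(), pmap.cols.tolist()))
        assert pixels == {(0, 0), (0, 1), (1, 0), (1, 1)}

    def test_identical_coordinates_collide(self):
        emb = self._emb([[0, 0], [1, 1], [1, 1]])
        pmap = tx.assign_pixels(emb, 4, 4)
        assert (pmap.rows[1], pmap.cols[1]) == (pmap.rows[2], pmap.cols[2])
        assert pmap.n_collisions == 1

    def test_inverse_index_recount_oracle(self):
        rng = np.random.default_rng(4)
        emb = self._emb(rng.normal(size=(500, 2)))
        pmap = tx.assign_pixels(emb, 10, 10)
        inv = pmap.inverse_index()
        assert sum(len(v) for v in inv.values()) == 500
        recount = pd.Series(
            list(zip(pmap.rows.tolist(), pmap.cols.tolist()))
        ).value_counts()
        for pixel, taxa in inv.items():
            assert len(taxa) == recount[pixel]
        assert pmap.max_taxa_per_pixel > 1  # small grid forces sharing

    def test_monotone_decollision_with_size(self):
        rng = np.random.default_rng(6)
        emb = self._emb(rng.normal(size=(300, 2)))
        maxima = [
            tx.assign_pixels(emb, s, s).max_taxa_per_pixel for s in (8, 16, 32, 64)
        ]
        assert maxima == sorted(maxima, reverse=True)


class TestRenderImages:
    def test_mass_conservation(self, small_images):
        stack = small_images["stack"]
        sums = stack.denormalized().sum(axis=(1, 2))
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_dominant_taxon_is_image_max(self):
        emb = tx.Embedding2D(
            taxa_ids=["a", "b", "c"],
            coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
            method="tsne",
            params={},
            seed=0,
        )
        pmap = tx.assign_pixels(emb, 4, 4)
        abund = pd.DataFrame(
            {"s1": [0.9, 0.05, 0.05]}, index=["a", "b", "c"]
        )
        stack = tx.render_images(abund, pmap)
        img = stack.images[0]
        assert img[pmap.rows[0], pmap.cols[0]] == img.max()

    def test_accumulation_oracle(self):
        rng = np.random.default_rng(11)
        n_taxa, n_samples = 100, 20
        coords = rng.normal(size=(n_taxa, 2))
        emb = tx.Embedding2D(
            taxa_ids=[f"t{i}" for i in range(n_taxa)],
            coords=coords, method="tsne", params={}, seed=0,
        )
        pmap = tx.assign_pixels(emb, 8, 8)
        abund = pd.DataFrame(
            rng.dirichlet(np.ones(n_taxa), size=n_samples).T,
            index=emb.taxa_ids,
            columns=[f"s{j}" for j in range(n_samples)],
        )
        stack = tx.render_images(abund, pmap)
        raw = stack.denormalized()
        expected = np.zeros_like(raw)
        for k, taxon in enumerate(emb.taxa_ids):  # brute-force accumulation
            expected[:, pmap.rows[k], pmap.cols[k]] += abund.loc[taxon].to_numpy()
        np.testing.assert_allclose(raw, expected, atol=1e-12)

    def test_rendering_is_linear(self):
        rng = np.random.default_rng(13)
        emb = tx.Embedding2D(
            taxa_ids=["a", "b", "c", "d"],
            coords=rng.normal(size=(4, 2)), method="tsne", params={}, seed=0,
        )
        pmap = tx.assign_pixels(emb, 3, 3)
        x = rng.dirichlet(np.ones(4))
        y = rng.dirichlet(np.ones(4))
        mix = 0.3 * x + 0.7 * y
        frames = [
            pd.DataFrame({"s": v}, index=emb.taxa_ids) for v in (x, y, mix)
        ]
        rx, ry, rmix = [tx.render_images(f, pmap, norm_max=1.0) for f in frames]
        np.testing.assert_allclose(
            rmix.images[0], 0.3 * rx.images[0] + 0.7 * ry.images[0], atol=1e-12
        )

    def test_unknown_taxon_rejected(self, small_images):
        pmap = small_images["pmap"]
        abund = pd.DataFrame({"s": [1.0]}, index=["not_a_taxon"])
        with pytest.raises(ValueError, match="absent"):
            tx.render_images(abund, pmap)

    def test_test_set_reuses_training_norm(self, small_sim, small_images):
        stack = small_images["stack"]
        pmap = small_images["pmap"]
        abund = small_sim["counts"].relative_abundance()
        again = tx.render_images(abund, pmap, norm_max=stack.norm_max)
        np.testing.assert_allclose(again.images, stack.images, atol=1e-12)


class TestEmbedTaxa:
    def test_tsne_deterministic(self, small_sim):
        fm = tx.build_feature_matrix(annot=small_sim["annot"], mode="metabolic")
        a = tx.embed_taxa(fm, perplexity=10, seed=3, max_iter=260)
        b = tx.embed_taxa(fm, perplexity=10, seed=3, max_iter=260)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_perplexity_bound_error(self, small_sim):
        fm = tx.build_feature_matrix(annot=small_sim["annot"], mode="metabolic")
        with pytest.raises(ValueError, match="perplexity"):
            tx.embed_taxa(fm, perplexity=len(fm.taxa_ids))

    def test_identical_rows_colocate(self):
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(1)
        base = rng.random((30, 6)) * 10
        base[3] = base[4] = base[5]  # three identical taxa
        fm = tx.TaxaFeatureMatrix(
            taxa_ids=[f"t{i}" for i in range(30)], values=base
        )
        emb = tx.embed_taxa(fm, perplexity=8, seed=0, max_iter=1000)
        typical = np.median(pdist(emb.coords))
        twin_dist = max(
            np.linalg.norm(emb.coords[3] - emb.coords[4]),
            np.linalg.norm(emb.coords[3] - emb.coords[5]),
        )
        assert twin_dist < 0.5 * typical

    def test_cluster_structure_preserved(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(7)
        a = rng.normal(0, 0.5, size=(15, 8))
        b = rng.normal(10, 0.5, size=(15, 8))
        fm = tx.TaxaFeatureMatrix(
            taxa_ids=[f"t{i}" for i in range(30)], values=np.vstack([a, b])
        )
        emb = tx.embed_taxa(fm, perplexity=8, seed=2, max_iter=400)
        labels = np.array([0] * 15 + [1] * 15)
        assert silhouette_score(emb.coords, labels) > 0.5

    def test_distance_input_pathway(self, small_sim):
        abund = small_sim["counts"].relative_abundance()
        d = tx.correlation_distance(abund)
        emb = tx.embed_taxa(d, perplexity=10, seed=1, max_iter=260)
        assert emb.params["input"] == "distance"
        assert emb.coords.shape == (len(d.taxa_ids), 2)


@settings(max_examples=20, deadline=None)
@given(
    n=st.integers(min_value=3, max_value=40),
    h=st.integers(min_value=2, max_value=12),
    w=st.integers(min_value=2, max_value=12),
    seed=st.integers(min_value=0, max_value=1000),
)
def test_pixel_assignment_total_function(n, h, w, seed):
    """Every taxon maps to exactly one in-bounds pixel for any cloud/grid."""
    rng = np.random.default_rng(seed)
    emb = tx.Embedding2D(
        taxa_ids=[f"t{i}" for i in range(n)],
        coords=rng.normal(size=(n, 2)),
        method="tsne",
        params={},
        seed=0,
    )
    pmap = tx.assign_pixels(emb, h, w)
    assert len(pmap.rows) == n
    assert (pmap.rows >= 0).all() and (pmap.rows < h).all()
    assert (pmap.cols >= 0).all() and (pmap.cols < w).all()
    inv = pmap.inverse_index()
    assert sorted(t for taxa in inv.values() for t in taxa) == sorted(emb.taxa_ids)
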