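"""Grad-CAM, class averaging, back-projection, selection, set algebra."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import taximage as tx
from taximage.nn import TrainConfig
from taximage.saliency import SaliencyMap


class TestGradcam:
    def test_range_and_dims(self, small_fitted, small_images):
        sal = tx.gradcam(small_fitted, small_images["stack"].images[0], 0)
        assert sal.values.shape == small_images["stack"].images[0].shape
        assert sal.values.min() >= 0 and sal.values.max() <= 1

    def test_zeroed_head_gives_zero_map(self, small_images):
        model = tx.build_model([(4, 3, 1)], 2, 12, 12, seed=0)
        fitted = tx.train(
            model,
            small_images["stack"].images,
            small_images["labels"],
            TrainConfig(epochs=2, patience=2, seed=0),
        )
        model.head.weight.value[...] = 0.0  # class score ignores features
        sal = tx.gradcam(fitted, small_images["stack"].images[0], 0)
        assert np.all(sal.values == 0)

    def test_untrained_model_rejected(self, small_images):
        model = tx.build_model([(4, 3, 1)], 2, 12, 12, seed=0)
        fitted = tx.FittedModel(
            network=model, classes=np.array(["a", "b"]),
            history=pd.DataFrame(), config=TrainConfig(),
        )
        with pytest.raises(ValueError, match="trained"):
            tx.gradcam(fitted, small_images["stack"].images[0], 0)

    def test_localizes_quadrant_signal_and_agrees_with_occlusion(self):
        """Signal lives in one quadrant -> saliency and occlusion find it."""
        rng = np.random.default_rng(0)
        n = 60
        imgs = rng.random((2 * n, 16, 16)) * 0.2
        labels = np.array(["neg"] * n + ["pos"] * n)
        imgs[n:, 2:6, 2:6] += 0.6
        model = tx.build_model([(8, 3, 1), (16, 3, 2)], 2, 16, 16, seed=0)
        fitted = tx.train(
            model, imgs, labels,
            TrainConfig(epochs=15, patience=15, seed=0, input_transform="none"),
        )
        pos_index = int(np.flatnonzero(fitted.classes == "pos")[0])
        sal = tx.class_saliency(fitted, imgs, labels, "pos")
        inside = sal.values[2:6, 2:6].mean()
        outside = (sal.values.sum() - sal.values[2:6, 2:6].sum()) / (256 - 16)
        assert inside > outside
        rhos = [
            spearmanr(
                tx.occlusion_scores(fitted, imgs[n + i], pos_index).ravel(),
                tx.gradcam(fitted, imgs[n + i], pos_index).values.ravel(),
            ).statistic
            for i in range(10)
        ]
        assert np.mean(rhos) > 0


class TestClassSaliency:
    def test_single_sample_equals_own_map(self, small_fitted, small_images):
        images = small_images["stack"].images
        labels = np.array(["only"] + ["other"] * (len(images) - 1))
        # restrict to the class the model knows: use class 0's own label
        labels = small_images["labels"].copy()
        target = labels[0]
        keep = np.concatenate([[0], np.flatnonzero(labels != target)])
        sal_single = tx.class_saliency(
            small_fitted, images[keep], labels[keep], target
        )
        idx = int(np.flatnonzero(small_fitted.classes == target)[0])
        direct = tx.gradcam(small_fitted, images[0], idx)
        np.testing.assert_allclose(sal_single.values, direct.values, atol=1e-12)

    def test_duplication_idempotent(self, small_fitted, small_images):
        images = small_images["stack"].images
        labels = small_images["labels"]
        once = tx.class_saliency(small_fitted, images, labels, labels[0])
        doubled = tx.class_saliency(
            small_fitted,
            np.concatenate([images, images]),
            np.concatenate([labels, labels]),
            labels[0],
        )
        np.testing.assert_allclose(once.values, doubled.values, atol=1e-10)

    def test_matches_loop_average_oracle(self, small_fitted, small_images):
        images = small_images["stack"].images[:10]
        labels = small_images["labels"][:10]
        target = labels[0]
        sal = tx.class_saliency(small_fitted, images, labels, target)
        idx = int(np.flatnonzero(small_fitted.classes == target)[0])
        members = np.flatnonzero(labels == target)
        acc = np.zeros_like(sal.values)
        for i in members:
            acc += tx.gradcam(small_fitted, images[i], idx).values
        acc /= len(members)
        peak = acc.max()
        if peak > 0:
            acc /= peak
        np.testing.assert_allclose(sal.values, acc, atol=1e-6)

    def test_missing_class_rejected(self, small_fitted, small_images):
        with pytest.raises(ValueError, match="no samples"):
            tx.class_saliency(
                small_fitted,
                small_images["stack"].images,
                small_images["labels"],
                "never_seen",
            )


class TestTaxaImportance:
    def test_uniform_saliency_scores_equal(self, small_images):
        pmap = small_images["pmap"]
        sal = SaliencyMap(np.ones((pmap.height, pmap.width)), "case")
        imp = tx.taxa_importance(sal, pmap)
        assert (imp.scores == 1.0).all()

    def test_single_hot_pixel(self, small_images):
        pmap = small_images["pmap"]
        values = np.zeros((pmap.height, pmap.width))
        r, c = int(pmap.rows[0]), int(pmap.cols[0])
        values[r, c] = 1.0
        imp = tx.taxa_importance(SaliencyMap(values, "case"), pmap)
        hot = {
            t for t, s in zip(imp.taxa_ids, imp.scores) if s == 1.0
        }
        assert hot == set(pmap.inverse_index()[(r, c)])
        assert all(
            s == 0 for t, s in zip(imp.taxa_ids, imp.scores) if t not in hot
        )

    def test_serialized_lookup_oracle(self, small_images, tmp_path):
        """Scores equal a brute-force lookup through the PixelMap TSV."""
        rng = np.random.default_rng(3)
        pmap = small_images["pmap"]
        values = rng.random((pmap.height, pmap.width))
        values /= values.max()
        imp = tx.taxa_importance(SaliencyMap(values, "case"), pmap)
        path = tmp_path / "pmap.tsv"
        pmap.to_tsv(path)
        table = pd.read_csv(path, sep="\t").set_index("taxon_id")
        for taxon, score in zip(imp.taxa_ids, imp.scores):
            row = table.loc[taxon]
            assert score == values[int(row["row"]), int(row["col"])]

    def test_shared_pixel_taxa_tie(self, small_images):
        rng = np.random.default_rng(4)
        pmap = small_images["pmap"]
        values = rng.random((pmap.height, pmap.width))
        imp = tx.taxa_importance(SaliencyMap(values / values.max(), "x"), pmap)
        scores = dict(zip(imp.taxa_ids, imp.scores))
        for taxa in pmap.inverse_index().values():
            assert len({scores[t] for t in taxa}) == 1

    def test_dim_mismatch_rejected(self, small_images):
        with pytest.raises(ValueError, match="match"):
            tx.taxa_importance(
                SaliencyMap(np.zeros((3, 3)), "x"), small_images["pmap"]
            )


class TestSelectImportant:
    def _imp(self, scores):
        scores = np.asarray(scores, dtype=float)
        return tx.TaxaImportance(
            taxa_ids=[f"t{i}" for i in range(len(scores))],
            scores=scores,
            class_label="case",
        )

    def test_percentile_zero_selects_all_nonzero(self):
        sel, rest = tx.select_important(self._imp([0.0, 0.1, 0.5, 0.9]), 0)
        assert sel == {"t1", "t2", "t3"}
        assert rest == {"t0"}

    def test_all_equal_scores_all_selected(self):
        sel, rest = tx.select_important(self._imp([0.4, 0.4, 0.4]), 90)
        assert sel == {"t0", "t1", "t2"} and rest == set()

    def test_sort_and_cut_oracle(self):
        rng = np.random.default_rng(5)
        scores = rng.random(100)
        sel, rest = tx.select_important(self._imp(scores), 90)
        threshold = np.percentile(scores[scores > 0], 90)
        expected = {f"t{i}" for i in range(100) if scores[i] >= threshold}
        assert sel == expected
        assert sel | rest == {f"t{i}" for i in range(100)}
        assert sel & rest == set()


class TestCommonUniquePartition:
    def test_identical_sets(self):
        common, unique = tx.common_unique_partition(
            {"a": {"x", "y"}, "b": {"x", "y"}}
        )
        assert common == {"x", "y"}
        assert unique == {"a": set(), "b": set()}

    def test_disjoint_sets(self):
        common, unique = tx.common_unique_partition({"a": {"x"}, "b": {"y"}})
        assert common == set()
        assert unique == {"a": {"x"}, "b": {"y"}}

    def test_random_sets_match_set_algebra(self):
        rng = np.random.default_rng(6)
        universe = [f"t{i}" for i in range(200)]
        groups = {
            g: set(rng.choice(universe, size=40, replace=False)) for g in "abcd"
        }
        common, unique = tx.common_unique_partition(groups)
        assert common == groups["a"] & groups["b"] & groups["c"] & groups["d"]
        for g in groups:
            others = set().union(*(groups[o] for o in groups if o != g))
            assert unique[g] == groups[g] - others

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            tx.common_unique_partition({"only": {"x"}})
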