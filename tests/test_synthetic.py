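"""Synthetic tile/slide generators and the simulated MRI arm."""

import numpy as np
import pytest

from gliomavote.embedding import embed, similarity_matrix
from gliomavote.sampling import passes_filters
from gliomavote.synthetic import (
    DEFAULT_RECIPES,
    MriSimParams,
    Region,
    SlideComposition,
    TileRecipe,
    generate_case_set,
    generate_mri_probs,
    generate_slide,
    generate_tile,
    write_case_set,
)

from .conftest import class_tiles


class TestGenerateTile:
    def test_blank_recipe_is_pure_white(self):
        tile = generate_tile(DEFAULT_RECIPES["blank"], 64, seed=0)
        assert np.all(tile == 255)

    def test_bitwise_deterministic(self):
        a = generate_tile(DEFAULT_RECIPES["A"], 128, seed=7)
        b = generate_tile(DEFAULT_RECIPES["A"], 128, seed=7)
        assert np.array_equal(a, b)
        c = generate_tile(DEFAULT_RECIPES["A"], 128, seed=8)
        assert not np.array_equal(a, c)

    def test_subtype_tiles_pass_filters_blank_and_marker_fail(self):
        # 200 seeds per the generator's contract: >= 95% acceptance for A
        accepted = sum(
            bool(passes_filters(generate_tile(DEFAULT_RECIPES["A"], 224, s))) for s in range(200)
        )
        assert accepted >= 190
        assert not passes_filters(generate_tile(DEFAULT_RECIPES["blank"], 64, 0))
        assert not passes_filters(generate_tile(DEFAULT_RECIPES["marker"], 64, 0))

    @pytest.mark.parametrize("label", ["A", "O", "G"])
    def test_filter_compatibility_of_channel_statistics(self, label):
        tiles = [generate_tile(DEFAULT_RECIPES[label], 224, s) for s in range(100)]
        for tile in tiles:
            arr = tile.astype(float)
            means = arr.mean(axis=(0, 1))
            assert np.all((means >= 50) & (means <= 150))
            assert np.all(arr.std(axis=(0, 1)) > 20)

    def test_class_separability_in_embedding_space(self, model):
        tiles, labels = [], []
        for label in ("A", "O", "G"):
            tiles += class_tiles(label, 20)
            labels += [label] * 20
        S = similarity_matrix(embed(tiles, model))
        labels = np.array(labels)
        same = labels[:, None] == labels[None, :]
        iu = np.triu_indices(len(labels), k=1)
        within = S[iu][same[iu]].mean()
        between = S[iu][~same[iu]].mean()
        assert within - between >= 0.05

    def test_invalid_recipes_and_sizes_rejected(self):
        with pytest.raises(ValueError):
            TileRecipe("X", (0, 0, 0))
        with pytest.raises(ValueError):
            TileRecipe("A", (300, 0, 0))
        with pytest.raises(ValueError):
            TileRecipe("A", (10, 10, 10), texture="stripes")
        with pytest.raises(ValueError):
            generate_tile(DEFAULT_RECIPES["A"], 16, 0)


class TestGenerateSlide:
    def test_mask_area_matches_composition(self):
        comp = SlideComposition(
            width_px=512, height_px=512,
            regions=(Region(0, 0, 512, 256, DEFAULT_RECIPES["A"]),),
        )
        slide, mask = generate_slide(comp, seed=1)
        assert slide.shape == (512, 512, 3) and mask.shape == (512, 512)
        assert (mask > 0).mean() == pytest.approx(0.5, abs=1e-6)

    def test_empty_regions_give_uniform_background(self):
        comp = SlideComposition(width_px=64, height_px=64, background=(10, 20, 30))
        slide, mask = generate_slide(comp, seed=0)
        assert np.all(slide == np.array([10, 20, 30], dtype=np.uint8))
        assert np.all(mask == 0)

    def test_deterministic_bytes(self):
        comp = SlideComposition(
            width_px=256, height_px=256,
            regions=(Region(10, 10, 200, 100, DEFAULT_RECIPES["G"]),),
        )
        a, ma = generate_slide(comp, seed=5)
        b, mb = generate_slide(comp, seed=5)
        assert a.tobytes() == b.tobytes() and ma.tobytes() == mb.tobytes()

    def test_out_of_bounds_and_overlap_rejected(self):
        r = DEFAULT_RECIPES["A"]
        with pytest.raises(ValueError):
            SlideComposition(width_px=100, height_px=100, regions=(Region(50, 50, 100, 10, r),))
        with pytest.raises(ValueError, match="overlap"):
            SlideComposition(width_px=100, height_px=100,
                             regions=(Region(0, 0, 60, 60, r), Region(40, 40, 30, 30, r)))


class TestMriSimulation:
    def test_perfect_accuracy_limit(self):
        cs = generate_case_set(30, mri=MriSimParams(accuracy=1.0), seed=0, render_slides=False)
        for case in cs.cases:
            assert max(case.mri_probs, key=case.mri_probs.get) == case.true_label

    def test_empirical_match_rate_tracks_accuracy(self):
        cs = generate_case_set(300, mri=MriSimParams(accuracy=0.7, seed=1), seed=2,
                               render_slides=False)
        rate = np.mean([max(c.mri_probs, key=c.mri_probs.get) == c.true_label for c in cs.cases])
        assert abs(rate - 0.7) <= 0.08

    def test_vectors_are_distributions(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            probs = generate_mri_probs("O", MriSimParams(accuracy=0.5, concentration=0.6), rng)
            p = np.array(list(probs.values()))
            assert np.all(p >= 0) and abs(p.sum() - 1.0) < 1e-9

    def test_degenerate_class_balance(self):
        cs = generate_case_set(3, class_balance=(1.0, 0.0, 0.0), seed=0, render_slides=False)
        assert [c.true_label for c in cs.cases] == ["A", "A", "A"]

    def test_case_k_independent_of_set_size(self):
        a = generate_case_set(3, seed=9, render_slides=False)
        b = generate_case_set(6, seed=9, render_slides=False)
        for ca, cb in zip(a.cases, b.cases[:3]):
            assert ca.true_label == cb.true_label
            assert ca.mri_probs == cb.mri_probs
            assert ca.age == cb.age

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MriSimParams(accuracy=1.5)
        with pytest.raises(ValueError):
            generate_case_set(0)
        with pytest.raises(ValueError):
            generate_case_set(3, class_balance=(0.5, 0.5, 0.5))


class TestWriteCaseSet:
    def test_layout_and_manifest_columns(self, tmp_path):
        cs = generate_case_set(2, seed=3, slide_size=128)
        paths = write_case_set(cs, tmp_path)
        import pandas as pd

        manifest = pd.read_csv(paths["manifest"])
        assert list(manifest.columns) == ["case_id", "slide_path", "true_label",
                                          "mri_prob_path", "age"]
        assert len(manifest) == 2
        mri = pd.read_csv(paths["mri_probs"])
        assert list(mri.columns) == ["case_id", "p_A", "p_O", "p_G"]
        for rel in manifest["slide_path"]:
            assert (tmp_path / rel).exists()
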