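import numpy as np
import pytest

from chisel.errors import ParameterError, StateError, ValidationError
from chisel.synthetic import degrade_patch, generate_scene, preset_spec
from chisel.tiling import (
    PatchQCModel,
    compute_tile_grid,
    extract_tile,
    qc_patch,
    sample_rois_two_circle,
    train_patch_qc,
)


def rects(grid, kinds=None):
    return {
        (t.r0, t.c0, t.r1, t.c1)
        for t in grid.tiles
        if kinds is None or t.kind in kinds
    }


class TestComputeTileGrid:
    def test_scheme_a_partitions_exactly(self):
        g = compute_tile_grid(2000, 2000, 1000, 100, "A")
        assert rects(g) == {
            (0, 0, 1000, 1000),
            (0, 1000, 1000, 2000),
            (1000, 0, 2000, 1000),
            (1000, 1000, 2000, 2000),
        }

    def test_scheme_b_adds_right_and_down_shifts_of_half_window(self):
        g = compute_tile_grid(2000, 2000, 1000, 100, "B")
        assert len(g.tiles) == 12 and g.shift == 50
        assert (0, 50, 1000, 1050) in rects(g, {"shifted-right"})
        assert (50, 0, 1050, 1000) in rects(g, {"shifted-down"})

    def test_scheme_c_single_tile_gets_four_shifts(self):
        g = compute_tile_grid(1000, 1000, 1000, 100, "C")
        assert len(g.tiles) == 5
        kinds = sorted(t.kind for t in g.tiles)
        assert kinds == sorted(
            ["base", "shifted-right", "shifted-down", "shifted-left", "shifted-up"]
        )

    def test_base_tiles_cover_every_pixel(self):
        g = compute_tile_grid(1500, 2300, 1000, 51, "A")
        cover = np.zeros((1500, 2300), dtype=int)
        for t in g.tiles:
            cover[max(t.r0, 0) : t.r1, max(t.c0, 0) : t.c1] += 1
        assert (cover >= 1).all()

    def test_interior_base_boundaries_covered_twice_under_scheme_b(self):
        g = compute_tile_grid(2000, 2000, 1000, 100, "B")
        cover = np.zeros((2000, 2000), dtype=int)
        for t in g.tiles:
            cover[max(t.r0, 0) : min(t.r1, 2000), max(t.c0, 0) : min(t.c1, 2000)] += 1
        assert (cover[:, 1000] >= 2).all() and (cover[1000, :] >= 2).all()

    def test_scheme_monotonicity(self):
        a = rects(compute_tile_grid(1700, 1700, 800, 60, "A"))
        b = rects(compute_tile_grid(1700, 1700, 800, 60, "B"))
        c = rects(compute_tile_grid(1700, 1700, 800, 60, "C"))
        assert a <= b <= c

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ParameterError):
            compute_tile_grid(100, 100, 0, 10, "A")
        with pytest.raises(ParameterError):
            compute_tile_grid(100, 100, 50, -1, "B")


class TestExtractTile:
    def test_interior_tile_is_exact_crop(self, rng):
        img = rng.integers(0, 255, (1200, 1200, 3), dtype=np.uint8)
        g = compute_tile_grid(1200, 1200, 600, 51, "A")
        t = g.tiles[0]
        assert (extract_tile(img, t) == img[t.r0 : t.r1, t.c0 : t.c1]).all()

    def test_border_tile_edge_replicated(self, rng):
        img = rng.integers(0, 255, (1500, 1500, 3), dtype=np.uint8)
        g = compute_tile_grid(1500, 1500, 1000, 51, "B")
        shifted = [t for t in g.tiles if t.c1 > 1500][0]
        patch = extract_tile(img, shifted)
        assert patch.shape == (1000, 1000, 3)
        pad_right = shifted.c1 - 1500
        # replicated columns equal the last real column
        assert (patch[:, -pad_right:] == patch[:, [-pad_right - 1]]).all()

    def test_patch_centers_identical_across_schemes(self, rng):
        img = rng.integers(0, 255, (900, 900, 3), dtype=np.uint8)
        for scheme in ("A", "B", "C"):
            g = compute_tile_grid(900, 900, 600, 51, scheme)
            base = [t for t in g.tiles if t.kind == "base"][0]
            assert (extract_tile(img, base) == img[:600, :600]).all()


class TestTwoCircleSampler:
    def test_corners_lie_on_the_circles(self):
        tiles = sample_rois_two_circle((3000.0, 2500.0), 1000, 50, seed=4)
        for t in tiles:
            d = np.hypot(t.c0 - 3000.0, t.r0 - 2500.0)
            assert min(abs(d - 500), abs(d - 2000)) < 1.0

    def test_zero_samples_empty(self):
        assert sample_rois_two_circle((0, 0), 1000, 0, seed=1) == []

    def test_seed_reproducibility(self):
        a = sample_rois_two_circle((100, 100), 500, 20, seed=9)
        b = sample_rois_two_circle((100, 100), 500, 20, seed=9)
        assert a == b


def _qc_training_set(n_per_class=40):
    patches, labels = [], []
    for s in range(n_per_class):
        sc = generate_scene(
            preset_spec(
                "wbcd", height=160, width=160, n_nuclei=6, cluster_fraction=0.0,
                seed=5000 + s,
            )
        )
        patches.append(sc.image)
        labels.append("keep")
        mode = "blank" if s % 2 == 0 else "blur"
        patches.append(degrade_patch(sc.image, mode, 0.01 if mode == "blank" else 8.0, seed=s))
        labels.append("skip")
    return patches, labels


class TestPatchQC:
    @pytest.fixture(scope="class")
    def qc_model(self):
        patches, labels = _qc_training_set()
        return train_patch_qc(patches, labels, seed=2), patches, labels

    def test_holdout_accuracy_high_on_separable_patches(self, qc_model):
        model, _, _ = qc_model
        assert model.holdout_accuracy >= 0.9

    def test_blank_patch_skipped_nuclei_patch_kept(self, qc_model):
        model, patches, labels = qc_model
        sc = generate_scene(
            preset_spec("wbcd", height=160, width=160, n_nuclei=6, seed=7777,
                        cluster_fraction=0.0)
        )
        assert qc_patch(sc.image, model) == "keep"
        assert qc_patch(degrade_patch(sc.image, "blank", 0.01), model) == "skip"
        assert qc_patch(degrade_patch(sc.image, "blur", 8.0), model) == "skip"

    def test_training_reproducible(self):
        patches, labels = _qc_training_set(10)
        m1 = train_patch_qc(patches, labels, seed=3)
        m2 = train_patch_qc(patches, labels, seed=3)
        assert (m1.mlp.W1 == m2.mlp.W1).all() and (m1.mlp.W2 == m2.mlp.W2).all()

    def test_empty_or_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_patch_qc([], [], seed=0)
        patches, _ = _qc_training_set(3)
        with pytest.raises(ValidationError):
            train_patch_qc(patches, ["keep"] * len(patches), seed=0)

    def test_untrained_model_raises_state_error(self):
        with pytest.raises(StateError):
            qc_patch(np.zeros((10, 10, 3), np.uint8), PatchQCModel())

    def test_json_roundtrip(self, qc_model, tmp_path):
        model, patches, _ = qc_model
        p = tmp_path / "qc.json"
        model.to_json(p)
        back = PatchQCModel.from_json(p)
        assert qc_patch(patches[0], back) == qc_patch(patches[0], model)
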