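"""Bipolarization, pattern learning, subsetting, and zoom merge/unmerge."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spirecon as sr
from spirecon.patterns import (augmentation_capacity, matrix_loss,
                               merge_patterns, unmerge_patterns)


class TestBipolarize:
    def test_sign_map_example(self):
        op = sr.bipolarize(np.array([[0.3, -0.2, 0.0, -5.0]]), 2, 2)
        # zero counts as non-negative -> +1; scale 1/sqrt(4)
        assert op.values.tolist() == [[0.5, -0.5, 0.5, -0.5]]

    def test_all_zero_parent_maps_to_plus(self):
        op = sr.bipolarize(np.zeros((3, 9)), 3, 3)
        assert np.all(op.values == 1.0 / 3.0)

    def test_entries_match_per_entry_sign_oracle(self, rng):
        parent = rng.standard_normal((3, 9))
        op = sr.bipolarize(parent, 3, 3)
        for i in range(3):
            for j in range(9):
                expected = (1.0 if parent[i, j] >= 0 else -1.0) / 3.0
                assert op.values[i, j] == expected

    def test_nonfinite_rejected_with_location(self):
        parent = np.zeros((2, 4))
        parent[1, 2] = np.nan
        with pytest.raises(ValueError, match="row 1, col 2"):
            sr.bipolarize(parent, 2, 2)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 8), st.integers(2, 4))
    def test_bipolar_range_exact(self, seed, m, side):
        op = sr.random_operator(min(m, side * side), side, side, seed=seed)
        s = 1.0 / math.sqrt(side * side)
        assert np.all((op.values == s) | (op.values == -s))


class TestHadamard:
    def test_orthonormal_and_zero_matrix_loss(self, rng):
        op = sr.hadamard_operator(4)
        gram = op.values.T @ op.values
        assert np.allclose(gram, np.eye(16), atol=1e-14)
        x = rng.random((5, 16))
        assert matrix_loss(op.values, x) < 1e-28

    def test_row_reshape_roundtrip(self):
        op = sr.hadamard_operator(4, n_rows=6)
        assert op.patterns().shape == (6, 4, 4)
        assert np.array_equal(op.patterns().reshape(6, 16), op.values)


class TestLearnPatterns:
    def test_learning_beats_random_init_on_held_out(self):
        scenes = [sr.gen_scene(sr.default_spec("nucleus", 4, seed=s)) for s in range(51)]
        train, held_out = scenes[:50], scenes[50]
        # 500 steps is a tiny budget: use a step size sized for it
        op, log = sr.learn_patterns(train, 8, 500, seed=11, lr=0.01)
        baseline = sr.random_operator(8, 4, 4, seed=11)
        x = held_out.intensities / held_out.intensities.max()
        assert matrix_loss(op.values, x.reshape(1, -1)) < matrix_loss(
            baseline.values, x.reshape(1, -1))
        assert log["final_loss"] <= log["initial_loss"]

    def test_training_loss_non_increasing_at_checkpoints(self):
        scenes = [sr.gen_scene(sr.default_spec("nucleus", 4, seed=s)) for s in range(30)]
        _, log = sr.learn_patterns(scenes, 6, 300, seed=4, log_every=100)
        # the returned operator is the best checkpoint, never above the start
        assert log["final_loss"] == min(log["losses"])

    def test_square_hadamard_init_is_already_optimal(self, rng):
        # with A orthonormal the objective is identically zero
        op = sr.hadamard_operator(2)
        assert matrix_loss(op.values, rng.random((3, 4))) < 1e-28

    def test_deterministic_per_seed(self):
        scenes = [sr.gen_scene(sr.default_spec("nucleus", 4, seed=s)) for s in range(10)]
        op1, _ = sr.learn_patterns(scenes, 4, 50, seed=5)
        op2, _ = sr.learn_patterns(scenes, 4, 50, seed=5)
        assert np.array_equal(op1.values, op2.values)

    @pytest.mark.parametrize("bad", ["empty", "m_too_big", "mismatched"])
    def test_validation_errors(self, bad, rng):
        scenes = [sr.ImageScene(rng.random((4, 4)))]
        if bad == "empty":
            with pytest.raises(ValueError):
                sr.learn_patterns([], 2, 10, seed=0)
        elif bad == "m_too_big":
            with pytest.raises(ValueError):
                sr.learn_patterns(scenes, 17, 10, seed=0)
        else:
            scenes.append(sr.ImageScene(rng.random((3, 3))))
            with pytest.raises(ValueError):
                sr.learn_patterns(scenes, 2, 10, seed=0)


class TestSelectSubset:
    def test_full_subset_is_identity(self, small_op, small_scene):
        rec = sr.measure(small_op, small_scene)
        sub_op, sub_rec = sr.select_subset(small_op, rec, small_op.n_rows, seed=0)
        assert np.array_equal(sub_op.values, small_op.values)
        assert np.array_equal(sub_rec.values, rec.values)

    @pytest.mark.parametrize("m", [1, 3, 7, 11])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noiseless_subset_consistency(self, small_op, small_scene, m, seed):
        rec = sr.measure(small_op, small_scene)
        sub_op, sub_rec = sr.select_subset(small_op, rec, m, seed=seed)
        # the mechanism is exact element selection ...
        rows = sub_rec.meta["source_rows"]
        assert np.array_equal(sub_rec.values, rec.values[rows])
        # ... and the selected elements satisfy the linear model
        assert np.allclose(sub_op.values @ small_scene.flatten(), sub_rec.values,
                           atol=1e-13)

    def test_row_order_preserved(self, small_op, small_scene):
        rec = sr.measure(small_op, small_scene)
        sub_op, sub_rec = sr.select_subset(small_op, rec, 5, seed=3)
        rows = sub_rec.meta["source_rows"]
        assert rows == sorted(rows)

    def test_subset_counts_cover_all_nonempty_sets(self):
        # the augmentation can in principle reach every nonempty row subset
        n_subsets = sum(
            1 for m in range(1, 6) for _ in itertools.combinations(range(5), m)
        )
        assert n_subsets == augmentation_capacity(5) == 31

    def test_invalid_m_rejected(self, small_op, small_scene):
        rec = sr.measure(small_op, small_scene)
        for m in (0, small_op.n_rows + 1):
            with pytest.raises(ValueError):
                sr.select_subset(small_op, rec, m, seed=0)


class TestZoom:
    def test_merge_shrinks_grid_128_to_32(self):
        op = sr.random_operator(3, 128, 128, seed=0)
        merged = merge_patterns(op, sr.ZoomSpec(4, 128))
        assert (merged.height, merged.width) == (32, 32)
        assert merged.provenance == "merged"
        assert merged.is_bipolar

    def test_merge_z1_keeps_signs_and_scale(self, small_op):
        merged = merge_patterns(small_op, sr.ZoomSpec(1, 4))
        assert np.array_equal(merged.values, small_op.values)

    def test_merge_matches_hand_computed_block_means(self):
        # one 4x4 pattern; 2x2 pooling -> signs of the block means
        signs = np.array([
            [+1, +1, -1, -1],
            [+1, -1, -1, -1],
            [-1, +1, +1, -1],
            [+1, +1, -1, +1],
        ], dtype=float)
        op = sr.bipolarize(signs.reshape(1, 16), 4, 4)
        merged = merge_patterns(op, sr.ZoomSpec(2, 4))
        # block means: [[+0.5, -1], [+0.5, 0]] -> signs [[+, -], [+, +]]
        expected = np.array([[1, -1], [1, 1]], dtype=float) / 2.0
        assert np.array_equal(merged.patterns()[0], expected)

    def test_zoom_spec_rejects_nondivisible(self):
        with pytest.raises(ValueError):
            sr.ZoomSpec(4, 30)

    def test_unmerge_upscales_block_constant(self):
        op = sr.random_operator(2, 8, 8, seed=1)
        zoom = sr.ZoomSpec(4, 32)
        up = unmerge_patterns(op, zoom)
        pats = up.patterns()
        assert pats.shape == (2, 32, 32)
        blocks = pats.reshape(2, 8, 4, 8, 4)
        assert np.all(blocks == blocks[:, :, :1, :, :1])  # every 4x4 block constant

    def test_merge_then_unmerge_recovers_block_constant_signs(self):
        base = sr.random_operator(3, 4, 4, seed=2)
        zoom = sr.ZoomSpec(2, 8)
        big = unmerge_patterns(base, zoom)          # block-constant on 8x8
        roundtrip = unmerge_patterns(merge_patterns(big, zoom), zoom)
        assert np.array_equal(np.sign(roundtrip.values), np.sign(big.values))

    def test_cross_grid_inner_product_identity(self, rng):
        # <unmerged row, x> = <merged row, block-sum(x)> / z  on random images
        base = sr.random_operator(5, 4, 4, seed=3)
        zoom = sr.ZoomSpec(2, 8)
        up = unmerge_patterns(base, zoom)
        x = rng.random((8, 8))
        block_sum = x.reshape(4, 2, 4, 2).sum(axis=(1, 3))
        lhs = up.values @ x.reshape(-1)
        rhs = (base.values @ block_sum.reshape(-1)) / zoom.factor
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestPersistence:
    def test_save_load_roundtrip(self, small_op, tmp_path):
        path = tmp_path / "op.npz"
        small_op.save(path)
        loaded = sr.SamplingOperator.load(path)
        assert np.array_equal(loaded.values, small_op.values)
        assert loaded.provenance == small_op.provenance
        assert (loaded.height, loaded.width) == (4, 4)

    def test_png_export(self, small_op, tmp_path):
        files = small_op.export_pattern_images(tmp_path, limit=2)
        assert len(files) == 2 and all(f.exists() for f in files)
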