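"""Segmentation model structure, training schedule and post-processing."""

import numpy as np
import pytest
from scipy import ndimage

from gramnet.endenet import (
    PlateauScheduler,
    SegModelConfig,
    SegTrainConfig,
    binarize,
    build_endenet,
    clear_fragments,
    load_seg_model,
    predict_probabilities,
    save_seg_model,
    scaled_min_area,
    train_segmentation,
    union_ensemble,
)


class TestArchitecture:
    def test_default_decoder_has_five_blocks(self):
        model = build_endenet(SegModelConfig())
        assert model.decoder_block_count == 5

    def test_first_decoder_block_outputs_256_channels(self):
        model = build_endenet(SegModelConfig())
        # last conv of the first decoder block
        convs = [l for l in model.dec_blocks[0].layers
                 if hasattr(l, "out_channels")]
        assert convs[-1].out_channels == 256

    def test_forward_shape_and_range_two_channel(self, rng):
        model = build_endenet(SegModelConfig(in_channels=2))
        x = rng.random((1, 2, 128, 128)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (1, 128, 128)
        assert np.all((p > 0) & (p < 1))

    def test_indivisible_input_rejected(self, rng):
        model = build_endenet(SegModelConfig())
        with pytest.raises(ValueError, match="divisible"):
            model.forward(rng.random((1, 1, 100, 100)).astype(np.float32))

    def test_efficientnet_style_encoder_builds(self, rng):
        cfg = SegModelConfig(encoder="effnet-b3-style", encoder_depth=3,
                             decoder_channels=(32, 16, 8))
        p = build_endenet(cfg).forward(rng.random((1, 1, 32, 32)).astype(np.float32))
        assert p.shape == (1, 32, 32)

    def test_bad_configs_rejected(self):
        with pytest.raises(ValueError):
            SegModelConfig(decoder_channels=(64, 32))
        with pytest.raises(ValueError):
            SegModelConfig(decoder_channels=(16, 32, 64, 128, 256))


class TestPlateauScheduler:
    def test_constant_stream_drops_after_patience(self):
        """Five consecutive non-improving epochs cut the LR to one tenth."""
        s = PlateauScheduler(1e-3, factor=0.1, patience=5)
        lrs = [s.step(1.0) for _ in range(6)]
        assert lrs[:5] == [1e-3] * 5
        assert lrs[5] == pytest.approx(1e-4)

    def test_improving_stream_never_drops(self):
        s = PlateauScheduler(1e-3, patience=5)
        for i in range(20):
            assert s.step(1.0 - 0.01 * i) == 1e-3

    def test_exhaustion_below_min_lr(self):
        s = PlateauScheduler(1e-3, factor=0.1, patience=1, min_lr=1e-6)
        for _ in range(10):
            s.step(1.0)
            if s.exhausted:
                break
        assert s.exhausted and s.lr < 1e-6


class TestTraining:
    def test_loss_decreases_on_phantoms(self, phantom_batch64):
        _, x, masks = phantom_batch64
        cfg = SegModelConfig(encoder_depth=3, decoder_channels=(16, 8, 4))
        model = build_endenet(cfg)
        model, hist = train_segmentation(
            model, (x[:32], masks[:32]), (x[32:40], masks[32:40]),
            train_cfg=SegTrainConfig(max_epochs=3, batch_size=8), seed=0)
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert len(hist["epoch"]) == 3

    def test_same_seed_identical_histories(self, phantom_batch64):
        _, x, masks = phantom_batch64
        def run():
            cfg = SegModelConfig(encoder_depth=3, decoder_channels=(8, 4, 2))
            model = build_endenet(cfg)
            _, h = train_segmentation(
                model, (x[:16], masks[:16]), (x[16:24], masks[16:24]),
                train_cfg=SegTrainConfig(max_epochs=2, batch_size=8), seed=42)
            return h
        h1, h2 = run(), run()
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_empty_data_rejected(self):
        model = build_endenet(SegModelConfig(encoder_depth=3,
                                             decoder_channels=(8, 4, 2)))
        empty = (np.zeros((0, 32, 32, 1), np.float32), np.zeros((0, 32, 32), np.float32))
        with pytest.raises(ValueError):
            train_segmentation(model, empty, empty)

    def test_model_roundtrip(self, tmp_path, rng):
        cfg = SegModelConfig(encoder_depth=3, decoder_channels=(8, 4, 2), seed=1)
        model = build_endenet(cfg)
        x = rng.random((2, 32, 32, 1)).astype(np.float32)
        expected = predict_probabilities(model, x)
        save_seg_model(model, tmp_path)
        np.testing.assert_allclose(predict_probabilities(load_seg_model(tmp_path), x),
                                   expected, rtol=1e-6)


class TestBinarize:
    def test_all_above_threshold(self):
        assert binarize(np.full((3, 3), 0.7)).all()

    def test_exact_half_is_foreground(self):
        assert binarize(np.array([[0.5]]))[0, 0]
        assert not binarize(np.array([[0.4999]]))[0, 0]

    def test_matches_comparison_oracle(self, rng):
        p = rng.random((20, 20))
        np.testing.assert_array_equal(binarize(p), p >= 0.5)


class TestClearFragments:
    def test_small_component_removed_large_kept(self):
        mask = np.zeros((64, 64), bool)
        mask[0:2, 0:2] = True            # 4-pixel fragment
        mask[10:48, 10:50] = True        # 1520-pixel component
        out = clear_fragments(mask, min_area=1024)
        assert not out[0:2, 0:2].any()
        assert out[10:48, 10:50].all()

    def test_empty_mask(self):
        m = np.zeros((8, 8), bool)
        np.testing.assert_array_equal(clear_fragments(m), m)

    def test_exactly_min_area_retained(self):
        mask = np.zeros((40, 40), bool)
        mask[0:32, 0:32] = True  # exactly 1024 pixels
        assert clear_fragments(mask, min_area=1024).sum() == 1024

    def test_one_below_min_area_removed(self):
        mask = np.zeros((40, 40), bool)
        mask[0:32, 0:32] = True
        mask[0, 0] = False  # 1023 pixels
        assert clear_fragments(mask, min_area=1024).sum() == 0

    def test_diagonal_pixels_are_eight_connected(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = mask[3, 3] = mask[4, 4] = True
        # one 8-connected component of size 3
        assert clear_fragments(mask, min_area=3).sum() == 3
        assert clear_fragments(mask, min_area=4).sum() == 0

    def test_brute_force_component_oracle(self, rng):
        """Matches an independent scipy labelling on random masks."""
        for _ in range(100):
            mask = rng.random((24, 24)) > rng.uniform(0.55, 0.85)
            min_area = int(rng.integers(2, 12))
            labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
            expected = np.zeros_like(mask)
            for lab in range(1, n + 1):
                comp = labels == lab
                if comp.sum() >= min_area:
                    expected |= comp
            np.testing.assert_array_equal(
                clear_fragments(mask, min_area=min_area), expected)

    def test_binarize_clear_idempotent(self, rng):
        p = rng.random((32, 32))
        m1 = clear_fragments(binarize(p), min_area=8)
        m2 = clear_fragments(binarize(m1.astype(float)), min_area=8)
        np.testing.assert_array_equal(m1, m2)

    def test_scaled_min_area(self):
        assert scaled_min_area((512, 512)) == 1024
        assert scaled_min_area((128, 128)) == 64


class TestUnionEnsemble:
    def test_or_identity_idempotence_disjoint(self, rng):
        m = rng.random((6, 6)) > 0.5
        np.testing.assert_array_equal(union_ensemble([m, np.zeros((6, 6), bool)]), m)
        np.testing.assert_array_equal(union_ensemble([m, m]), m)
        a = np.zeros((4, 4), bool)
        b = np.zeros((4, 4), bool)
        a[0, 0] = b[2, 2] = True
        assert union_ensemble([a, b]).sum() == 2
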