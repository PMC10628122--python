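"""pix2pix architecture, scaling conventions, training behavior, and the
spectrally-normalized discriminator variant."""

import numpy as np
import pandas as pd
import pytest

from virtustain import nn
from virtustain.registration import warp_and_crop
from virtustain.staining import (
    DiscriminatorConfig,
    GeneratorConfig,
    LossConfig,
    Pix2PixTranslator,
    TrainConfig,
    build_discriminator,
    build_generator,
    load_checkpoint,
    rescale_output,
    save_checkpoint,
    scale_to_model_range,
    stain,
    train,
)
from virtustain.synthetic import cell_box, random_scene, render_scene


def _paired_patches(n_scenes=4, per_scene=5, size=32):
    """Brightfield/dsDNA patch pairs cropped from aligned synthetic scenes."""
    src, tgt = [], []
    for seed in range(n_scenes):
        spec = random_scene(seed, homography="identity", bg_jitter=0)
        render = render_scene(spec)
        for cell in spec.cells[:per_scene]:
            box = cell_box(cell)
            src.append(warp_and_crop(render.bfi, np.eye(3), [box], out_size=size)[0])
            tgt.append(warp_and_crop(render.dsdna, np.eye(3), [box], out_size=size)[0])
    return np.stack(src), np.stack(tgt)


class TestScaling:
    @pytest.mark.parametrize("v, expected", [(0, -1.0), (255, 1.0), (51, -0.6)])
    def test_forward_scaling(self, v, expected):
        out = scale_to_model_range(np.array([[v]], dtype=np.uint8))
        assert out[0, 0] == pytest.approx(expected)

    @pytest.mark.parametrize("v, expected", [(-1.0, 0.0), (1.0, 1.0), (0.0, 0.5)])
    def test_output_rescaling(self, v, expected):
        assert rescale_output(np.array([v]))[0] == pytest.approx(expected)

    def test_forward_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            scale_to_model_range(np.array([300.0]))

    def test_rescale_rejects_beyond_tolerance(self):
        with pytest.raises(ValueError):
            rescale_output(np.array([1.1]))
        # within tolerance: clipped, not rejected
        assert rescale_output(np.array([1.0 + 1e-8]))[0] == 1.0

    def test_roundtrip_endpoints_and_monotone(self):
        v = np.arange(0, 256, dtype=np.uint8)
        out = rescale_output(scale_to_model_range(v))
        assert out[0] == 0.0 and out[-1] == 1.0
        assert np.all(np.diff(out) > 0)


class TestGeneratorArchitecture:
    def test_depth_auto_reduction_and_shape(self):
        gen = build_generator(image_size=64, seed=0)
        assert len(gen.enc) == 5  # 64 px supports five stride-2 encoders
        x = np.zeros((1, 1, 64, 64), dtype=nn.DTYPE)
        assert gen.forward(x, train=False).shape == (1, 1, 64, 64)

    def test_bottleneck_reaches_one_by_one(self):
        gen = build_generator(image_size=32, seed=0)
        x = np.zeros((2, 1, 32, 32), dtype=nn.DTYPE)
        h = x
        for blk in gen.enc:
            h = blk.forward(h, train=False)
        h = gen.bottleneck.forward(h, train=False)
        assert h.shape[2:] == (1, 1)

    def test_output_bounded_by_tanh(self, rng):
        gen = build_generator(image_size=32, seed=1)
        x = rng.standard_normal((2, 1, 32, 32)).astype(nn.DTYPE)
        out = gen.forward(x, train=False)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_invalid_size_names_minimum(self):
        with pytest.raises(ValueError, match="16"):
            build_generator(image_size=48)

    def test_seeded_build_is_reproducible(self):
        g1 = build_generator(image_size=32, seed=5)
        g2 = build_generator(image_size=32, seed=5)
        for p1, p2 in zip(g1.params(), g2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_mismatched_depths_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            GeneratorConfig(encoder_filters=(64, 128), decoder_filters=(64,))


class TestDiscriminator:
    def test_scores_strictly_in_unit_interval(self, rng):
        disc = build_discriminator(image_size=32, seed=0)
        x = rng.standard_normal((2, 2, 32, 32)).astype(nn.DTYPE)
        s = disc.forward(x)
        assert np.all(s > 0) and np.all(s < 1)

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            build_discriminator(image_size=16)

    def test_seeded_build_is_reproducible(self):
        d1 = build_discriminator(image_size=32, seed=2)
        d2 = build_discriminator(image_size=32, seed=2)
        for p1, p2 in zip(d1.params(), d2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_spectral_norm_bounds_singular_values_during_training(self, rng):
        """After each update step every spectrally-normalized convolution
        keeps its top singular value at or below one (Lipschitz control)."""
        disc = build_discriminator(
            DiscriminatorConfig(spectral_norm=True), image_size=32, seed=0
        )
        opt = nn.Adam(disc.params(), lr=1e-3)
        x = rng.standard_normal((2, 2, 32, 32)).astype(nn.DTYPE)
        for step in range(10):
            opt.zero_grad()
            z = disc.forward_logits(x, train=True)
            _, dz = nn.bce_with_logits(z, float(step % 2))
            disc.backward_logits(dz)
            opt.step()
            for conv in disc.conv_layers():
                sv = np.linalg.svd(conv.normalized_weight(), compute_uv=False)[0]
                assert sv <= 1 + 1e-3


class TestTraining:
    def test_pure_l1_training_converges(self):
        src, tgt = _paired_patches()
        _, log = train(
            src, tgt,
            lcfg=LossConfig(lambda_gan=0.0),
            tcfg=TrainConfig(epochs=50, seed=0, batch_size=1),
        )
        assert log["g_l1_loss"].iloc[-1] < 0.25 * log["g_l1_loss"].iloc[0]

    def test_identity_task_learned(self):
        src, _ = _paired_patches()
        gen, _ = train(
            src, src,
            lcfg=LossConfig(lambda_gan=0.0),
            tcfg=TrainConfig(epochs=50, seed=0, batch_size=1),
        )
        x = scale_to_model_range(src)[:, None].astype(nn.DTYPE)
        out = gen.forward(x, train=False)
        assert np.abs(out - x).mean() < 0.1

    def test_training_is_deterministic(self):
        src, tgt = _paired_patches(n_scenes=2, per_scene=3)
        _, log1 = train(src, tgt, tcfg=TrainConfig(epochs=2, seed=3))
        _, log2 = train(src, tgt, tcfg=TrainConfig(epochs=2, seed=3))
        pd.testing.assert_frame_equal(log1, log2)

    def test_nan_input_aborts_with_epoch_diagnostic(self):
        src, tgt = _paired_patches(n_scenes=1, per_scene=2)
        src = src.astype(float)
        src[0, 0, 0] = np.nan
        with pytest.raises(RuntimeError, match="epoch 1"):
            train(src, tgt, tcfg=TrainConfig(epochs=1, seed=0))

    def test_empty_dataset_rejected(self):
        empty = np.zeros((0, 32, 32), dtype=np.uint8)
        with pytest.raises(ValueError):
            train(empty, empty)

    def test_loss_weights_validated(self):
        with pytest.raises(ValueError):
            LossConfig(lambda_l1=0.0, lambda_gan=0.0)


@pytest.fixture(scope="module")
def quick_generator():
    src, tgt = _paired_patches(n_scenes=2, per_scene=3)
    gen, _ = train(
        src, tgt,
        lcfg=LossConfig(lambda_gan=0.0),
        tcfg=TrainConfig(epochs=5, seed=0, batch_size=2),
    )
    return gen, src


class TestStain:
    def test_output_in_unit_interval(self, quick_generator):
        gen, src = quick_generator
        out = stain(gen, src)
        assert out.shape == src.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_inference_is_deterministic(self, quick_generator):
        gen, src = quick_generator
        np.testing.assert_array_equal(stain(gen, src), stain(gen, src))

    def test_size_mismatch_rejected(self, quick_generator):
        gen, _ = quick_generator
        with pytest.raises(ValueError, match="built"):
            stain(gen, np.zeros((1, 64, 64), dtype=np.uint8))

    def test_checkpoint_roundtrip(self, quick_generator, tmp_path):
        gen, src = quick_generator
        path = save_checkpoint(gen, tmp_path / "g.npz")
        restored = load_checkpoint(path)
        np.testing.assert_array_equal(stain(gen, src), stain(restored, src))


class TestEstimatorInterface:
    def test_fit_predict_and_params(self):
        src, tgt = _paired_patches(n_scenes=2, per_scene=3)
        model = Pix2PixTranslator(epochs=2, batch_size=2, seed=0)
        assert model.get_params()["epochs"] == 2
        model.fit(src, tgt)
        out = model.predict(src)
        assert out.shape == src.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
        assert list(model.history_.columns) == [
            "epoch", "d_loss", "g_gan_loss", "g_l1_loss", "total"
        ]

    def test_unknown_arch_rejected(self):
        src, tgt = _paired_patches(n_scenes=1, per_scene=2)
        with pytest.raises(ValueError, match="arch"):
            Pix2PixTranslator(arch="cyclegan").fit(src, tgt)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        model = Pix2PixTranslator(epochs=3, lambda_l1=50.0)
        cloned = clone(model)
        assert cloned.get_params() == model.get_params()
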