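"""Translator architecture, rebalancing weights, losses, training contract."""

import dataclasses

import numpy as np
import pytest

from veus.codec import encode_elasticity
from veus.gan import (Checkpoint, DiscriminatorConfig, GeneratorConfig,
                      build_discriminator, build_generator,
                      discriminator_losses, fit_rebalance_table,
                      generator_loss, learning_rate_at, load_checkpoint,
                      save_checkpoint, synthesize, tiny_discriminator_config,
                      tiny_generator_config, tiny_train_config, train,
                      TrainConfig)
from veus.phantom import generate_dataset


class TestGeneratorArchitecture:
    def test_default_channel_plan_is_the_full_scale_unet(self):
        cfg = GeneratorConfig()
        assert cfg.encoder_out_channels == (64, 128, 256, 512, 512, 512, 512)
        assert cfg.decoder_in_channels == (512, 1024, 1024, 1024, 512, 256, 128)
        assert cfg.kernel_size == 4
        assert cfg.decoder_out_channels() == (512, 512, 512, 256, 128, 64)

    def test_full_generator_shapes_and_tanh_range(self):
        gen = build_generator(GeneratorConfig(), seed=0)
        x = np.random.default_rng(0).standard_normal((1, 1, 256, 256))
        # bottleneck: 7 stride-2 halvings of 256 give a 2x2 map at 512 channels
        out = gen.forward(x, train=False)
        assert out.shape == (1, 3, 256, 256)
        assert out.min() >= -1.0 and out.max() <= 1.0
        a = gen.enc_convs[0].forward(x, False)
        for i in range(1, gen.m):
            a = gen.enc_bns[i].forward(
                gen.enc_convs[i].forward(gen.enc_acts[i].forward(a, False), False), False)
        assert a.shape == (1, 512, 2, 2)

    def test_inconsistent_decoder_channels_rejected(self):
        # decoder block 0 would have to emit 512 - 512 = 0 channels
        bad = GeneratorConfig(decoder_in_channels=(512, 512, 1024, 1024, 512, 256, 128))
        with pytest.raises(ValueError, match="incompatible|bottleneck"):
            build_generator(bad)
        # first decoder input must equal the bottleneck width
        bad2 = GeneratorConfig(decoder_in_channels=(256, 1024, 1024, 1024, 512, 256, 128))
        with pytest.raises(ValueError, match="incompatible|bottleneck"):
            build_generator(bad2)

    def test_tiny_generator_output_shape(self):
        gen = build_generator(tiny_generator_config(), seed=1)
        out = gen.forward(np.zeros((2, 1, 64, 64)), train=False)
        assert out.shape == (2, 3, 64, 64)


class TestDiscriminator:
    def test_patch_map_single_channel_and_spatial(self):
        d = build_discriminator(DiscriminatorConfig(), seed=0)
        z = d.forward(np.zeros((1, 4, 256, 256)), train=False)
        assert z.shape[1] == 1
        assert z.shape[2] > 1 and z.shape[3] > 1  # a patch map, not a scalar

    def test_wrong_input_channels_rejected(self):
        d = build_discriminator(tiny_discriminator_config(), seed=0)
        with pytest.raises(ValueError, match="channels"):
            d.forward(np.zeros((1, 3, 64, 64)))

    def test_patch_scores_have_bounded_receptive_field(self):
        """Perturbing one input pixel may only move patch scores whose
        receptive field covers that pixel — locality is what makes the
        discriminator a Markov-random-field texture model."""
        d = build_discriminator(tiny_discriminator_config(), seed=3)
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1, 4, 64, 64))
        base = d.forward(x, train=False)
        x2 = x.copy()
        x2[0, 0, 0, 0] += 10.0  # corner pixel
        moved = np.abs(d.forward(x2, train=False) - base)[0, 0]
        changed = np.argwhere(moved > 1e-9)
        assert changed.size > 0
        # strides 2,2,2 then k=4 output layer: the corner pixel can reach
        # only the first few patch rows/cols
        assert changed[:, 0].max() <= 4 and changed[:, 1].max() <= 4
        assert moved[-1, -1] == 0.0


class TestRebalanceTable:
    def _two_color_images(self, n_red, n_blue):
        img = np.zeros((1, n_red + n_blue, 3), np.uint8)
        img[0, :n_red] = (255, 0, 0)
        img[0, n_red:] = (0, 0, 255)
        return [img]

    def test_uniform_distribution_gives_gamma_q(self):
        table = fit_rebalance_table(self._two_color_images(10, 10),
                                    alpha=0.8, normalize=False)
        assert table.q == 2
        assert table.gamma_raw == pytest.approx([2.0, 2.0])

    def test_alpha_zero_gives_gamma_q_regardless(self):
        table = fit_rebalance_table(self._two_color_images(15, 5),
                                    alpha=0.0, normalize=False)
        assert table.gamma_raw == pytest.approx([table.q, table.q])

    def test_alpha_one_half_probability_gives_two(self):
        table = fit_rebalance_table(self._two_color_images(10, 10),
                                    alpha=1.0, normalize=False)
        assert table.gamma_raw == pytest.approx([2.0, 2.0])
        skewed = fit_rebalance_table(self._two_color_images(30, 10),
                                     alpha=1.0, normalize=False)
        # P = 0.75 / 0.25 -> gamma = 4/3 and 4
        assert sorted(skewed.gamma_raw) == pytest.approx([4 / 3, 4.0])

    def test_rare_colors_weighted_above_common(self):
        table = fit_rebalance_table(self._two_color_images(90, 10), alpha=0.8)
        rare = table.gamma[table.empirical_dist.argmin()]
        common = table.gamma[table.empirical_dist.argmax()]
        assert rare > common > 0

    def test_normalized_gamma_has_unit_expectation(self):
        table = fit_rebalance_table(self._two_color_images(70, 30), alpha=0.8)
        assert float((table.empirical_dist * table.gamma).sum()) == pytest.approx(1.0)

    def test_weight_map_matches_bin_weights(self, bar):
        levels = np.arange(1, 257).reshape(16, 16)
        img = encode_elasticity(levels, bar).astype(np.uint8)
        table = fit_rebalance_table([img], alpha=0.8)
        wmap = table.weight_map(img / 255.0)
        assert wmap.shape == (16, 16)
        assert (wmap > 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fit_rebalance_table([])


class TestLossClosedForms:
    def _setup(self, rng):
        x = rng.random((16, 16))
        y = rng.random((16, 16, 3))
        roi = (4, 4, 8, 8)
        half = lambda a, b: np.full((3, 3), 0.5)
        return x, y, roi, half

    def test_generator_total_is_two_ln_two_at_half_probability(self, rng):
        x, y, roi, half = self._setup(rng)
        out = generator_loss(x, y.copy(), y, roi, None, half, half, 100.0)
        assert out["l1"] == 0.0
        assert out["total"] == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_perfect_fool_limit_is_zero(self, rng):
        x, y, roi, _ = self._setup(rng)
        ones = lambda a, b: np.ones((3, 3))
        out = generator_loss(x, y.copy(), y, roi, None, ones, ones, 100.0)
        assert out["total"] == pytest.approx(0.0, abs=1e-6)

    def test_lambda_scales_only_the_l1_component(self, rng):
        x, y, roi, half = self._setup(rng)
        yv = y + 0.1
        a = generator_loss(x, yv, y, roi, None, half, half, 100.0)
        b = generator_loss(x, yv, y, roi, None, half, half, 200.0)
        assert b["weighted_l1"] == pytest.approx(2 * a["weighted_l1"])
        assert b["adv_global"] == a["adv_global"]
        assert b["total"] - b["weighted_l1"] == pytest.approx(
            a["total"] - a["weighted_l1"])

    def test_discriminator_loss_at_half_probability(self, rng):
        x, y, roi, half = self._setup(rng)
        out = discriminator_losses(x, y, y + 0.05, roi, half, half)
        assert out["d_global"] == pytest.approx(2 * np.log(2), abs=1e-9)
        assert out["d_tumor"] == pytest.approx(2 * np.log(2), abs=1e-9)
        assert out["weighted_total"] == pytest.approx(2 * np.log(2), abs=1e-9)

    def test_perfect_classification_limit(self, rng):
        x, y, roi, _ = self._setup(rng)
        perfect = {"real": lambda a, b: np.ones((3, 3)),
                   "fake": lambda a, b: np.zeros((3, 3))}
        calls = iter(["real", "fake", "real", "fake"])
        d = lambda a, b: (np.ones((3, 3)) if next(calls) == "real"
                          else np.zeros((3, 3)))
        out = discriminator_losses(x, y, y + 0.05, roi, d, d)
        assert out["weighted_total"] == pytest.approx(0.0, abs=1e-5)

    def test_symmetry_under_label_and_pair_exchange(self, rng):
        x, y, roi, _ = self._setup(rng)
        yv = y + 0.05
        p = 0.3
        d_const = lambda a, b: np.full((3, 3), p)
        swapped = lambda a, b: np.full((3, 3), 1.0 - p)
        out = discriminator_losses(x, y, yv, roi, d_const, d_const)
        out_sw = discriminator_losses(x, yv, y, roi, swapped, swapped)
        assert out["d_global"] == pytest.approx(out_sw["d_global"])


class TestTraining:
    def test_lr_schedule_endpoints(self):
        cfg = TrainConfig()
        assert learning_rate_at(cfg, 1) == 2e-4
        assert learning_rate_at(cfg, 100) == 2e-4
        assert learning_rate_at(cfg, 150) == pytest.approx(1e-4)
        assert learning_rate_at(cfg, 200) == 0.0

    def test_smoke_run_writes_checkpoint_with_finite_losses(
            self, tiny_params, tmp_path):
        cases = generate_dataset(tiny_params, 8, 0.5, seed=20)
        cfg = tiny_train_config(epochs=2, seed=2)
        ckpt, log = train(cases, cfg, log_path=tmp_path / "log.csv")
        assert len(log) == 2
        assert np.isfinite(log[["l1", "adv_g", "d_global", "d_tumor"]].to_numpy()).all()
        save_checkpoint(ckpt, tmp_path / "ckpt.npz")
        assert (tmp_path / "ckpt.npz").exists()
        assert (tmp_path / "log.csv").exists()

    def test_l1_only_training_reduces_l1(self, tiny_params):
        cases = generate_dataset(tiny_params, 64, 0.5, seed=21)
        cfg = tiny_train_config(epochs=30, seed=3, adversarial=False)
        _, log = train(cases, cfg)
        assert log.l1.iloc[-1] < log.l1.iloc[0]

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train([], tiny_train_config())


@pytest.fixture(scope="module")
def trained(tiny_params):
    cases = generate_dataset(tiny_params, 8, 0.5, seed=22)
    ckpt, _ = train(cases, tiny_train_config(epochs=2, seed=4))
    return ckpt, cases


class TestSynthesizeAndCheckpoint:

    def test_inference_is_deterministic(self, trained):
        ckpt, cases = trained
        a = synthesize(cases[0].bus, ckpt)
        b = synthesize(cases[0].bus, ckpt)
        assert (a == b).all()

    def test_output_matches_input_dimensions(self, trained):
        ckpt, cases = trained
        out = synthesize(cases[0].bus, ckpt)
        assert out.shape == (*cases[0].bus.shape, 3)
        assert out.dtype == np.uint8
        odd = synthesize(cases[0].bus[:50, :60], ckpt)
        assert odd.shape == (50, 60, 3)

    def test_checkpoint_round_trip_reproduces_outputs(self, trained, tmp_path):
        ckpt, cases = trained
        save_checkpoint(ckpt, tmp_path / "ckpt.npz")
        again = load_checkpoint(tmp_path / "ckpt.npz")
        assert (synthesize(cases[1].bus, again) ==
                synthesize(cases[1].bus, ckpt)).all()
        assert again.config == ckpt.config
        assert again.table.q == ckpt.table.q

    def test_corrupt_checkpoint_rejected(self, tmp_path):
        path = tmp_path / "bad.npz"
        path.write_bytes(b"not a checkpoint")
        with pytest.raises(ValueError, match="corrupt|unreadable"):
            load_checkpoint(path)
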