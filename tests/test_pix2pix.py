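"""Conditional-translator core: objective values against hand-computed
oracles, architecture contracts, training dynamics, serialization."""

import numpy as np
import pytest

from translung.pairs_io import ImagePair
from translung.phantom import PhantomParams, generate_dataset
from translung.pix2pix import (
    DiscriminatorSpec,
    GeneratorSpec,
    TrainConfig,
    build_discriminator,
    build_generator,
    cgan_objective,
    l1_loss,
    load_checkpoint,
    save_checkpoint,
    segment,
    train,
    translate,
)

SIZE = 32  # smallest valid translator resolution; keeps unit tests fast
GSPEC = GeneratorSpec(input_size=SIZE, base_channels=4)
DSPEC = DiscriminatorSpec(patch_depth=2, base_channels=4)


@pytest.fixture(scope="module")
def pairs32():
    params = PhantomParams(image_size=SIZE)
    train_pairs, _ = generate_dataset(2, 0, params, seed=3)
    return train_pairs


class TestObjectives:
    def test_uninformative_critic_value(self):
        p = np.full((3, 3), 0.5)
        assert cgan_objective(p, p) == pytest.approx(2.0 * np.log(0.5), abs=1e-9)

    def test_perfect_critic_approaches_zero(self):
        val = cgan_objective(np.full((2, 2), 1.0 - 1e-9), np.full((2, 2), 1e-9))
        assert -1e-5 < val <= 0.0

    def test_scalar_evaluation(self):
        assert cgan_objective(np.array([[0.9]]), np.array([[0.2]])) == pytest.approx(
            np.log(0.9) + np.log(0.8), abs=1e-9
        )

    def test_saturated_probabilities_stay_finite(self):
        val = cgan_objective(np.zeros((2, 2)), np.ones((2, 2)))
        assert np.isfinite(val)

    def test_l1_identity_and_constants(self):
        a = np.full((4, 4), 0.2, dtype=np.float32)
        b = np.full((4, 4), 0.5, dtype=np.float32)
        assert l1_loss(a, a) == 0.0
        assert l1_loss(a, b) == pytest.approx(0.3, abs=1e-7)

    def test_l1_hand_computed(self):
        target = np.array([[0.0, 1.0], [1.0, 0.0]])
        gen = np.array([[0.25, 0.75], [0.5, 0.5]])
        assert l1_loss(target, gen) == pytest.approx(0.375)

    def test_l1_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            l1_loss(np.zeros((2, 2)), np.zeros((3, 3)))


class TestGenerator:
    def test_output_range_and_shape_untrained(self, rng):
        gen = build_generator(GSPEC, seed=0)
        x = rng.random((1, 1, SIZE, SIZE)).astype(np.float32)
        out = gen.forward(x)
        assert out.shape == x.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_depth_follows_input_size(self):
        spec = GeneratorSpec(input_size=64, base_channels=4)
        assert spec.depth == 6
        gen = build_generator(spec, seed=0)
        with pytest.raises(ValueError, match="64x64"):
            gen.forward(np.zeros((1, 1, 32, 32), dtype=np.float32))

    def test_depth_mismatch_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            GeneratorSpec(input_size=64, depth=4)

    def test_seeded_init_reproducible(self, rng):
        x = rng.random((1, 1, SIZE, SIZE)).astype(np.float32)
        a = build_generator(GSPEC, seed=5).forward(x)
        b = build_generator(GSPEC, seed=5).forward(x)
        assert np.array_equal(a, b)


class TestDiscriminator:
    def test_probability_range(self, rng):
        disc = build_discriminator(DSPEC, seed=0)
        x = rng.random((1, 1, SIZE, SIZE)).astype(np.float32)
        y = rng.random((1, 1, SIZE, SIZE)).astype(np.float32)
        p = disc.forward(x, y)
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_patch_grid_shrinks(self, rng):
        disc = build_discriminator(DiscriminatorSpec(patch_depth=3, base_channels=4), seed=0)
        x = rng.random((1, 1, 256, 256)).astype(np.float32)
        p = disc.forward(x, x)
        assert 1 < p.shape[2] < 256 and 1 < p.shape[3] < 256

    def test_determinism_and_shape_check(self, rng):
        disc = build_discriminator(DSPEC, seed=2)
        x = rng.random((1, 1, SIZE, SIZE)).astype(np.float32)
        assert np.array_equal(disc.forward(x, x), disc.forward(x, x))
        with pytest.raises(ValueError, match="shape"):
            disc.forward(x, x[:, :, :16, :16])


class TestTraining:
    def test_zero_epochs_returns_usable_model(self):
        model = train([], GSPEC, DSPEC, TrainConfig(epochs=0, seed=0))
        assert model.history == []
        img = np.zeros((SIZE, SIZE), dtype=np.float32)
        assert segment(model, img).shape == (SIZE, SIZE)

    def test_empty_pairs_with_epochs_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            train([], GSPEC, DSPEC, TrainConfig(epochs=1, seed=0))

    def test_memorizes_single_pair(self, pairs32):
        model = train(pairs32[:1], GSPEC, DSPEC, TrainConfig(epochs=120, seed=0))
        assert model.history[-1].g_l1 < model.history[0].g_l1

    def test_loss_identity_every_epoch(self, pairs32):
        model = train(pairs32, GSPEC, DSPEC, TrainConfig(epochs=3, seed=1))
        assert len(model.history) == 3
        for h in model.history:
            assert h.g_total == h.g_adv + model.config.lambda_l1 * h.g_l1
            assert h.g_l1 >= 0.0
            assert np.isfinite([h.d_loss, h.g_adv, h.g_l1, h.g_total]).all()

    def test_size_mismatch_rejected(self, pairs32):
        bad = ImagePair(image=np.zeros((64, 64), dtype=np.float32),
                        mask=np.zeros((64, 64), dtype=np.uint8), pair_id="bad")
        with pytest.raises(ValueError, match="expected"):
            train([bad], GSPEC, DSPEC, TrainConfig(epochs=1, seed=0))


@pytest.fixture(scope="module")
def trained_model(pairs32):
    return train(pairs32, GSPEC, DSPEC, TrainConfig(epochs=2, seed=0))


class TestInference:
    @pytest.fixture()
    def model(self, trained_model):
        return trained_model

    def test_deterministic_mode_repeatable(self, model, pairs32):
        img = pairs32[0].image
        a = translate(model, img, stochastic=False)
        b = translate(model, img, stochastic=False)
        assert np.array_equal(a, b)

    def test_stochastic_mode_seeded(self, model, pairs32):
        img = pairs32[0].image
        a = translate(model, img, stochastic=True, seed=3)
        b = translate(model, img, stochastic=True, seed=3)
        c = translate(model, img, stochastic=True, seed=4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_segment_is_valid_mask(self, model, pairs32):
        mask = segment(model, pairs32[0].image)
        assert set(np.unique(mask)) <= {0, 1}
        assert mask.shape == (SIZE, SIZE)

    def test_checkpoint_round_trip(self, model, pairs32, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        img = pairs32[0].image
        assert np.array_equal(translate(model, img), translate(loaded, img))
        assert [h.g_l1 for h in loaded.history] == [h.g_l1 for h in model.history]


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(epochs=-1), dict(lambda_l1=-1.0), dict(learning_rate=0.0),
        dict(batch_size=0), dict(device="gpu"),
    ])
    def test_invalid_config(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
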