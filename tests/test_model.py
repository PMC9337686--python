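"""Architecture contracts of the translator, discriminator and losses."""

import numpy as np
import pytest

from actin2nucleus.nn.autograd import Tensor
from actin2nucleus.nn.model import (Discriminator, ModelConfig,
                                    TokenSequence, Translator,
                                    adversarial_losses,
                                    weighted_reconstruction_loss)

RNG = np.random.default_rng(7)


def tiny_cfg(**kw):
    base = dict(image_size_px=16, encoder_blocks=2, transformer_blocks=2,
                attention_heads=2, token_channels=8, base_channels=4,
                seed=1)
    base.update(kw)
    return ModelConfig(**base)


class TestConfig:
    def test_divisibility_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(image_size_px=100, encoder_blocks=4)

    def test_alpha_bound(self):
        with pytest.raises(ValueError):
            ModelConfig(alpha=0.5)

    def test_presets(self):
        desk = ModelConfig.from_preset("desk")
        assert desk.image_size_px == 64 and desk.encoder_blocks == 2
        paper = ModelConfig.from_preset("paper")
        assert paper.encoder_blocks == 4 and paper.transformer_blocks == 12
        assert paper.image_size_px == 256


class TestEncode:
    def test_token_count_from_downsampling(self):
        # side / 2^blocks: 16 px with 2 blocks -> 4x4 map, 16 tokens
        model = Translator(tiny_cfg())
        x = RNG.random((2, 16, 16)).astype(np.float32)
        fmap, seq = model.encode(x)
        assert fmap.shape == (2, 8, 4, 4)
        assert seq.tokens.shape == (2, 16, 8)
        assert seq.position_embedding.shape == (16, 8)

    def test_indivisible_input_rejected(self):
        model = Translator(tiny_cfg())
        with pytest.raises(ValueError):
            model.encode(RNG.random((100, 100)).astype(np.float32))

    def test_tokens_are_rowmajor_flattening_plus_epos(self):
        model = Translator(tiny_cfg())
        x = RNG.random((1, 16, 16)).astype(np.float32)
        fmap, seq = model.encode(x)
        manual = fmap.data[0].transpose(1, 2, 0).reshape(16, 8) \
            + seq.position_embedding
        np.testing.assert_allclose(seq.tokens.data[0], manual, rtol=1e-5)


class TestTransformer:
    def test_zero_weights_reduce_to_identity(self):
        # with the MSA and MLP output projections zeroed, each layer is
        # z_l = 0 + z_{l-1}: the stack is the identity map
        model = Translator(tiny_cfg())
        for block in model.transformer:
            block.attn.proj.w.data[:] = 0
            block.attn.proj.b.data[:] = 0
            block.fc2.w.data[:] = 0
            block.fc2.b.data[:] = 0
        _, seq = model.encode(RNG.random((1, 16, 16)).astype(np.float32))
        out = model.transformer_apply(seq)
        np.testing.assert_allclose(out.tokens.data, seq.tokens.data,
                                   rtol=1e-5, atol=1e-6)

    def test_shape_preserved_for_any_depth(self):
        model = Translator(tiny_cfg(transformer_blocks=3))
        _, seq = model.encode(RNG.random((2, 16, 16)).astype(np.float32))
        out = model.transformer_apply(seq)
        assert out.tokens.shape == seq.tokens.shape

    def test_permutation_equivariance(self):
        # permuting tokens together with their position embeddings permutes
        # the output identically (attention itself is order-agnostic)
        model = Translator(tiny_cfg(transformer_blocks=1))
        z = RNG.standard_normal((1, 4, 8)).astype(np.float32)
        perm = np.array([2, 0, 3, 1])

        def apply(tokens):
            seq = TokenSequence(Tensor(tokens), model.pos_embed.data)
            return model.transformer_apply(seq).tokens.data

        out = apply(z)
        out_perm = apply(z[:, perm])
        np.testing.assert_allclose(out_perm, out[:, perm], rtol=2e-4,
                                   atol=1e-5)


class TestDecode:
    def test_resolution_doubling_chain(self):
        model = Translator(tiny_cfg())
        _, seq = model.encode(RNG.random((1, 16, 16)).astype(np.float32))
        outs = model.decode(model.transformer_apply(seq))
        assert [o.shape[-1] for o in outs] == [8, 16]
        assert outs[-1].shape == (1, 1, 16, 16)

    def test_outputs_finite_for_random_weights(self):
        model = Translator(tiny_cfg(seed=99))
        outs = model.forward(RNG.random((3, 16, 16)).astype(np.float32))
        for o in outs:
            assert np.isfinite(o.data).all()
            assert (o.data >= 0).all() and (o.data <= 1).all()


class TestDiscriminator:
    def test_one_score_per_image(self):
        disc = Discriminator(tiny_cfg())
        scores = disc(RNG.random((5, 16, 16)).astype(np.float32))
        assert scores.shape == (5, 1)
        assert np.isfinite(scores.data).all()

    def test_deterministic_under_fixed_weights(self):
        cfg = tiny_cfg()
        x = RNG.random((2, 16, 16)).astype(np.float32)
        a = Discriminator(cfg)(x).data
        b = Discriminator(cfg)(x).data
        np.testing.assert_array_equal(a, b)


class TestWeightedReconstructionLoss:
    def test_identity_gives_zero(self):
        img = RNG.random((8, 8))
        lb = weighted_reconstruction_loss(img, img, np.ones((8, 8)), 10)
        assert lb.rec_total == 0.0

    def test_alpha_one_collapses_to_plain_l1(self):
        a, b = RNG.random((6, 6)), RNG.random((6, 6))
        m = (RNG.random((6, 6)) > 0.5).astype(float)
        lb = weighted_reconstruction_loss(a, b, m, alpha=1)
        assert lb.rec_total == pytest.approx(np.abs(a - b).sum(), rel=1e-5)

    def test_printed_formula_2x2_case(self):
        i_gt = np.array([[1.0, 0.0], [0.0, 0.0]])
        i_out = np.array([[0.5, 0.2], [0.0, 0.0]])
        m = np.array([[1.0, 0.0], [0.0, 0.0]])
        lb = weighted_reconstruction_loss(i_out, i_gt, m, alpha=10)
        assert lb.rec_foreground == pytest.approx(0.5)
        assert lb.rec_background == pytest.approx(0.2)
        assert lb.rec_total == pytest.approx(5.2)

    def test_decomposition_invariant(self):
        for _ in range(5):
            a, b = RNG.random((2, 12, 12)), RNG.random((2, 12, 12))
            m = (RNG.random((2, 12, 12)) > 0.8).astype(float)
            alpha = float(RNG.uniform(1, 20))
            lb = weighted_reconstruction_loss(a, b, m, alpha)
            assert lb.rec_total == pytest.approx(
                alpha * lb.rec_foreground + lb.rec_background, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            weighted_reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 3)),
                                         np.zeros((2, 2)), 10)
        with pytest.raises(ValueError):
            weighted_reconstruction_loss(np.zeros((2, 2)), np.zeros((2, 2)),
                                         np.full((2, 2), 0.5), 10)


class TestAdversarialLosses:
    def test_perfect_discriminator_limit(self):
        g, d = adversarial_losses(np.array([0.999999]), np.array([1e-6]))
        assert d == pytest.approx(0.0, abs=1e-4)
        assert g > 10                                # generator punished

    def test_indifferent_discriminator_closed_form(self):
        g, d = adversarial_losses(np.array([0.5, 0.5]), np.array([0.5, 0.5]))
        assert d == pytest.approx(-2 * np.log(0.5), rel=1e-6)
        assert g == pytest.approx(-np.log(0.5), rel=1e-6)

    def test_generator_gradient_pushes_fakes_up(self):
        # improving fake scores must reduce the generator loss
        logit = Tensor(np.array([[0.3]], np.float32), requires_grad=True)
        loss = (-logit).softplus().mean()            # -log sigmoid(logit)
        loss.backward()
        assert logit.grad[0, 0] < 0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            adversarial_losses(np.array([]), np.array([0.5]))


class TestCheckpointRoundtrip:
    def test_state_survives_save_load(self, tmp_path):
        from actin2nucleus.nn.train import (load_checkpoint, save_checkpoint,
                                            train)
        cfg = tiny_cfg(batch_size=2, learning_rate_g=1e-3)
        actin = RNG.random((4, 16, 16)).astype(np.float32)
        nucleus = RNG.random((4, 16, 16)).astype(np.float32)
        masks = (nucleus > 0.7).astype(np.float32)
        state = train((actin, nucleus), masks, cfg, iterations=3)
        path = tmp_path / "m.ckpt.npz"
        save_checkpoint(state, path)
        loaded = load_checkpoint(path)
        assert loaded.iteration == 3
        np.testing.assert_array_equal(
            loaded.generator.predict_array(actin[0]),
            state.generator.predict_array(actin[0]))
        assert [l.rec_total for l in loaded.loss_history] == pytest.approx(
            [l.rec_total for l in state.loss_history], rel=1e-6)
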