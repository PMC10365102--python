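"""Architecture contracts of the CNN-transformer encoder-decoder."""

import numpy as np
import pytest

from conftest import set_all_params_zero
from lungseg.model import (ModelConfig, MultiHeadSelfAttention, ResidualBlock,
                           TransformerLayer, TransResUNet, save_checkpoint,
                           load_checkpoint)
from lungseg.nn import tensor as T
from lungseg.nn.optim import RMSprop


class TestModelConfig:
    def test_defaults_follow_vit_b_conventions(self):
        cfg = ModelConfig()
        assert (cfg.transformer_layers, cfg.embed_dim) == (12, 768)
        assert cfg.mlp_dim == 4 * 768
        assert cfg.token_grid == 64 and cfg.num_tokens == 4096

    @pytest.mark.parametrize("kwargs", [
        {"input_side": 60},                       # not divisible by 8*p
        {"embed_dim": 65, "attention_heads": 4},  # K % h != 0
        {"patch_stride": 3},
        {"encoder_channels": (8, 16)},
        {"num_classes": 3},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ModelConfig(**{**dict(input_side=64, encoder_channels=(8, 16, 32),
                                  transformer_layers=2, embed_dim=64,
                                  attention_heads=4), **kwargs})

    def test_json_round_trip(self):
        cfg = ModelConfig.tiny()
        assert ModelConfig.from_json(cfg.to_json()) == cfg


class TestResidualBlock:
    def test_zero_weights_identity(self, rng):
        block = ResidualBlock(4, 4, rng).eval()
        set_all_params_zero(block)
        x = T.Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_projection_when_channels_change(self, rng):
        block = ResidualBlock(4, 8, rng).eval()
        assert block.proj is not None
        x = T.Tensor(rng.normal(size=(1, 4, 6, 6)).astype(np.float32))
        y = block(x)
        assert y.shape == (1, 8, 6, 6)
        assert np.isfinite(y.data).all()

    def test_spatial_size_preserved(self, rng):
        block = ResidualBlock(3, 3, rng).eval()
        x = T.Tensor(rng.normal(size=(1, 3, 10, 10)).astype(np.float32))
        assert block(x).shape == x.shape


class TestTransformerPieces:
    def test_zero_weight_layer_is_identity(self, rng):
        cfg = ModelConfig.tiny()
        layer = TransformerLayer(cfg, rng).eval()
        set_all_params_zero(layer)
        x = T.Tensor(rng.normal(size=(2, 10, cfg.embed_dim)).astype(np.float32))
        np.testing.assert_array_equal(layer(x).data, x.data)

    def test_single_token_attention_closed_form(self, rng):
        # With one token, attention weights are trivially 1, so MSA reduces
        # to out-projection of the value projection.
        msa = MultiHeadSelfAttention(16, 4, rng, drop=0.0).eval()
        x = T.Tensor(rng.normal(size=(1, 1, 16)).astype(np.float32))
        expect = msa.out(msa.v(x))
        np.testing.assert_allclose(msa(x).data, expect.data, atol=1e-6)

    def test_empty_stack_passes_tokens_through(self, rng):
        cfg = ModelConfig(input_side=32, encoder_channels=(4, 8, 16),
                          transformer_layers=0, embed_dim=32, attention_heads=4)
        model = TransResUNet(cfg, seed=0).eval()
        assert model.layers == []
        x = T.Tensor(rng.normal(size=(1, 16, 32)).astype(np.float32))
        out = x
        for layer in model.layers:
            out = layer(out)
        np.testing.assert_array_equal(out.data, x.data)

    def test_token_permutation_equivariance_without_positions(self, rng):
        cfg = ModelConfig.tiny(32)
        model = TransResUNet(cfg, seed=3).eval()
        model.embed.pos.data[...] = 0.0
        tokens = rng.normal(size=(1, cfg.num_tokens, cfg.embed_dim)).astype(np.float32)
        perm = rng.permutation(cfg.num_tokens)

        def run_stack(t):
            x = T.Tensor(t)
            for layer in model.layers:
                x = layer(x)
            return model.final_norm(x).data

        np.testing.assert_allclose(run_stack(tokens)[:, perm],
                                   run_stack(tokens[:, perm]), atol=1e-4)


CONFIG_GRID = [
    ModelConfig(input_side=32, encoder_channels=(4, 8, 16),
                transformer_layers=1, embed_dim=32, attention_heads=2),
    ModelConfig(input_side=64, encoder_channels=(8, 16, 32),
                transformer_layers=2, embed_dim=64, attention_heads=4),
    ModelConfig(input_side=32, encoder_channels=(6, 12, 24),
                transformer_layers=1, embed_dim=48, attention_heads=4,
                patch_stride=2),
    ModelConfig(input_side=64, encoder_channels=(4, 8, 12),
                transformer_layers=1, embed_dim=40, attention_heads=5,
                patch_stride=4, mlp_dim=64),
]


class TestForwardContract:
    @pytest.mark.parametrize("cfg", CONFIG_GRID, ids=lambda c: f"S{c.input_side}p{c.patch_stride}")
    def test_shapes_across_config_grid(self, cfg, rng):
        model = TransResUNet(cfg, seed=0).eval()
        x = rng.normal(size=(1, 1, cfg.input_side, cfg.input_side)).astype(np.float32)
        f1, f2, f3 = model.encoder(T.Tensor(x))
        s, (c1, c2, c3) = cfg.input_side, cfg.encoder_channels
        assert f1.shape == (1, c1, s // 2, s // 2)
        assert f2.shape == (1, c2, s // 4, s // 4)
        assert f3.shape == (1, c3, s // 8, s // 8)
        tokens = model.encode_tokens(f3)
        assert tokens.shape == (1, cfg.num_tokens, cfg.embed_dim)
        logits = model(x)
        assert logits.shape == (1, 2, s, s)
        assert np.isfinite(logits.data).all()

    def test_probability_map_contract(self, rng):
        model = TransResUNet(ModelConfig.tiny(32), seed=0)
        img = rng.random((32, 32)).astype(np.float32)
        prob = model.predict_proba(img)
        assert prob.shape == (32, 32)
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_softmax_channels_sum_to_one(self, rng):
        model = TransResUNet(ModelConfig.tiny(32), seed=0).eval()
        logits = model(rng.normal(size=(1, 1, 32, 32)).astype(np.float32))
        probs = T.softmax(T.transpose(logits, (0, 2, 3, 1))).data
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, rng):
        model = TransResUNet(ModelConfig.tiny(32), seed=0).eval()
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model(x).data, model(x).data)

    def test_tiny_parameter_budget(self):
        assert TransResUNet(ModelConfig.tiny(64), seed=0).num_parameters() < 2_000_000

    def test_one_rmsprop_step_decreases_loss(self, rng):
        model = TransResUNet(ModelConfig.tiny(32), seed=0)
        model.eval()  # freeze batch-norm stats so the comparison is clean
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        target = np.zeros((1, 32, 32), dtype=np.int64)
        target[:, 8:24, 8:24] = 1
        loss0 = T.softmax_cross_entropy(model(x), target)
        model.zero_grad()
        loss0.backward()
        # RMSprop's first step is ~lr/sqrt(1-alpha) per weight regardless of
        # gradient size, so "small" here means small lr
        RMSprop(model.parameters(), lr=1e-6).step()
        loss1 = T.softmax_cross_entropy(model(x), target)
        assert float(loss1.data) < float(loss0.data)


class TestCheckpoint:
    def test_save_load_round_trip(self, rng, tmp_path):
        model = TransResUNet(ModelConfig.tiny(32), seed=5).eval()
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path)
        clone = load_checkpoint(path).eval()
        assert clone.cfg == model.cfg
        x = rng.normal(size=(1, 1, 32, 32)).astype(np.float32)
        np.testing.assert_array_equal(model(x).data, clone(x).data)
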