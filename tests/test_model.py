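"""FN-SSIR architecture: shape contracts, parameter count, ablations."""

import numpy as np
import pytest

from fnssir.epochs import EpochSet
from fnssir.model import (ABLATABLE, FNSSIR, ModelConfig, ablate, minmax_scale)
from fnssir.plane import build_grid

TINY = dict(T=100, pools=((3, 3, 5), (3, 3, 2)), msstcn_filters=(1, 1))


def expected_parameter_count(cfg: ModelConfig) -> int:
    """Layer-by-layer arithmetic, written independently of the model code."""
    f1, f2 = cfg.msstcn_filters
    taps = [int(np.prod(k)) for k in cfg.msstcn_kernels]
    n = 0
    # unit 1: three kernels (1 -> f1 each) + bias (3 f1) + BN gamma/beta
    n += f1 * sum(taps) + 3 * f1 + 2 * 3 * f1
    # unit 2: three kernels (3 f1 -> f2 each) + bias + BN
    n += f2 * 3 * f1 * sum(taps) + 3 * f2 + 2 * 3 * f2
    # CAE encoder/decoder (temporal kernels only)
    c1, c2 = cfg.cae_filters
    n += c1 * 1 * cfg.cae_kernel_t + c1
    n += c2 * c1 * cfg.cae_kernel_t + c2
    n += c2 * c1 * cfg.cae_deconv_t + c1
    n += c1 * 1 * cfg.cae_deconv_t + 1
    # LSTMs: 4H(F + H + 1) each
    h, w = cfg.spatial_out
    in_a = 3 * f2 * h * w
    in_b = len(cfg.cae_channels) * (cfg.T // cfg.steps)
    for n_in, hid in ((in_a, cfg.lstm_a_units), (in_b, cfg.lstm_b_units)):
        n += 4 * hid * (n_in + hid + 1)
    # attention: three d x d maps + biases
    d = cfg.attention_dim
    n += 3 * (d * d + d)
    # classifier head
    n += cfg.steps * d * cfg.n_classes + cfg.n_classes
    return n


class TestDefaultContract:
    def test_shapes_and_parameter_count(self, rng):
        """Default 9x9x1200 input: 24 steps, 120-d fused features, 3 logits;
        trainable parameter total equals the independent layer-by-layer sum."""
        cfg = ModelConfig()
        assert cfg.steps == 24
        assert cfg.spatial_out == (1, 1)
        assert cfg.msstcn_feat == 48
        assert cfg.cae_feat == 300
        model = FNSSIR(cfg, seed=0)
        assert model.parameter_count == expected_parameter_count(cfg)
        assert model.attn_dim == 120
        plane = rng.standard_normal((2, 1, 9, 9, 1200)).astype(np.float32)
        cae = rng.random((2, 1, 6, 1200)).astype(np.float32)
        z = model.unit2.forward(model.unit1.forward(plane, False), False)
        assert z.shape == (2, 48, 1, 1, 24)
        logits, recon = model.forward(plane, cae)
        assert logits.shape == (2, 3)
        assert recon.shape == (2, 1, 6, 1200)
        assert model.head.W.value.shape == (24 * 120, 3)

    def test_batch7_three_logits(self, rng):
        cfg = ModelConfig(**TINY)
        model = FNSSIR(cfg, seed=0)
        plane = rng.standard_normal((7, 1, 9, 9, 100)).astype(np.float32)
        cae = rng.random((7, 1, 6, 100)).astype(np.float32)
        logits, _ = model.forward(plane, cae)
        assert logits.shape == (7, 3)

    def test_inference_deterministic(self, rng):
        model = FNSSIR(ModelConfig(**TINY), seed=0)
        plane = rng.standard_normal((3, 1, 9, 9, 100)).astype(np.float32)
        cae = rng.random((3, 1, 6, 100)).astype(np.float32)
        a, _ = model.forward(plane, cae, training=False)
        b, _ = model.forward(plane, cae, training=False)
        assert np.array_equal(a, b)

    def test_tiny_config_parameter_count(self):
        cfg = ModelConfig(**TINY)
        assert FNSSIR(cfg).parameter_count == expected_parameter_count(cfg)


class TestCAE:
    def test_encoder_quarters_decoder_restores(self, rng):
        model = FNSSIR(ModelConfig(), seed=0)
        x = rng.random((2, 1, 6, 1200)).astype(np.float32)
        enc = model.encoder.forward(x, False)
        assert enc.shape == (2, 16, 6, 300)
        rec = model.decoder.forward(enc, False)
        assert rec.shape == (2, 1, 6, 1200)
        assert rec.min() >= 0.0 and rec.max() <= 1.0   # sigmoid range

    def test_time_not_divisible_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(T=102, pools=((3, 3, 2), (3, 3, 3))).validate()

    def test_minmax_scaling(self, rng):
        x = rng.standard_normal((3, 1, 6, 50)) * 40 - 10
        y = minmax_scale(x)
        assert y.min() >= 0.0 and y.max() <= 1.0 + 1e-9
        assert np.allclose(y.max(axis=-1), 1.0, atol=1e-6)


class TestAblation:
    def test_without_cae_runs_without_cae_input(self, rng):
        cfg = ablate(ModelConfig(**TINY), "CAE")
        model = FNSSIR(cfg, seed=0)
        plane = rng.standard_normal((2, 1, 9, 9, 100)).astype(np.float32)
        logits, recon = model.forward(plane, None)
        assert logits.shape == (2, 3) and recon is None
        assert model.attn_dim == cfg.lstm_a_units

    def test_without_msstcn_runs_without_plane(self, rng):
        cfg = ablate(ModelConfig(**TINY), "MSSTCN")
        model = FNSSIR(cfg, seed=0)
        cae = rng.random((2, 1, 6, 100)).astype(np.float32)
        logits, recon = model.forward(None, cae)
        assert logits.shape == (2, 3) and recon is not None

    def test_without_lstm_sa_has_no_recurrent_params(self, rng):
        cfg = ablate(ModelConfig(**TINY), "LSTM-SA")
        model = FNSSIR(cfg, seed=0)
        names = [p.name for p in model.params()]
        assert not any("lstm" in n or "attn" in n for n in names)
        plane = rng.standard_normal((2, 1, 9, 9, 100)).astype(np.float32)
        cae = rng.random((2, 1, 6, 100)).astype(np.float32)
        assert model.forward(plane, cae)[0].shape == (2, 3)

    def test_unknown_component_rejected(self):
        with pytest.raises(ValueError, match="unknown component"):
            ablate(ModelConfig(), "FOO")


def test_gradient_reaches_every_parameter(rng):
    """After one backward pass on random data, no branch is dead."""
    from fnssir import nn

    model = FNSSIR(ModelConfig(**TINY, dropout_p=0.2), seed=0)
    plane = rng.standard_normal((6, 1, 9, 9, 100)).astype(np.float32)
    cae = rng.random((6, 1, 6, 100)).astype(np.float32)
    labels = np.array([0, 1, 2, 0, 1, 2])
    logits, recon = model.forward(plane, cae, training=True)
    _, dlogits = nn.softmax_cross_entropy(logits, labels)
    _, drecon = nn.mse_loss(recon, np.zeros_like(recon))
    model.backward(dlogits, 0.1 * drecon.astype(np.float32))
    for p in model.params():
        assert np.any(p.grad != 0), f"dead parameter tensor {p.name}"


def test_alternative_montage_grid_contract(rng):
    """A 22-channel montage on a 7x7 grid with adapted pools keeps the
    step/feature contract."""
    channels = ["Fz", "FC3", "FC1", "FCz", "FC2", "FC4", "C5", "C3", "C1",
                "Cz", "C2", "C4", "C6", "CP3", "CP1", "CPz", "CP2", "CP4",
                "P1", "Pz", "P2", "POz"]
    grid = build_grid(channels, (7, 7))
    cfg = ModelConfig(grid_shape=(7, 7), T=200,
                      pools=((7, 7, 5), (1, 1, 4)), msstcn_filters=(1, 1))
    assert cfg.steps == 10
    model = FNSSIR(cfg, seed=0)
    ep = EpochSet(rng.standard_normal((4, len(channels), 200)),
                  rng.integers(0, 3, 4), channels, 100.0)
    plane_x, cae_x = model.prepare_inputs(ep, grid)
    assert plane_x.shape == (4, 1, 7, 7, 200)
    logits, _ = model.forward(plane_x, cae_x)
    assert logits.shape == (4, 3)


def test_fingerprint_lists_all_layers():
    import json

    model = FNSSIR(ModelConfig(**TINY), seed=0)
    fp = json.loads(model.fingerprint())
    assert fp["n_params"] == model.parameter_count
    assert len(fp["layers"]) == len(model.params())
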