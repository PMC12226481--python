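"""The FN-SSIR decoding network.

Three branches over a common trial:

* **MSSTCN** — two multi-scale spatial-temporal units.  Each unit applies
  three parallel same-padded 3D convolutions (kernels (3,3,3), (5,5,5),
  (7,9,7)) with per-convolution batch normalisation to the electrode-plane
  tensor X in R^{1 x H x W x T}, concatenates them along channels, then
  ReLU -> average pooling ((3,3,5) after unit 1, (3,3,10) after unit 2);
  dropout (p = 0.5) follows the second pooling.  On the default 9x9x1200
  input the spatial extent collapses to 1x1 and time to 24 steps.
* **CAE** — a convolutional auto-encoder over the min-max-scaled signals of
  six frontocentral/central electrodes (FC3, FCz, FC4, C3, Cz, C4):
  encoder Conv(1,3)+ReLU+MaxPool(1,2) twice (time /4), decoder two
  transposed convolutions (kernel (1,4), stride (1,2)) back to full length
  with a sigmoid output.  The denoised reconstruction, cut into as many
  windows as the MSSTCN emits steps, forms the second feature sequence.
* **LSTM-SA** — LSTM-A (40 units) over the MSSTCN sequence, LSTM-B (80
  units) over the CAE sequence; per-step concatenation (120) feeds scaled
  dot-product self-attention (d = 120), which is flattened and classified
  by a dense layer.

Ablation variants remove one branch at a time while keeping the rest wired.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .epochs import EpochSet
from .plane import GridMap, to_plane

__all__ = ["ModelConfig", "FNSSIR", "ablate", "minmax_scale",
           "DEFAULT_CAE_CHANNELS", "ABLATABLE"]

DEFAULT_CAE_CHANNELS = ("FC3", "FCz", "FC4", "C3", "Cz", "C4")
ABLATABLE = ("MSSTCN", "CAE", "LSTM-SA")


@dataclass
class ModelConfig:
    grid_shape: tuple[int, int] = (9, 9)
    T: int = 1200
    msstcn_kernels: tuple = ((3, 3, 3), (5, 5, 5), (7, 9, 7))
    msstcn_filters: tuple[int, int] = (8, 16)
    pools: tuple = ((3, 3, 5), (3, 3, 10))
    dropout_p: float = 0.5
    cae_channels: tuple = DEFAULT_CAE_CHANNELS
    cae_filters: tuple[int, int] = (8, 16)
    cae_kernel_t: int = 3
    cae_pool_t: int = 2
    cae_deconv_t: int = 4
    lstm_a_units: int = 40
    lstm_b_units: int = 80
    attention_dim: int = 120
    n_classes: int = 3
    ablate_component: str | None = None

    # -- derived shape arithmetic -------------------------------------------
    def validate(self) -> None:
        H, W = self.grid_shape
        (p0a, p1a, p2a), (p0b, p1b, p2b) = self.pools
        for name, extent, div in (("H", H, p0a * p0b), ("W", W, p1a * p1b),
                                  ("T", self.T, p2a * p2b)):
            if extent % div:
                raise ValueError(f"pools {self.pools} do not divide {name}={extent}: "
                                 f"{extent} % {div} != 0")
        if self.T % 4:
            raise ValueError("CAE needs T divisible by 4")
        if self.T % self.steps:
            raise ValueError("T must divide into the MSSTCN step count")
        if self.ablate_component is None and \
                self.attention_dim != self.lstm_a_units + self.lstm_b_units:
            raise ValueError("attention_dim must equal lstm_a_units + lstm_b_units")
        if self.ablate_component is not None and self.ablate_component not in ABLATABLE:
            raise ValueError(f"unknown component {self.ablate_component!r}; "
                             f"choose from {ABLATABLE}")

    @property
    def steps(self) -> int:
        return self.T // (self.pools[0][2] * self.pools[1][2])

    @property
    def spatial_out(self) -> tuple[int, int]:
        H, W = self.grid_shape
        return (H // (self.pools[0][0] * self.pools[1][0]),
                W // (self.pools[0][1] * self.pools[1][1]))

    @property
    def msstcn_feat(self) -> int:
        h, w = self.spatial_out
        return 3 * self.msstcn_filters[1] * h * w

    @property
    def cae_feat(self) -> int:
        return len(self.cae_channels) * (self.T // self.steps)


def minmax_scale(x: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Scale each trial/channel row of [..., T] into [0, 1]."""
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    return (x - lo) / (hi - lo + eps)


class _MSSTCNUnit:
    """Three parallel same-padded 3D convolutions (fused over a shared FFT),
    per-channel batch normalisation (equivalent to per-convolution BN since
    BN acts channel-wise), then ReLU -> average pooling."""

    def __init__(self, c_in, f, kernels, pool, rng, first_layer, dtype, name):
        self.conv = nn.MultiScaleConv3d(c_in, f, kernels, rng,
                                        first_layer=first_layer, dtype=dtype,
                                        name=f"{name}.conv")
        self.bn = nn.BatchNorm(f * len(kernels), dtype=dtype, name=f"{name}.bn")
        self.relu = nn.ReLU()
        self.pool = nn.AvgPool3d(pool)

    def params(self):
        return self.conv.params() + self.bn.params()

    def forward(self, x, training):
        y = self.bn.forward(self.conv.forward(x, training), training)
        return self.pool.forward(self.relu.forward(y, training), training)

    def backward(self, dy):
        dy = self.relu.backward(self.pool.backward(dy))
        return self.conv.backward(self.bn.backward(dy))


class FNSSIR:
    """Force-variation MI decoder; see the module docstring for the wiring."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        self.cfg = cfg = cfg or ModelConfig()
        cfg.validate()
        rng = np.random.default_rng(seed)
        self.rng = rng
        self.dtype = dtype
        f1, f2 = cfg.msstcn_filters
        ab = cfg.ablate_component
        self.has_msstcn = ab != "MSSTCN"
        self.has_cae = ab != "CAE"
        self.has_lstm = ab != "LSTM-SA"

        if self.has_msstcn:
            self.unit1 = _MSSTCNUnit(1, f1, cfg.msstcn_kernels, cfg.pools[0],
                                     rng, True, dtype, "msstcn.u1")
            self.unit2 = _MSSTCNUnit(3 * f1, f2, cfg.msstcn_kernels, cfg.pools[1],
                                     rng, False, dtype, "msstcn.u2")
            self.drop = nn.Dropout(cfg.dropout_p, rng)

        if self.has_cae:
            c1, c2 = cfg.cae_filters
            kt, pt, dt = cfg.cae_kernel_t, cfg.cae_pool_t, cfg.cae_deconv_t
            self.encoder = nn.Sequential(
                nn.Conv2dTime(1, c1, kt, rng, dtype=dtype, name="cae.conv1"),
                nn.ReLU(), nn.MaxPoolTime(pt),
                nn.Conv2dTime(c1, c2, kt, rng, dtype=dtype, name="cae.conv2"),
                nn.ReLU(), nn.MaxPoolTime(pt),
            )
            self.decoder = nn.Sequential(
                nn.ConvTranspose2dTime(c2, c1, dt, pt, 1, rng, dtype=dtype,
                                       name="cae.deconv1"),
                nn.ReLU(),
                nn.ConvTranspose2dTime(c1, 1, dt, pt, 1, rng, dtype=dtype,
                                       name="cae.deconv2"),
                nn.Sigmoid(),
            )

        steps = cfg.steps
        if self.has_lstm:
            d = 0
            if self.has_msstcn:
                self.lstm_a = nn.LSTM(cfg.msstcn_feat, cfg.lstm_a_units, rng,
                                      dtype=dtype, name="lstm_a")
                d += cfg.lstm_a_units
            if self.has_cae:
                self.lstm_b = nn.LSTM(cfg.cae_feat, cfg.lstm_b_units, rng,
                                      dtype=dtype, name="lstm_b")
                d += cfg.lstm_b_units
            if ab is None and d != cfg.attention_dim:  # pragma: no cover
                raise ValueError("attention_dim inconsistent with LSTM units")
            self.attn_dim = d
            self.attention = nn.SelfAttention(d, rng, dtype=dtype)
            head_in = steps * d
        else:
            head_in = 0
            if self.has_msstcn:
                head_in += steps * cfg.msstcn_feat
            if self.has_cae:
                head_in += steps * cfg.cae_feat
        self.flatten = nn.Flatten()
        self.head = nn.Dense(head_in, cfg.n_classes, rng, dtype=dtype, name="head")

    # -- plumbing ------------------------------------------------------------
    def params(self) -> list[nn.Parameter]:
        out = []
        if self.has_msstcn:
            out += self.unit1.params() + self.unit2.params()
        if self.has_cae:
            out += self.encoder.params() + self.decoder.params()
        if self.has_lstm:
            if self.has_msstcn:
                out += self.lstm_a.params()
            if self.has_cae:
                out += self.lstm_b.params()
            out += self.attention.params()
        out += self.head.params()
        return out

    @property
    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    def fingerprint(self) -> str:
        layers = [{"name": p.name, "shape": list(p.value.shape)}
                  for p in self.params()]
        return json.dumps({"n_params": self.parameter_count, "layers": layers},
                          indent=1)

    # -- forward / backward --------------------------------------------------
    def _seq_shape(self, z):
        # [B, C, h, w, steps] -> [B, steps, C*h*w]
        B = z.shape[0]
        steps = z.shape[-1]
        return np.ascontiguousarray(
            z.reshape(B, -1, steps).transpose(0, 2, 1))

    def forward(self, plane_x: np.ndarray | None, cae_x: np.ndarray | None,
                training: bool = False):
        """Returns (logits, reconstruction-or-None).

        ``plane_x``: [B, 1, H, W, T] electrode-plane tensor (MSSTCN input);
        ``cae_x``: [B, 1, C_m, T] min-max-scaled electrode subset.
        """
        cfg = self.cfg
        steps = cfg.steps
        recon = None
        seqs = []
        if self.has_msstcn:
            if plane_x is None:
                raise ValueError("model requires the electrode-plane input")
            z = self.unit1.forward(np.asarray(plane_x, dtype=self.dtype), training)
            z = self.unit2.forward(z, training)
            z = self.drop.forward(z, training)
            self._mss_shape = z.shape
            seqs.append(self._seq_shape(z))
        if self.has_cae:
            if cae_x is None:
                raise ValueError("model requires the CAE electrode-subset input")
            cae_x = np.asarray(cae_x, dtype=self.dtype)
            enc = self.encoder.forward(cae_x, training)
            recon = self.decoder.forward(enc, training)
            B = recon.shape[0]
            seqs.append(np.ascontiguousarray(
                recon.reshape(B, len(cfg.cae_channels), steps, -1)
                     .transpose(0, 2, 1, 3).reshape(B, steps, -1)))
        self._seqs_in = seqs
        if self.has_lstm:
            outs = []
            if self.has_msstcn:
                outs.append(self.lstm_a.forward(seqs[0], training))
            if self.has_cae:
                outs.append(self.lstm_b.forward(seqs[-1], training))
            fused = outs[0] if len(outs) == 1 else np.concatenate(outs, axis=2)
            att = self.attention.forward(fused, training)
            flat = self.flatten.forward(att, training)
        else:
            flat = np.concatenate([s.reshape(s.shape[0], -1) for s in seqs], axis=1)
            self._flat_splits = [s.shape for s in seqs]
        logits = self.head.forward(flat, training)
        return logits, recon

    def backward(self, dlogits: np.ndarray, drecon: np.ndarray | None = None):
        cfg = self.cfg
        dflat = self.head.backward(dlogits)
        dseqs = []
        if self.has_lstm:
            datt = self.flatten.backward(dflat)
            dfused = self.attention.backward(datt)
            pos = 0
            if self.has_msstcn:
                ua = cfg.lstm_a_units
                dseqs.append(self.lstm_a.backward(
                    np.ascontiguousarray(dfused[:, :, pos:pos + ua])))
                pos += ua
            if self.has_cae:
                dseqs.append(self.lstm_b.backward(
                    np.ascontiguousarray(dfused[:, :, pos:])))
        else:
            pos = 0
            for shape in self._flat_splits:
                size = int(np.prod(shape[1:]))
                dseqs.append(dflat[:, pos:pos + size].reshape(shape))
                pos += size
        if self.has_msstcn:
            dseq = dseqs.pop(0)
            B, C, h, w, steps = self._mss_shape
            dz = np.ascontiguousarray(
                dseq.transpose(0, 2, 1).reshape(self._mss_shape))
            dz = self.drop.backward(dz)
            self.unit1.backward(self.unit2.backward(dz))
        if self.has_cae:
            dseq = dseqs.pop(0)
            B = dseq.shape[0]
            steps = cfg.steps
            drec = dseq.reshape(B, steps, len(cfg.cae_channels), -1) \
                       .transpose(0, 2, 1, 3).reshape(B, 1, len(cfg.cae_channels), -1)
            drec = np.ascontiguousarray(drec)
            if drecon is not None:
                drec = drec + drecon
            self.encoder.backward(self.decoder.backward(drec))

    # -- inference helpers ---------------------------------------------------
    def prepare_inputs(self, epochs: EpochSet, grid: GridMap | None):
        """Build (plane_x, cae_x) batches from an EpochSet."""
        plane_x = None
        if self.has_msstcn:
            if grid is None:
                raise ValueError("grid required for the MSSTCN branch")
            plane_x = to_plane(epochs, grid, dtype=self.dtype).values
        cae_x = None
        if self.has_cae:
            rows = [epochs.get_channel(c) for c in self.cfg.cae_channels]
            raw = np.stack(rows, axis=1)[:, None]  # [n, 1, C_m, T]
            cae_x = minmax_scale(raw).astype(self.dtype)
        return plane_x, cae_x

    def predict_logits(self, plane_x, cae_x, batch_size: int = 32) -> np.ndarray:
        n = (plane_x if plane_x is not None else cae_x).shape[0]
        out = []
        for i in range(0, n, batch_size):
            sl = slice(i, i + batch_size)
            logits, _ = self.forward(
                None if plane_x is None else plane_x[sl],
                None if cae_x is None else cae_x[sl], training=False)
            out.append(logits)
        return np.concatenate(out, axis=0)

    def predict(self, plane_x, cae_x, batch_size: int = 32) -> np.ndarray:
        return np.argmax(self.predict_logits(plane_x, cae_x, batch_size), axis=1)


def ablate(cfg: ModelConfig, which: str) -> ModelConfig:
    """Config for the network without one branch (W/o MSSTCN / CAE / LSTM-SA)."""
    if which not in ABLATABLE:
        raise ValueError(f"unknown component {which!r}; choose from {ABLATABLE}")
    new = replace(cfg, ablate_component=which)
    if which == "MSSTCN":
        new = replace(new, attention_dim=cfg.lstm_b_units)
    elif which == "CAE":
        new = replace(new, attention_dim=cfg.lstm_a_units)
    new.validate()
    return new
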