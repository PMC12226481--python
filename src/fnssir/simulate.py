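"""Synthetic force-intensity-variation motor-imagery EEG.

Forward model of the paradigm: each 3-class trial contains two 5-s imagery
segments separated by a 2-s preparation gap, preceded by a 2-s pre-onset
baseline.  The three classes are force-variation sequences

    LMF (0): large -> medium,  LSF (1): large -> small,  MSF (2): medium -> small.

Injected signatures, all force-scaled:

* alpha (10 Hz) and beta (24 Hz) sensorimotor rhythms, spatially Gaussian
  around C3, whose amplitude is multiplicatively suppressed (ERD) during a
  window covering a force-dependent fraction of each imagery segment; deeper
  and spatially wider suppression for larger imagined force;
* a frontocentral negative MRCP transient starting ~0.5 s after each segment
  onset and peaking at ~1 s, more negative for larger force;
* 1/f background noise, and per-trial jitter of ERD onset/duration emulating
  within- and between-subject variability.

The generator echoes its injected parameters (`effect_ground_truth`) so the
analysis and decoding stages can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .plane import project_montage

__all__ = ["SyntheticConfig", "generate_dataset", "generate_subjects",
           "effect_ground_truth", "CLASS_NAMES", "CLASS_FORCES",
           "DEFAULT_CHANNELS"]

CLASS_NAMES = ("LMF", "LSF", "MSF")
CLASS_FORCES = {0: ("large", "medium"), 1: ("large", "small"), 2: ("medium", "small")}

# 30-channel sensorimotor montage (fronto-central through parietal rows)
DEFAULT_CHANNELS = (
    "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
)


@dataclass
class SyntheticConfig:
    n_trials_per_class: int = 42
    fs: float = 100.0
    epoch_s: float = 12.0
    pre_s: float = 2.0                      # baseline before the first MI onset
    mi_segments: tuple = ((0.0, 5.0), (7.0, 12.0))
    channel_names: tuple = DEFAULT_CHANNELS
    erd_depth_db: dict = field(default_factory=lambda: {"large": -6.0, "medium": -4.0, "small": -2.0})
    erd_dur_frac: dict = field(default_factory=lambda: {"large": 1.0, "medium": 0.8, "small": 0.6})
    erd_topo_sigma: float = 1.5             # grid cells, around C3
    erd_extent_scale: dict = field(default_factory=lambda: {"large": 1.2, "medium": 1.0, "small": 0.8})
    mrcp_peak_uv: dict = field(default_factory=lambda: {"large": -8.0, "medium": -5.0, "small": -3.0})
    mrcp_onset_s: float = 0.5
    mrcp_peak_s: float = 1.0
    mrcp_topo_sigma: float = 3.5            # grid cells; the slow potential has a
                                            # broad frontocentral field (FC3..FC4)
    alpha_freq: float = 10.0
    beta_freq: float = 24.0
    alpha_amp_uv: float = 20.0              # rhythm amplitude at C3
    beta_amp_uv: float = 10.0
    carrier_topo_sigma: float = 2.5         # spatial spread of the rhythms
    noise_exponent: float = 1.0             # 1/f^a background slope
    noise_scale_uv: float = 10.0            # background RMS per channel
    subject_jitter: float = 0.25            # SD (s) of ERD onset/duration jitter
    erd_ramp_s: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        for name, d in (("erd_depth_db", self.erd_depth_db),
                        ("mrcp_peak_uv", self.mrcp_peak_uv)):
            if not (d["large"] <= d["medium"] <= d["small"]):
                raise ValueError(f"{name} must be ordered large <= medium <= small "
                                 "(more negative = stronger)")
        if set(CLASS_FORCES) != {0, 1, 2}:
            raise ValueError("class/force mapping is defined for exactly 3 classes")
        for ch in ("C3", "FCz", "FC3"):
            if ch not in self.channel_names:
                raise ValueError(f"montage must include {ch}")

    def null(self) -> "SyntheticConfig":
        """Copy with every injected effect removed (noise + rhythms only)."""
        zero = {"large": 0.0, "medium": 0.0, "small": 0.0}
        return replace(self, erd_depth_db=dict(zero), mrcp_peak_uv=dict(zero))


def _grid_coords(channel_names) -> np.ndarray:
    """Continuous electrode positions in 9x9-grid cell units (row, col)."""
    pts = project_montage(channel_names)
    out = np.empty_like(pts)
    for axis, extent in ((0, 8.0), (1, 8.0)):
        lo, hi = pts[:, axis].min(), pts[:, axis].max()
        span = hi - lo
        out[:, axis] = extent / 2 if span == 0 else (pts[:, axis] - lo) / span * extent
    return out


def _spatial_gauss(coords: np.ndarray, center: np.ndarray, sigma: float) -> np.ndarray:
    d2 = np.sum((coords - center) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * sigma ** 2))


def _one_over_f(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                exponent: float, rms: float) -> np.ndarray:
    white = rng.standard_normal((n_ch, n))
    spec = np.fft.rfft(white, axis=-1)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n, axis=-1)
    x *= rms / np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x


def _erd_gain(t: np.ndarray, on: float, off: float, depth_db: float,
              ramp: float) -> np.ndarray:
    """Smooth multiplicative gain profile: 1 outside [on, off], 10^(d/20) inside."""
    g_min = 10.0 ** (depth_db / 20.0)
    prof = np.zeros_like(t)
    if off > on:
        rise = np.clip((t - on) / max(ramp, 1e-9), 0.0, 1.0)
        fall = np.clip((off - t) / max(ramp, 1e-9), 0.0, 1.0)
        prof = np.minimum(rise, fall)
        prof = 0.5 - 0.5 * np.cos(np.pi * prof)  # raised-cosine edges
    return 1.0 + (g_min - 1.0) * prof


def _mrcp_bump(t: np.ndarray, onset: float, peak: float, amp: float) -> np.ndarray:
    """Half-cosine (sin^2) transient from `onset`, peaking at `peak`, width symmetric."""
    half = peak - onset
    tau = (t - onset) / (2.0 * half)
    prof = np.where((tau >= 0) & (tau <= 1), np.sin(np.pi * np.clip(tau, 0, 1)) ** 2, 0.0)
    return amp * prof


def _simulate(cfg: SyntheticConfig, rng: np.random.Generator,
              subject_bias: tuple[float, float] = (0.0, 0.0),
              subject_id: str = "S00") -> EpochSet:
    cfg.validate()
    names = list(cfg.channel_names)
    n_ch = len(names)
    n = int(round((cfg.pre_s + cfg.epoch_s) * cfg.fs))
    t = -cfg.pre_s + np.arange(n) / cfg.fs
    coords = _grid_coords(names)
    c3 = coords[names.index("C3")]
    mrcp_center = 0.5 * (coords[names.index("FCz")] + coords[names.index("C3")])
    carrier_w = _spatial_gauss(coords, c3, cfg.carrier_topo_sigma)
    mrcp_w = _spatial_gauss(coords, mrcp_center, cfg.mrcp_topo_sigma)

    labels = np.repeat(np.arange(3), cfg.n_trials_per_class)
    rng.shuffle(labels)
    data = np.empty((labels.size, n_ch, n))
    onset_bias, dur_bias = subject_bias

    for k, cls in enumerate(labels):
        x = _one_over_f(rng, n_ch, n, cfg.fs, cfg.noise_exponent, cfg.noise_scale_uv)
        # per-trial timing jitter (shared across bands/channels)
        jit_on = onset_bias + rng.normal(0.0, cfg.subject_jitter)
        jit_dur = dur_bias + rng.normal(0.0, cfg.subject_jitter)
        forces = CLASS_FORCES[int(cls)]
        # ERD spatial depth profile per segment
        seg_windows = []
        for (s0, s1), force in zip(cfg.mi_segments, forces):
            seg_len = s1 - s0
            on = s0 + np.clip(jit_on, 0.0, 0.3 * seg_len)
            dur = np.clip(cfg.erd_dur_frac[force] * seg_len + jit_dur,
                          0.2 * seg_len, seg_len - (on - s0))
            seg_windows.append((on, on + dur, force))
        for f0, amp in ((cfg.alpha_freq, cfg.alpha_amp_uv),
                        (cfg.beta_freq, cfg.beta_amp_uv)):
            phase = rng.uniform(0, 2 * np.pi)
            carrier = np.cos(2 * np.pi * f0 * t + phase)
            # per-channel gain: depth attenuated away from C3, extent force-scaled
            gain = np.ones((n_ch, n))
            for on, off, force in seg_windows:
                sigma = cfg.erd_topo_sigma * cfg.erd_extent_scale[force]
                depth_ch = cfg.erd_depth_db[force] * _spatial_gauss(coords, c3, sigma)
                for ci in range(n_ch):
                    if carrier_w[ci] < 1e-3:
                        continue
                    gain[ci] *= _erd_gain(t, on, off, depth_ch[ci], cfg.erd_ramp_s)
            x += (amp * carrier_w)[:, None] * gain * carrier[None, :]
        # MRCP transient after each segment onset
        for (s0, _), force in zip(cfg.mi_segments, forces):
            bump = _mrcp_bump(t, s0 + cfg.mrcp_onset_s,
                              s0 + cfg.mrcp_peak_s, cfg.mrcp_peak_uv[force])
            x += mrcp_w[:, None] * bump[None, :]
        data[k] = x

    # baseline-correct to the 1-s pre-onset window, as the preprocessing would
    b0, b1 = int(round((cfg.pre_s - 1.0) * cfg.fs)), int(round(cfg.pre_s * cfg.fs))
    data -= data[:, :, b0:b1].mean(axis=2, keepdims=True)
    return EpochSet(data, labels, names, cfg.fs, t0=-cfg.pre_s, subject_id=subject_id)


def generate_dataset(cfg: SyntheticConfig | None = None) -> EpochSet:
    """One synthetic recording session: 3 * n_trials_per_class labelled epochs."""
    cfg = cfg or SyntheticConfig()
    return _simulate(cfg, np.random.default_rng(cfg.seed))


def generate_subjects(cfg: SyntheticConfig | None = None, n_subjects: int = 3
                      ) -> list[EpochSet]:
    """Independent subjects sharing the paradigm but with systematic ERD
    onset/duration offsets, for leave-one-subject-out evaluation."""
    cfg = cfg or SyntheticConfig()
    root = np.random.default_rng(cfg.seed)
    out = []
    for s in range(n_subjects):
        bias = (root.normal(0.0, cfg.subject_jitter),
                root.normal(0.0, cfg.subject_jitter))
        out.append(_simulate(cfg, np.random.default_rng(root.integers(2 ** 31)),
                             subject_bias=bias, subject_id=f"S{s + 1:02d}"))
    return out


def effect_ground_truth(cfg: SyntheticConfig | None = None) -> pd.DataFrame:
    """The injected per-class, per-segment effect parameters (recovery targets)."""
    cfg = cfg or SyntheticConfig()
    rows = []
    for cls, forces in CLASS_FORCES.items():
        for seg, force in enumerate(forces):
            rows.append({
                "class": cls, "class_name": CLASS_NAMES[cls], "segment": seg,
                "force": force,
                "erd_depth_db": cfg.erd_depth_db[force],
                "erd_dur_frac": cfg.erd_dur_frac[force],
                "mrcp_peak_uv": cfg.mrcp_peak_uv[force],
            })
    return pd.DataFrame(rows)
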