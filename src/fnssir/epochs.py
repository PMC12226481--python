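"""EEG epoch container, preprocessing chain, and on-disk I/O.

The preprocessing chain mirrors the standard offline pipeline for sensorimotor
motor-imagery studies: zero-phase FIR bandpass (0.1-30 Hz), common average
reference, decimation to 100 Hz, 12-s epoching around the first imagery onset,
and baseline correction against the 1-s pre-onset window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import h5py
import numpy as np
import pandas as pd
from fractions import Fraction

__all__ = [
    "EpochSet",
    "PreprocessConfig",
    "FormatError",
    "bandpass_fir",
    "common_average_reference",
    "resample_to",
    "extract_epochs",
    "crop",
    "read_epochs",
    "write_epochs",
    "read_raw_continuous",
    "epochs_from_raw",
    "preprocess_continuous",
]


class FormatError(ValueError):
    """Raised when an on-disk epoch container violates the documented layout."""


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``data`` is [n_trials, n_channels, n_samples] in uV.

    ``t0`` is the epoch start in seconds relative to the first motor-imagery
    onset (t = 0), so sample ``i`` covers time ``[t0 + i/fs, t0 + (i+1)/fs)``.
    """

    data: np.ndarray
    labels: np.ndarray
    channel_names: list[str]
    fs: float
    t0: float = 0.0
    subject_id: str = "S00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.channel_names = [str(c) for c in self.channel_names]
        self.validate()

    def validate(self) -> None:
        if self.data.ndim != 3:
            raise FormatError("data must be [n_trials, n_channels, n_samples]")
        if not np.all(np.isfinite(self.data)):
            raise FormatError("data contains non-finite values")
        if self.labels.shape != (self.data.shape[0],):
            raise FormatError("labels length must equal n_trials")
        if self.labels.size and self.labels.min() < 0:
            raise FormatError("labels must be non-negative class indices")
        if len(self.channel_names) != self.data.shape[1]:
            raise FormatError("channel_names length must equal n_channels")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise FormatError("channel_names must be unique")
        if self.fs <= 0:
            raise FormatError("fs must be positive")

    # -- convenience ---------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs "
                           f"(have {', '.join(self.channel_names)})") from None

    def get_channel(self, name: str) -> np.ndarray:
        """[n_trials, n_samples] view of one electrode."""
        return self.data[:, self.channel_index(name), :]

    def select_trials(self, idx: np.ndarray) -> "EpochSet":
        return replace(self, data=self.data[idx], labels=self.labels[idx])

    def select_classes(self, classes) -> "EpochSet":
        mask = np.isin(self.labels, np.atleast_1d(classes))
        return self.select_trials(np.flatnonzero(mask))


@dataclass
class PreprocessConfig:
    band_lo: float = 0.1
    band_hi: float = 30.0
    fir_order: int | None = None   # None -> automatic (transition width <= band_lo)
    target_fs: float = 100.0
    epoch_window: tuple[float, float] = (0.0, 12.0)
    baseline_window: tuple[float, float] = (-1.0, 0.0)

    def validate(self, fs: float | None = None) -> None:
        if not (0 < self.band_lo < self.band_hi):
            raise ValueError("need 0 < band_lo < band_hi")
        nyq = (fs if fs is not None else self.target_fs) / 2.0
        if self.band_hi >= nyq:
            raise ValueError(f"band_hi {self.band_hi} Hz is at/above Nyquist {nyq} Hz")
        if self.epoch_window[0] >= self.epoch_window[1]:
            raise ValueError("epoch_window start must precede end")


def bandpass_fir(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Zero-phase Hamming-window FIR bandpass, applied per channel.

    ``x`` is [..., n_samples]; the filter order defaults to the automatic
    choice with transition widths no wider than the low band edge.
    """
    import mne

    cfg = cfg or PreprocessConfig()
    cfg.validate(fs=fs)
    length = "auto" if cfg.fir_order is None else int(cfg.fir_order)
    x64 = np.ascontiguousarray(np.asarray(x, dtype=np.float64))
    # transition width <= band_lo (a 0.1 Hz edge therefore needs a ~33 s
    # impulse response: filter continuous recordings, not short epochs)
    l_trans = min(cfg.band_lo, 2.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = mne.filter.filter_data(
            x64, sfreq=fs, l_freq=cfg.band_lo, h_freq=cfg.band_hi,
            filter_length=length, l_trans_bandwidth=l_trans,
            h_trans_bandwidth="auto", method="fir", phase="zero",
            fir_window="hamming", verbose=False,
        )
    return out


def common_average_reference(x: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous mean across channels (axis -2)."""
    x = np.asarray(x)
    if x.shape[-2] < 2:
        raise ValueError("common average reference needs at least 2 channels")
    return x - x.mean(axis=-2, keepdims=True)


def resample_to(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase anti-aliased resampling along the last axis."""
    if fs_out <= 0:
        raise ValueError("fs_out must be positive")
    if fs_out > fs_in:
        raise ValueError("only downsampling (fs_out <= fs_in) is supported")
    if fs_out == fs_in:
        return np.asarray(x).copy()
    from scipy.signal import resample_poly

    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    return resample_poly(np.asarray(x, dtype=np.float64), frac.numerator,
                         frac.denominator, axis=-1)


def extract_epochs(
    x: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    cfg: PreprocessConfig | None = None,
    labels: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    subject_id: str = "S00",
) -> EpochSet:
    """Cut epochs around the given onset samples and baseline-correct them.

    Each epoch covers ``cfg.epoch_window`` (seconds, half-open) relative to its
    onset; the per-channel mean of ``cfg.baseline_window`` is subtracted.  When
    the baseline window extends before the epoch window, the epoch is widened
    to include it (so the generator's default [-1, 0) baseline is part of the
    stored epoch whenever epoch_window starts at 0 or earlier).
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("continuous signal must be [n_channels, n_samples]")
    n_ch, n_samp = x.shape
    t_start = min(cfg.epoch_window[0], cfg.baseline_window[0])
    t_end = cfg.epoch_window[1]
    i0 = int(round(t_start * fs))
    n_len = int(round((t_end - t_start) * fs))
    b0 = int(round((cfg.baseline_window[0] - t_start) * fs))
    b1 = int(round((cfg.baseline_window[1] - t_start) * fs))
    epochs = np.empty((len(onsets), n_ch, n_len))
    for k, onset in enumerate(np.asarray(onsets, dtype=np.int64)):
        lo, hi = onset + i0, onset + i0 + n_len
        if lo < 0 or hi > n_samp:
            raise IndexError(
                f"trial {k}: epoch window [{lo}, {hi}) outside recording of "
                f"{n_samp} samples")
        seg = x[:, lo:hi]
        base = seg[:, b0:b1].mean(axis=1, keepdims=True) if b1 > b0 else 0.0
        epochs[k] = seg - base
    if labels is None:
        labels = np.zeros(len(onsets), dtype=np.int64)
    if channel_names is None:
        channel_names = [f"CH{i}" for i in range(n_ch)]
    return EpochSet(epochs, labels, channel_names, fs, t0=t_start,
                    subject_id=subject_id)


def crop(epochs: EpochSet, tmin: float, tmax: float) -> EpochSet:
    """Restrict epochs to the half-open time window [tmin, tmax)."""
    i0 = int(round((tmin - epochs.t0) * epochs.fs))
    i1 = int(round((tmax - epochs.t0) * epochs.fs))
    if i0 < 0 or i1 > epochs.n_samples or i0 >= i1:
        raise ValueError(f"crop window [{tmin}, {tmax}) outside epoch "
                         f"[{epochs.t0}, {epochs.t0 + epochs.n_samples / epochs.fs})")
    return replace(epochs, data=epochs.data[:, :, i0:i1], t0=tmin)


def preprocess_continuous(
    x: np.ndarray,
    fs: float,
    onsets: np.ndarray,
    cfg: PreprocessConfig | None = None,
    labels: np.ndarray | None = None,
    channel_names: list[str] | None = None,
    subject_id: str = "S00",
) -> EpochSet:
    """Full chain: FIR bandpass -> CAR -> downsample -> epoch + baseline."""
    cfg = cfg or PreprocessConfig()
    y = bandpass_fir(x, fs, cfg)
    y = common_average_reference(y)
    y = resample_to(y, fs, cfg.target_fs)
    scale = cfg.target_fs / fs
    new_onsets = np.round(np.asarray(onsets) * scale).astype(np.int64)
    return extract_epochs(y, cfg.target_fs, new_onsets, cfg, labels=labels,
                          channel_names=channel_names, subject_id=subject_id)


# ---------------------------------------------------------------------------
# On-disk container: HDF5 with datasets `data` (float32, uV) and `labels`
# (int16), root attributes `fs`, `t0`, `subject_id`, `channel_names`.
# ---------------------------------------------------------------------------

def write_epochs(path, epochs: EpochSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32),
                         track_times=False)
        f.create_dataset("labels", data=epochs.labels.astype(np.int16),
                         track_times=False)
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["t0"] = float(epochs.t0)
        f.attrs["subject_id"] = epochs.subject_id
        f.attrs["channel_names"] = [np.bytes_(c.encode()) for c in epochs.channel_names]


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        for name in ("data", "labels"):
            if name not in f:
                raise FormatError(f"missing dataset {name!r} in {path}")
        for attr in ("fs", "t0", "channel_names"):
            if attr not in f.attrs:
                raise FormatError(f"missing attribute {attr!r} in {path}")
        names = [c.decode() if isinstance(c, bytes) else str(c)
                 for c in f.attrs["channel_names"]]
        try:
            return EpochSet(
                data=f["data"][()].astype(np.float64),
                labels=f["labels"][()],
                channel_names=names,
                fs=float(f.attrs["fs"]),
                t0=float(f.attrs["t0"]),
                subject_id=str(f.attrs.get("subject_id", "S00")),
            )
        except FormatError:
            raise
        except ValueError as e:  # pragma: no cover - defensive
            raise FormatError(str(e)) from e


# ---------------------------------------------------------------------------
# Optional import from standard continuous-EEG files (EDF / GDF).
# ---------------------------------------------------------------------------

def read_raw_continuous(path):
    """Read an EDF/GDF recording; returns (data [n_ch, n_samp] uV, fs, names)."""
    import mne

    p = str(path)
    if p.lower().endswith(".edf"):
        raw = mne.io.read_raw_edf(p, preload=True, verbose=False)
    elif p.lower().endswith(".gdf"):
        raw = mne.io.read_raw_gdf(p, preload=True, verbose=False)
    else:
        raise FormatError(f"unsupported continuous format: {p}")
    return raw.get_data() * 1e6, float(raw.info["sfreq"]), list(raw.ch_names)


def epochs_from_raw(path, events_csv, cfg: PreprocessConfig | None = None,
                    subject_id: str = "S00") -> EpochSet:
    """Epoch a continuous EDF/GDF file using a CSV events table.

    The events table has columns ``onset_sample`` (in the file's native rate)
    and ``label``.
    """
    data, fs, names = read_raw_continuous(path)
    ev = pd.read_csv(events_csv)
    for col in ("onset_sample", "label"):
        if col not in ev.columns:
            raise FormatError(f"events table lacks column {col!r}")
    return preprocess_continuous(
        data, fs, ev["onset_sample"].to_numpy(), cfg,
        labels=ev["label"].to_numpy(), channel_names=names,
        subject_id=subject_id)
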