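"""Event-related spectral perturbation (ERSP), band power, topography, MRCP.

Power is estimated by complex Morlet decomposition (cycles = max(3, f/2)).
The canonical ERSP output is trial-averaged power converted to dB relative to
the mean pre-onset baseline power of each frequency:

    ERSP(f, t) = 10 * log10( P(f, t) / P_base(f) ),
    P(f, t) = (1/n) * sum_k |F_k(f, t)|^2.

Raw mean power is available via ``db=False``.  Epochs are mirror-padded by
1 s before the wavelet transform to limit edge bias; the outermost ~0.5 s of
any map should still be treated as unreliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .epochs import EpochSet

__all__ = ["ERSPMap", "BandSummary", "tf_power", "ersp", "band_curve",
           "topography", "mrcp_average", "ALPHA_BAND", "BETA_BAND",
           "BETA_NARROW_BAND", "DEFAULT_FREQS", "DEFAULT_BASELINE"]

ALPHA_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 30.0)
BETA_NARROW_BAND = (22.0, 27.0)   # narrow beta range used for time curves
DEFAULT_FREQS = np.arange(8.0, 31.0, 1.0)
DEFAULT_BASELINE = (-2.0, 0.0)
_EDGE_PAD_S = 1.0


@dataclass
class ERSPMap:
    values: np.ndarray           # [n_freqs, n_times], dB (or raw power)
    freqs: np.ndarray
    times: np.ndarray
    channel: str
    baseline_window: tuple[float, float]
    db: bool = True


@dataclass
class BandSummary:
    band: tuple[float, float]
    window: tuple[float, float]
    per_channel_db: dict[str, float]
    per_time_db: np.ndarray | None = None
    times: np.ndarray | None = None


def _n_cycles(freqs: np.ndarray) -> np.ndarray:
    return np.maximum(3.0, np.asarray(freqs) / 2.0)


def tf_power(x: np.ndarray, fs: float, freqs) -> np.ndarray:
    """Instantaneous power of single-channel trials via complex Morlet wavelets.

    ``x`` is [n_trials, n_samples] (or [n_samples]); returns
    [n_trials, n_freqs, n_samples] (or [n_freqs, n_samples]).
    """
    from mne.time_frequency import tfr_array_morlet

    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs >= fs / 2.0):
        raise ValueError(f"frequencies must be below Nyquist ({fs / 2} Hz)")
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    n = x.shape[-1]
    pad = min(int(round(_EDGE_PAD_S * fs)), n - 1)
    xp = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        power = tfr_array_morlet(xp[:, None, :], sfreq=fs, freqs=freqs,
                                 n_cycles=_n_cycles(freqs), output="power",
                                 zero_mean=True, verbose=False)
    power = power[:, 0, :, pad:pad + n]
    return power[0] if single else power


def ersp(epochs: EpochSet, channel: str, freqs=DEFAULT_FREQS,
         baseline_window: tuple[float, float] = DEFAULT_BASELINE,
         db: bool = True) -> ERSPMap:
    """Trial-averaged time-frequency power, optionally baselined in dB."""
    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    x = epochs.get_channel(channel)
    power = tf_power(x, epochs.fs, freqs).mean(axis=0)  # [n_freqs, n_times]
    times = epochs.times
    if db:
        b0, b1 = baseline_window
        mask = (times >= b0) & (times < b1)
        if not mask.any():
            raise ValueError(f"baseline window {baseline_window} outside epoch "
                             f"[{times[0]}, {times[-1]}]")
        base = power[:, mask].mean(axis=1, keepdims=True)
        values = 10.0 * np.log10(power / base)
    else:
        values = power
    return ERSPMap(values, freqs, times, channel, baseline_window, db=db)


def band_curve(tf_map: ERSPMap, band: tuple[float, float]) -> np.ndarray:
    """Mean over the frequency rows inside ``band`` (inclusive), per time point."""
    lo, hi = band
    rows = (tf_map.freqs >= lo) & (tf_map.freqs <= hi)
    if not rows.any():
        raise ValueError(f"band {band} contains none of the map frequencies")
    return tf_map.values[rows].mean(axis=0)


def topography(epochs: EpochSet, band: tuple[float, float] = ALPHA_BAND,
               window: tuple[float, float] = (0.0, 12.0),
               baseline_window: tuple[float, float] = DEFAULT_BASELINE,
               channels=None) -> BandSummary:
    """Per-channel mean ERSP (dB) over a band x time window, for scalp maps."""
    names = list(channels) if channels is not None else epochs.channel_names
    freqs = np.arange(np.ceil(band[0]), np.floor(band[1]) + 1.0)
    w0, w1 = window
    per_channel = {}
    for name in names:
        m = ersp(epochs, name, freqs=freqs, baseline_window=baseline_window)
        tmask = (m.times >= w0) & (m.times < w1)
        if not tmask.any():
            raise ValueError(f"window {window} outside epoch")
        per_channel[name] = float(band_curve(m, band)[tmask].mean())
    return BandSummary(band=band, window=window, per_channel_db=per_channel)


def mrcp_average(epochs: EpochSet, channel: str = "FC3", lowpass_hz: float = 5.0,
                 per_class: bool = True):
    """Trial-averaged low-pass (<= lowpass_hz) waveform, baselined to pre-onset.

    Returns ``(times, {class: waveform})`` when ``per_class`` else
    ``(times, waveform)``.  Averaging across trials suppresses the broadband
    background so the slow negative movement-related potential emerges.
    """
    import mne

    if epochs.n_trials < 1:
        raise ValueError("need at least one trial")
    x = epochs.get_channel(channel)
    times = epochs.times

    def _avg(trials: np.ndarray) -> np.ndarray:
        w = trials.mean(axis=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            w = mne.filter.filter_data(w.astype(np.float64), sfreq=epochs.fs,
                                       l_freq=None, h_freq=lowpass_hz,
                                       verbose=False)
        pre = (times >= max(times[0], -1.0)) & (times < 0.0)
        return w - (w[pre].mean() if pre.any() else w.mean())

    if not per_class:
        return times, _avg(x)
    return times, {int(c): _avg(x[epochs.labels == c])
                   for c in np.unique(epochs.labels)}
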