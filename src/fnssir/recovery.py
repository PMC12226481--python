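"""Parameter recovery: measure injected ERD/MRCP signatures back from data.

These routines close the loop between the generator and the analysis stack:
the generator injects known per-force effect sizes, and the functions here
estimate them from the simulated epochs with the same pipeline a study would
apply to real recordings (per-class ERSP band curves at C3, per-class
trial-averaged MRCP at FC3).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .epochs import EpochSet
from .ersp import ALPHA_BAND, band_curve, ersp, mrcp_average
from .simulate import CLASS_FORCES, CLASS_NAMES, SyntheticConfig

__all__ = ["recover_erd_depths", "recover_mrcp", "mrcp_field_weight"]


def recover_erd_depths(epochs: EpochSet, cfg: SyntheticConfig,
                       channel: str = "C3",
                       band: tuple[float, float] = ALPHA_BAND) -> pd.DataFrame:
    """Per (class, segment) mean band ERSP during the injected ERD window.

    The measurement window starts 0.75 s after the segment onset (clear of
    the onset ramp and jitter) and ends 0.5 s before the injected ERD
    offset, so the estimate reflects the plateau depth.
    """
    freqs = np.arange(np.floor(band[0]), np.ceil(band[1]) + 1.0)
    rows = []
    for cls in range(3):
        m = ersp(epochs.select_classes(cls), channel, freqs=freqs)
        curve = band_curve(m, band)
        for seg, (s0, s1) in enumerate(cfg.mi_segments):
            force = CLASS_FORCES[cls][seg]
            w0 = s0 + 0.75
            w1 = s0 + cfg.erd_dur_frac[force] * (s1 - s0) - 0.5
            mask = (m.times >= w0) & (m.times < w1)
            rows.append({
                "class": cls, "class_name": CLASS_NAMES[cls], "segment": seg,
                "force": force,
                "injected_db": cfg.erd_depth_db[force],
                "recovered_db": float(curve[mask].mean()),
            })
    return pd.DataFrame(rows)


def mrcp_field_weight(cfg: SyntheticConfig, channel: str = "FC3") -> float:
    """Injected spatial attenuation of the MRCP field at ``channel``."""
    from .simulate import _grid_coords, _spatial_gauss

    names = list(cfg.channel_names)
    coords = _grid_coords(names)
    center = 0.5 * (coords[names.index("FCz")] + coords[names.index("C3")])
    return float(_spatial_gauss(coords, center, cfg.mrcp_topo_sigma)
                 [names.index(channel)])


def recover_mrcp(epochs: EpochSet, cfg: SyntheticConfig,
                 channel: str = "FC3") -> pd.DataFrame:
    """Per-class minimum of the averaged slow waveform after the first onset.

    Searches [0.25, 1.75] s around the expected transient; ``grand_min_time``
    rows carry the timing of the all-trial average (the most stable timing
    estimate).
    """
    times, waves = mrcp_average(epochs, channel)
    _, grand = mrcp_average(epochs, channel, per_class=False)
    search = (times >= 0.25) & (times < 1.75)
    t_search = times[search]
    w = mrcp_field_weight(cfg, channel)
    rows = []
    for cls in range(3):
        force = CLASS_FORCES[cls][0]
        wave = waves[cls][search]
        k = int(np.argmin(wave))
        rows.append({
            "class": cls, "class_name": CLASS_NAMES[cls], "force": force,
            "injected_uv": cfg.mrcp_peak_uv[force],
            "injected_at_channel_uv": cfg.mrcp_peak_uv[force] * w,
            "recovered_min_uv": float(wave[k]),
            "recovered_min_time_s": float(t_search[k]),
            "grand_min_time_s": float(t_search[int(np.argmin(grand[search]))]),
        })
    return pd.DataFrame(rows)
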