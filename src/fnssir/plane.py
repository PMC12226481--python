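"""Electrode-plane construction and distance-based interpolation (DBI).

Scalp electrodes named by the 10-20/10-10 system are projected onto a 2D
plane (azimuthal-equidistant projection of their spherical coordinates) and
snapped to an H x W grid that mirrors the layout of topographic maps.  Vacant
grid cells inside the electrode convex hull are filled by inverse-distance
weighting over the nearest placed electrodes; cells outside the hull are
zero.  The result is the 3D input tensor X in R^{1 x H x W x T} consumed by
the multi-scale spatial-temporal convolution branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .epochs import EpochSet

__all__ = ["GridMap", "PlaneTensor", "load_montage", "project_montage",
           "build_grid", "to_plane", "DEFAULT_GRID_SHAPE"]

DEFAULT_GRID_SHAPE = (9, 9)
_N_NEIGHBOURS = 4  # placed electrodes contributing to each vacant cell


def load_montage(path=None) -> pd.DataFrame:
    """Load the spherical-coordinate table (columns channel, theta, phi; degrees)."""
    if path is None:
        with resources.files("fnssir.data").joinpath("montage_1020.csv").open() as f:
            table = pd.read_csv(f, comment="#")
    else:
        table = pd.read_csv(path, comment="#")
    missing = {"channel", "theta", "phi"} - set(table.columns)
    if missing:
        raise ValueError(f"montage table lacks columns {sorted(missing)}")
    return table


def project_montage(channel_names, montage: pd.DataFrame | None = None) -> np.ndarray:
    """Azimuthal-equidistant projection: (y anterior->posterior, x left->right)."""
    table = montage if montage is not None else load_montage()
    coords = {str(r.channel): (float(r.theta), float(r.phi))
              for r in table.itertuples()}
    pts = np.empty((len(channel_names), 2))
    for i, name in enumerate(channel_names):
        if name not in coords:
            raise KeyError(f"channel {name!r} not in montage coordinate table")
        theta, phi = coords[name]
        rho = theta  # arc length from vertex, in degrees
        # y grows toward posterior so that row 0 is frontal, as in topo maps
        pts[i] = (-rho * np.cos(np.deg2rad(phi)), rho * np.sin(np.deg2rad(phi)))
    return pts


@dataclass
class GridMap:
    """Assignment of named electrodes to grid cells plus interpolation weights."""

    shape: tuple[int, int]
    placed: dict[str, tuple[int, int]]
    weights: dict[tuple[int, int], list[tuple[str, float]]]
    outside_mask: np.ndarray  # [H, W] bool, True where outside the hull

    def validate(self) -> None:
        cells = list(self.placed.values())
        if len(set(cells)) != len(cells):
            raise ValueError("two channels share a grid cell")
        for cell, wl in self.weights.items():
            total = sum(w for _, w in wl)
            if not np.isclose(total, 1.0):
                raise ValueError(f"weights at cell {cell} sum to {total}")
            if any(w < 0 for _, w in wl):
                raise ValueError(f"negative weight at cell {cell}")
            if self.outside_mask[cell]:
                raise ValueError(f"outside cell {cell} carries weights")

    def to_json(self) -> str:
        return json.dumps({
            "shape": list(self.shape),
            "placed": {ch: list(rc) for ch, rc in self.placed.items()},
            "weights": {f"{r},{c}": [[ch, w] for ch, w in wl]
                        for (r, c), wl in self.weights.items()},
            "outside_mask": self.outside_mask.astype(int).tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GridMap":
        d = json.loads(text)
        weights = {tuple(int(v) for v in k.split(",")): [(ch, float(w)) for ch, w in wl]
                   for k, wl in d["weights"].items()}
        return cls(tuple(d["shape"]), {ch: tuple(rc) for ch, rc in d["placed"].items()},
                   weights, np.asarray(d["outside_mask"], dtype=bool))


def build_grid(channel_names, shape: tuple[int, int] = DEFAULT_GRID_SHAPE,
               montage: pd.DataFrame | None = None) -> GridMap:
    """Snap projected electrodes to an H x W grid and precompute DBI weights.

    Vacant cells inside the electrode convex hull receive inverse-distance
    weights (power 1) over the ``_N_NEIGHBOURS`` nearest placed electrodes;
    a cell coincident with an electrode copies it exactly.
    """
    from scipy.spatial import Delaunay

    channel_names = list(channel_names)
    if len(set(channel_names)) != len(channel_names):
        raise ValueError("duplicate channel names")
    H, W = shape
    pts = project_montage(channel_names, montage)
    # normalize each axis to span the grid exactly
    grid_pos = np.empty_like(pts)
    for axis, extent in ((0, H - 1), (1, W - 1)):
        lo, hi = pts[:, axis].min(), pts[:, axis].max()
        span = hi - lo
        grid_pos[:, axis] = extent / 2.0 if span == 0 else (pts[:, axis] - lo) / span * extent

    placed: dict[str, tuple[int, int]] = {}
    for name, (r, c) in zip(channel_names, np.round(grid_pos).astype(int)):
        cell = (int(r), int(c))
        if cell in placed.values():
            other = next(ch for ch, rc in placed.items() if rc == cell)
            raise ValueError(
                f"channels {other!r} and {name!r} snap to the same cell {cell}; "
                f"use a larger grid shape than {shape}")
        placed[name] = cell

    # convex hull membership via Delaunay triangulation of the placed points;
    # degenerate sets (< 3 points or collinear) fall back to the bounding box
    tri = None
    if len(channel_names) >= 3:
        from scipy.spatial import QhullError
        try:
            tri = Delaunay(grid_pos)
        except QhullError:
            tri = None
    bbox = (grid_pos.min(axis=0) - 1e-9, grid_pos.max(axis=0) + 1e-9)
    outside = np.ones(shape, dtype=bool)
    weights: dict[tuple[int, int], list[tuple[str, float]]] = {}
    occupied = set(placed.values())
    k = min(_N_NEIGHBOURS, len(channel_names))
    for r in range(H):
        for c in range(W):
            p = np.array([r, c], dtype=float)
            if tri is not None:
                inside = bool(tri.find_simplex(p) >= 0)
            else:
                inside = bool(np.all(p >= bbox[0]) and np.all(p <= bbox[1]))
            if (r, c) in occupied:
                outside[r, c] = False
                continue
            if not inside:
                continue
            outside[r, c] = False
            d = np.linalg.norm(grid_pos - p, axis=1)
            exact = np.flatnonzero(d < 1e-9)
            if exact.size:
                weights[(r, c)] = [(channel_names[exact[0]], 1.0)]
                continue
            nearest = np.argsort(d, kind="stable")[:k]
            inv = 1.0 / d[nearest]
            inv /= inv.sum()
            weights[(r, c)] = [(channel_names[i], float(w))
                               for i, w in zip(nearest, inv)]
    grid = GridMap((H, W), placed, weights, outside)
    grid.validate()
    return grid


@dataclass
class PlaneTensor:
    """Per-trial 1 x H x W x T stack of electrode-plane frames."""

    values: np.ndarray  # [n_trials, 1, H, W, T]
    grid: GridMap
    fs: float


def interpolation_matrix(grid: GridMap, channel_names) -> np.ndarray:
    """[H*W, n_channels] linear map from channel signals to grid-cell signals."""
    H, W = grid.shape
    idx = {name: i for i, name in enumerate(channel_names)}
    M = np.zeros((H * W, len(channel_names)))
    for name, (r, c) in grid.placed.items():
        if name not in idx:
            raise KeyError(f"grid channel {name!r} missing from epochs")
        M[r * W + c, idx[name]] = 1.0
    for (r, c), wl in grid.weights.items():
        for name, w in wl:
            M[r * W + c, idx[name]] += w
    return M


def to_plane(epochs: EpochSet, grid: GridMap, dtype=np.float32) -> PlaneTensor:
    """Map an EpochSet onto the electrode plane.

    Placed cells copy their electrode's signal exactly; vacant in-hull cells
    are convex combinations of their neighbours; outside-hull cells are zero.
    """
    H, W = grid.shape
    M = interpolation_matrix(grid, epochs.channel_names)
    flat = np.tensordot(M, epochs.data, axes=([1], [1]))  # [H*W, n, T]
    values = np.ascontiguousarray(
        flat.reshape(H, W, epochs.n_trials, epochs.n_samples)
            .transpose(2, 0, 1, 3)[:, None], dtype=dtype)
    return PlaneTensor(values, grid, epochs.fs)
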