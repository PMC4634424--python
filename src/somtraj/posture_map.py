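"""Basic posture units: U-matrix, watershed basins and shallow-basin merging.

A trained map is summarised by its U-matrix (per-neuron mean weight distance
to the 8-connected grid neighbors, min-max normalized).  Watershed flooding
from the regional minima of the U-matrix partitions the grid into catchment
basins; each basin is one basic posture unit.  Shallow basins — those whose
lowest boundary saddle rises less than ``depth_frac`` above their own minimum
— are merged into the neighbor across that saddle, which counters the usual
watershed over-segmentation.  The representative posture of a basin is the
weight vector of its minimum-U neuron.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from skimage.morphology import local_minima
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .som import SOMGrid, find_winner

__all__ = [
    "DEFAULT_DEPTH_FRAC",
    "PostureMap",
    "compute_umatrix",
    "watershed_basins",
    "merge_shallow_basins",
    "build_posture_map",
    "assign_basin",
]

DEFAULT_DEPTH_FRAC = 0.05

_NEIGH8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def compute_umatrix(grid: SOMGrid) -> np.ndarray:
    """Mean weight-space distance to the 8 grid neighbors, normalized to [0,1].

    Edge and corner neurons average over their existing neighbors only.  A
    constant surface (e.g. identical weights) is returned as all zeros rather
    than divided by a zero range.
    """
    M, N = grid.M, grid.N
    w = grid.weights.reshape(M, N, -1)
    u = np.zeros((M, N))
    for i in range(M):
        for j in range(N):
            dists = [
                np.linalg.norm(w[i, j] - w[i + di, j + dj])
                for di, dj in _NEIGH8
                if 0 <= i + di < M and 0 <= j + dj < N
            ]
            u[i, j] = np.mean(dists)
    rng = u.max() - u.min()
    if rng <= 0:
        return np.zeros_like(u)
    return (u - u.min()) / rng


def watershed_basins(umatrix: np.ndarray) -> np.ndarray:
    """Marker-controlled watershed of the U-matrix.

    The surface is quantized to 256 gray levels; markers are the 8-connected
    regional minima, and flooding proceeds by increasing height with
    8-connectivity.  Returns an (M, N) int array of labels 1..B covering
    every cell.
    """
    u = np.asarray(umatrix, dtype=float)
    q = np.round(u * 255.0).astype(np.int32)
    minima = local_minima(q, connectivity=2, allow_borders=True)
    markers = cc_label(minima, connectivity=2)
    if markers.max() == 0:  # constant surface: everything is one plateau
        return np.ones_like(q, dtype=int)
    labels = watershed(q, markers=markers, connectivity=2)
    return labels.astype(int)


def _basin_adjacency(labels: np.ndarray, u: np.ndarray):
    """Saddle heights between 8-adjacent basins.

    The saddle between two basins is the minimum over their shared boundary
    of max(u[a], u[b]) for adjacent cell pairs a, b — the lowest height at
    which flooding joins them.
    """
    M, N = labels.shape
    saddles: dict[tuple[int, int], float] = {}
    for i in range(M):
        for j in range(N):
            la = labels[i, j]
            for di, dj in ((0, 1), (1, 0), (1, 1), (1, -1)):  # scan each pair once
                i2, j2 = i + di, j + dj
                if not (0 <= i2 < M and 0 <= j2 < N):
                    continue
                lb = labels[i2, j2]
                if la == lb:
                    continue
                key = (min(la, lb), max(la, lb))
                h = max(u[i, j], u[i2, j2])
                if key not in saddles or h < saddles[key]:
                    saddles[key] = h
    return saddles


def _renumber(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..B in row-major first-appearance order."""
    out = np.zeros_like(labels)
    mapping: dict[int, int] = {}
    for v in labels.ravel():
        if v not in mapping:
            mapping[v] = len(mapping) + 1
    for old, new in mapping.items():
        out[labels == old] = new
    return out


def merge_shallow_basins(
    labels: np.ndarray, umatrix: np.ndarray, depth_frac: float = DEFAULT_DEPTH_FRAC
) -> np.ndarray:
    """Iteratively absorb shallow basins into their deepest-saddle neighbor.

    A basin's depth is its lowest boundary saddle minus its minimum U-value
    (both on the normalized scale).  While any basin has depth < depth_frac,
    the shallowest one is merged into the neighbor sharing its lowest saddle.
    The number of basins never increases; labels are renumbered 1..B.
    """
    if not 0.0 <= depth_frac <= 1.0:
        raise ValueError("depth_frac must be in [0, 1]")
    labels = np.asarray(labels).copy()
    u = np.asarray(umatrix, dtype=float)
    while True:
        ids = np.unique(labels)
        if len(ids) <= 1:
            break
        saddles = _basin_adjacency(labels, u)
        mins = {b: u[labels == b].min() for b in ids}
        # depth and merge partner (lowest saddle, tie -> smaller neighbor id)
        best: dict[int, tuple[float, int]] = {}
        for (a, b), h in sorted(saddles.items()):
            for this, other in ((a, b), (b, a)):
                d = h - mins[this]
                if this not in best or d < best[this][0]:
                    best[this] = (d, other)
        shallow = [(d, b, tgt) for b, (d, tgt) in best.items() if d < depth_frac]
        if not shallow:
            break
        d, b, tgt = min(shallow)  # shallowest first; ties -> smallest label
        labels[labels == b] = tgt
    return _renumber(labels)


@dataclass
class PostureMap:
    """Trained grid plus its partition into basic posture units."""

    grid: SOMGrid
    umatrix: np.ndarray  # (M, N), in [0, 1]
    labeling: np.ndarray  # (M, N), ints 1..B
    representatives: dict[int, np.ndarray]  # basin id -> weight vector

    @property
    def n_units(self) -> int:
        return int(self.labeling.max())

    def to_json(self, path) -> None:
        obj = {
            "M": self.grid.M,
            "N": self.grid.N,
            "weights": self.grid.weights.tolist(),
            "umatrix": self.umatrix.tolist(),
            "labeling": self.labeling.tolist(),
            "representatives": {str(k): v.tolist() for k, v in self.representatives.items()},
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "PostureMap":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            grid=SOMGrid(M=obj["M"], N=obj["N"], weights=np.array(obj["weights"])),
            umatrix=np.array(obj["umatrix"]),
            labeling=np.array(obj["labeling"], dtype=int),
            representatives={int(k): np.array(v) for k, v in obj["representatives"].items()},
        )


def build_posture_map(grid: SOMGrid, data=None, depth_frac: float = DEFAULT_DEPTH_FRAC) -> PostureMap:
    """U-matrix -> watershed -> shallow-basin merge -> representatives.

    ``data`` is accepted for interface symmetry with training but is not
    needed: the representative of each basin is the weight vector of its
    minimum-U neuron (ties -> lowest row-major index).
    """
    u = compute_umatrix(grid)
    labels = watershed_basins(u)
    labels = merge_shallow_basins(labels, u, depth_frac=depth_frac)
    reps: dict[int, np.ndarray] = {}
    flat_u = u.ravel()
    flat_l = labels.ravel()
    for b in np.unique(flat_l):
        members = np.flatnonzero(flat_l == b)
        core = members[np.argmin(flat_u[members])]  # argmin keeps lowest index on ties
        reps[int(b)] = grid.weights[core].copy()
    return PostureMap(grid=grid, umatrix=u, labeling=labels, representatives=reps)


def assign_basin(pmap: PostureMap, x) -> int:
    """Basin id of the winning neuron for ``x``."""
    j = find_winner(pmap.grid, x)
    return int(pmap.labeling.ravel()[j])
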