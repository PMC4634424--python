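"""Kohonen self-organizing map on a rectangular grid.

Training follows the classic online rule: find the Euclidean winner, then pull
every neuron toward the input with a Gaussian lateral-neighborhood weight
exp(-d^2 / (2 sigma^2)), learning rate decaying linearly as
eta(k) = eta0 * (1 - k / n_epochs) with k counted per completed epoch.
Defaults: eta0 = 0.1, n_epochs = 100, sigma = 1.0.

Initialization is a linear map spanning the first two principal directions of
the training data (shrunk to stay inside the data bounding box), with a
seeded-jitter fallback when the data rank is below 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "SOMGrid",
    "TrainingSchedule",
    "initialize_grid",
    "find_winner",
    "update_weights",
    "train",
    "quantization_error",
]


@dataclass
class SOMGrid:
    """M x N neuron grid with one weight vector per neuron (row-major)."""

    M: int
    N: int
    weights: np.ndarray  # (M*N, dim)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.M < 1 or self.N < 1:
            raise ValueError("grid dimensions must be positive")
        if self.weights.shape[0] != self.M * self.N:
            raise ValueError("weights must have M*N rows")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def dim(self) -> int:
        return self.weights.shape[1]

    def grid_coords(self) -> np.ndarray:
        """(M*N, 2) array of (row, col) coordinates, row-major."""
        rows, cols = np.divmod(np.arange(self.M * self.N), self.N)
        return np.stack([rows, cols], axis=1).astype(float)

    def lateral_sqdist(self) -> np.ndarray:
        """(M*N, M*N) squared Euclidean distances between grid coordinates."""
        c = self.grid_coords()
        diff = c[:, None, :] - c[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff)

    def to_json(self, path, schedule: "TrainingSchedule | None" = None) -> None:
        obj = {
            "M": self.M,
            "N": self.N,
            "dim": self.dim,
            "weights": self.weights.tolist(),
        }
        if schedule is not None:
            obj["schedule"] = asdict(schedule)
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SOMGrid":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(M=obj["M"], N=obj["N"], weights=np.array(obj["weights"]))


@dataclass
class TrainingSchedule:
    """Online-training hyperparameters; defaults are the reference settings."""

    eta0: float = 0.1
    n_epochs: int = 100
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.eta0 <= 1.0:
            raise ValueError("eta0 must be in (0, 1]")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def _as_matrix(data) -> np.ndarray:
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2 or arr.shape[0] == 0:
        raise ValueError("data must be a non-empty (n, dim) array")
    return arr


def initialize_grid(data, M: int, N: int, seed: int = 0) -> SOMGrid:
    """Linear (PCA-plane) initialization inside the data bounding box.

    The grid is laid out on the plane of the two leading principal components,
    with node coefficients spanning the data's projections.  The layout is
    shrunk toward the data mean just enough to keep every weight inside the
    axis-aligned bounding box.  If the data has rank < 2 the missing
    direction is replaced by seeded uniform jitter (then clipped to the box).
    """
    arr = _as_matrix(data)
    if M < 2 or N < 2:
        raise ValueError("grid must be at least 2 x 2")
    mean = arr.mean(axis=0)
    centered = arr - mean
    lo, hi = arr.min(axis=0), arr.max(axis=0)

    # Degenerate cloud: every weight collapses onto the single data point.
    if not np.any(np.abs(centered) > 0):
        return SOMGrid(M=M, N=N, weights=np.tile(mean, (M * N, 1)))

    # Principal directions via SVD of the centered data.
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    rank = int(np.sum(svals > svals[0] * 1e-9))

    rows, cols = np.divmod(np.arange(M * N), N)
    weights = np.tile(mean, (M * N, 1))
    rng = np.random.default_rng(seed)
    for axis, (pos, npos) in enumerate(((rows, M), (cols, N))):
        t = pos / (npos - 1)  # 0..1 along the grid axis
        if axis < rank:
            proj = centered @ vt[axis]
            coeff = proj.min() + t * (proj.max() - proj.min())
            weights += coeff[:, None] * vt[axis]
        else:
            span = 0.05 * (hi - lo)
            weights += rng.uniform(-1.0, 1.0, size=(M * N, 1)) * span

    # Shrink toward the mean until inside the bounding box (mean is inside,
    # so a factor in [0, 1] always exists); keeps PCA-plane membership.
    offset = weights - mean
    scale = 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        over = np.where(offset > 0, (hi - mean) / offset, np.inf)
        under = np.where(offset < 0, (lo - mean) / offset, np.inf)
    limit = min(np.min(over), np.min(under))
    if np.isfinite(limit):
        scale = min(1.0, limit)
    weights = mean + scale * offset
    weights = np.clip(weights, lo, hi)  # guard against roundoff
    return SOMGrid(M=M, N=N, weights=weights)


def find_winner(grid: SOMGrid, x) -> int:
    """Index of the minimum-Euclidean-distance neuron (row-major linear index).

    Ties are broken toward the lowest linear index.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.dim,):
        raise ValueError(f"query has dimension {x.shape}, grid expects ({grid.dim},)")
    d2 = np.einsum("ij,ij->i", grid.weights - x, grid.weights - x)
    return int(np.argmin(d2))


def update_weights(grid: SOMGrid, x, winner: int, eta: float, sigma: float) -> SOMGrid:
    """One online update: pull all neurons toward ``x``.

    w_j <- w_j + eta * exp(-d_{j*,j}^2 / (2 sigma^2)) * (x - w_j), where d is
    the Euclidean distance between grid coordinates.  Returns a new grid.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError("eta must be in [0, 1]")
    x = np.asarray(x, dtype=float)
    lam = np.exp(-grid.lateral_sqdist()[winner] / (2.0 * sigma**2))
    new_w = grid.weights + eta * lam[:, None] * (x - grid.weights)
    return SOMGrid(M=grid.M, N=grid.N, weights=new_w)


def train(data, M: int, N: int, schedule: TrainingSchedule | None = None) -> SOMGrid:
    """Full online training loop.

    Runs ``schedule.n_epochs`` epochs over the data, reshuffled each epoch by
    the seeded generator.  The learning rate is constant within an epoch and
    decays linearly across epochs: eta(k) = eta0 * (1 - k / n_epochs) for
    completed-epoch counter k.  Deterministic given the seed.
    """
    if schedule is None:
        schedule = TrainingSchedule()
    arr = _as_matrix(data)
    grid = initialize_grid(arr, M, N, seed=schedule.seed)
    rng = np.random.default_rng(schedule.seed)
    lat2 = grid.lateral_sqdist()
    lam_all = np.exp(-lat2 / (2.0 * schedule.sigma**2))  # (P, P), row per winner
    weights = grid.weights.copy()
    n = arr.shape[0]
    for epoch in range(schedule.n_epochs):
        eta = schedule.eta0 * (1.0 - epoch / schedule.n_epochs)
        order = rng.permutation(n)
        if eta <= 0.0:
            continue
        for i in order:
            x = arr[i]
            diff = weights - x
            j = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
            weights -= eta * lam_all[j][:, None] * diff
    return SOMGrid(M=M, N=N, weights=weights)


def quantization_error(grid: SOMGrid, data) -> float:
    """Mean Euclidean distance of data vectors to their winning weight."""
    arr = _as_matrix(data)
    d2 = ((arr[:, None, :] - grid.weights[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min(axis=1)).mean())
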