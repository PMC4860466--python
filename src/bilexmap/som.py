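"""Generic self-organizing map on a rectangular 30x40 grid.

Weight vectors self-organize so that nearby nodes come to represent similar
inputs.  Training uses a truncated Gaussian neighborhood kernel whose width
equals the current integer radius, a learning rate annealed linearly from 0.2
to 0.1 over the first 100 epochs, and a self-adjusting radius: every 5 epochs
the mean quantization error (QE) of the last 5 epochs is compared with that of
the previous 5, and the radius shrinks by 1 when the two means agree within
25%, i.e. when learning has plateaued at the current resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "MapGrid",
    "NeighborhoodState",
    "TrainingSchedule",
    "find_bmu",
    "find_bmus",
    "update_map",
    "quantization_error",
    "adapt_radius",
    "learning_rate",
    "neighborhood_field",
]

DEFAULT_ROWS = 30
DEFAULT_COLS = 40


def grid_coordinates(rows: int, cols: int) -> np.ndarray:
    """(rows*cols, 2) array of (row, col) positions in row-major node order."""
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(float)


@dataclass
class MapGrid:
    """One SOM layer: node weights plus grid geometry.

    Grid distance between nodes is Euclidean on (row, col) coordinates, with
    no wraparound.  Node indices are row-major.
    """

    rows: int
    cols: int
    dim: int
    weights: np.ndarray
    rng_seed: int | None = None

    # pairwise squared grid distances, built lazily (shared per shape)
    _dist2: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.rows * self.cols, self.dim):
            raise ValueError(
                f"weights shape {self.weights.shape} != "
                f"({self.rows * self.cols}, {self.dim})"
            )

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    @property
    def coordinates(self) -> np.ndarray:
        return grid_coordinates(self.rows, self.cols)

    def grid_dist2(self) -> np.ndarray:
        """(n, n) squared grid distances between all node pairs (cached)."""
        if self._dist2 is None:
            c = self.coordinates
            d = c[:, None, :] - c[None, :, :]
            self._dist2 = (d * d).sum(axis=-1)
        return self._dist2

    @classmethod
    def initialize(
        cls,
        dim: int,
        rows: int = DEFAULT_ROWS,
        cols: int = DEFAULT_COLS,
        rng: np.random.Generator | int | None = None,
    ) -> "MapGrid":
        """Random initial weights, uniform in [0, 1] per coordinate."""
        seed = rng if isinstance(rng, (int, np.integer)) else None
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        w = gen.uniform(0.0, 1.0, size=(rows * cols, dim))
        return cls(rows=rows, cols=cols, dim=dim, weights=w,
                   rng_seed=int(seed) if seed is not None else None)


def _check_dim(grid: MapGrid, x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (grid.dim,):
        raise ValueError(f"input dimension {x.shape} does not match map dim {grid.dim}")
    return x


def find_bmu(grid: MapGrid, x: np.ndarray) -> int:
    """Best matching unit: argmin Euclidean distance; ties -> lowest index."""
    x = _check_dim(grid, x)
    d2 = ((grid.weights - x) ** 2).sum(axis=1)
    return int(np.argmin(d2))


def find_bmus(grid: MapGrid, X: np.ndarray) -> np.ndarray:
    """Vectorized BMU search for a batch of inputs (rows of X)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != grid.dim:
        raise ValueError(f"input dimension {X.shape[1]} does not match map dim {grid.dim}")
    d2 = cdist(X, grid.weights, metric="sqeuclidean")
    return d2.argmin(axis=1)


def update_map(
    grid: MapGrid, x: np.ndarray, bmu: int, lr: float, radius: int
) -> MapGrid:
    """Move the BMU and its grid neighbors toward x (in place).

    Nodes within grid distance <= radius move by lr * exp(-d^2 / (2 sigma^2))
    toward x, with sigma = radius (sigma = 1 when radius = 0, where only the
    BMU itself moves).  Returns the same grid for chaining.
    """
    x = _check_dim(grid, x)
    if not 0.0 <= lr <= 1.0:
        raise ValueError(f"learning rate {lr} outside [0, 1]")
    if lr == 0.0:
        return grid
    d2 = grid.grid_dist2()[bmu]
    sigma = max(float(radius), 1.0)
    mask = d2 <= float(radius) ** 2
    idx = np.nonzero(mask)[0]
    g = lr * np.exp(-d2[idx] / (2.0 * sigma * sigma))
    grid.weights[idx] += g[:, None] * (x - grid.weights[idx])
    return grid


def neighborhood_field(grid: MapGrid, center: int, radius: float) -> np.ndarray:
    """Gaussian activation bump over the grid, truncated at the radius.

    Activation of node i is exp(-d_i^2 / (2 sigma^2)) for grid distance
    d_i <= radius (sigma = max(radius, 1)), zero beyond; the center node has
    activation 1.
    """
    d2 = grid.grid_dist2()[center]
    sigma = max(float(radius), 1.0)
    out = np.exp(-d2 / (2.0 * sigma * sigma))
    out[d2 > float(radius) ** 2] = 0.0
    return out


def quantization_error(grid: MapGrid, X: np.ndarray) -> float:
    """Mean input-space distance between stimuli and their BMUs' weights."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 0:
        raise ValueError("quantization error undefined for an empty stimulus set")
    d = cdist(X, grid.weights)
    return float(d.min(axis=1).mean())


@dataclass
class NeighborhoodState:
    """Self-adjusting neighborhood radius driven by the QE plateau rule."""

    radius: int = 15
    radius_floor: int = 1
    check_interval: int = 5
    qe_history: list[float] = field(default_factory=list)

    def record(self, qe: float) -> None:
        self.qe_history.append(float(qe))


def adapt_radius(state: NeighborhoodState) -> NeighborhoodState:
    """Apply the 25% plateau rule at a check boundary.

    Requires at least two full check intervals of QE history.  The radius
    drops by 1 iff the mean QE of the last interval is within 25% of the mean
    of the interval before it, and never drops below the floor.
    """
    k = state.check_interval
    if len(state.qe_history) < 2 * k:
        raise ValueError(
            f"need at least {2 * k} epochs of QE history, have {len(state.qe_history)}"
        )
    current = float(np.mean(state.qe_history[-k:]))
    previous = float(np.mean(state.qe_history[-2 * k : -k]))
    if abs(current - previous) <= 0.25 * previous and state.radius > state.radius_floor:
        state.radius -= 1
    return state


@dataclass(frozen=True)
class TrainingSchedule:
    """Learning-rate anneal and Hebbian constants for one training run."""

    lr_start: float = 0.2
    lr_end: float = 0.1
    lr_anneal_epochs: int = 100
    hebbian_lr: float = 0.2  # beta in the Hebbian rule
    total_epochs: int = 500

    def lr(self, epoch: int) -> float:
        return learning_rate(
            epoch, self.lr_start, self.lr_end, self.lr_anneal_epochs
        )


def learning_rate(
    epoch: int, lr_start: float = 0.2, lr_end: float = 0.1, anneal_epochs: int = 100
) -> float:
    """Linear decrease from lr_start to lr_end over the anneal window."""
    if epoch >= anneal_epochs:
        return lr_end
    return lr_start + (lr_end - lr_start) * epoch / anneal_epochs
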