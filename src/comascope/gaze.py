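"""Gaze-epoch featurization: fixation-frequency heatmaps and projections.

Each gaze epoch becomes a fixed-size 2-D grid counting how often the
fixation point fell in each cell — an estimate of the probability that the
participant was looking at that part of the screen — plus its x- and
y-axis projections.  The grid (default 64 x 64) is the eye-tracker input
of the autoencoder; a per-pixel map would make the network input
needlessly large, so screen pixels are binned onto the grid.

Conventions: x rightward, y downward, row-major ``grid[row=y, col=x]``
indexing, half-open cell boundaries.  Samples outside the screen (tracking
loss) are excluded from the grid and counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["GazeHeatmap", "compute_heatmap", "project_heatmap", "normalize_heatmap"]


@dataclass
class GazeHeatmap:
    """Fixation-frequency grid for one gaze epoch."""

    grid: np.ndarray  # H x W, non-negative
    n_samples: int  # on-screen samples counted into the grid
    n_offscreen: int  # excluded samples (tracking loss)
    screen_size: tuple[int, int]  # (width_px, height_px)
    normalized: bool = False

    @property
    def x_projection(self) -> np.ndarray:
        """Column sums (length W); sums to the grid total."""
        return self.grid.sum(axis=0)

    @property
    def y_projection(self) -> np.ndarray:
        """Row sums (length H); sums to the grid total."""
        return self.grid.sum(axis=1)


def compute_heatmap(
    x: np.ndarray,
    y: np.ndarray,
    screen_size: tuple[int, int] = (1920, 1080),
    grid_size: tuple[int, int] = (64, 64),
) -> GazeHeatmap:
    """Bin on-screen gaze samples into an H x W fixation-frequency grid.

    A sample at pixel (px, py) with 0 <= px < width and 0 <= py < height
    increments the cell containing it; off-screen samples are excluded and
    tallied in ``n_offscreen``.  An empty epoch yields a zero grid.
    """
    h, w = grid_size
    if h <= 0 or w <= 0:
        raise ValueError("grid size must be positive")
    width, height = screen_size
    if width <= 0 or height <= 0:
        raise ValueError("screen size must be positive")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    on = (x >= 0) & (x < width) & (y >= 0) & (y < height)
    # integer cell indices with half-open boundaries
    col = np.floor(x[on] * w / width).astype(int)
    row = np.floor(y[on] * h / height).astype(int)
    grid = np.zeros((h, w))
    np.add.at(grid, (row, col), 1.0)
    return GazeHeatmap(
        grid=grid,
        n_samples=int(on.sum()),
        n_offscreen=int(len(x) - on.sum()),
        screen_size=(width, height),
    )


def project_heatmap(h: GazeHeatmap) -> tuple[np.ndarray, np.ndarray]:
    """Column- and row-sum projections of the grid (x then y)."""
    return h.x_projection, h.y_projection


def normalize_heatmap(h: GazeHeatmap) -> GazeHeatmap:
    """Scale the grid to unit mass (a probability map); idempotent.

    A zero grid (no on-screen samples) is returned unchanged apart from
    the ``normalized`` flag.
    """
    total = h.grid.sum()
    grid = h.grid / total if total > 0 else h.grid.copy()
    return replace(h, grid=grid, normalized=True)
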