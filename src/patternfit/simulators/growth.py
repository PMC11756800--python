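"""Stochastic lattice growth models: Eden and diffusion-limited aggregation.

Both produce binary occupancy grids grown from a single seed site.  The
Eden model occupies one uniformly chosen perimeter site per growth event
(compact colony-like clusters); DLA releases random walkers from a circle
just outside the cluster and sticks them on first 4-neighbour contact
(ramified fractal clusters).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._common import GRID_SIZE

__all__ = ["StochasticGrowthConfig", "simulate_growth", "GrowthTruncationWarning"]

_NBRS = ((1, 0), (-1, 0), (0, 1), (0, -1))


class GrowthTruncationWarning(UserWarning):
    """The cluster reached the grid edge before events were exhausted."""


@dataclass(frozen=True)
class StochasticGrowthConfig:
    model: str = "eden"  # "eden" or "dla"
    events: int = 400
    seed_site: tuple | None = None  # defaults to the grid center
    seed: int = 0
    launch_margin: int = 5  # DLA: launch radius = cluster radius + margin
    kill_factor: float = 3.0  # DLA: kill radius = kill_factor * launch radius

    def __post_init__(self) -> None:
        if self.events < 0:
            raise ValueError("growth events must be >= 0")
        if self.model not in ("eden", "dla"):
            raise ValueError(f"unknown growth model: {self.model!r}")


def simulate_growth(config: StochasticGrowthConfig, size: int = GRID_SIZE) -> np.ndarray:
    """Grow a binary cluster; deterministic given ``config.seed``.

    Emits :class:`GrowthTruncationWarning` if the cluster touches the grid
    edge before all events complete (the manifest records this flag).
    """
    site = config.seed_site or (size // 2, size // 2)
    if not (0 <= site[0] < size and 0 <= site[1] < size):
        raise ValueError("seed site outside grid")
    if config.model == "eden":
        return _eden(config, site, size)
    return _dla(config, site, size)


def _eden(config, site, size):
    rng = np.random.default_rng(config.seed)
    grid = np.zeros((size, size), dtype=float)
    grid[site] = 1.0
    in_perim = np.zeros((size, size), dtype=bool)
    perim = []

    def add_perimeter(y, x):
        for dy, dx in _NBRS:
            ny, nx = y + dy, x + dx
            if 0 <= ny < size and 0 <= nx < size and grid[ny, nx] == 0 \
                    and not in_perim[ny, nx]:
                in_perim[ny, nx] = True
                perim.append((ny, nx))

    add_perimeter(*site)
    for event in range(config.events):
        if not perim:
            warnings.warn("Eden cluster filled the grid before events exhausted",
                          GrowthTruncationWarning)
            break
        idx = int(rng.integers(len(perim)))
        y, x = perim[idx]
        perim[idx] = perim[-1]
        perim.pop()
        in_perim[y, x] = False
        grid[y, x] = 1.0
        if y in (0, size - 1) or x in (0, size - 1):
            warnings.warn("Eden cluster reached the grid edge",
                          GrowthTruncationWarning)
        add_perimeter(y, x)
    return grid


def _dla(config, site, size):
    rng = np.random.default_rng(config.seed)
    grid = np.zeros((size, size), dtype=float)
    cy, cx = site
    grid[cy, cx] = 1.0
    cluster_radius = 0.0
    max_extent = min(cy, cx, size - 1 - cy, size - 1 - cx)
    steps = np.array(_NBRS)
    for particle in range(config.events):
        launch_r = cluster_radius + config.launch_margin
        if launch_r >= max_extent:
            warnings.warn("DLA cluster reached the grid edge",
                          GrowthTruncationWarning)
            break
        kill_r = min(config.kill_factor * launch_r, max_extent)
        stuck = False
        while not stuck:
            theta = rng.uniform(0.0, 2.0 * np.pi)
            y = int(round(cy + launch_r * np.sin(theta)))
            x = int(round(cx + launch_r * np.cos(theta)))
            while True:
                dy, dx = steps[rng.integers(4)]
                y += dy
                x += dx
                r = np.hypot(y - cy, x - cx)
                if r > kill_r or not (0 <= y < size and 0 <= x < size):
                    break  # walker lost; relaunch
                if grid[y, x] == 1.0:
                    break  # landed on the cluster; relaunch (shouldn't stick inside)
                if (grid[y + 1, x] if y + 1 < size else 0) or \
                   (grid[y - 1, x] if y - 1 >= 0 else 0) or \
                   (grid[y, x + 1] if x + 1 < size else 0) or \
                   (grid[y, x - 1] if x - 1 >= 0 else 0):
                    grid[y, x] = 1.0
                    cluster_radius = max(cluster_radius, r)
                    stuck = True
                    break
    return grid
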