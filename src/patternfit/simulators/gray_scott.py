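"""Gray-Scott reaction-diffusion simulator.

    du/dt = -u v^2 + F (1 - u) + D_u Lap(u)
    dv/dt =  u v^2 - (F + k) v + D_v Lap(v)

The trivial steady state is (u, v) = (1, 0); patterns nucleate from a
perturbed central patch and evolve slowly, so a single simulation yields
a series of morphologically distinct snapshots over time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import GRID_SIZE, check_finite, laplacian

__all__ = ["GrayScottParams", "simulate_gray_scott"]


@dataclass(frozen=True)
class GrayScottParams:
    """Feed rate F, kill rate k, diffusivities, and snapshot times (in steps)."""

    F: float = 0.037
    k: float = 0.06
    D_u: float = 0.16
    D_v: float = 0.08
    capture_times: tuple = (500, 1000, 2000, 4000, 8000, 16000)
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.F < 0 or self.k < 0:
            raise ValueError("F and k must be >= 0")
        if list(self.capture_times) != sorted(set(self.capture_times)):
            raise ValueError("capture times must be strictly increasing")


def simulate_gray_scott(params: GrayScottParams, seed: int = 0,
                        size: int = GRID_SIZE, perturb: bool = True):
    """Run to the last capture time; return a list of v-field snapshots.

    With ``perturb=False`` the field starts exactly at the homogeneous
    state (1, 0) and stays there.  Otherwise a central square patch is
    seeded with (u, v) = (0.5, 0.25) plus small seeded noise.
    """
    u = np.ones((size, size))
    v = np.zeros((size, size))
    if perturb:
        rng = np.random.default_rng(seed)
        r = max(size // 16, 2)
        c = size // 2
        u[c - r:c + r, c - r:c + r] = 0.5
        v[c - r:c + r, c - r:c + r] = 0.25
        u += rng.uniform(-0.01, 0.01, size=u.shape)
        v += np.abs(rng.uniform(0.0, 0.01, size=v.shape))
    captures = list(params.capture_times)
    if not captures:
        return []
    snapshots = []
    dt = params.dt
    for step in range(1, captures[-1] + 1):
        uvv = u * v * v
        u = u + dt * (-uvv + params.F * (1.0 - u) + params.D_u * laplacian(u))
        v = v + dt * (uvv - (params.F + params.k) * v + params.D_v * laplacian(v))
        if step % 1000 == 0:
            check_finite(v, "gray-scott", step)
        if step in captures:
            check_finite(v, "gray-scott", step)
            snapshots.append(v.copy())
    return snapshots
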