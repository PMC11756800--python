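"""Edwards-Wilkinson stochastic interface model.

    dh/dt = nu * Lap(h) + eta(x, t)

integrated by explicit Euler with seeded Gaussian noise increments of
standard deviation ``noise_amp * sqrt(dt)`` per step.  The height field
roughens diffusively from a flat start.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import GRID_SIZE, check_finite, laplacian

__all__ = ["EWParams", "simulate_edwards_wilkinson"]


@dataclass(frozen=True)
class EWParams:
    nu: float = 1.0
    noise_amp: float = 1.0
    dt: float = 0.1
    steps: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nu * self.dt > 0.25 + 1e-12:
            raise ValueError("explicit scheme unstable: require nu*dt <= 1/4")


def simulate_edwards_wilkinson(params: EWParams, size: int = GRID_SIZE) -> np.ndarray:
    """Integrate from a flat interface; deterministic given ``params.seed``."""
    rng = np.random.default_rng(params.seed)
    h = np.zeros((size, size))
    amp = params.noise_amp * np.sqrt(params.dt)
    for step in range(1, params.steps + 1):
        h = h + params.dt * params.nu * laplacian(h)
        if params.noise_amp > 0:
            h = h + amp * rng.standard_normal(h.shape)
        if step % 1000 == 0:
            check_finite(h, "edwards-wilkinson", step)
    return h
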