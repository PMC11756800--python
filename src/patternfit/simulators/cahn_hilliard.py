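"""Cahn-Hilliard phase separation (conserved order parameter).

    dc/dt = Lap(c^3 - c) - gamma * Lap(Lap(c))

integrated semi-implicitly in Fourier space: the stiff biharmonic term is
treated implicitly and the nonlinear chemical potential explicitly.  The
spatial mean of c is conserved exactly (the k = 0 mode never changes).
Used as an out-of-dataset probe pattern, not as part of the selection
library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import GRID_SIZE, check_finite, spectral_k2, uniform_noise

__all__ = ["CahnHilliardParams", "simulate_cahn_hilliard"]


@dataclass(frozen=True)
class CahnHilliardParams:
    gamma: float = 0.1
    mobility: float = 1.0
    dt: float = 0.1
    steps: int = 4000
    seed: int = 0
    init_amp: float = 0.1


def simulate_cahn_hilliard(params: CahnHilliardParams, init=None,
                           size: int = GRID_SIZE) -> np.ndarray:
    """Coarsening field from seeded uniform noise (or a supplied init)."""
    if init is None:
        c = uniform_noise((size, size), params.init_amp, params.seed)
    else:
        c = np.array(init, dtype=float)
        size = c.shape[0]
    k2 = spectral_k2(size)
    M, dt = params.mobility, params.dt
    denom = 1.0 + dt * M * params.gamma * k2 * k2
    ch = np.fft.rfft2(c)
    for step in range(1, params.steps + 1):
        f = c ** 3 - c
        ch = (ch - dt * M * k2 * np.fft.rfft2(f)) / denom
        c = np.fft.irfft2(ch, s=(size, size))
        if step % 1000 == 0:
            check_finite(c, "cahn-hilliard", step)
    check_finite(c, "cahn-hilliard", params.steps)
    return c
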