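"""Shared helpers for the lattice simulators.

All PDE/lattice models run on a square grid with unit spacing and
periodic boundaries; simulators emit raw float fields and leave raster
normalization to :mod:`patternfit.imaging`.
"""

from __future__ import annotations

import numpy as np

GRID_SIZE = 128


class DivergenceError(RuntimeError):
    """A field became non-finite during integration."""

    def __init__(self, model: str, step: int):
        super().__init__(f"{model} diverged at step {step}")
        self.model = model
        self.step = step


def laplacian(field: np.ndarray) -> np.ndarray:
    """5-point periodic Laplacian with unit spacing (vectorised over leading axes)."""
    return (np.roll(field, 1, axis=-1) + np.roll(field, -1, axis=-1)
            + np.roll(field, 1, axis=-2) + np.roll(field, -1, axis=-2)
            - 4.0 * field)


def uniform_noise(shape, amplitude: float, seed: int) -> np.ndarray:
    """Seeded uniform noise on (-amplitude, amplitude)."""
    rng = np.random.default_rng(seed)
    return rng.uniform(-amplitude, amplitude, size=shape)


def check_finite(field: np.ndarray, model: str, step: int) -> None:
    if not np.isfinite(field).all():
        raise DivergenceError(model, step)


def spectral_k2(n: int) -> np.ndarray:
    """Squared wavenumber grid for rfft2 on an n x n unit-spacing lattice."""
    kx = 2.0 * np.pi * np.fft.fftfreq(n)
    ky = 2.0 * np.pi * np.fft.rfftfreq(n)
    return kx[:, None] ** 2 + ky[None, :] ** 2
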