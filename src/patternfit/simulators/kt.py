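"""Kernel-based Turing (KT) model.

Discrete-time pattern formation without explicit reaction kinetics: the
field is updated synchronously by convolving it with a radially symmetric
short-range-activation / long-range-inhibition kernel, adding the result,
and clipping to fixed bounds.  Periodic convolution is done in Fourier
space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import GRID_SIZE, check_finite, uniform_noise

__all__ = ["KTParams", "simulate_kt"]


@dataclass(frozen=True)
class KTParams:
    """Activation/inhibition disk kernel, clip bounds, time step and step count."""

    act_amp: float = 0.08
    act_radius: float = 3.0
    inh_amp: float = 0.015
    inh_radius: float = 8.0
    clip_low: float = 0.0
    clip_high: float = 1.0
    dt: float = 1.0
    steps: int = 300

    def __post_init__(self) -> None:
        if self.inh_radius <= self.act_radius:
            raise ValueError("inhibition radius must exceed activation radius")
        if self.clip_low >= self.clip_high:
            raise ValueError("clip bounds invalid: low must be < high")


def _kernel(params: KTParams, size: int) -> np.ndarray:
    if 2 * params.inh_radius + 1 > size:
        raise ValueError("interaction kernel larger than grid")
    ax = np.arange(size)
    d = np.minimum(ax, size - ax).astype(float)  # periodic distance per axis
    r = np.sqrt(d[:, None] ** 2 + d[None, :] ** 2)
    kern = np.zeros((size, size))
    kern[r <= params.act_radius] += params.act_amp
    kern[(r > params.act_radius) & (r <= params.inh_radius)] -= params.inh_amp
    return kern


def simulate_kt(params: KTParams, seed: int = 0, size: int = GRID_SIZE) -> np.ndarray:
    """Synchronous kernel update: u <- clip(u + dt * (kernel (*) u))."""
    mid = 0.5 * (params.clip_low + params.clip_high)
    u = mid + uniform_noise((size, size), 0.01 * (params.clip_high - params.clip_low),
                            seed)
    u = np.clip(u, params.clip_low, params.clip_high)
    kern_hat = np.fft.rfft2(_kernel(params, size))
    for step in range(1, params.steps + 1):
        conv = np.fft.irfft2(np.fft.rfft2(u) * kern_hat, s=(size, size))
        u = np.clip(u + params.dt * conv, params.clip_low, params.clip_high)
        if step % 100 == 0:
            check_finite(u, "kt", step)
    return u
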