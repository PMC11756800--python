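"""Anisotropic phase-field model of dendritic solidification.

Kobayashi-type coupled equations for a phase variable p in [0, 1] and a
temperature field T:

    tau dp/dt = div(eps^2 grad p) - d/dx(eps eps' p_y) + d/dy(eps eps' p_x)
                + p (1 - p) (p - 1/2 + m),   m = (alpha/pi) atan(gamma (T_e - T))
    dT/dt     = Lap(T) + K dp/dt

with interface width eps modulated by the local interface orientation,
eps = eps0 (1 + delta cos(j (theta - theta0))).  A central nucleus grows
into an undercooled melt; dataset replicates vary only the stochastic
noise applied to the initial condition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._common import GRID_SIZE, check_finite

__all__ = ["PhaseFieldParams", "simulate_phase_field"]


@dataclass(frozen=True)
class PhaseFieldParams:
    anisotropy: float = 0.10  # delta
    mode_number: int = 6  # j
    mobility: float = 3333.3  # 1/tau
    latent_heat: float = 1.8  # K
    noise_amp: float = 0.01  # amplitude of initial-condition noise
    seed: int = 0
    eps0: float = 0.01
    alpha: float = 0.9
    gamma: float = 10.0
    t_eq: float = 1.0
    theta0: float = 0.0
    dx: float = 0.03
    dt: float = 1.0e-4
    steps: int = 1800
    nucleus_radius: float = 2.0  # in cells


def _grad(field, dx):
    gy = (np.roll(field, -1, axis=0) - np.roll(field, 1, axis=0)) / (2 * dx)
    gx = (np.roll(field, -1, axis=1) - np.roll(field, 1, axis=1)) / (2 * dx)
    return gx, gy


def _lap(field, dx):
    return (np.roll(field, 1, 0) + np.roll(field, -1, 0)
            + np.roll(field, 1, 1) + np.roll(field, -1, 1) - 4 * field) / (dx * dx)


def simulate_phase_field(params: PhaseFieldParams, size: int = GRID_SIZE) -> np.ndarray:
    """Grow an anisotropic nucleus; returns the phase field p in [0, 1]."""
    rng = np.random.default_rng(params.seed)
    p = np.zeros((size, size))
    if params.nucleus_radius > 0:
        yy, xx = np.mgrid[0:size, 0:size]
        r2 = (yy - size // 2) ** 2 + (xx - size // 2) ** 2
        p[r2 <= params.nucleus_radius ** 2] = 1.0
    if params.noise_amp > 0:
        p = np.clip(p + params.noise_amp * rng.uniform(-1, 1, p.shape), 0.0, 1.0)
    T = np.zeros((size, size))
    dx, dt = params.dx, params.dt
    for step in range(1, params.steps + 1):
        px, py = _grad(p, dx)
        theta = np.arctan2(py, px)
        eps = params.eps0 * (1.0 + params.anisotropy
                             * np.cos(params.mode_number * (theta - params.theta0)))
        deps = -params.eps0 * params.anisotropy * params.mode_number \
            * np.sin(params.mode_number * (theta - params.theta0))
        # anisotropic gradient terms
        a_y = eps * deps * px  # appears inside d/dy
        a_x = eps * deps * py  # appears inside d/dx
        term1 = (np.roll(a_y, -1, 0) - np.roll(a_y, 1, 0)) / (2 * dx)
        term2 = -(np.roll(a_x, -1, 1) - np.roll(a_x, 1, 1)) / (2 * dx)
        e2 = eps * eps
        gx_e, gy_e = _grad(e2, dx)
        div_term = e2 * _lap(p, dx) + gx_e * px + gy_e * py
        m = (params.alpha / np.pi) * np.arctan(params.gamma * (params.t_eq - T))
        dp = params.mobility * dt * (term1 + term2 + div_term
                                     + p * (1.0 - p) * (p - 0.5 + m))
        p = np.clip(p + dp, 0.0, 1.0)
        T = T + dt * (_lap(T, dx) + params.latent_heat * dp / dt)
        if step % 500 == 0:
            check_finite(p, "phase-field", step)
    check_finite(p, "phase-field", params.steps)
    return p
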