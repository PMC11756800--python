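"""Linear stability analysis of the two-species Turing model.

The reaction-diffusion system analysed here is

    du/dt = f_u*u - f_v*v + q*u**2 - u**3 + D_u * Lap(u)
    dv/dt = g_u*u - g_v*v             + D_v * Lap(v)

Linearising about the homogeneous state (u, v) = (0, 0) gives, for a
perturbation of wavenumber k, the 2x2 matrix

    M(k) = [[f_u - D_u k**2,  -f_v          ],
            [g_u,             -g_v - D_v k**2]]

whose dominant eigenvalue real part is the growth rate lambda(k) (the
dispersion relation).  Diffusion-driven instability produces a band of
wavenumbers (k_left, k_right) with lambda > 0; the fastest-growing
wavenumber k_max sets the dominant spatial scale of the emerging pattern
(stripe width / spot spacing), and the band-width feature

    D_k = ln(k_right**2 / k_left**2) = ln((A + B) / (A - B))

with A = D_v f_u - D_u g_v and B = sqrt(A**2 - 4 D_u D_v (f_v g_u - f_u g_v))
distinguishes labyrinthine (wide-band) from straight-striped (narrow-band)
patterns.  Closed forms are validated against numeric oracles computed
directly from the eigenvalues, which are treated as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "TuringParams",
    "DispersionCurve",
    "AnalyticFeatures",
    "growth_rate",
    "dispersion_curve",
    "kmax_closed",
    "kmax_numeric",
    "kmax_two_parameter_form",
    "dk_closed",
    "band_numeric",
    "has_positive_band",
    "analytic_features",
    "dominant_wavenumber",
]


class NoBandError(ValueError):
    """No band of positive growth rates exists for these parameters."""


class DegenerateDiffusionError(ValueError):
    """Closed forms require distinct diffusivities (D_u != D_v)."""


@dataclass(frozen=True)
class TuringParams:
    """Parameters of the Turing reaction-diffusion model.

    ``f_u, f_v, g_u, g_v`` are the linear reaction coefficients (1/time),
    ``q`` the quadratic coefficient, ``D_u, D_v`` the diffusivities
    (length^2/time).  Defaults hold the estimation-protocol constants with
    ``f_v`` and ``g_v`` as the free parameters.
    """

    f_u: float = 0.51
    f_v: float = 0.8
    g_u: float = 0.81
    g_v: float = 0.8
    q: float = 0.0
    D_u: float = 0.1
    D_v: float = 1.0

    def __post_init__(self) -> None:
        if self.D_u <= 0 or self.D_v <= 0:
            raise ValueError("diffusivities must be positive")


@dataclass(frozen=True)
class DispersionCurve:
    k: np.ndarray
    growth: np.ndarray


@dataclass(frozen=True)
class AnalyticFeatures:
    """Closed-form pattern features plus the unstable band edges."""

    k_max: float
    D_k: float
    A: float
    B: float
    k_left: float
    k_right: float


def growth_rate(k, params: TuringParams):
    """Growth rate lambda(k): max real part of the eigenvalues of M(k).

    Vectorised over ``k``; accepts scalars or arrays of wavenumbers >= 0.
    """
    k2 = np.asarray(k, dtype=float) ** 2
    tr = params.f_u - params.g_v - (params.D_u + params.D_v) * k2
    det = (params.f_u - params.D_u * k2) * (-params.g_v - params.D_v * k2) \
        + params.f_v * params.g_u
    disc = tr * tr - 4.0 * det
    lam = np.where(disc >= 0.0, (tr + np.sqrt(np.maximum(disc, 0.0))) / 2.0, tr / 2.0)
    return lam if lam.ndim else float(lam)


def dispersion_curve(params: TuringParams, k_max: float = np.pi, n: int = 2048) -> DispersionCurve:
    """Sample lambda(k) on [0, k_max] (default up to the Nyquist wavenumber)."""
    k = np.linspace(0.0, k_max, n)
    return DispersionCurve(k=k, growth=growth_rate(k, params))


def kmax_closed(params: TuringParams) -> float:
    """Closed-form fastest-growing wavenumber.

    Derived from d(lambda)/d(k^2) = 0 of the dispersion relation:

        k_max^2 = [(D_u + D_v) sqrt(f_v g_u) - sqrt(D_u D_v) (f_u + g_v)]
                  / [sqrt(D_u D_v) (D_v - D_u)]
    """
    Du, Dv = params.D_u, params.D_v
    if Du == Dv:
        raise DegenerateDiffusionError("k_max closed form undefined for D_u == D_v")
    fg = params.f_v * params.g_u
    if fg < 0:
        raise NoBandError("f_v*g_u < 0: no cross-activation loop")
    s = ((Du + Dv) * math.sqrt(fg) - math.sqrt(Du * Dv) * (params.f_u + params.g_v)) \
        / (math.sqrt(Du * Dv) * (Dv - Du))
    if s <= 0:
        raise NoBandError("expression under the radical is non-positive: no unstable band")
    return math.sqrt(s)


def kmax_two_parameter_form(f_u: float = 0.51, g_u: float = 0.81,
                            D_u: float = 0.1, D_v: float = 1.0):
    """Factor ``kmax_closed`` into the two-free-parameter form.

    Holding the protocol constants fixed, k_max(f_v, g_v) factors as

        k_max = C * sqrt(c2 * sqrt(f_v) - D_u * (f_u + g_v))

    with C = sqrt(1 / (D_u (D_v - D_u))) and
    c2 = (D_u + D_v) sqrt(g_u) sqrt(D_u / D_v).  Returns ``(C, c2)``;
    with the default constants C = 3.33 and c2 = 0.313.
    """
    if D_u == D_v:
        raise DegenerateDiffusionError("factored form undefined for D_u == D_v")
    C = math.sqrt(1.0 / (D_u * (D_v - D_u)))
    c2 = (D_u + D_v) * math.sqrt(g_u) * math.sqrt(D_u / D_v)
    return C, c2


def has_positive_band(params: TuringParams) -> bool:
    """True iff lambda(k) > 0 somewhere at k > 0 while k=0 is stable."""
    k = np.linspace(1e-4, np.pi, 2000)
    return bool(growth_rate(0.0, params) < 0 and np.any(growth_rate(k, params) > 0))


def kmax_numeric(params: TuringParams, k_hi: float = np.pi) -> float:
    """Numeric argmax of the dispersion relation (oracle for the closed form).

    Dense scan on [0, k_hi] followed by bounded golden-section refinement.
    """
    k = np.linspace(0.0, k_hi, 10_000)
    lam = growth_rate(k, params)
    i = int(np.argmax(lam))
    if lam[i] <= 0:
        raise NoBandError("no positive growth rate on the scanned range")
    lo = k[max(i - 1, 0)]
    hi = k[min(i + 1, len(k) - 1)]
    res = minimize_scalar(lambda kk: -growth_rate(kk, params),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x)


def band_numeric(params: TuringParams, k_hi: float = np.pi):
    """Zero crossings (k_left, k_right) of lambda(k), bisection to 1e-8."""
    km = kmax_numeric(params, k_hi)
    f = lambda kk: growth_rate(kk, params)
    if f(1e-9) >= 0:
        raise NoBandError("homogeneous mode unstable: band not bracketed at k=0")
    hi = k_hi
    while f(hi) >= 0:
        hi *= 2.0
        if hi > 1e4:
            raise NoBandError("upper band edge not bracketed")
    k_left = brentq(f, 1e-9, km, xtol=1e-12)
    k_right = brentq(f, km, hi, xtol=1e-12)
    return float(k_left), float(k_right)


def dk_closed(params: TuringParams) -> float:
    """Band-width feature D_k = ln((A+B)/(A-B)) = ln(k_right^2 / k_left^2).

    A = D_v f_u - D_u g_v; B = sqrt(A^2 - 4 D_u D_v (f_v g_u - f_u g_v)).
    Requires A > B > 0 (a positive band with a stable homogeneous mode).
    """
    A = params.D_v * params.f_u - params.D_u * params.g_v
    rad = A * A - 4.0 * params.D_u * params.D_v * (params.f_v * params.g_u
                                                   - params.f_u * params.g_v)
    if rad < 0:
        raise NoBandError("negative discriminant: no real band edges")
    B = math.sqrt(rad)
    if not (A > B >= 0):
        raise NoBandError("A <= B: no positive unstable band")
    if B == 0.0:
        return 0.0
    return math.log((A + B) / (A - B))


def analytic_features(params: TuringParams) -> AnalyticFeatures:
    """Bundle k_max, D_k, A, B and the numeric band edges."""
    A = params.D_v * params.f_u - params.D_u * params.g_v
    dk = dk_closed(params)
    B = A * (math.exp(dk) - 1.0) / (math.exp(dk) + 1.0)
    kl, kr = band_numeric(params)
    return AnalyticFeatures(k_max=kmax_closed(params), D_k=dk, A=A, B=B,
                            k_left=kl, k_right=kr)


def radial_power_spectrum(image: np.ndarray):
    """Radially averaged power spectrum of a square image (DC at bin 0).

    Returns ``(k_centers, power)`` with wavenumbers in radians per pixel
    (dx = 1, so these share units with the analytic features).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("radial spectrum requires a square 2-d image")
    n = img.shape[0]
    F = np.fft.fft2(img - img.mean())
    P = np.abs(F) ** 2
    freq = np.fft.fftfreq(n)  # cycles per pixel
    kx, ky = np.meshgrid(freq, freq, indexing="ij")
    kr = 2.0 * np.pi * np.sqrt(kx**2 + ky**2)
    nbins = n // 2
    edges = np.linspace(0.0, np.pi, nbins + 1)
    which = np.clip(np.digitize(kr.ravel(), edges) - 1, 0, nbins - 1)
    power = np.bincount(which, weights=P.ravel(), minlength=nbins)
    counts = np.maximum(np.bincount(which, minlength=nbins), 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, power / counts


def dominant_wavenumber(image: np.ndarray) -> float:
    """Dominant radial wavenumber of an image (argmax of the spectrum, DC excluded)."""
    centers, power = radial_power_spectrum(image)
    power = power.copy()
    power[0] = 0.0
    if not np.any(power > 0):
        raise ValueError("flat image: dominant wavenumber undefined")
    return float(centers[int(np.argmax(power))])
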