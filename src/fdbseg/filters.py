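r"""Directional-Hilbert Butterworth bandpass (DHBB) filter bank.

The oriented texture of a fingerprint occupies a ring of frequencies (the
inter-ridge band) and, locally, a narrow range of orientations.  The filter
bank built here captures both: a Butterworth bandpass selects the radial band
and an n-th order directional Hilbert transform (an iterated Riesz transform
projected on a unit vector) selects the orientation.  Their pointwise product
on the discrete frequency grid is the DHBB subband spectrum

    phi_hat_l(w) = h_hat_l^n(w) * g_hat^gamma(w),      l = 0..L-1,

with ``h_hat_l^n(w) = (-j)^n cos^n(angle(w) - pi*l/L)`` and ``g_hat^gamma``
a two-dimensional Butterworth bandpass assembled from 1D responses along the
two axes on a Cartesian split of the frequency plane.

Two bandpass variants are provided.  ``original`` evaluates the analog
magnitude response

    b_hat(w) = (w*Delta)^{2 gamma} / [ (w*Delta)^{2 gamma} + (w^2 - p^2)^{2 gamma} ],

with bandwidth ``Delta = omega_H - omega_L`` and geometric-mean peak
``p = sqrt(omega_H * omega_L)`` (``b_hat(p) = 1``).  ``bilinear`` maps the
factorized analog transfer function through the bilinear substitution
``j*w ~ 2(e^{jw}-1)/(e^{jw}+1)``, giving a complex discrete-frequency response
with a slightly narrower passband; it is the default used by the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EvaluationError, ParameterError
from .params import FDBParams

__all__ = [
    "ButterworthSpec",
    "FrequencyGrid",
    "FilterBank",
    "butterworth_1d",
    "butterworth_roots",
    "butterworth_bilinear_1d",
    "butterworth_2d_spectrum",
    "directional_hilbert_spectrum",
    "dhbb_filterbank",
]

# (-j)^n cycles with period 4; table lookup keeps the constant exact.
_MINUS_J_POW = (1.0 + 0.0j, -1.0j, -1.0 + 0.0j, 1.0j)


@dataclass(frozen=True)
class ButterworthSpec:
    """Butterworth bandpass parameters: order and cutoff frequencies."""

    gamma: int
    omega_L: float = 0.3
    omega_H: float = 1.0
    variant: str = "bilinear"

    def __post_init__(self) -> None:
        if self.gamma < 1 or int(self.gamma) != self.gamma:
            raise ParameterError(f"gamma must be a positive integer, got {self.gamma}")
        if not 0.0 < self.omega_L < self.omega_H <= np.pi:
            raise ParameterError(
                f"cutoffs must satisfy 0 < omega_L < omega_H <= pi, got ({self.omega_L}, {self.omega_H})"
            )
        if self.variant not in ("bilinear", "original"):
            raise ParameterError(f"unknown variant {self.variant!r}")

    @property
    def delta(self) -> float:
        """Bandwidth Delta = omega_H - omega_L."""
        return self.omega_H - self.omega_L

    @property
    def p(self) -> float:
        """Geometric-mean peak frequency, p^2 = omega_H * omega_L."""
        return float(np.sqrt(self.omega_H * self.omega_L))


@dataclass(frozen=True)
class FrequencyGrid:
    """DFT sample frequencies of a padded image, in radians per sample.

    ``omega1`` varies along image columns (horizontal axis), ``omega2`` along
    rows; both lie in [-pi, pi) in the native (unshifted) DFT layout, so
    filters built on this grid multiply image spectra without any fftshift.
    ``a`` and ``b`` are the horizontal and vertical half-widths of the spatial
    domain, used by the Cartesian frequency split.
    """

    omega1: np.ndarray
    omega2: np.ndarray
    a: float
    b: float

    @classmethod
    def for_shape(cls, shape: tuple[int, int]) -> "FrequencyGrid":
        rows, cols = shape
        if rows < 2 or cols < 2:
            raise ParameterError(f"grid shape must be at least 2x2, got {shape}")
        w_col = 2.0 * np.pi * np.fft.fftfreq(cols)
        w_row = 2.0 * np.pi * np.fft.fftfreq(rows)
        omega2, omega1 = np.meshgrid(w_row, w_col, indexing="ij")
        return cls(omega1=omega1, omega2=omega2, a=cols / 2.0, b=rows / 2.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.omega1.shape


@dataclass(frozen=True)
class FilterBank:
    """L oriented DHBB subband spectra on a shared frequency grid."""

    spectra: list
    n: int
    L: int
    theta: np.ndarray
    butterworth: ButterworthSpec
    grid: FrequencyGrid

    def __post_init__(self) -> None:
        if len(self.spectra) != self.L:
            raise ParameterError("spectra count must equal L")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def butterworth_1d(omega: np.ndarray, spec: ButterworthSpec) -> np.ndarray:
    """Magnitude response of the 1D Butterworth bandpass.

    Evaluated in the pole-free form ``(w*Delta)^{2g} / [(w*Delta)^{2g} +
    (w^2 - p^2)^{2g}]``; the removable singularity at DC is assigned its
    limit 0.  Values lie in [0, 1] with the unique maximum 1 at ``w = p``.
    """
    omega = np.asarray(omega, dtype=float)
    if not np.all(np.isfinite(omega)):
        raise ParameterError("omega must be finite")
    g2 = 2 * spec.gamma
    out = np.zeros_like(omega)
    nz = omega != 0.0
    # ratio form is overflow-safe: ratio**2g -> inf yields b_hat -> 0
    with np.errstate(over="ignore", divide="ignore"):
        ratio = (omega[nz] ** 2 - spec.p**2) / (omega[nz] * spec.delta)
        out[nz] = 1.0 / (1.0 + ratio**g2)
    return out


def butterworth_roots(gamma: int) -> np.ndarray:
    """Factorization nodes t_k = exp(pi*j*(gamma + 2k - 1)/(2*gamma)), k=1..gamma.

    The negative squares -t_k^2 enumerate the gamma complex roots of -1, so
    ``prod_k (t^2 - t_k^2) = (-1)^gamma (t^{2 gamma} + 1)``.
    """
    if gamma < 1 or int(gamma) != gamma:
        raise ParameterError(f"gamma must be a positive integer, got {gamma}")
    k = np.arange(1, gamma + 1)
    return np.exp(1j * np.pi * (gamma + 2 * k - 1) / (2 * gamma))


def butterworth_bilinear_1d(omega: np.ndarray, spec: ButterworthSpec) -> np.ndarray:
    """Discrete-frequency Butterworth bandpass via the bilinear transform.

    Product over the factorization nodes t_k of

        2*Delta*(e^{2jw} - 1)
        -----------------------------------------------------------------
        (4 + p^2 - 2*Delta*t_k) e^{2jw} + (2p^2 - 8) e^{jw} + 4 + p^2 + 2*Delta*t_k

    Complex-valued; vanishes at DC (and at the Nyquist frequency, where the
    bilinear map sends e^{jw} = -1 to infinite analog frequency).
    """
    omega = np.asarray(omega, dtype=float)
    z = np.exp(1j * omega)
    z2 = z * z
    d, p2 = spec.delta, spec.p**2
    out = np.ones_like(z)
    num = 2.0 * d * (z2 - 1.0)
    for tk in butterworth_roots(spec.gamma):
        den = (4.0 + p2 - 2.0 * d * tk) * z2 + (2.0 * p2 - 8.0) * z + (4.0 + p2 + 2.0 * d * tk)
        bad = np.abs(den) < 1e-14
        if np.any(bad):
            w_bad = omega[bad].ravel()[0] if omega.ndim else float(omega)
            raise EvaluationError(f"bilinear factor has a pole on the grid at omega={w_bad}")
        out = out * (num / den)
    return out


def butterworth_2d_spectrum(grid: FrequencyGrid, spec: ButterworthSpec) -> np.ndarray:
    """2D Butterworth bandpass on a Cartesian split of the frequency plane.

    Each frequency takes the 1D response along exactly one axis: the
    horizontal branch where ``b*|w1| >= a*|w2|`` (ties included) and the
    vertical branch elsewhere, so the two indicators partition the plane.
    """
    if spec.variant == "bilinear":
        resp1 = butterworth_bilinear_1d(grid.omega1, spec)
        resp2 = butterworth_bilinear_1d(grid.omega2, spec)
    else:
        resp1 = butterworth_1d(np.abs(grid.omega1), spec)
        resp2 = butterworth_1d(np.abs(grid.omega2), spec)
    chi_h = grid.b * np.abs(grid.omega1) >= grid.a * np.abs(grid.omega2)
    return np.where(chi_h, resp1, resp2)


def directional_hilbert_spectrum(
    grid: FrequencyGrid, l: int, L: int, n: int
) -> np.ndarray:
    """Spectrum of the n-th order directional Hilbert transform along theta_l.

    ``(-j)^n cos^n(angle(w) - pi*l/L)`` off DC, 0 at DC (where the direction
    cosine is undefined; the composed bandpass vanishes there anyway).  Large
    n concentrates the response around the orientation theta_l = pi*l/L.
    Real-valued for even n.
    """
    if not 0 <= l < L:
        raise ParameterError(f"orientation index l={l} out of range for L={L}")
    if n < 1 or int(n) != n:
        raise ParameterError(f"Hilbert order n must be a positive integer, got {n}")
    theta = np.pi * l / L
    ang = np.arctan2(grid.omega2, grid.omega1)
    c = np.cos(ang - theta) ** n
    c[(grid.omega1 == 0.0) & (grid.omega2 == 0.0)] = 0.0
    const = _MINUS_J_POW[n % 4]
    if n % 2 == 0:
        return const.real * c
    return const * c.astype(complex)


def dhbb_filterbank(shape: tuple[int, int], params: FDBParams) -> FilterBank:
    """Build the L-orientation DHBB filter bank for a padded image shape."""
    grid = FrequencyGrid.for_shape(shape)
    spec = ButterworthSpec(
        gamma=params.gamma,
        omega_L=params.omega_L,
        omega_H=params.omega_H,
        variant=params.variant,
    )
    bandpass = butterworth_2d_spectrum(grid, spec)
    spectra = [
        directional_hilbert_spectrum(grid, l, params.L, params.n) * bandpass
        for l in range(params.L)
    ]
    theta = np.pi * np.arange(params.L) / params.L
    return FilterBank(
        spectra=spectra, n=params.n, L=params.L, theta=theta, butterworth=spec, grid=grid
    )
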