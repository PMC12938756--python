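"""Time-domain photon-migration forward model for a semi-infinite medium.

The temporal point spread function (TPSF) — the distribution of photon
times of flight between a source and a detector a distance ``rho`` apart
on the surface of a homogeneous turbid half-space — is modelled in the
diffusion approximation with a zero-boundary (single image source)
condition:

    R(rho, t) = (4 pi D v)^(-3/2) * z0 * t^(-5/2)
                * exp(-(rho^2 + z0^2) / (4 D v t)) * exp(-mu_a * v * t)

where ``v = c / n`` is the speed of light in tissue (mm/ps),
``z0 = 1 / mu_s'`` the depth of the equivalent isotropic source and
``D`` the diffusion coefficient.  By default ``D = 1 / (3 mu_s')``,
independent of absorption, so the Beer–Lambert factorisation
``R(mu_a, t) = R(0, t) * exp(-mu_a v t)`` is exact; the historical
convention ``D = 1 / (3 (mu_a + mu_s'))`` is available behind a flag.

Units throughout: times in picoseconds (ps), lengths in millimetres
(mm), optical coefficients in mm^-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import integrate
from scipy.signal import fftconvolve

#: Speed of light in vacuum, mm/ps.
C_VACUUM_MM_PER_PS = 0.299792458

DConvention = Literal["scatter", "scatter+absorption"]


class QuadratureError(RuntimeError):
    """Numerical integration failed to reach the requested tolerance."""


@dataclass(frozen=True, eq=False)
class TimeAxis:
    """Uniform time base of a TCSPC histogram.

    Parameters
    ----------
    bin_edges
        Strictly increasing bin edges in picoseconds; widths must be
        uniform to within 1 part in 1e9.  At least two bins.
    """

    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        if edges.ndim != 1 or edges.size < 3:
            raise ValueError("time axis needs at least 2 bins (3 edges)")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        w = widths[0]
        if np.max(np.abs(widths - w)) > 1e-9 * w:
            raise ValueError("bin widths must be uniform to within 1 part in 1e9")

    @classmethod
    def regular(cls, n_bins: int = 1000, bin_width_ps: float = 10.0,
                t_start_ps: float = 0.0) -> "TimeAxis":
        """Regular axis starting at ``t_start_ps`` (left-edge = time zero)."""
        edges = t_start_ps + bin_width_ps * np.arange(n_bins + 1, dtype=float)
        return cls(edges)

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def __eq__(self, other: object):
        if not isinstance(other, TimeAxis):
            return NotImplemented
        return (self.bin_edges.shape == other.bin_edges.shape
                and bool(np.array_equal(self.bin_edges, other.bin_edges)))

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True)
class ProbeGeometry:
    """Source–detector geometry and refractive context of one probe.

    ``rho_mm`` is the source–detector separation on the tissue surface;
    ``n_tissue`` the tissue refractive index (default 1.4, the common
    soft-tissue value).
    """

    rho_mm: float
    n_tissue: float = 1.4
    c_vacuum: float = C_VACUUM_MM_PER_PS

    def __post_init__(self) -> None:
        if self.rho_mm <= 0:
            raise ValueError("rho_mm must be > 0")
        if self.n_tissue < 1:
            raise ValueError("n_tissue must be >= 1")

    @property
    def speed(self) -> float:
        """Speed of light in tissue, mm/ps."""
        return self.c_vacuum / self.n_tissue


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced scattering at one wavelength (mm^-1)."""

    wavelength_nm: float
    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if not (self.mu_a >= 0):
            raise ValueError("mu_a must be >= 0")
        if not (self.mu_s_prime > 0):
            raise ValueError("mu_s_prime must be > 0")


@dataclass(eq=False)
class TPSFCurve:
    """A model or measured reflectance curve on a :class:`TimeAxis`.

    ``values`` are nonnegative per-bin densities of arbitrary amplitude;
    ``area`` is their raw sum (counts-like convention, so discrete
    convolution multiplies areas).
    """

    axis: TimeAxis
    values: np.ndarray
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (self.axis.n_bins,):
            raise ValueError(
                f"values shape {vals.shape} does not match axis with "
                f"{self.axis.n_bins} bins")
        if not np.all(np.isfinite(vals)):
            raise ValueError("curve values must be finite")
        if np.any(vals < 0):
            raise ValueError("curve values must be nonnegative")
        self.values = vals

    @property
    def area(self) -> float:
        return float(self.values.sum())


def diffusion_coefficient(optics: OpticalProperties,
                          convention: DConvention = "scatter") -> float:
    """Diffusion coefficient D in mm for the chosen convention."""
    if convention == "scatter":
        return 1.0 / (3.0 * optics.mu_s_prime)
    if convention == "scatter+absorption":
        return 1.0 / (3.0 * (optics.mu_a + optics.mu_s_prime))
    raise ValueError(f"unknown diffusion-coefficient convention {convention!r}")


def reflectance_density(t_ps, optics: OpticalProperties,
                        geometry: ProbeGeometry, *,
                        d_convention: DConvention = "scatter"):
    """Evaluate R(rho, t) at arbitrary times (vectorised).

    Returns 0 for t <= 0 and wherever the closed form under- or
    overflows; never NaN/inf.
    """
    t = np.asarray(t_ps, dtype=float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    v = geometry.speed
    D = diffusion_coefficient(optics, d_convention)
    z0 = 1.0 / optics.mu_s_prime
    a = (geometry.rho_mm ** 2 + z0 ** 2) / (4.0 * D * v)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    with np.errstate(over="ignore", under="ignore"):
        log_r = (-1.5 * np.log(4.0 * np.pi * D * v) + np.log(z0)
                 - 2.5 * np.log(tp) - a / tp - optics.mu_a * v * tp)
        vals = np.exp(log_r)
    vals[~np.isfinite(vals)] = 0.0
    out[pos] = vals
    return float(out[0]) if scalar else out


def diffusion_reflectance(optics: OpticalProperties, geometry: ProbeGeometry,
                          axis: TimeAxis, *, t_shift_ps: float = 0.0,
                          d_convention: DConvention = "scatter") -> TPSFCurve:
    """Model TPSF sampled at the bin centers of ``axis``.

    ``t_shift_ps`` translates the curve later in time (used by the
    fitter to absorb the TCSPC trigger offset).
    """
    vals = reflectance_density(axis.centers - t_shift_ps, optics, geometry,
                               d_convention=d_convention)
    return TPSFCurve(axis, vals)


def _irf_values(irf) -> np.ndarray:
    if hasattr(irf, "counts"):
        return np.asarray(irf.counts, dtype=float)
    return np.asarray(irf.values, dtype=float)


def convolve_with_irf(tpsf: TPSFCurve, irf) -> TPSFCurve:
    """Discrete linear convolution with an instrument response, truncated
    to the original axis length.

    Areas multiply (up to the truncated tail); centroids satisfy
    ``centroid(out) = centroid(tpsf) + centroid(irf) - t_origin`` with
    ``t_origin`` the first bin center — the exact first-moment property
    of the index-sum convolution.
    """
    if not (tpsf.axis == irf.axis):
        raise ValueError(
            "time axes differ between TPSF and IRF "
            f"(bin widths {tpsf.axis.bin_width} ps and {irf.axis.bin_width} ps)")
    other = _irf_values(irf)
    full = fftconvolve(tpsf.values, other)
    out = np.maximum(full[: tpsf.axis.n_bins], 0.0)
    return TPSFCurve(tpsf.axis, out, amplitude=tpsf.amplitude)


def mean_time(curve: TPSFCurve) -> float:
    """Count-weighted centroid (first moment) of the curve, in ps."""
    total = curve.values.sum()
    if total <= 0:
        raise ValueError("mean_time undefined for zero-area curve")
    return float(np.dot(curve.values, curve.axis.centers) / total)


def _peak_time(optics: OpticalProperties, geometry: ProbeGeometry,
               d_convention: DConvention = "scatter") -> float:
    """Mode of R(t): root of s*t^2 + 2.5*t - a = 0."""
    v = geometry.speed
    D = diffusion_coefficient(optics, d_convention)
    z0 = 1.0 / optics.mu_s_prime
    a = (geometry.rho_mm ** 2 + z0 ** 2) / (4.0 * D * v)
    s = optics.mu_a * v
    if s == 0:
        return a / 2.5
    return (-2.5 + np.sqrt(2.5 ** 2 + 4.0 * s * a)) / (2.0 * s)


def total_reflectance(optics: OpticalProperties, geometry: ProbeGeometry, *,
                      horizon_ps: float = 20000.0, rtol: float = 1e-8,
                      d_convention: DConvention = "scatter") -> float:
    """Time integral of the TPSF over [0, horizon_ps] by adaptive quadrature.

    Strictly decreasing in mu_a.  Raises :class:`QuadratureError` with
    the achieved tolerance if the integrator cannot reach ``rtol``.
    """
    tp = _peak_time(optics, geometry, d_convention)

    def f(t: float) -> float:
        return reflectance_density(t, optics, geometry, d_convention=d_convention)

    points = sorted({min(tp, horizon_ps * 0.5), min(10.0 * tp, horizon_ps * 0.9)})
    val, err = integrate.quad(f, 0.0, horizon_ps, points=points,
                              limit=200, epsabs=0.0, epsrel=rtol * 1e-2)
    if not np.isfinite(val) or val <= 0 or err > rtol * val:
        achieved = err / val if val > 0 else np.inf
        raise QuadratureError(
            f"quadrature achieved relative tolerance {achieved:.3e} "
            f"(requested {rtol:.1e})")
    return float(val)


def stationary_reflectance(optics: OpticalProperties,
                           geometry: ProbeGeometry) -> float:
    """Closed-form time integral of the zero-boundary TPSF (D = 1/(3 mu_s')).

    R_total = z0 (mu_eff + 1/r1) exp(-mu_eff r1) / (2 pi r1^2), with
    r1 = sqrt(rho^2 + z0^2) and mu_eff = sqrt(3 mu_a mu_s').  Obtained
    from the Bessel-K(3/2) Laplace identity; serves as an independent
    oracle for :func:`total_reflectance`.
    """
    z0 = 1.0 / optics.mu_s_prime
    r1 = np.hypot(geometry.rho_mm, z0)
    mu_eff = np.sqrt(3.0 * optics.mu_a * optics.mu_s_prime)
    return float(z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1)
                 / (2.0 * np.pi * r1 ** 2))


def mean_path_length_cw(optics: OpticalProperties,
                        geometry: ProbeGeometry) -> float:
    """Closed-form mean photon path length -d ln R_total / d mu_a, in mm.

    Valid for the mu_a-independent diffusion coefficient, where the
    absorption derivative of the log time-integrated reflectance equals
    v <t> exactly.
    """
    if optics.mu_a <= 0:
        raise ValueError("closed-form path length requires mu_a > 0")
    D = diffusion_coefficient(optics, "scatter")
    z0 = 1.0 / optics.mu_s_prime
    r1 = np.hypot(geometry.rho_mm, z0)
    mu_eff = np.sqrt(optics.mu_a / D)
    dmu_eff = 1.0 / (2.0 * np.sqrt(optics.mu_a * D))
    return float((r1 - 1.0 / (mu_eff + 1.0 / r1)) * dmu_eff)
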