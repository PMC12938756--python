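"""Inversion of TCSPC histograms to tissue optical properties.

A measured time-of-flight histogram is fitted with the diffusion-model
TPSF convolved with the measured instrument response function (IRF),
by Poisson-weighted nonlinear least squares over four free parameters:
mu_a, mu_s', a log-amplitude, and a trigger time shift.  The module
also computes the derived per-measurement optical parameters compared
between probe sites: photon count rate, attenuation (optical density)
and mean optical path length, plus a segment-level quality filter that
rejects unstable acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import fftconvolve

from .forward import (
    OpticalProperties,
    ProbeGeometry,
    TimeAxis,
    TPSFCurve,
    mean_time,
    reflectance_density,
    total_reflectance,
)

MIDLINE = "midline"
LATERAL = "lateral"


@dataclass(eq=False)
class TimeHistogram:
    """Binned photon time-of-flight counts for one wavelength/site/segment."""

    axis: TimeAxis
    counts: np.ndarray
    acquisition_s: float
    wavelength_nm: Optional[float] = None
    site: Optional[str] = None
    segment_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (self.axis.n_bins,):
            raise ValueError(
                f"counts shape {c.shape} does not match axis with "
                f"{self.axis.n_bins} bins")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("counts must be finite and nonnegative")
        if self.acquisition_s <= 0:
            raise ValueError("acquisition_s must be > 0")
        self.counts = c

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def as_curve(self) -> TPSFCurve:
        return TPSFCurve(self.axis, self.counts)


@dataclass(eq=False)
class InstrumentResponse:
    """IRF histogram plus the incident photon budget it references.

    ``total_incident`` is the number of photons launched into the tissue
    during ``acquisition_s`` seconds; it anchors the attenuation
    (optical density) scale.
    """

    axis: TimeAxis
    counts: np.ndarray
    total_incident: Optional[float] = None
    acquisition_s: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.shape != (self.axis.n_bins,):
            raise ValueError(
                f"counts shape {c.shape} does not match axis with "
                f"{self.axis.n_bins} bins")
        if not np.all(np.isfinite(c)) or np.any(c < 0):
            raise ValueError("IRF counts must be finite and nonnegative")
        if c.sum() <= 0:
            raise ValueError("IRF must have positive area")
        self.counts = c

    @property
    def area(self) -> float:
        return float(self.counts.sum())

    def as_curve(self) -> TPSFCurve:
        return TPSFCurve(self.axis, self.counts)


@dataclass
class FitOptions:
    """Tunables of the histogram fit.

    The fit window runs from where the (lightly smoothed) rising edge
    first reaches ``rise_fraction`` of the peak to where the tail falls
    below ``tail_fraction`` of the peak — the usual TRS fitting-range
    convention.
    """

    mu_a_bounds: tuple = (1e-4, 1.0)
    mu_s_prime_bounds: tuple = (0.05, 5.0)
    t_shift_bounds_ps: tuple = (-200.0, 200.0)
    rise_fraction: float = 0.01
    tail_fraction: float = 1e-3
    smooth_bins: int = 5
    min_total_counts: float = 1e4
    min_window_bins: int = 20
    n_restarts: int = 3
    reweight_passes: int = 1
    xtol: float = 1e-12
    ftol: float = 1e-12
    gtol: float = 1e-12
    max_nfev: int = 400
    d_convention: str = "scatter"


@dataclass
class FitResult:
    """Converged optical properties and fit diagnostics."""

    optics: OpticalProperties
    amplitude: float
    t_shift_ps: float
    reduced_chi2: float
    n_iterations: int
    converged: bool
    fit_window: tuple
    n_restarts_used: int = 0
    message: str = ""


@dataclass
class DerivedOpticalParams:
    """Per-measurement parameters compared between probe sites."""

    count_rate: float              # counts / s
    attenuation: float             # optical density, log10 units
    mean_path_length_mm: float     # centroid estimator
    model_path_length_mm: float    # -d ln R_total / d mu_a at the fit
    path_flagged: bool = False


def _fit_window(counts: np.ndarray, options: FitOptions) -> tuple:
    kernel = np.ones(options.smooth_bins) / options.smooth_bins
    smooth = np.convolve(counts, kernel, mode="same")
    peak = smooth.max()
    if peak <= 0:
        raise ValueError("empty histogram")
    ipk = int(np.argmax(smooth))
    above = np.nonzero(smooth[: ipk + 1] >= options.rise_fraction * peak)[0]
    lo = int(above[0]) if above.size else 0
    below = np.nonzero(smooth[ipk:] < options.tail_fraction * peak)[0]
    hi = int(ipk + below[0]) if below.size else counts.size
    if hi - lo < options.min_window_bins:
        raise ValueError(
            f"fit window [{lo}, {hi}) narrower than "
            f"{options.min_window_bins} bins")
    return lo, hi


def fit_tpsf(hist: TimeHistogram, irf: InstrumentResponse,
             geometry: ProbeGeometry,
             init: Optional[OpticalProperties] = None,
             options: Optional[FitOptions] = None) -> FitResult:
    """Recover (mu_a, mu_s') from one histogram by nonlinear least squares.

    Minimizes Poisson-weighted squared residuals between the measurement
    and ``amplitude * conv(R(t - t_shift), IRF)`` over the fit window.
    Initial weights are ``1/max(counts, 1)``; by default one further
    pass refits with weights taken from the fitted model
    (``1/max(model, 1)``), which removes the small upward bias that
    data-driven weights induce through the noise–weight correlation.
    Returns ``converged=False`` (after jittered restarts) rather than
    raising when the optimizer stalls or pins a parameter at a bound.
    """
    options = options or FitOptions()
    if not (hist.axis == irf.axis):
        raise ValueError(
            "histogram and IRF time axes differ "
            f"(bin widths {hist.axis.bin_width} ps and {irf.axis.bin_width} ps)")
    counts = hist.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    if total < options.min_total_counts:
        raise ValueError(
            f"total counts {total:.0f} below configured minimum "
            f"{options.min_total_counts:.0f}")
    lo, hi = _fit_window(counts, options)
    centers = hist.axis.centers
    irf_norm = irf.counts / irf.counts.sum()
    n = hist.axis.n_bins
    weights = 1.0 / np.sqrt(np.maximum(counts[lo:hi], 1.0))
    wl = hist.wavelength_nm if hist.wavelength_nm is not None else 0.0

    def model_shape(mu_a: float, mu_sp: float, t_shift: float) -> np.ndarray:
        optics = OpticalProperties(wl, mu_a, mu_sp)
        curve = reflectance_density(centers - t_shift, optics, geometry,
                                    d_convention=options.d_convention)
        conv = fftconvolve(curve, irf_norm)[:n]
        return np.maximum(conv, 0.0)

    def make_residuals(w: np.ndarray):
        def residuals(x: np.ndarray) -> np.ndarray:
            mu_a, mu_sp, log_amp, t_shift = x
            model = np.exp(log_amp) * model_shape(mu_a, mu_sp, t_shift)
            return (model[lo:hi] - counts[lo:hi]) * w
        return residuals

    residuals = make_residuals(weights)

    if init is None:
        init = OpticalProperties(wl, 0.01, 1.0)
    # multiplicative jitters applied on restart when the first fit stalls
    jitters = [(1.0, 1.0), (0.6, 1.5), (1.6, 0.7), (0.5, 0.6)]
    best = None
    restarts_used = 0
    for k, (ja, js) in enumerate(jitters[: options.n_restarts + 1]):
        mu_a0 = float(np.clip(init.mu_a * ja, *options.mu_a_bounds))
        mu_sp0 = float(np.clip(init.mu_s_prime * js, *options.mu_s_prime_bounds))
        shape0 = model_shape(mu_a0, mu_sp0, 0.0)
        denom = shape0[lo:hi].sum()
        if denom <= 0:
            continue
        log_amp0 = float(np.log(counts[lo:hi].sum() / denom))
        x0 = np.array([mu_a0, mu_sp0, log_amp0, 0.0])
        lower = [options.mu_a_bounds[0], options.mu_s_prime_bounds[0],
                 log_amp0 - 15.0, options.t_shift_bounds_ps[0]]
        upper = [options.mu_a_bounds[1], options.mu_s_prime_bounds[1],
                 log_amp0 + 15.0, options.t_shift_bounds_ps[1]]
        res = least_squares(residuals, x0, bounds=(lower, upper),
                            x_scale=[0.01, 1.0, 1.0, 50.0],
                            xtol=options.xtol, ftol=options.ftol,
                            gtol=options.gtol, max_nfev=options.max_nfev)
        mu_a, mu_sp = res.x[0], res.x[1]
        at_bound = (
            mu_a <= options.mu_a_bounds[0] * (1 + 1e-9)
            or mu_a >= options.mu_a_bounds[1] * (1 - 1e-9)
            or mu_sp <= options.mu_s_prime_bounds[0] * (1 + 1e-9)
            or mu_sp >= options.mu_s_prime_bounds[1] * (1 - 1e-9))
        ok = bool(res.success) and not at_bound
        if best is None or res.cost < best[0].cost:
            best = (res, ok)
        restarts_used = k
        if ok:
            break
    res, ok = best
    for _ in range(options.reweight_passes if ok else 0):
        mu_a, mu_sp, log_amp, t_shift = res.x
        model = np.exp(log_amp) * model_shape(mu_a, mu_sp, t_shift)
        w = 1.0 / np.sqrt(np.maximum(model[lo:hi], 1.0))
        res2 = least_squares(make_residuals(w), res.x,
                             bounds=(lower, upper),
                             x_scale=[0.01, 1.0, 1.0, 50.0],
                             xtol=options.xtol, ftol=options.ftol,
                             gtol=options.gtol, max_nfev=options.max_nfev)
        if not res2.success:
            break
        res = res2
    mu_a, mu_sp, log_amp, t_shift = res.x
    dof = max(hi - lo - 4, 1)
    return FitResult(
        optics=OpticalProperties(wl, float(mu_a), float(mu_sp)),
        amplitude=float(np.exp(log_amp)),
        t_shift_ps=float(t_shift),
        reduced_chi2=float(2.0 * res.cost / dof),
        n_iterations=int(res.nfev),
        converged=ok,
        fit_window=(lo, hi),
        n_restarts_used=restarts_used,
        message=str(res.message),
    )


def count_rate(hist: TimeHistogram) -> float:
    """Detected photon rate, counts per second."""
    return hist.total_counts / hist.acquisition_s


def attenuation(hist: TimeHistogram, irf: InstrumentResponse) -> float:
    """Optical density log10(incident / detected), rates matched in time.

    Incident and detected photon numbers are each normalized by their
    own acquisition duration before taking the ratio, so the quantity is
    invariant under joint rescaling of both.
    """
    if irf.total_incident is None or irf.total_incident <= 0:
        raise ValueError("IRF carries no positive total_incident reference")
    detected = hist.total_counts
    if detected <= 0:
        raise ValueError("attenuation undefined for zero detected counts")
    incident_rate = irf.total_incident / irf.acquisition_s
    detected_rate = detected / hist.acquisition_s
    return float(np.log10(incident_rate / detected_rate))


@dataclass
class PathLengthResult:
    """Centroid and model estimators of the mean optical path length."""

    centroid_mm: float
    model_mm: float
    flagged: bool


def mean_path_length(fit: FitResult, hist: TimeHistogram,
                     irf: InstrumentResponse, geometry: ProbeGeometry, *,
                     fd_step: float = 1e-5) -> PathLengthResult:
    """Mean optical path length in mm, two estimators.

    Primary: IRF-corrected centroid, v * (t̄_hist - t̄_irf).  Cross-check:
    -d ln(R_total)/d mu_a at the fitted optics by central finite
    difference (the standard attenuation-derivative identity).  A
    negative centroid difference is flagged, never clamped.
    """
    dt = mean_time(hist.as_curve()) - mean_time(irf.as_curve())
    centroid_mm = geometry.speed * dt
    mu_a = fit.optics.mu_a
    step = min(fd_step, mu_a / 2) if mu_a > 0 else fd_step
    up = replace(fit.optics, mu_a=mu_a + step)
    down = replace(fit.optics, mu_a=max(mu_a - step, 1e-9))
    lr_up = np.log(total_reflectance(up, geometry))
    lr_dn = np.log(total_reflectance(down, geometry))
    model_mm = float(-(lr_up - lr_dn) / (up.mu_a - down.mu_a))
    return PathLengthResult(centroid_mm=float(centroid_mm),
                            model_mm=model_mm,
                            flagged=bool(dt <= 0))


def merge_segments(segments: Sequence[TimeHistogram]) -> TimeHistogram:
    """Sum segment histograms into one acquisition."""
    if not segments:
        raise ValueError("no segments to merge")
    first = segments[0]
    counts = np.zeros(first.axis.n_bins)
    acq = 0.0
    for seg in segments:
        if not (seg.axis == first.axis):
            raise ValueError("segments live on different time axes")
        counts += seg.counts
        acq += seg.acquisition_s
    return TimeHistogram(first.axis, counts, acq,
                         wavelength_nm=first.wavelength_nm,
                         site=first.site, segment_id="merged",
                         meta=dict(first.meta))


def _dispersion_ratio(counts: np.ndarray, smooth_bins: int = 5) -> float:
    """Variance of Poisson-standardized residuals about a moving average.

    ~0.8 for clean Poisson data (the window includes the bin itself);
    large for spiky or drifting segments.  Bins with smoothed mean < 5
    are ignored.
    """
    kernel = np.ones(smooth_bins) / smooth_bins
    smooth = np.convolve(counts, kernel, mode="same")
    mask = smooth >= 5
    if mask.sum() < 10:
        return 0.0
    z = (counts[mask] - smooth[mask]) / np.sqrt(smooth[mask])
    return float(np.var(z))


@dataclass
class QualityReport:
    accepted: list
    rejected: list
    records: list  # dicts: segment_id, rule, value


def quality_filter(segments: Sequence[TimeHistogram], *,
                   rate_tolerance: float = 0.10,
                   dispersion_max: float = 3.0,
                   smooth_bins: int = 5) -> QualityReport:
    """Reject segments with unstable count rates or non-Poisson dispersion.

    A segment is rejected when its count rate deviates from the series
    median by more than ``rate_tolerance`` (fractional), or when its
    within-segment dispersion ratio exceeds ``dispersion_max``.  A single
    segment has no median reference and is accepted on the rate rule.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("quality_filter requires at least one segment")
    rates = np.array([count_rate(s) for s in segments])
    median_rate = float(np.median(rates))
    accepted, rejected, records = [], [], []
    for seg, rate in zip(segments, rates):
        rule = None
        value = None
        if len(segments) > 1 and median_rate > 0:
            dev = abs(rate - median_rate) / median_rate
            if dev > rate_tolerance:
                rule, value = "count_rate_deviation", dev
        if rule is None:
            ratio = _dispersion_ratio(seg.counts, smooth_bins)
            if ratio > dispersion_max:
                rule, value = "dispersion_ratio", ratio
        if rule is None:
            accepted.append(seg)
        else:
            rejected.append(seg)
            records.append({"segment_id": seg.segment_id,
                            "rule": rule, "value": value})
    return QualityReport(accepted=accepted, rejected=rejected, records=records)
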