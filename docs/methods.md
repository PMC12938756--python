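# Methods

## Forward model

Photon transport is modelled by the diffusion approximation for a
semi-infinite homogeneous medium with a zero boundary condition (single
image source at depth `z0 = 1/μs′`). The package uses the
absorption-independent diffusion coefficient `D = 1/(3 μs′)` — the
modern TRS convention — which makes the Beer–Lambert factorisation
`R(μa, t) = R(0, t)·exp(−μa v t)` exact; the historical
`D = 1/(3(μa+μs′))` variant is available via the `d_convention` flag.
The extrapolated-boundary solution and layered or curved geometries are
out of scope. Tissue refractive index defaults to `n = 1.4`
(`c = 0.299792458 mm/ps`). The closed form is evaluated in log space;
it is defined as 0 at `t ≤ 0` and wherever the exponentials under- or
overflow, so no NaN can propagate.

The time base is a uniform TCSPC axis, default 1000 bins × 10 ps
(0–10 ns), left edge at time zero, with model evaluation at bin
centers. Discrete convolution with the instrument response follows the
plain truncated linear convolution: mass at output index `k` comes from
index pairs summing to `k`, so the output centroid equals
`centroid(a) + centroid(b) − t₀` with `t₀` the first bin center. One
consequence is a half-bin-width (≈5 ps, ≈1 mm) downward offset of the
centroid path-length estimator on self-generated data; at the optical
properties of interest this stays well below the 1% agreement tolerance
against the model-based estimator.

The time-integrated reflectance is computed by adaptive quadrature over
0–20 ns (relative tolerance 1e-8, integration failure raises with the
achieved tolerance). An independently derived closed form,
`R_total = z0 (μeff + 1/r1) e^(−μeff r1) / (2π r1²)` with
`r1 = √(ρ² + z0²)`, `μeff = √(3 μa μs′)`, serves as its oracle and as
the fast analytic path length `−d ln R_total/d μa`.

## Histogram inversion

Four free parameters: μa, μs′, a log-amplitude and a trigger time
shift (without the shift, IRF misalignment biases μs′). Bounds:
μa ∈ [1e-4, 1] mm⁻¹, μs′ ∈ [0.05, 5] mm⁻¹, shift ∈ ±200 ps. The fit
window runs from where the lightly smoothed rising edge first reaches
1% of peak to where the tail falls below 0.1% of peak (a common TRS
convention; proprietary instrument windows are not public). Residuals
are Poisson-weighted, initially by `1/max(counts, 1)`. Because weights
computed from the noisy data correlate with the residuals, that
weighting biases μa upward by a few tenths of a percent at 10⁶ counts
— small, but systematic and slightly condition-dependent, which is
enough to contaminate a paired null comparison at n = 30. The fitter
therefore refits once with weights taken from the fitted model
(`reweight_passes = 1`), which removes the bias (measured residual bias
≈ 0.01%, within Monte Carlo error). Non-convergence triggers up to
three jittered restarts and is reported via `converged=False`, never an
exception; a parameter pinned at a bound is treated as non-converged.

Derived parameters: count rate (total counts / acquisition time);
attenuation `log10(incident rate / detected rate)` referenced to the
IRF's incident-photon budget (instrument definitions are unpublished;
the synthetic generator uses the same convention so the quantity is
internally consistent); mean optical path length with the IRF-corrected
centroid as primary estimator and `−∂ln R_total/∂μa` at the fitted
optics as cross-check — both are reported, and a negative centroid
difference is flagged rather than clamped. Whether a given instrument's
"path length" is centroid- or fit-based is not generally disclosed,
hence both.

The segment quality filter operationalizes "stable count rates and
temporal profiles" as: reject a segment whose count rate deviates more
than 10% from the series median, or whose variance of
Poisson-standardized residuals about a 5-bin moving average exceeds 3
(clean Poisson data give ≈0.8). A single segment has no median
reference and is accepted.

## Chromophore decomposition and endpoints

The 3×2 extinction system is solved by least squares so the
near-isosbestic 801 nm row contributes; the residual norm is kept as a
QC output and a rank-deficient matrix raises with its condition number.
Negative concentrations are reported with a flag, never clipped —
clipping would silently break `totalHb = oxyHb + deoxyHb`. The shipped
extinction table is compiled from standard literature tabulations
(converted to μM⁻¹ mm⁻¹) and is fully overridable; absolute
concentration comparability with any specific instrument is not
claimed — correctness claims are round-trip claims. Background
absorption defaults to the water spectrum × 0.90 volume fraction
(neonatal brain), with a zero-background mode for tests. CBV evaluates
its defining formula literally; the unit bookkeeping was verified by
hand (50 µM tHb, 15 g/dL venous, Dt = 1.05 → 3.225/1.575 ≈ 2.048
mL/100 g) before being frozen into tests.

## Synthetic cohort

Each synthetic subject draws site-independent hemodynamics — totalHb ~
N(45, 8) µM, ScO₂ ~ N(65, 5) % (converted to oxy/deoxy), venous tHb ~
N(15, 2) g/dL truncated above 5 — and site-dependent optics: midline
μs′ per wavelength ~ N(0.9, 0.1) mm⁻¹ (inside the 0.5–1.0 mm⁻¹
gray/white bracket), lateral μs′ = midline × factor ~ N(0.90, 0.03),
lateral detected intensity × factor ~ N(1.3, 0.1) truncated above 1.
The site effect is multiplicative on μs′ and intensity, not a geometry
change; an optional lateral ρ-shortening mode (off by default) probes
the curvature hypothesis. Acquisitions are 5 minutes at 10⁶
counts/wavelength against a shared Gaussian IRF (FWHM 150 ps), emitted
as 10 × 30 s segments, with independent per-bin Poisson noise. All
distribution parameters are configuration, chosen once as plausible for
term-corrected neonates; none is presented as a measured cohort value,
since no cohort-level reference numbers are available to anchor them.

What the generator does *not* emulate: motion-artifact waveforms,
superficial venous contamination, layered or curved anatomy,
inter-device variability, or drift within an acquisition. Passing
tests therefore demonstrate the correctness and calibration of the
estimation and statistics chain under the stated model, not robustness
to those real-world effects.

A parameter-level fast path (`generate_parameter_cohort`) samples the
derived per-site records directly — truth × (1 + Gaussian fit scatter:
μa 2%, μs′ 1%, path 0.5%, counts 0.1%, the order of Poisson-fit scatter
at 10⁶ counts) — for statistical calibration studies over hundreds of
replicate cohorts. Under the null the type-I error of the comparison
stage does not depend on those scatter magnitudes.

## Paired statistics

"Paired t or Wilcoxon, as appropriate" is operationalized as a
Shapiro–Wilk gate at α = 0.05 on the paired differences, recorded per
row. Wilcoxon drops zero differences, uses midranks for ties, an exact
null for n ≤ 25 without ties and otherwise the normal approximation
with continuity correction. Constant-zero differences short-circuit to
a degenerate non-significant row. Significance is flagged at
uncorrected p < 0.05 (matching the analysis convention emulated); a
Holm-adjusted column is emitted but not used for flags. The single
intensity and attenuation rows are across-wavelength means of the
per-wavelength values; path length, μs′ and μa are wavelength-resolved
(14 rows total).

## Problem sizes and determinism

Default analyses run at n = 30 paired subjects, 10⁶ counts per
wavelength, 100-seed recovery calibrations and 200-replicate null
calibrations — sizes at which every reported rate is stable while the
full suite stays desk-scale. All randomness flows from explicit seeds
through `numpy.random.Generator`; identical (config, seed) reproduces
datasets, fits and comparison tables bit-identically, and every output
table records the configuration hash.

## Known limitations

- The homogeneous semi-infinite diffusion model ignores the layered
  neonatal head; recovered μa/μs′ are effective-medium values.
- The centroid path length inherits the half-bin convolution offset
  (≈1 mm at 10 ps bins) and a small truncation bias from the finite
  10 ns axis.
- Attenuation depends on an incident-photon reference that real
  devices define internally; only within-study contrasts are
  meaningful.
- The extinction table and water background are literature compilations;
  absolute hemoglobin values shift with that choice, while round-trip
  and site-contrast results do not.
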