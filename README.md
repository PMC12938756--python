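# neotrs

Time-resolved near-infrared spectroscopy (TRS) quantification for
neonatal cerebral monitoring, with a synthetic paired-site study
generator.

TRS instruments launch picosecond light pulses into the head and
histogram single-photon arrival times (TCSPC). Because the *shape* of
the time-of-flight distribution separates absorption from scattering,
TRS yields absolute tissue optical properties — unlike continuous-wave
oximetry. `neotrs` implements the full chain from raw histograms to
clinical endpoints, plus the paired midline-vs-lateral forehead
comparison used to assess whether probe position affects those
endpoints.

## Model

The temporal point spread function of a semi-infinite homogeneous
medium (diffusion approximation, zero-boundary condition) is

```
R(ρ, t) = (4πDv)^(-3/2) · z₀ · t^(-5/2) · exp(−(ρ² + z₀²)/(4Dvt)) · exp(−μₐvt)
```

with `v = c/n`, `z₀ = 1/μs′`, and `D = 1/(3 μs′)` (absorption-independent
by default, so `R(μₐ,t) = R(0,t)·e^(−μₐvt)` exactly). A measured
histogram is fitted with `amplitude · (R ∗ IRF)(t − t₀)` by
Poisson-weighted least squares over (μₐ, μs′, amplitude, trigger shift).

Fitted absorption at 762/801/836 nm is decomposed through

```
μₐ(λ) = ε_oxy(λ)[oxyHb] + ε_deoxy(λ)[deoxyHb] + μₐ_background(λ)
```

and the endpoints follow as

```
totalHb = [oxyHb] + [deoxyHb]                          (µM)
ScO₂    = [oxyHb]/([oxyHb]+[deoxyHb]) × 100            (%)
CBV     = totalHb·MW_Hb·10⁻⁶ / (tHb_venous·10⁻²·Dt·10) (mL/100 g)
```

with `MW_Hb = 64500 g/mol`, tissue density `Dt = 1.05 g/mL` and the
venous hemoglobin concentration in g/dL.

Derived optical parameters per measurement: photon count rate,
attenuation `log10(incident/detected)` (OD), and mean optical path
length `⟨L⟩ = v·(t̄_hist − t̄_IRF)` (cross-checked against
`−∂ln R_total/∂μₐ`).

## Worked example

Simulate one 5-minute, 10⁶-count acquisition at 801 nm (ρ = 30 mm,
150 ps IRF) and invert it:

```python
import numpy as np
from neotrs import *
from neotrs.cohort import make_irf

axis = TimeAxis.regular(1000, 10.0)            # 0–10 ns, 10 ps bins
geom = ProbeGeometry(rho_mm=30.0, n_tissue=1.4)
irf  = make_irf(axis, fwhm_ps=150.0, t0_ps=300.0, area=1e6,
                total_incident=1e12, acquisition_s=300.0)

truth = OpticalProperties(801, mu_a=0.0115, mu_s_prime=0.9)
tpsf  = diffusion_reflectance(truth, geom, axis)
model = convolve_with_irf(tpsf, InstrumentResponse(axis, irf.counts / irf.area))
rng   = np.random.default_rng(0)
counts = rng.poisson(model.values * (1e6 / model.values.sum()))
hist  = TimeHistogram(axis, counts.astype(float), 300.0, wavelength_nm=801)

fit = fit_tpsf(hist, irf, geom)
pl  = mean_path_length(fit, hist, irf, geom)
print(f"mu_a  = {fit.optics.mu_a:.5f} mm^-1   (truth 0.01150)")
print(f"mu_s' = {fit.optics.mu_s_prime:.4f} mm^-1    (truth 0.9000)")
print(f"<L>   = {pl.centroid_mm:.1f} mm (centroid), {pl.model_mm:.1f} mm (model)")
print(f"A     = {attenuation(hist, irf):.3f} OD, rate = {count_rate(hist):.0f} /s")
```

prints

```
mu_a  = 0.01148 mm^-1   (truth 0.01150)
mu_s' = 0.8993 mm^-1    (truth 0.9000)
<L>   = 192.3 mm (centroid), 193.5 mm (model)
A     = 5.999 OD, rate = 3340 /s
```

— absorption and scattering recovered to a fraction of a percent from a
single noisy histogram, a ~190 mm mean photon path over a 30 mm
probe spacing, and a 6-OD attenuation typical of a transcranial
measurement.

The end-to-end study (synthetic cohort of 30 paired subjects →
quality filter → fits → hemodynamics → paired statistics) runs from
the command line:

```
neotrs run --seed 42 --out results/
```

writing `truth.tsv`, `fit_results.tsv`, `parameters.tsv` and a 14-row
`comparison.tsv`. `neotrs simulate / fit / hemo / compare` expose the
individual stages.

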