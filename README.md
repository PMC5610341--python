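# hemospec

Quantitative hemoglobin measurement by fiber-probe **diffuse reflectance
spectroscopy (DRS)**, as a tested, reusable Python pipeline that runs
entirely on synthetic data.

In visible-band DRS, light delivered by illumination fibers migrates through
a turbid medium — scattered by microstructure, absorbed by chromophores —
and the fraction re-collected by a central fiber encodes the absorption
coefficient μ_a(λ) and the reduced scattering coefficient μ_s′(λ). For a
liquid phantom of oxygenated hemoglobin and polystyrene microspheres these
follow

- Beer–Lambert: μ_a(λ) = ε(λ)·c_Hb, with ε the (effective) extinction
  spectrum and c_Hb the hemoglobin concentration in μM;
- Lorenz–Mie theory: μ_s′(λ) = Q_sca(x, m)·πr²·ρ·(1 − g), well approximated
  over 430–630 nm by the power law μ_s′ = A·(λ/530 nm)^(−b).

The package implements the full measurement-and-retrieval chain around
those two models:

- **Scaled Monte Carlo transport** (`hemospec.montecarlo`): a weighted-photon
  random walk in a semi-infinite medium with Henyey–Greenstein scattering
  builds a reusable *photon bank*; records rescale to any (μ_a, μ_s) by
  r′ = r·μ_s,ref/μ_s and w′ = w·exp(−μ_a L′). An analytic ring–disc overlap
  converts exit radii into the reflectance of a 6-around-1 probe (400 μm
  cores, 480 μm pitch). A diffusion-dipole closed form serves as an
  independent cross-check.
- **Phantom optics** (`hemospec.optics`): Lorenz–Mie efficiencies and
  asymmetry from the partial-wave series, Cauchy dispersion for water and
  polystyrene, Beer–Lambert absorption, power-law μ_s′.
- **Spectrometer chain** (`hemospec.processing`): raw Bayer mosaic → grey
  (2×2 cell sums) → slit-summed 1-D spectrum → linear wavelength calibration
  → peak/FWHM resolution analysis → background-subtracted reflectance ratio
  R(λ) = (sample − background)/(reference − background).
- **Calibration and inversion** (`hemospec.forward`, `hemospec.inversion`):
  a reference phantom of known properties pins the per-wavelength instrument
  factor k(λ) = measured/predicted; bounded nonlinear least squares then
  retrieves θ = (c_Hb, A, b) from any calibrated spectrum over 430–630 nm,
  and a leave-one-out study uses each of the 16 phantoms as reference once.
- **Synthetic data** (`hemospec.synthetic`): the 16-phantom titration series
  (c_Hb = 5.39…36.16 μM; fixed sphere count, so μ_s′ dilutes linearly in c),
  an oxyhemoglobin-like ε(λ) with Soret/β/α bands, instrument response +
  background + multiplicative noise, and synthetic Bayer frames.

## Worked example

```python
import numpy as np
import hemospec as hs

grid = np.linspace(430, 630, 51)
bank = hs.simulate_bank(mu_s_ref=100.0, g=hs.mie_g(), n_photons=100_000, seed=42)
model = hs.ReflectanceModel(bank, hs.ProbeGeometry())

ext = hs.default_extinction_model()
phantoms = hs.make_table1_series()
instrument = hs.default_instrument(grid, noise_cv=0.02, seed=1)
inputs = hs.make_study_inputs(phantoms, ext, model.predict, instrument)
study = hs.leave_one_out_study(inputs, model, hs.synth_extinction(ext, grid))
print(f"mu_a {study.mean_pct_err_mua:.2f}%  mu_s' {study.mean_pct_err_musp:.2f}%")
```

which prints, after a few minutes of Monte Carlo and 256 inversions:

```
mu_a 2.92%  mu_s' 0.66%
```

i.e. across all 240 phantom/reference pairs the retrieved band-averaged
absorption (equivalently c_Hb, since μ_a = ε·c_Hb) deviates from the design
values by 2.92% on average and the reduced scattering by 0.66% — the
reference-phantom spread contributed by 2% multiplicative measurement noise
alone, without real-instrument imperfections. `examples/` holds five
narrative scripts, one per capability (phantom series, image chain, optics,
photon bank, retrieval study).

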