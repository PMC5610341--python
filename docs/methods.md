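# Methods

This note documents the models behind `hemospec`, the defaults they ship
with, and what the synthetic studies do and do not demonstrate.

## Phantom design and its two regression anchors

The phantom series emulates a titration: a polystyrene-microsphere
suspension (1 μm diameter, in water) receives increasing volumes of an
oxygenated-hemoglobin stock, producing 16 samples with c_Hb from 5.39 to
36.16 μM. Because the number of spheres is fixed while the volume grows,
the sphere density — and with it μ_s′ — dilutes as V₀/V_i = 1 − c_i/S for
stock concentration S. Two regressions on the printed design table recover
everything the generator needs:

- **ε̄ = 0.08545 cm⁻¹·μM⁻¹** — the no-intercept least-squares slope of the
  expected band-averaged μ_a on c (the band-effective extinction, with the
  ln 10 factor folded in so μ_a = ε·c directly);
- **μ_s′ = 13.484 − 0.17410·c cm⁻¹** — the ordinary least-squares dilution
  line, giving S = 77.45 μM and dilution_i = 1/(1 − c_i/S).

Both linear models reproduce all 16 printed μ_a and μ_s′ values within
±0.006 cm⁻¹ (R² > 0.9999), which is what makes the table usable as ground
truth. All band averages in the package are arithmetic means of the samples
falling in 430–630 nm, computed by one shared routine.

## Synthetic extinction spectrum

The real extinction curve of the hemoglobin stock is not recoverable from
band-averaged data, so the generator uses a stand-in: Gaussian bands at
415 nm (Soret, σ = 20 nm), 541 nm (β, σ = 15), 576 nm (α, σ = 13), plus a
broad underlay at 470 nm (σ = 65) representing the non-Gaussian Soret wing,
and a small constant baseline (0.4% of the Soret amplitude) keeping ε > 0
out to 1000 nm. Amplitude ratios (1 : 0.22 : 0.35 : 0.38) were chosen once
so the spectrum's peak-to-band-mean ratios match tabulated oxyhemoglobin
(≈2.9 at 430 nm, ≈1.5 at the α/β peaks, ≈0.05 at 630 nm). After evaluation
the curve is rescaled globally so its 430–630 nm mean equals ε̄; with that
normalization μ_a = ε(λ)·c_i reproduces the design table for every phantom
regardless of the shape details.

## Scattering model

Refractive indices come from visible-range Cauchy fits (water:
n = 1.3248 + 2873/λ²[nm]; polystyrene: n = 1.5725 + 0.0031080/λ² +
0.00034779/λ⁴, λ in μm), giving the relative index m ≈ 1.19. Mie
efficiencies use the partial-wave series truncated at
N = ⌈x + 4x^(1/3) + 2⌉, with the logarithmic derivative by downward
recurrence and the Riccati–Bessel functions by upward recurrence — stable
for the x ≲ 20 relevant here, and verified against an independent
high-truncation series built on `scipy.special` Bessel functions (agreement
10⁻¹⁵ at x = 10) and the Rayleigh limit.

Two consequences of the Mie curve are frozen into the pipeline:

- **Anisotropy g = 0.929**, the 530 nm value for 1 μm polystyrene in water.
  g varies only weakly over the band, and single-bank similarity scaling
  requires one g, so both the generator and the transport bank use this
  value.
- **Scattering power b ≈ 0.60**: the least-squares exponent of
  A(λ/530)^(−b) fitted to the Mie μ_s′ curve, which tracks it within 1.5%
  across the band.

The generator's ground-truth μ_s′(λ) uses that fitted power law (band mean
anchored to the dilution line) rather than the raw Mie curve, so the
retrieval's scattering family contains the truth and noiseless studies
measure the inversion itself, not a 1.5% shape mismatch. The raw Mie shape
remains available (`scatter_shape="mie"`) for studying that mismatch
deliberately. The absolute sphere density is not recoverable from the
design table; it is reported only as the density that makes the undiluted
Mie band average equal the dilution-line intercept.

## Monte Carlo transport and the photon bank

`simulate_bank` runs a weighted-photon random walk in a homogeneous
semi-infinite medium: pencil beam normally incident, step lengths sampled
from μ_s,ref alone (absorption excluded), Henyey–Greenstein deflection via
the closed-form inverse CDF, Fresnel treatment at the top boundary, Russian
roulette (threshold 10⁻⁴, survival 1/10) for low weights. Every escaping
photon appends (exit radius, total path, weight) to the bank. Scaling to a
target medium is the standard similarity transform r′ = r·μ_s,ref/μ_s,
L′ = L·μ_s,ref/μ_s, w′ = w·exp(−μ_a·L′), which lets one bank serve every
wavelength and every optimizer iterate.

Numerical choices:

- **Boundary**: n_rel = 1 by default (probe in contact with the liquid,
  index-matched); with n_rel ≠ 1 the Fresnel-transmitted fraction is
  recorded and the photon continues with the reflected weight (weight
  splitting), so a matched-boundary photon yields exactly one record.
- **Path cap**: the walk stops after 30 000 scattering mean free paths
  (300 cm at μ_s,ref = 100 cm⁻¹). A non-absorbing matched half-space is
  recurrent — every photon escapes eventually — so capped photons (≈3% of
  launches) are flushed to the bank at their current lateral radius, keeping
  the energy budget exact: exit weight + roulette weight = launched weight
  to better than 10⁻⁹. Their reweighted contribution is < e⁻³⁰ for any
  μ_a ≥ 0.1 cm⁻¹, so downstream reflectances are unbiased in practice. The
  cap being dimensionless keeps banks at different μ_s,ref exactly similar.
- **Probe collection**: with the medium rotationally symmetric the six
  illumination fibers are equivalent, so collection reduces to a single
  source–detector pair at the 480 μm pitch. The probability that an exit at
  radius r′ from its (uniformly distributed) launch point lands on the
  collection face is computed by an exact 1-D quadrature of the circle–disc
  overlap fraction (192-node Gauss–Legendre, tabulated on 3000 radii and
  interpolated); it matches a brute-force double integral to ~10⁻⁵. The
  collection support is only 0.008–0.088 cm, which also lets exact forward
  evaluations window the radius-sorted bank.
- **Validation**: rescaled banks agree with fresh simulations bin-by-bin
  within Monte Carlo error over a 3×3 (μ_a, μ_s) grid, and the impulse
  reflectance at ρ = 1 cm (μ_a = 0.1, μ_s′ = 10 cm⁻¹) agrees with the
  diffusion-dipole closed form within a few percent.

## Calibration and inversion

Measurements are reduced to R(λ) = (sample − background)/(reference −
background); wavelengths where the denominator is non-positive are dropped
(not clipped) so fits never see them. A reference phantom with known
(μ_a, μ_s′) then pins k(λ) = measured/predicted per wavelength — per
wavelength, not scalar, because k must absorb the spectrally structured
instrument response.

The retrieval minimizes Σ_λ [R_model(λ; c, A, b) − measured(λ)/k(λ)]² over
430–630 nm with `scipy.optimize.least_squares` (trust-region reflective),
bounds c ∈ [0, 100] μM, A ∈ [1, 50] cm⁻¹, b ∈ [0, 4], and four
deterministic starts on a coarse (c, A) grid to escape the Soret-tail /
scattering trade-off. Each start first converges on a cubic-spline
surrogate of log R(μ_a, μ_s′) (precomputed once per bank on a 97×66 grid;
accurate to ~10⁻⁴ relative); the best start is then polished against the
exact windowed-bank evaluator, which also defines the reported residual.
The polish restores exactness: self-referenced noiseless inversions reach
residuals ~10⁻¹⁵ and noiseless cross-referenced retrievals recover c_Hb to
well below 0.01%.

The leave-one-out study uses each phantom as reference once, inverts all
others, and aggregates per-phantom means/standard deviations across
references plus mean absolute percent errors of band-averaged μ_a, μ_s′ and
c_Hb over all (phantom, non-self reference) pairs. Self-referenced runs are
recorded separately and excluded from the error means. Since μ_a = ε·c_Hb
with one shared ε, the μ_a and c_Hb percent errors coincide exactly.

## Study conditions and problem sizes

The default synthetic study uses a 51-point grid over 430–630 nm (4 nm
spacing, commensurate with a ~5 nm-resolution instrument), a photon bank of
1–1.5×10⁵ photons at μ_s,ref = 100 cm⁻¹, a single shared
reflectance-standard measurement and background (taken once for all
phantoms, as in the emulated protocol), and 2% multiplicative Gaussian
noise applied per wavelength to sample and reference counts — a
conservative stand-in, since no noise characterization of the real
instrument is available. Under these conditions the 16-phantom study
yields mean errors of roughly 3% in μ_a/c_Hb and below 1% in μ_s′,
comfortably inside the 9.2%/8.1% reported for the physical experiment.

## What the synthetic studies show — and what they don't

The generator shares its forward physics with the inversion (same bank,
same probe model, same ε), so the studies measure the *retrieval
machinery*: calibration algebra, optimizer robustness, noise propagation
through the reference-phantom scheme, including the qualitative edge effect
(end phantoms see references from one side only and tend to larger spread).
They do not probe model error of a real instrument: chromatic collection
efficiency, probe–surface coupling, stray light, wavelength-calibration
drift, or deviations of real hemoglobin spectra from the synthetic shape.
The physical experiment's 9.2%/8.1% figures therefore act as upper bounds the clean
synthetic pipeline should beat, not as values it should equal. Likewise
the spectrometer-hardware figures (~5 nm FWHM, 400–1000 nm range) are
emulated, not reproduced: the image chain demonstrates software fidelity
(line centers to 0.1 nm, FWHM to 1%) on synthetic frames.

## Known limitations

- Homogeneous semi-infinite medium only: no layers, no time resolution,
  no polarization.
- Non-absorbing spheres (real m) only in the Mie module; dependent
  scattering at high sphere density is ignored.
- Oxygen saturation is fixed at 100%: single-chromophore Beer–Lambert, no
  oxy/deoxy unmixing.
- The probe model treats fiber faces as ideal apertures (no numerical
  aperture cut, no fiber transmission spectrum).
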