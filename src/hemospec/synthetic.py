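"""Synthetic inputs: the 16-phantom titration series and emulated measurements.

The liquid-phantom design this module replicates is a titration: a fixed
number of 1 um polystyrene microspheres in water, with oxygenated hemoglobin
stock added stepwise. Adding stock volume V grows the total volume, so the
sphere density — and with it mu_s' — dilutes linearly in the hemoglobin
concentration: V_i/V_0 = 1/(1 - c_i/S) for stock concentration S. The
printed design table (16 concentrations from 5.39 to 36.16 uM with expected
band-averaged mu_a and mu_s') pins two anchors that this module recovers by
regression: the band-effective extinction epsilon-bar (no-intercept slope of
mu_a on c) and the dilution line mu_s' = a + slope * c.

On top of the series the module fabricates everything a pipeline run needs:
an oxyhemoglobin-like extinction spectrum (Soret/alpha/beta Gaussian bands),
probe measurements with instrument response, ambient background and
multiplicative noise, and raw Bayer-mosaic spectral images for the
spectrometer processing chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .inversion import StudyInput, fit_beer_lambert, fit_dilution
from .optics import OpticalProperties, fit_power_law, mie_g, mie_musp_spectrum
from .processing import DispersionMap
from .spectrum import Spectrum, band_mean

__all__ = [
    "TABLE1",
    "ExtinctionModel",
    "PhantomSpec",
    "InstrumentModel",
    "epsilon_bar",
    "dilution_line",
    "make_table1_series",
    "expected_band_mua",
    "expected_band_musp",
    "synth_extinction",
    "default_extinction_model",
    "phantom_optical_properties",
    "mie_scatter_power",
    "default_instrument",
    "synth_measurement",
    "make_study_inputs",
    "synth_bayer_image",
    "write_series_csv",
    "read_series_csv",
    "BAND",
]

BAND = (430.0, 630.0)
_SPHERE_RADIUS_UM = 0.5

#: printed phantom design table: concentration (uM), expected band-averaged
#: mu_a (cm^-1) and mu_s' (cm^-1); used as input data for the anchors below
TABLE1 = pd.DataFrame(
    {
        "id": np.arange(1, 17),
        "hb_conc_uM": [5.39, 8.80, 11.90, 14.74, 17.34, 19.73, 21.94, 23.98,
                       25.89, 27.66, 29.31, 30.86, 32.31, 33.67, 34.95, 36.16],
        "expected_mua_cm1": [0.46, 0.75, 1.02, 1.26, 1.48, 1.69, 1.87, 2.05,
                             2.21, 2.36, 2.50, 2.64, 2.76, 2.88, 2.99, 3.09],
        "expected_musp_cm1": [12.55, 11.95, 11.41, 10.92, 10.46, 10.05, 9.66,
                              9.31, 8.98, 8.67, 8.38, 8.11, 7.86, 7.62, 7.40,
                              7.19],
    }
)


@lru_cache(maxsize=1)
def epsilon_bar() -> float:
    """Band-effective extinction (cm^-1/uM): no-intercept slope of the table."""
    return fit_beer_lambert(
        np.column_stack([TABLE1["hb_conc_uM"], TABLE1["expected_mua_cm1"]])
    )


@lru_cache(maxsize=1)
def dilution_line() -> tuple[float, float]:
    """(a, slope) of the table's mu_s' = a + slope * c dilution line."""
    return fit_dilution(
        np.column_stack([TABLE1["hb_conc_uM"], TABLE1["expected_musp_cm1"]])
    )


@lru_cache(maxsize=1)
def _base_density_per_ml() -> float:
    """Sphere density of the undiluted suspension.

    Solved so the Mie band-averaged mu_s' of the undiluted suspension equals
    the dilution-line intercept a; the absolute density is otherwise not
    recoverable from the design table.
    """
    a, _ = dilution_line()
    grid = np.arange(BAND[0], BAND[1] + 1.0, 5.0)
    per_sphere = mie_musp_spectrum(grid, radius_um=_SPHERE_RADIUS_UM,
                                   density_per_ml=1.0)
    return a / per_sphere.band_mean(*BAND)


@dataclass(frozen=True)
class PhantomSpec:
    """One liquid phantom of the titration series."""

    id: int
    hb_conc_um: float
    dilution: float                       # V_i / V_0 >= 1
    scatterer: tuple[float, float]        # (radius_um, base_density_per_ml)

    def __post_init__(self) -> None:
        if self.hb_conc_um <= 0:
            raise ValueError("concentration must be positive")
        if self.dilution < 1.0:
            raise ValueError("titration can only add volume: dilution >= 1")


def make_table1_series() -> list[PhantomSpec]:
    """The 16-phantom series with dilutions from the fitted titration model.

    dilution_i = 1 / (1 - c_i / S) with the stock concentration S = -a/slope
    taken from the design table's dilution line, so that the implied
    band-averaged mu_s' = a / dilution reproduces every printed value.
    Pure and deterministic.
    """
    a, slope = dilution_line()
    stock = -a / slope
    base = _base_density_per_ml()
    out = []
    for row in TABLE1.itertuples():
        dil = 1.0 / (1.0 - row.hb_conc_uM / stock)
        out.append(
            PhantomSpec(
                id=int(row.id),
                hb_conc_um=float(row.hb_conc_uM),
                dilution=float(dil),
                scatterer=(_SPHERE_RADIUS_UM, base),
            )
        )
    return out


def expected_band_mua(phantom: PhantomSpec) -> float:
    """Design-table band-averaged mu_a: epsilon-bar * c."""
    return epsilon_bar() * phantom.hb_conc_um


def expected_band_musp(phantom: PhantomSpec) -> float:
    """Design-table band-averaged mu_s': undiluted value over the dilution."""
    a, _ = dilution_line()
    return a / phantom.dilution


# --------------------------------------------------------------------------
# extinction spectrum
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtinctionModel:
    """Oxyhemoglobin-like extinction: Gaussian Soret/beta/alpha bands.

    ``bands`` lists (center_nm, sigma_nm, relative_amplitude); a small
    constant baseline (relative to the largest amplitude) keeps the spectrum
    strictly positive into the near infrared. After evaluation the spectrum
    is globally rescaled so its mean over 430-630 nm equals
    ``band_mean_target`` — the only feature of the real extinction curve
    recoverable from the design table.
    """

    bands: tuple[tuple[float, float, float], ...] = (
        (415.0, 20.0, 1.00),   # Soret
        (470.0, 65.0, 0.22),   # broad underlay: non-Gaussian Soret wing / valley fill
        (541.0, 15.0, 0.35),   # beta
        (576.0, 13.0, 0.38),   # alpha
    )
    band_mean_target: float | None = None   # cm^-1/uM; None -> table anchor
    baseline_frac: float = 0.004

    def target(self) -> float:
        return self.band_mean_target if self.band_mean_target is not None else epsilon_bar()


def default_extinction_model() -> ExtinctionModel:
    return ExtinctionModel()


def _extinction_shape(model: ExtinctionModel, grid: np.ndarray) -> np.ndarray:
    amps = np.array([a for _, _, a in model.bands])
    if np.all(amps <= 0):
        raise ValueError("all band amplitudes zero: spectrum not positive")
    raw = np.zeros_like(grid)
    for center, sigma, amp in model.bands:
        raw = raw + amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    raw = raw + model.baseline_frac * amps.max()
    return raw


def synth_extinction(model: ExtinctionModel, grid) -> Spectrum:
    """Evaluate the extinction model on a wavelength grid in [400, 1000] nm.

    Normalization uses the caller's grid samples inside 430-630 nm when at
    least two fall there (so band means computed downstream hit the target
    exactly on that grid); otherwise an internal 1 nm band grid is used.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < 400.0 or grid.max() > 1000.0:
        raise ValueError("grid outside the supported 400-1000 nm range")
    raw = _extinction_shape(model, grid)
    in_band = (grid >= BAND[0]) & (grid <= BAND[1])
    if np.count_nonzero(in_band) >= 2:
        mean_raw = float(np.mean(raw[in_band]))
    else:
        ref_grid = np.arange(BAND[0], BAND[1] + 1.0, 1.0)
        mean_raw = float(np.mean(_extinction_shape(model, ref_grid)))
    return Spectrum(grid, raw * (model.target() / mean_raw), unit="cm-1/uM")


@lru_cache(maxsize=8)
def mie_scatter_power(radius_um: float = _SPHERE_RADIUS_UM) -> float:
    """Power-law exponent b of the Mie mu_s' curve over the fit band.

    Least-squares fit of A (lambda/530)^-b to the polystyrene-in-water Mie
    curve (b ~ 0.6 for 1 um spheres; the raw curve deviates from the fitted
    law by < 1.5% across 430-630 nm).
    """
    grid = np.arange(BAND[0], BAND[1] + 1.0, 5.0)
    _, b = fit_power_law(mie_musp_spectrum(grid, radius_um=radius_um))
    return b


def phantom_optical_properties(
    phantom: PhantomSpec,
    epsilon: Spectrum,
    g: float | None = None,
    scatter_shape: str = "power_law",
) -> OpticalProperties:
    """Ground-truth mu_a(lambda), mu_s'(lambda), g for one phantom.

    mu_a = epsilon * c. mu_s'(lambda) is scaled so its 430-630 nm mean
    equals the design value a / dilution; its spectral shape is, by default,
    the power law whose exponent is fitted to the polystyrene-in-water Mie
    curve — the same one-parameter family the retrieval uses, so that
    noiseless synthetic studies probe the inversion rather than a shape
    mismatch. ``scatter_shape="mie"`` substitutes the raw Mie curve
    (deviating < 1.5% from the power law). The anisotropy is frozen at the
    530 nm Mie value unless overridden (single-bank similarity scaling
    assumes one g).
    """
    grid = epsilon.wavelengths
    radius = phantom.scatterer[0]
    if scatter_shape == "power_law":
        shape = (grid / 530.0) ** (-mie_scatter_power(radius))
    elif scatter_shape == "mie":
        shape = mie_musp_spectrum(grid, radius_um=radius).values
    else:
        raise ValueError(f"unknown scatter_shape {scatter_shape!r}")
    in_band = (grid >= BAND[0]) & (grid <= BAND[1])
    if np.count_nonzero(in_band) >= 2:
        shape_mean = float(np.mean(shape[in_band]))
    else:
        ref_grid = np.arange(BAND[0], BAND[1] + 1.0, 5.0)
        if scatter_shape == "power_law":
            shape_mean = float(
                np.mean((ref_grid / 530.0) ** (-mie_scatter_power(radius)))
            )
        else:
            shape_mean = mie_musp_spectrum(
                ref_grid, radius_um=radius
            ).band_mean(*BAND)
    musp = shape * (expected_band_musp(phantom) / shape_mean)
    return OpticalProperties(
        grid=grid,
        mu_a=epsilon.values * phantom.hb_conc_um,
        mu_sp=musp,
        g=mie_g() if g is None else g,
    )


# --------------------------------------------------------------------------
# instrument and measurements
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InstrumentModel:
    """Lamp + spectrometer response, ambient background, multiplicative noise."""

    response: Spectrum          # counts per unit reflectance, > 0
    background_level: float     # counts (ambient light)
    noise_cv: float             # multiplicative coefficient of variation
    seed: int

    def __post_init__(self) -> None:
        if np.any(self.response.values <= 0):
            raise ValueError("instrument response must be strictly positive")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")


def default_instrument(
    grid,
    gain_counts: float = 30000.0,
    background_level: float = 200.0,
    noise_cv: float = 0.02,
    seed: int = 0,
) -> InstrumentModel:
    """A smooth lamp/detector response peaking near 560 nm, 2% noise."""
    grid = np.asarray(grid, dtype=float)
    resp = gain_counts * (0.55 + 0.45 * np.exp(-0.5 * ((grid - 560.0) / 110.0) ** 2))
    return InstrumentModel(
        response=Spectrum(grid, resp, "counts"),
        background_level=background_level,
        noise_cv=noise_cv,
        seed=seed,
    )


def _noisy(values: np.ndarray, cv: float, rng: np.random.Generator) -> np.ndarray:
    return values * (1.0 + cv * rng.standard_normal(values.size))


def synth_measurement(
    phantom: PhantomSpec,
    ext: ExtinctionModel,
    forward: Callable[[OpticalProperties], Spectrum],
    instrument: InstrumentModel,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """One probe measurement triple (sample, reference, background) in counts.

    sample     = background + response * R_true * (1 + noise)
    reference  = background + response * 1      * (1 + noise)   (flat standard)
    background = background level exactly

    The forward predictor must return reflectance on the instrument grid.
    Noise draws come from a generator freshly seeded with the instrument
    seed, so identical inputs give identical triples.
    """
    grid = instrument.response.wavelengths
    eps = synth_extinction(ext, grid)
    props = phantom_optical_properties(phantom, eps)
    r_true = forward(props)
    if not r_true.same_grid(instrument.response):
        raise ValueError("forward model grid does not match instrument grid")
    rng = np.random.default_rng(instrument.seed)
    bg = instrument.background_level
    sample = bg + instrument.response.values * _noisy(
        r_true.values, instrument.noise_cv, rng
    )
    reference = bg + _noisy(instrument.response.values, instrument.noise_cv, rng)
    background = np.full(grid.size, float(bg))
    return (
        Spectrum(grid, sample, "counts"),
        Spectrum(grid, reference, "counts"),
        Spectrum(grid, background, "counts"),
    )


def make_study_inputs(
    phantoms: Sequence[PhantomSpec],
    ext: ExtinctionModel,
    forward: Callable[[OpticalProperties], Spectrum],
    instrument: InstrumentModel,
) -> list[StudyInput]:
    """Measurement set for the leave-one-out study.

    Emulates the usual measurement protocol: each phantom gets its own sample
    spectrum, while a single reflectance-standard spectrum (taken once,
    after all phantoms) and a single background are shared by every triple.
    All noise derives from one generator seeded with the instrument seed.
    """
    grid = instrument.response.wavelengths
    eps = synth_extinction(ext, grid)
    rng = np.random.default_rng(instrument.seed)
    bg = instrument.background_level
    reference = Spectrum(
        grid, bg + _noisy(instrument.response.values, instrument.noise_cv, rng),
        "counts",
    )
    background = Spectrum(grid, np.full(grid.size, float(bg)), "counts")
    out = []
    for ph in phantoms:
        props = phantom_optical_properties(ph, eps)
        r_true = forward(props)
        if not r_true.same_grid(instrument.response):
            raise ValueError("forward model grid does not match instrument grid")
        sample = Spectrum(
            grid,
            bg + instrument.response.values
            * _noisy(r_true.values, instrument.noise_cv, rng),
            "counts",
        )
        out.append(
            StudyInput(
                phantom_id=ph.id,
                c_hb_um=ph.hb_conc_um,
                triple=(sample, reference, background),
                truth=props,
                expected_band_mua=expected_band_mua(ph),
                expected_band_musp=expected_band_musp(ph),
            )
        )
    return out


# --------------------------------------------------------------------------
# raw spectral images
# --------------------------------------------------------------------------

_CHANNEL_LAYOUT = {
    "RGGB": (("R", "G"), ("G", "B")),
    "BGGR": (("B", "G"), ("G", "R")),
    "GRBG": (("G", "R"), ("B", "G")),
    "GBRG": (("G", "B"), ("R", "G")),
}

_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def synth_bayer_image(
    lines: Sequence[tuple[float, float, float]],
    dispersion: DispersionMap,
    shape: tuple[int, int] = (64, 1024),
    pattern: str = "RGGB",
    seed: int | None = None,
    channel_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    bit_depth: int = 10,
) -> np.ndarray:
    """Raw Bayer-mosaic frame of spectral lines, integer counts.

    Each line (center_nm, fwhm_nm, intensity) becomes a Gaussian column
    profile, constant along rows (the slit direction), weighted per mosaic
    channel. With ``seed`` set, Poisson shot noise is applied. Values are
    clipped to the sensor bit depth (10-bit default).
    """
    rows, cols = shape
    if rows % 2 or cols % 2 or rows == 0 or cols == 0:
        raise ValueError("sensor dimensions must be even and nonzero")
    if pattern not in _CHANNEL_LAYOUT:
        raise ValueError(f"unknown Bayer pattern {pattern!r}")
    col_px = np.arange(cols, dtype=float)
    profile = np.zeros(cols)
    for center_nm, fwhm_nm, intensity in lines:
        if intensity < 0:
            raise ValueError("line intensity must be non-negative")
        c_px = float(dispersion.nm_to_pixel(center_nm))
        if not 0.0 <= c_px <= cols - 1:
            raise ValueError(
                f"line at {center_nm} nm maps to pixel {c_px:.1f}, off sensor"
            )
        sigma_px = fwhm_nm / (_FWHM_TO_SIGMA * abs(dispersion.slope))
        profile += intensity * np.exp(-0.5 * ((col_px - c_px) / sigma_px) ** 2)

    weights = dict(zip("RGB", channel_weights))
    layout = _CHANNEL_LAYOUT[pattern]
    img = np.empty((rows, cols))
    for rp in range(2):
        for cp in range(2):
            img[rp::2, cp::2] = profile[cp::2] * weights[layout[rp][cp]]
    if seed is not None:
        img = np.random.default_rng(seed).poisson(img).astype(float)
    return np.clip(np.rint(img), 0, 2**bit_depth - 1).astype(np.uint16)


# --------------------------------------------------------------------------
# series persistence
# --------------------------------------------------------------------------

def write_series_csv(phantoms: Sequence[PhantomSpec], path) -> None:
    pd.DataFrame(
        {
            "id": [p.id for p in phantoms],
            "hb_conc_uM": [p.hb_conc_um for p in phantoms],
            "dilution": [p.dilution for p in phantoms],
            "expected_mua_cm1": [expected_band_mua(p) for p in phantoms],
            "expected_musp_cm1": [expected_band_musp(p) for p in phantoms],
        }
    ).to_csv(path, index=False, float_format="%.17g")


def read_series_csv(path) -> list[PhantomSpec]:
    df = pd.read_csv(path)
    base = _base_density_per_ml()
    return [
        PhantomSpec(
            id=int(r.id),
            hb_conc_um=float(r.hb_conc_uM),
            dilution=float(r.dilution),
            scatterer=(_SPHERE_RADIUS_UM, base),
        )
        for r in df.itertuples()
    ]
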