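"""Spectrometer software chain: raw mosaic image to calibrated spectrum.

Mirrors a slit spectrograph whose CMOS sensor returns raw Bayer-mosaic
frames: the mosaic is collapsed to a grey image by summing the four pixels
of each 2x2 color cell (no demosaic interpolation), the grey image is summed
along the slit axis into a 1-D count spectrum, a linear pixel-to-wavelength
map fitted against calibration-lamp lines assigns wavelengths, and peaks are
characterized by their FWHM via linear interpolation of the half-maximum
crossings. The diffuse reflectance ratio (sample - background) /
(reference - background) closes the chain.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import signal

from .spectrum import Spectrum

__all__ = [
    "DispersionMap",
    "CalibrationFit",
    "PeakReport",
    "bayer_to_grey",
    "image_to_spectrum",
    "calibrate_wavelength",
    "apply_dispersion",
    "peak_pixel_positions",
    "find_peaks_fwhm",
    "diffuse_reflectance",
    "read_pgm",
    "write_pgm",
    "save_dispersion",
    "load_dispersion",
]

BAYER_PATTERNS = ("RGGB", "BGGR", "GRBG", "GBRG")


@dataclass(frozen=True)
class DispersionMap:
    """Linear pixel-to-wavelength map: lambda = slope * pixel + intercept."""

    slope: float        # nm per pixel
    intercept: float    # nm at pixel 0

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("dispersion slope must be nonzero")

    def pixel_to_nm(self, pixel):
        return self.slope * np.asarray(pixel, dtype=float) + self.intercept

    def nm_to_pixel(self, nm):
        return (np.asarray(nm, dtype=float) - self.intercept) / self.slope


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted dispersion map with its per-line residuals (nm)."""

    dispersion: DispersionMap
    residuals_nm: np.ndarray
    rms_nm: float


@dataclass(frozen=True)
class PeakReport:
    """Detected spectral lines: (center_nm, fwhm_nm, height) per peak."""

    centers_nm: np.ndarray
    fwhm_nm: np.ndarray
    heights: np.ndarray

    def __len__(self) -> int:
        return self.centers_nm.size


def bayer_to_grey(raw: np.ndarray, pattern: str = "RGGB") -> np.ndarray:
    """Collapse a Bayer mosaic to grey by summing each 2x2 cell (R+G+G+B).

    All four mosaic layouts sum identically; the pattern argument is
    validated so callers state their sensor layout explicitly. Output
    dimensions are halved and total counts are conserved exactly.
    """
    raw = np.asarray(raw)
    if pattern not in BAYER_PATTERNS:
        raise ValueError(f"unknown Bayer pattern {pattern!r}")
    if raw.ndim != 2:
        raise ValueError("raw image must be 2-D")
    h, w = raw.shape
    if h % 2 or w % 2 or h == 0 or w == 0:
        raise ValueError("image dimensions must be even and nonzero")
    return (
        raw[0::2, 0::2].astype(np.int64)
        + raw[0::2, 1::2]
        + raw[1::2, 0::2]
        + raw[1::2, 1::2]
    )


def image_to_spectrum(grey: np.ndarray, slit_axis: str = "rows") -> Spectrum:
    """Sum the grey image along the slit direction into a pixel-indexed spectrum.

    ``slit_axis="rows"`` means the slit runs along image rows are stacked,
    i.e. each column is one dispersion position and values are column sums.
    The returned Spectrum has pixel indices 0..N-1 as its grid (counts).
    """
    grey = np.asarray(grey)
    if grey.ndim != 2 or grey.size == 0:
        raise ValueError("need a non-empty 2-D image")
    if slit_axis == "rows":
        vals = grey.sum(axis=0)
    elif slit_axis == "cols":
        vals = grey.sum(axis=1)
    else:
        raise ValueError("slit_axis must be 'rows' or 'cols'")
    return Spectrum(np.arange(vals.size, dtype=float), vals.astype(float), "counts")


def calibrate_wavelength(pixel_peaks, known_nm) -> CalibrationFit:
    """Least-squares linear fit lambda = slope * pixel + intercept.

    Needs at least two distinct (pixel, wavelength) pairs from a calibration
    lamp; reports per-line residuals and their RMS in nm.
    """
    px = np.asarray(pixel_peaks, dtype=float)
    nm = np.asarray(known_nm, dtype=float)
    if px.size != nm.size:
        raise ValueError("pixel and wavelength lists differ in length")
    if px.size < 2:
        raise ValueError("need at least two calibration lines")
    if np.ptp(px) == 0:
        raise ValueError("all pixel positions identical; cannot fit a line")
    slope, intercept = np.polyfit(px, nm, 1)
    fitted = slope * px + intercept
    res = nm - fitted
    return CalibrationFit(
        dispersion=DispersionMap(float(slope), float(intercept)),
        residuals_nm=res,
        rms_nm=float(np.sqrt(np.mean(res**2))),
    )


def apply_dispersion(spec_px: Spectrum, disp: DispersionMap) -> Spectrum:
    """Convert a pixel-indexed spectrum to a wavelength grid (kept increasing)."""
    nm = disp.pixel_to_nm(spec_px.wavelengths)
    vals = spec_px.values
    if disp.slope < 0:
        nm, vals = nm[::-1], vals[::-1]
    return Spectrum(nm, vals, spec_px.unit)


def peak_pixel_positions(
    spec_px: Spectrum, min_height: float = 0.2, window_frac: float = 0.2
) -> np.ndarray:
    """Sub-pixel line centers by center-of-mass around each detected maximum.

    The centroid is taken over the contiguous region around the peak above
    ``window_frac`` of its height; exact for symmetric noiseless profiles.
    """
    v = spec_px.values
    idx, _ = signal.find_peaks(v, height=min_height * v.max())
    if idx.size == 0:
        raise ValueError("no peaks found")
    centers = []
    for i in idx:
        thr = window_frac * v[i]
        lo = i
        while lo > 0 and v[lo - 1] > thr:
            lo -= 1
        hi = i
        while hi < v.size - 1 and v[hi + 1] > thr:
            hi += 1
        seg = slice(lo, hi + 1)
        centers.append(
            float(np.sum(spec_px.wavelengths[seg] * v[seg]) / np.sum(v[seg]))
        )
    return np.array(centers)


def _half_crossing(wl, v, i_peak, half, direction):
    """Wavelength where the spectrum crosses ``half`` on one side of a peak."""
    i = i_peak
    while 0 <= i < v.size and v[i] > half:
        i += direction
    if i < 0 or i >= v.size:
        return None
    j = i - direction  # last sample above half
    # linear interpolation between the bracketing samples
    t = (half - v[j]) / (v[i] - v[j])
    return wl[j] + t * (wl[i] - wl[j])


def find_peaks_fwhm(spec: Spectrum, min_height: float = 0.2) -> PeakReport:
    """Local maxima above ``min_height`` * max, with FWHM per peak.

    FWHM is measured by linearly interpolating the half-maximum crossings on
    each side of the peak in the wavelength domain; the reported center is
    refined by parabolic interpolation through the three samples around the
    maximum. Peaks whose half-maximum level never crosses inside the grid
    are dropped.
    """
    v = spec.values
    wl = spec.wavelengths
    if np.ptp(v) == 0:
        raise ValueError("flat spectrum: no peaks")
    idx, props = signal.find_peaks(v, height=min_height * np.max(v))
    if idx.size == 0:
        raise ValueError("no peaks above threshold")
    centers, widths, heights = [], [], []
    for i in idx:
        # parabolic refinement through the three samples around the maximum
        # recovers the off-grid apex (position and height) before halving
        height = v[i]
        center = wl[i]
        if 0 < i < v.size - 1:
            denom = v[i - 1] - 2.0 * v[i] + v[i + 1]
            if denom != 0:
                delta = float(np.clip(0.5 * (v[i - 1] - v[i + 1]) / denom, -0.5, 0.5))
                center = wl[i] + delta * (wl[i + 1] - wl[i - 1]) / 2.0
                height = v[i] - 0.25 * (v[i - 1] - v[i + 1]) * delta
        half = 0.5 * height
        left = _half_crossing(wl, v, i, half, -1)
        right = _half_crossing(wl, v, i, half, +1)
        if left is None or right is None:
            continue
        centers.append(center)
        widths.append(right - left)
        heights.append(height)
    if not centers:
        raise ValueError("no measurable peaks (half maximum outside the grid)")
    return PeakReport(np.array(centers), np.array(widths), np.array(heights))


def diffuse_reflectance(
    sample: Spectrum, reference: Spectrum, background: Spectrum
) -> Spectrum:
    """R(lambda) = (sample - background) / (reference - background).

    All three spectra must share one grid. Wavelengths where the
    background-subtracted reference is non-positive are excluded from the
    output grid (rather than clipped), so downstream fits never see them.
    """
    if not (sample.same_grid(reference) and sample.same_grid(background)):
        raise ValueError("sample, reference, background grids differ")
    denom = reference.values - background.values
    ok = denom > 0
    if not np.any(ok):
        raise ValueError("reference does not exceed background anywhere")
    r = (sample.values[ok] - background.values[ok]) / denom[ok]
    return Spectrum(sample.wavelengths[ok], r, "reflectance")


# --------------------------------------------------------------------------
# file formats
# --------------------------------------------------------------------------

def write_pgm(path, image: np.ndarray) -> None:
    """Write a 16-bit binary PGM (P5)."""
    img = np.asarray(image)
    if img.min() < 0 or img.max() > 65535:
        raise ValueError("image values outside 16-bit range")
    iio.imwrite(Path(path), img.astype(np.uint16))


def read_pgm(path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path)))


def save_dispersion(path, fit: CalibrationFit) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope_nm_per_px": fit.dispersion.slope,
                "intercept_nm": fit.dispersion.intercept,
                "residual_rms_nm": fit.rms_nm,
            },
            indent=1,
        )
    )


def load_dispersion(path) -> DispersionMap:
    d = json.loads(Path(path).read_text())
    return DispersionMap(d["slope_nm_per_px"], d["intercept_nm"])
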