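"""Wavelength-indexed spectra.

The package's basic container: an ordered wavelength grid (nm) carrying one
real value per wavelength, tagged with a unit so that count spectra,
dimensionless reflectance and absorption/scattering coefficients (cm^-1)
cannot be confused silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["Spectrum", "band_mask", "band_mean"]

#: recognised unit tags
UNITS = ("counts", "reflectance", "cm-1", "cm-1/uM", "dimensionless")


@dataclass(frozen=True)
class Spectrum:
    """A spectrum sampled on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm, strictly increasing.
    values : array of float
        One finite value per wavelength.
    unit : str
        One of ``counts``, ``reflectance``, ``cm-1``, ``cm-1/uM``,
        ``dimensionless``.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    unit: str = "dimensionless"

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        va = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", va)
        if wl.ndim != 1 or va.ndim != 1 or wl.size != va.size:
            raise ValueError("wavelengths and values must be 1-D of equal length")
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if not (np.all(np.isfinite(wl)) and np.all(np.isfinite(va))):
            raise ValueError("non-finite wavelength or value")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")

    def __len__(self) -> int:
        return self.wavelengths.size

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "Spectrum":
        """Same grid, new values (and optionally a new unit tag)."""
        return Spectrum(self.wavelengths, values, unit or self.unit)

    def same_grid(self, other: "Spectrum", atol: float = 1e-9) -> bool:
        return self.wavelengths.size == other.wavelengths.size and np.allclose(
            self.wavelengths, other.wavelengths, atol=atol, rtol=0.0
        )

    def band(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to wavelengths in [lo, hi] nm (inclusive)."""
        m = band_mask(self.wavelengths, lo, hi)
        if not np.any(m):
            raise ValueError(f"no samples in band [{lo}, {hi}] nm")
        return Spectrum(self.wavelengths[m], self.values[m], self.unit)

    def band_mean(self, lo: float, hi: float) -> float:
        """Arithmetic mean of the values sampled in [lo, hi] nm."""
        return band_mean(self.wavelengths, self.values, lo, hi)

    def interp(self, grid: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a new grid (must lie inside the old one)."""
        grid = np.asarray(grid, dtype=float)
        if grid.min() < self.wavelengths[0] or grid.max() > self.wavelengths[-1]:
            raise ValueError("target grid extends beyond the spectrum")
        return Spectrum(grid, np.interp(grid, self.wavelengths, self.values), self.unit)

    # ---- CSV round trip: two columns wavelength_nm,value -------------------

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, unit: str = "dimensionless") -> "Spectrum":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy(), unit)


def band_mask(wavelengths: np.ndarray, lo: float, hi: float) -> np.ndarray:
    wl = np.asarray(wavelengths, dtype=float)
    return (wl >= lo) & (wl <= hi)


def band_mean(wavelengths, values, lo: float, hi: float) -> float:
    """Mean over the samples falling in [lo, hi] nm.

    Band averages throughout the package (expected coefficient tables,
    retrieved values, percent errors) use this one definition so that all
    comparisons are on the same footing.
    """
    m = band_mask(wavelengths, lo, hi)
    if not np.any(m):
        raise ValueError(f"no samples in band [{lo}, {hi}] nm")
    return float(np.mean(np.asarray(values, dtype=float)[m]))
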