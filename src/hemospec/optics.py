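"""Phantom optical properties.

Absorption of oxygenated hemoglobin via the Beer-Lambert law, reduced
scattering of polystyrene microspheres in water via Lorenz-Mie theory, and
the power-law parameterization of mu_s' used by the inversion.

Conventions
-----------
* The extinction coefficient epsilon(lambda) is "effective", in
  cm^-1 per uM with the ln(10) factor folded in, so that
  mu_a = epsilon * c holds directly for a concentration c in uM.
* Refractive indices come from Cauchy-type dispersion fits valid across the
  visible and near infrared (400-1000 nm); both are normally dispersive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectrum import Spectrum

__all__ = [
    "OpticalProperties",
    "MieInput",
    "hb_mu_a",
    "mie_efficiencies",
    "musp_from_mie",
    "musp_power_law",
    "fit_power_law",
    "refractive_index",
    "mie_musp_spectrum",
    "mie_g",
]

# Cauchy dispersion coefficients, lambda in nm (water) / um (polystyrene).
# Water: n = A + B / lambda^2 anchored at 430 and 630 nm (n = 1.3403, 1.3320).
_WATER_A = 1.3248
_WATER_B = 2873.0  # nm^2
# Polystyrene: n = A + B/lambda^2 + C/lambda^4, lambda in um; the widely used
# visible-range fit giving n(589 nm) = 1.584, i.e. m ~ 1.19 relative to water.
_PS_A = 1.5725
_PS_B = 0.0031080  # um^2
_PS_C = 0.00034779  # um^4

_LAMBDA_MIN, _LAMBDA_MAX = 400.0, 1000.0


@dataclass(frozen=True)
class OpticalProperties:
    """mu_a(lambda) and mu_s'(lambda) in cm^-1 with anisotropy g on one grid."""

    grid: np.ndarray        # nm
    mu_a: np.ndarray        # cm^-1
    mu_sp: np.ndarray       # cm^-1
    g: float                # anisotropy, frozen per similarity scaling

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        mu_a = np.asarray(self.mu_a, dtype=float)
        mu_sp = np.asarray(self.mu_sp, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "mu_a", mu_a)
        object.__setattr__(self, "mu_sp", mu_sp)
        if not (grid.shape == mu_a.shape == mu_sp.shape):
            raise ValueError("grid, mu_a, mu_sp must share one shape")
        if np.any(mu_a < 0):
            raise ValueError("mu_a must be non-negative")
        if np.any(mu_sp <= 0):
            raise ValueError("mu_sp must be positive")
        if not -1.0 < self.g < 1.0:
            raise ValueError("anisotropy g must lie in (-1, 1)")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "wavelength_nm": self.grid,
                "mu_a_cm1": self.mu_a,
                "mu_sp_cm1": self.mu_sp,
                "g": np.full(self.grid.size, self.g),
            }
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "OpticalProperties":
        df = pd.read_csv(path, float_precision="round_trip")
        g = df["g"].to_numpy()
        if np.ptp(g) > 1e-12:
            raise ValueError("expected a single anisotropy value per table")
        return cls(
            df["wavelength_nm"].to_numpy(),
            df["mu_a_cm1"].to_numpy(),
            df["mu_sp_cm1"].to_numpy(),
            float(g[0]),
        )


@dataclass(frozen=True)
class MieInput:
    """One Mie evaluation: sphere radius, vacuum wavelength, indices, density."""

    radius_um: float
    wavelength_nm: float
    n_particle: float
    n_medium: float
    density_per_ml: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius must be positive")
        if self.n_particle <= 1.0 or self.n_medium <= 1.0:
            raise ValueError("refractive indices must exceed 1")
        if self.density_per_ml < 0:
            raise ValueError("density must be non-negative")

    @property
    def size_parameter(self) -> float:
        # x = 2 pi r n_medium / lambda, both lengths in the same unit
        return 2.0 * np.pi * self.radius_um * 1e3 * self.n_medium / self.wavelength_nm

    @property
    def relative_index(self) -> float:
        return self.n_particle / self.n_medium


def hb_mu_a(epsilon: Spectrum, conc_um: float) -> Spectrum:
    """Beer-Lambert absorption: mu_a(lambda) = epsilon(lambda) * c.

    ``epsilon`` carries effective extinction in cm^-1/uM; ``conc_um`` is the
    hemoglobin concentration in uM. Exactly linear in the concentration.
    """
    if conc_um < 0:
        raise ValueError("concentration must be non-negative")
    return epsilon.with_values(epsilon.values * conc_um, unit="cm-1")


def refractive_index(material: str, wavelength_nm) -> np.ndarray | float:
    """Real refractive index of ``polystyrene`` or ``water`` at 400-1000 nm."""
    lam = np.asarray(wavelength_nm, dtype=float)
    if np.any(lam < _LAMBDA_MIN) or np.any(lam > _LAMBDA_MAX):
        raise ValueError("wavelength outside the supported 400-1000 nm range")
    if material == "water":
        n = _WATER_A + _WATER_B / lam**2
    elif material == "polystyrene":
        lu = lam / 1000.0
        n = _PS_A + _PS_B / lu**2 + _PS_C / lu**4
    else:
        raise ValueError(f"unknown material {material!r}")
    return float(n) if np.isscalar(wavelength_nm) else n


def _wiscombe_terms(x: float) -> int:
    return int(np.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))


def mie_efficiencies(x: float, m: float) -> tuple[float, float]:
    """Lorenz-Mie scattering efficiency and asymmetry for a non-absorbing sphere.

    Parameters
    ----------
    x : float
        Size parameter 2 pi r n_medium / lambda, > 0.
    m : float
        Relative refractive index n_particle / n_medium (real, > 0).

    Returns
    -------
    (Q_sca, g)
        Scattering efficiency and mean cosine of the scattering angle.

    Notes
    -----
    The partial-wave series is truncated at N = ceil(x + 4 x^(1/3) + 2).
    The logarithmic derivative D_n(mx) is computed by downward recurrence
    (started well above N), the Riccati-Bessel functions psi_n and chi_n by
    upward recurrence, which is stable for the moderate size parameters
    (x <~ 20) of micron-scale phantom scatterers.
    """
    if x <= 0:
        raise ValueError("size parameter must be positive")
    if m <= 0:
        raise ValueError("relative index must be positive")
    n_terms = _wiscombe_terms(x)
    mx = m * x

    # downward recurrence for D_n(mx) = psi_n'(mx)/psi_n(mx)
    n_start = max(n_terms, int(np.ceil(abs(mx)))) + 16
    d = np.zeros(n_start + 1)
    for n in range(n_start, 0, -1):
        rn = n / mx
        d[n - 1] = rn - 1.0 / (d[n] + rn)

    # upward recurrence for psi_n(x), chi_n(x); index 0..N
    psi = np.empty(n_terms + 1)
    chi = np.empty(n_terms + 1)
    psi_prev, psi_cur = np.cos(x), np.sin(x)   # psi_{-1}, psi_0
    chi_prev, chi_cur = -np.sin(x), np.cos(x)  # chi_{-1}, chi_0
    psi[0], chi[0] = psi_cur, chi_cur
    for n in range(1, n_terms + 1):
        psi_next = (2 * n - 1) / x * psi_cur - psi_prev
        chi_next = (2 * n - 1) / x * chi_cur - chi_prev
        psi[n], chi[n] = psi_next, chi_next
        psi_prev, psi_cur = psi_cur, psi_next
        chi_prev, chi_cur = chi_cur, chi_next
    xi = psi - 1j * chi

    a = np.zeros(n_terms + 1, dtype=complex)
    b = np.zeros(n_terms + 1, dtype=complex)
    for n in range(1, n_terms + 1):
        da = d[n] / m + n / x
        db = d[n] * m + n / x
        a[n] = (da * psi[n] - psi[n - 1]) / (da * xi[n] - xi[n - 1])
        b[n] = (db * psi[n] - psi[n - 1]) / (db * xi[n] - xi[n - 1])

    n = np.arange(1, n_terms + 1, dtype=float)
    q_sca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a[1:]) ** 2 + np.abs(b[1:]) ** 2))
    asym = np.sum(
        n[:-1] * (n[:-1] + 2) / (n[:-1] + 1)
        * np.real(a[1:-1] * np.conj(a[2:]) + b[1:-1] * np.conj(b[2:]))
    )
    asym += np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a[1:] * np.conj(b[1:])))
    g = (4.0 / (x**2 * q_sca)) * asym
    return float(q_sca), float(g)


def musp_from_mie(inp: MieInput) -> tuple[float, float]:
    """Reduced scattering coefficient (cm^-1) and anisotropy for one sphere type.

    mu_s = Q_sca * pi r^2 * density; mu_s' = mu_s (1 - g). The geometric
    cross-section uses the radius in cm, the density in spheres per cm^3 (mL).
    """
    q_sca, g = mie_efficiencies(inp.size_parameter, inp.relative_index)
    r_cm = inp.radius_um * 1e-4
    mu_s = q_sca * np.pi * r_cm**2 * inp.density_per_ml
    return float(mu_s * (1.0 - g)), g


def mie_musp_spectrum(
    grid_nm: np.ndarray,
    radius_um: float = 0.5,
    density_per_ml: float = 1.0,
) -> Spectrum:
    """mu_s'(lambda) of polystyrene spheres in water across a wavelength grid.

    Refractive indices are evaluated per wavelength from the built-in
    dispersion fits. With ``density_per_ml=1`` the result is the per-sphere
    mu_s' shape, useful for anchoring an unknown absolute density.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    vals = np.empty(grid_nm.size)
    for i, lam in enumerate(grid_nm):
        inp = MieInput(
            radius_um=radius_um,
            wavelength_nm=float(lam),
            n_particle=float(refractive_index("polystyrene", lam)),
            n_medium=float(refractive_index("water", lam)),
            density_per_ml=density_per_ml,
        )
        vals[i], _ = musp_from_mie(inp)
    return Spectrum(grid_nm, vals, unit="cm-1")


def mie_g(wavelength_nm: float = 530.0, radius_um: float = 0.5) -> float:
    """Anisotropy of polystyrene-in-water spheres at one wavelength.

    The Monte Carlo photon bank freezes g at its 530 nm value: g varies only
    weakly over 430-630 nm and single-bank similarity scaling assumes one g.
    """
    inp = MieInput(
        radius_um=radius_um,
        wavelength_nm=wavelength_nm,
        n_particle=float(refractive_index("polystyrene", wavelength_nm)),
        n_medium=float(refractive_index("water", wavelength_nm)),
        density_per_ml=1.0,
    )
    _, g = musp_from_mie(inp)
    return g


def musp_power_law(a_cm1: float, b: float, lambda0_nm: float, grid_nm) -> Spectrum:
    """Power-law reduced scattering mu_s'(lambda) = A (lambda/lambda0)^-b."""
    if a_cm1 <= 0:
        raise ValueError("amplitude A must be positive")
    if b < 0:
        raise ValueError("scatter power b must be non-negative")
    grid_nm = np.asarray(grid_nm, dtype=float)
    return Spectrum(grid_nm, a_cm1 * (grid_nm / lambda0_nm) ** (-b), unit="cm-1")


def fit_power_law(musp: Spectrum, lambda0_nm: float = 530.0) -> tuple[float, float]:
    """Least-squares (A, b) of the power law to a mu_s' spectrum (log domain)."""
    if np.any(musp.values <= 0):
        raise ValueError("mu_s' must be positive to fit a power law")
    x = np.log(musp.wavelengths / lambda0_nm)
    design = np.column_stack([np.ones_like(x), -x])
    coef, *_ = np.linalg.lstsq(design, np.log(musp.values), rcond=None)
    return float(np.exp(coef[0])), float(coef[1])
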