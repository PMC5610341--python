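"""Fast forward reflectance model and reference-phantom calibration.

``ReflectanceModel`` composes bank rescaling with probe collection to predict
the probe reflectance spectrum R_model(lambda) for arbitrary optical
properties, reusing one photon bank for every wavelength and every candidate
parameter set. A measured spectrum of a reference phantom with known
properties then pins the instrument's unknown spectral scale factor
k(lambda) = measured / predicted, after which any measurement can be mapped
onto the model's absolute scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .montecarlo import PhotonBank, ProbeGeometry, ScaledBank, _p_table, probe_collect, scale_bank
from .optics import OpticalProperties
from .spectrum import Spectrum

__all__ = [
    "ReflectanceModel",
    "CalibrationFactor",
    "predict_spectrum",
    "calibrate",
    "apply_calibration",
    "save_calibration",
    "load_calibration",
]


class ReflectanceModel:
    """Scaled-Monte-Carlo probe reflectance R(mu_a, mu_s') from one bank.

    Exact evaluations window the radius-sorted bank to the probe's collection
    support, so each (mu_a, mu_s') point costs a fraction of the bank. A lazy
    cubic-spline surrogate of log R over a (mu_a, mu_s') rectangle serves as
    a cheap stand-in inside optimization loops; final results are always
    polished against the exact evaluator.
    """

    def __init__(self, bank: PhotonBank, geom: ProbeGeometry):
        self.bank = bank
        self.geom = geom
        self.g = bank.meta.g
        r_grid, p_grid = _p_table(geom.fiber_core_radius, geom.center_separation)
        # collection support: p(r) = 0 outside [r_lo, r_hi]; pad one grid
        # cell on each side so the interpolated tails are fully included
        nz = np.nonzero(p_grid > 0.0)[0]
        self._r_lo = r_grid[max(nz[0] - 1, 0)] if nz.size else 0.0
        self._r_hi = r_grid[min(nz[-1] + 1, r_grid.size - 1)] if nz.size else 0.0
        self._r_grid = r_grid
        self._p_grid = p_grid
        self._surrogate = None
        self._surrogate_box = None

    # ---- exact evaluation ------------------------------------------------

    def reflectance(self, mu_a: float, mu_sp: float) -> float:
        """Exact probe reflectance at one (mu_a [cm^-1], mu_s' [cm^-1])."""
        if mu_sp <= 0:
            raise ValueError("mu_sp must be positive")
        mu_s = mu_sp / (1.0 - self.g)
        f = self.bank.meta.mu_s_ref / mu_s
        # only records whose scaled radius lands in the collection annulus
        lo = np.searchsorted(self.bank.exit_radius, self._r_lo / f, side="left")
        hi = np.searchsorted(self.bank.exit_radius, self._r_hi / f, side="right")
        if hi <= lo:
            return 0.0
        r = self.bank.exit_radius[lo:hi] * f
        w = self.bank.weight[lo:hi] * np.exp(
            -mu_a * self.bank.path_length[lo:hi] * f
        )
        p = np.interp(r, self._r_grid, self._p_grid, left=0.0, right=0.0)
        return float(
            np.sum(w * p) * self.bank.meta.record_scale / self.bank.meta.n_launched
        )

    def reflectance_many(self, mu_a: np.ndarray, mu_sp: np.ndarray) -> np.ndarray:
        mu_a = np.asarray(mu_a, dtype=float)
        mu_sp = np.asarray(mu_sp, dtype=float)
        return np.array(
            [self.reflectance(a, s) for a, s in zip(mu_a, mu_sp)]
        )

    def predict(self, props: OpticalProperties) -> Spectrum:
        """R_model(lambda) for per-wavelength properties (exact, deterministic)."""
        if props.grid.size == 0:
            raise ValueError("empty wavelength grid")
        if abs(props.g - self.g) > 1e-12:
            raise ValueError("props anisotropy differs from the bank's g")
        return Spectrum(
            props.grid,
            self.reflectance_many(props.mu_a, props.mu_sp),
            unit="reflectance",
        )

    # ---- surrogate -------------------------------------------------------

    def surrogate(
        self,
        mu_a_range: tuple[float, float] = (0.0, 12.0),
        mu_sp_range: tuple[float, float] = (2.5, 22.0),
        n_mu_a: int = 97,
        n_mu_sp: int = 66,
    ):
        """Cubic spline of log R over a (mu_a, mu_s') rectangle (cached)."""
        box = (mu_a_range, mu_sp_range, n_mu_a, n_mu_sp)
        if self._surrogate is None or self._surrogate_box != box:
            mua = np.linspace(*mu_a_range, n_mu_a)
            musp = np.linspace(*mu_sp_range, n_mu_sp)
            logr = np.empty((n_mu_a, n_mu_sp))
            for i, a in enumerate(mua):
                for j, s in enumerate(musp):
                    logr[i, j] = np.log(self.reflectance(a, s))
            spl = RectBivariateSpline(mua, musp, logr, kx=3, ky=3)
            lo_a, hi_a = mu_a_range
            lo_s, hi_s = mu_sp_range

            def _eval(mu_a_arr, mu_sp_arr):
                a = np.clip(mu_a_arr, lo_a, hi_a)
                s = np.clip(mu_sp_arr, lo_s, hi_s)
                return np.exp(spl.ev(a, s))

            self._surrogate = _eval
            self._surrogate_box = box
        return self._surrogate


def predict_spectrum(
    bank: PhotonBank, geom: ProbeGeometry, props: OpticalProperties
) -> Spectrum:
    """One-shot wrapper: per-wavelength scale_bank + probe_collect composition."""
    return ReflectanceModel(bank, geom).predict(props)


# --------------------------------------------------------------------------
# reference-phantom calibration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationFactor:
    """Per-wavelength instrument scale factor from a reference phantom."""

    k: Spectrum
    reference_id: int

    def __post_init__(self) -> None:
        if np.any(self.k.values <= 0):
            raise ValueError("calibration factor must be positive everywhere")


def calibrate(
    measured_ref: Spectrum, predicted_ref: Spectrum, reference_id: int = -1
) -> CalibrationFactor:
    """k(lambda) = measured / predicted for the reference phantom.

    The factor is wavelength-dependent so it can absorb the spectrally
    structured instrument response, not just a global gain.
    """
    if not measured_ref.same_grid(predicted_ref):
        raise ValueError("measured and predicted reference grids differ")
    if np.any(predicted_ref.values <= 0):
        raise ValueError("predicted reference must be positive everywhere")
    k = measured_ref.with_values(
        measured_ref.values / predicted_ref.values, unit="dimensionless"
    )
    return CalibrationFactor(k=k, reference_id=reference_id)


def apply_calibration(cal: CalibrationFactor, measured: Spectrum) -> Spectrum:
    """Map a measurement onto the model's absolute scale: measured / k."""
    if not cal.k.same_grid(measured):
        raise ValueError("calibration and measurement grids differ")
    return measured.with_values(measured.values / cal.k.values, unit="reflectance")


def save_calibration(cal: CalibrationFactor, prefix) -> None:
    prefix = Path(prefix)
    pd.DataFrame(
        {"wavelength_nm": cal.k.wavelengths, "k": cal.k.values}
    ).to_csv(prefix.with_suffix(".csv"), index=False, float_format="%.17g")
    prefix.with_suffix(".json").write_text(
        json.dumps({"reference_id": cal.reference_id})
    )


def load_calibration(prefix) -> CalibrationFactor:
    prefix = Path(prefix)
    df = pd.read_csv(prefix.with_suffix(".csv"), float_precision="round_trip")
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return CalibrationFactor(
        k=Spectrum(df["wavelength_nm"].to_numpy(), df["k"].to_numpy()),
        reference_id=int(meta["reference_id"]),
    )
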