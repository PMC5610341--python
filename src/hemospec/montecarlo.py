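"""Weighted-photon Monte Carlo transport for diffuse reflectance.

Simulates photon migration in a semi-infinite homogeneous turbid medium and
records every photon that re-emerges through the top surface: its radial exit
distance from the launch point, its total path length, and the weight it
carried out. Absorption is deliberately *excluded* from the random walk —
steps are sampled from the scattering coefficient alone — so that a single
"photon bank" can later be rescaled to any (mu_a, mu_s) pair: radii and path
lengths scale with mu_s_ref/mu_s, and absorption is applied analytically as
a Beer-Lambert reweighting exp(-mu_a * L). This is the scaled Monte Carlo
scheme that makes the inverse model fast enough to sit inside a fit loop.

The fiber-probe collection step converts the bank's radially-resolved exit
weights into the reflectance seen by a 6-around-1 probe, using an analytic
ring-disc overlap probability (exact under the rotational symmetry of the
medium).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
from numba import njit
from numpy.polynomial.legendre import leggauss

from .spectrum import Spectrum

__all__ = [
    "PhotonBank",
    "ProbeGeometry",
    "ScaledBank",
    "simulate_bank",
    "scale_bank",
    "probe_collect",
    "collection_probability",
    "diffusion_reflectance",
    "save_bank",
    "load_bank",
]


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeGeometry:
    """6-around-1 fiber reflectance probe, dimensions in cm.

    Defaults follow a 400 um core diameter (200 um radius) and ~480 um
    center-to-center separation between the central collection fiber and each
    of the six surrounding illumination fibers.
    """

    fiber_core_radius: float = 0.02     # cm (200 um)
    center_separation: float = 0.048    # cm (480 um)
    n_illumination_fibers: int = 6

    def __post_init__(self) -> None:
        if self.fiber_core_radius <= 0:
            raise ValueError("fiber core radius must be positive")
        if self.center_separation < 0:
            raise ValueError("separation must be non-negative")
        if self.n_illumination_fibers < 1:
            raise ValueError("need at least one illumination fiber")


@dataclass(frozen=True)
class BankMeta:
    mu_s_ref: float
    g: float
    n_rel: float
    n_launched: int
    seed: int
    max_path_mfp: float
    n_capped: int = 0
    exit_weight: float = 0.0
    roulette_weight: float = 0.0   # net: terminations minus survival boosts
    records_total: int = 0
    record_scale: float = 1.0  # >1 when reservoir-capped


@dataclass(frozen=True)
class PhotonBank:
    """Exit-photon archive from one baseline simulation, sorted by radius."""

    exit_radius: np.ndarray   # cm, from launch point
    path_length: np.ndarray   # cm, cumulative
    weight: np.ndarray        # dimensionless, in (0, 1]
    meta: BankMeta

    def __len__(self) -> int:
        return self.exit_radius.size


@dataclass(frozen=True)
class ScaledBank:
    """Records of a bank rescaled to a target (mu_a, mu_s)."""

    exit_radius: np.ndarray
    weight: np.ndarray
    n_launched: int
    record_scale: float = 1.0


# --------------------------------------------------------------------------
# random walk kernel
# --------------------------------------------------------------------------

@njit(cache=False)
def _fresnel_up(ci: float, n_rel: float) -> float:
    """Unpolarized Fresnel reflectance, inside (index n_rel) -> outside (1)."""
    if n_rel == 1.0:
        return 0.0
    si2 = 1.0 - ci * ci
    st2 = n_rel * n_rel * si2
    if st2 >= 1.0:
        return 1.0  # total internal reflection
    ct = np.sqrt(1.0 - st2)
    rs = (n_rel * ci - ct) / (n_rel * ci + ct)
    rp = (ci - n_rel * ct) / (ci + n_rel * ct)
    return 0.5 * (rs * rs + rp * rp)


@njit(cache=False)
def _walk(mu_s, g, n_rel, n_photons, seed, max_path, w_min, roulette_m,
          r_out, l_out, w_out):
    """Per-photon loop. Returns (n_records, exit_w, roulette_w, n_capped, overflow)."""
    np.random.seed(seed)
    cap = r_out.shape[0]
    cnt = 0
    exit_w = 0.0
    roulette_w = 0.0
    n_capped = 0
    overflow = 0
    for _ in range(n_photons):
        x = 0.0; y = 0.0; z = 0.0
        ux = 0.0; uy = 0.0; uz = 1.0
        w = 1.0
        length = 0.0
        alive = True
        while alive:
            s = -np.log(np.random.random()) / mu_s
            if uz < 0.0:
                sb = -z / uz
                if sb <= s:
                    # reach the top surface within this step
                    x += ux * sb
                    y += uy * sb
                    z = 0.0
                    length += sb
                    rf = _fresnel_up(-uz, n_rel)
                    if rf < 1.0:
                        t = w * (1.0 - rf)
                        if cnt >= cap:
                            overflow = 1
                            return cnt, exit_w, roulette_w, n_capped, overflow
                        r_out[cnt] = np.sqrt(x * x + y * y)
                        l_out[cnt] = length
                        w_out[cnt] = t
                        cnt += 1
                        exit_w += t
                        w *= rf
                        if w <= 1e-300:
                            alive = False
                            break
                    uz = -uz
                    s -= sb
            x += ux * s
            y += uy * s
            z += uz * s
            length += s
            if length >= max_path:
                # flush: in a non-absorbing half-space the photon escapes with
                # certainty; record it at its current lateral position so the
                # weight budget stays exact (negligible after reweighting).
                if cnt >= cap:
                    overflow = 1
                    return cnt, exit_w, roulette_w, n_capped, overflow
                r_out[cnt] = np.sqrt(x * x + y * y)
                l_out[cnt] = length
                w_out[cnt] = w
                cnt += 1
                exit_w += w
                n_capped += 1
                alive = False
                break
            # Henyey-Greenstein deflection
            if g != 0.0:
                tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * np.random.random())
                ct = (1.0 + g * g - tmp * tmp) / (2.0 * g)
            else:
                ct = 2.0 * np.random.random() - 1.0
            if ct > 1.0:
                ct = 1.0
            elif ct < -1.0:
                ct = -1.0
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * np.random.random()
            cp = np.cos(phi)
            sp = np.sin(phi)
            if uz > 0.99999 or uz < -0.99999:
                ux = st * cp
                uy = st * sp
                uz = ct if uz >= 0.0 else -ct
            else:
                den = np.sqrt(1.0 - uz * uz)
                nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
                nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
                nuz = -den * st * cp + uz * ct
                ux = nux
                uy = nuy
                uz = nuz
            # Russian roulette
            if w < w_min:
                if np.random.random() * roulette_m < 1.0:
                    # survival boost is booked against the roulette budget so
                    # exit + roulette = launched stays an exact identity
                    roulette_w -= w * (roulette_m - 1.0)
                    w *= roulette_m
                else:
                    roulette_w += w
                    alive = False
    return cnt, exit_w, roulette_w, n_capped, overflow


def simulate_bank(
    mu_s_ref: float,
    g: float,
    n_rel: float = 1.0,
    n_photons: int = 100_000,
    seed: int = 0,
    max_path_mfp: float = 30_000.0,
    w_min: float = 1e-4,
    roulette_m: float = 10.0,
    max_records: int | None = None,
) -> PhotonBank:
    """Run a baseline (absorption-free) simulation and build a photon bank.

    A pencil beam enters normally at the origin. Step lengths are sampled
    from mu_s_ref alone; the Henyey-Greenstein phase function with fixed g
    deflects each step; at the top boundary the Fresnel-transmitted fraction
    of the weight is recorded as an exit and the photon continues with the
    reflected remainder (weight splitting), so with a matched boundary
    (n_rel = 1) each photon yields exactly one record. Photons whose weight
    falls below ``w_min`` face Russian roulette with survival 1/``roulette_m``.
    Photons exceeding ``max_path_mfp`` scattering mean free paths of total
    path are flushed to the bank at their current lateral radius (see module
    docstring); their count is kept in the meta. A dimensionless cap keeps
    banks at different mu_s_ref exactly similar to each other.

    Identical arguments (including seed) produce identical banks.
    """
    if mu_s_ref <= 0:
        raise ValueError("mu_s_ref must be positive")
    if not -1.0 < g < 1.0:
        raise ValueError("anisotropy g must lie in (-1, 1)")
    if n_rel <= 0:
        raise ValueError("relative refractive index must be positive")
    if n_photons < 1:
        raise ValueError("need at least one photon")
    cap = n_photons + 64 if n_rel == 1.0 else n_photons * 16 + 64
    r_out = np.empty(cap)
    l_out = np.empty(cap)
    w_out = np.empty(cap)
    while True:
        cnt, exit_w, roulette_w, n_capped, overflow = _walk(
            float(mu_s_ref), float(g), float(n_rel), int(n_photons), int(seed),
            float(max_path_mfp) / float(mu_s_ref), float(w_min), float(roulette_m),
            r_out, l_out, w_out,
        )
        if not overflow:
            break
        cap *= 4
        r_out = np.empty(cap)
        l_out = np.empty(cap)
        w_out = np.empty(cap)

    r, length, w = r_out[:cnt].copy(), l_out[:cnt].copy(), w_out[:cnt].copy()
    records_total = cnt
    record_scale = 1.0
    if max_records is not None and cnt > max_records:
        # reservoir-style deterministic thinning: keep a uniform subset and
        # boost the per-record weight so the estimator stays unbiased
        rng = np.random.default_rng(seed + 1)
        keep = np.sort(rng.choice(cnt, size=max_records, replace=False))
        r, length, w = r[keep], length[keep], w[keep]
        record_scale = cnt / max_records

    order = np.argsort(r, kind="stable")
    meta = BankMeta(
        mu_s_ref=float(mu_s_ref), g=float(g), n_rel=float(n_rel),
        n_launched=int(n_photons), seed=int(seed), max_path_mfp=float(max_path_mfp),
        n_capped=int(n_capped), exit_weight=float(exit_w),
        roulette_weight=float(roulette_w), records_total=int(records_total),
        record_scale=float(record_scale),
    )
    return PhotonBank(r[order], length[order], w[order], meta)


# --------------------------------------------------------------------------
# similarity rescaling and probe collection
# --------------------------------------------------------------------------

def scale_bank(bank: PhotonBank, mu_a: float, mu_s: float,
               g: float | None = None) -> ScaledBank:
    """Rescale bank records to a target medium (mu_a, mu_s).

    r' = r * (mu_s_ref / mu_s), L' = L * (mu_s_ref / mu_s),
    w' = w * exp(-mu_a * L'). The target anisotropy must equal the bank's
    (pass ``g`` to assert it); similarity in g is not rescalable.
    """
    if mu_s <= 0:
        raise ValueError("target mu_s must be positive")
    if mu_a < 0:
        raise ValueError("mu_a must be non-negative")
    if g is not None and abs(g - bank.meta.g) > 1e-12:
        raise ValueError(
            f"target g={g} differs from bank g={bank.meta.g}; rebuild the bank"
        )
    f = bank.meta.mu_s_ref / mu_s
    r = bank.exit_radius * f
    w = bank.weight * np.exp(-mu_a * bank.path_length * f)
    return ScaledBank(r, w, bank.meta.n_launched, bank.meta.record_scale)


def _circle_fraction(rho: np.ndarray, r: np.ndarray, a: float) -> np.ndarray:
    """Fraction of a circle of radius r centered at distance rho from a disc
    center that lies inside the disc of radius a (azimuth uniform)."""
    rho = np.asarray(rho, dtype=float)
    r = np.asarray(r, dtype=float)
    rho_b, r_b = np.broadcast_arrays(rho, r)
    out = np.zeros(rho_b.shape)
    degenerate = (rho_b < 1e-15) | (r_b < 1e-15)
    # degenerate cases: a point — inside iff the other distance < a
    out[degenerate] = ((rho_b + r_b)[degenerate] < a).astype(float)
    nd = ~degenerate
    arg = np.empty_like(out)
    arg[nd] = (rho_b[nd] ** 2 + r_b[nd] ** 2 - a * a) / (2.0 * rho_b[nd] * r_b[nd])
    arg = np.clip(arg, -1.0, 1.0)
    out[nd] = np.arccos(arg[nd]) / np.pi
    return out


@lru_cache(maxsize=16)
def _p_table(radius: float, separation: float) -> tuple[np.ndarray, np.ndarray]:
    """Tabulated collection probability p(r) for one probe geometry.

    p(r) = E over launch points s uniform on the source fiber face, exit
    azimuth uniform, of the probability that a photon exiting at distance r
    from s lands on the collection fiber face. Reduced to a single radial
    quadrature: the density of rho = |s - detector center| carries an arc
    factor, and the azimuthal average is the circle-disc overlap fraction.
    """
    a = radius       # collection fiber radius
    b = radius       # source fiber radius
    d = separation
    nodes, wts = leggauss(192)
    lo, hi = max(0.0, d - b), d + b
    rho = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    jac = 0.5 * (hi - lo) * wts
    if d < 1e-15:
        beta = np.where(rho <= b, np.pi, 0.0)
    else:
        argb = (rho**2 + d**2 - b**2) / (2.0 * rho * d)
        beta = np.arccos(np.clip(argb, -1.0, 1.0))
    pdf = 2.0 * rho * beta / (np.pi * b * b)   # integrates to 1 over [lo, hi]

    r_max = d + b + a
    r_grid = np.linspace(0.0, r_max * 1.001, 3000)
    frac = _circle_fraction(rho[None, :], r_grid[:, None], a)   # (nr, nquad)
    p_grid = frac @ (pdf * jac)
    return r_grid, p_grid


def collection_probability(r, geom: ProbeGeometry) -> np.ndarray:
    """Probability that an exit at radius r from its launch point is collected."""
    r_grid, p_grid = _p_table(geom.fiber_core_radius, geom.center_separation)
    return np.interp(np.asarray(r, dtype=float), r_grid, p_grid, left=0.0, right=0.0)


def probe_collect(scaled: ScaledBank, geom: ProbeGeometry) -> float:
    """Probe reflectance: collected weight fraction per launched photon.

    The six illumination fibers are equivalent by the medium's rotational
    symmetry, so a single equivalent source at the printed center separation
    is exact; the result is already normalized per unit launched power.
    """
    p = collection_probability(scaled.exit_radius, geom)
    return float(np.sum(scaled.weight * p) * scaled.record_scale / scaled.n_launched)


# --------------------------------------------------------------------------
# diffusion-dipole oracle
# --------------------------------------------------------------------------

def diffusion_reflectance(mu_a: float, mu_sp: float, rho, n_rel: float = 1.0):
    """Steady-state diffuse reflectance per unit area at radius rho (cm).

    Closed-form dipole solution with an extrapolated boundary: an isotropic
    source at depth z0 = 1/(mu_a + mu_s') and its image above the
    extrapolated plane at z = -2*A*D, where A encodes internal reflection
    (A = 1 for a matched boundary). Valid in the high-albedo, large-rho
    diffusive regime; intended as an independent cross-check of the Monte
    Carlo model, not as the forward model itself.
    """
    rho = np.asarray(rho, dtype=float)
    mu_t = mu_a + mu_sp
    z0 = 1.0 / mu_t
    diff = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(3.0 * mu_a * mu_t)
    if n_rel == 1.0:
        a_fac = 1.0
    else:
        rd = -1.440 / n_rel**2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel
        a_fac = (1.0 + rd) / (1.0 - rd)
    zb = 2.0 * a_fac * diff
    r1 = np.sqrt(z0**2 + rho**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho**2)
    term1 = z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
    term2 = (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    out = (term1 + term2) / (4.0 * np.pi)
    return float(out) if np.isscalar(rho) or rho.ndim == 0 else out


# --------------------------------------------------------------------------
# persistence
# --------------------------------------------------------------------------

def save_bank(bank: PhotonBank, prefix) -> None:
    """Write records to <prefix>.csv and metadata to <prefix>.json."""
    prefix = Path(prefix)
    header = "exit_radius_cm,path_length_cm,weight"
    data = np.column_stack([bank.exit_radius, bank.path_length, bank.weight])
    np.savetxt(prefix.with_suffix(".csv"), data, delimiter=",",
               header=header, comments="", fmt="%.17g")
    meta = {k: getattr(bank.meta, k) for k in bank.meta.__dataclass_fields__}
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_bank(prefix) -> PhotonBank:
    prefix = Path(prefix)
    data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", skiprows=1,
                      ndmin=2)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return PhotonBank(data[:, 0], data[:, 1], data[:, 2], BankMeta(**meta))
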