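"""Photon transport: conservation, similarity scaling, probe collection,
diffusion cross-check, persistence."""

import numpy as np
import pytest

import hemospec as hs
from hemospec.montecarlo import ScaledBank, collection_probability


def binned_reflectance(scaled, bins):
    """Radial reflectance profile with per-bin Monte Carlo standard errors."""
    area = np.pi * (bins[1:] ** 2 - bins[:-1] ** 2)
    w, _ = np.histogram(scaled.exit_radius, bins, weights=scaled.weight)
    w2, _ = np.histogram(scaled.exit_radius, bins, weights=scaled.weight**2)
    n = scaled.n_launched
    return w / n / area, np.sqrt(w2) / n / area


class TestSimulateBank:
    def test_identical_seed_identical_bank(self):
        a = hs.simulate_bank(80.0, 0.85, n_photons=5000, seed=9)
        b = hs.simulate_bank(80.0, 0.85, n_photons=5000, seed=9)
        np.testing.assert_array_equal(a.exit_radius, b.exit_radius)
        np.testing.assert_array_equal(a.path_length, b.path_length)
        np.testing.assert_array_equal(a.weight, b.weight)

    def test_matched_boundary_total_reflectance_unity(self, bank100):
        # no absorption, matched boundary: every photon escapes with weight 1
        n = bank100.meta.n_launched
        total = bank100.weight.sum() / n
        se = bank100.weight.std() / np.sqrt(n)
        assert abs(total - 1.0) <= max(3 * se, 1e-12)

    def test_energy_bookkeeping_identity(self, bank100):
        meta = bank100.meta
        budget = meta.exit_weight + meta.roulette_weight
        assert budget == pytest.approx(meta.n_launched, abs=1e-9 * meta.n_launched)

    def test_energy_bookkeeping_with_mismatched_boundary(self):
        # Fresnel weight splitting and roulette both active; the roulette
        # budget nets terminations against survival boosts
        bank = hs.simulate_bank(80.0, 0.8, n_rel=1.4, n_photons=4000, seed=17)
        meta = bank.meta
        budget = meta.exit_weight + meta.roulette_weight
        assert budget == pytest.approx(meta.n_launched, rel=1e-9)
        assert np.all((bank.weight > 0) & (bank.weight <= 1.0))

    def test_mean_exit_radius_scales_inversely_with_mu_s(self, bank100, bank50):
        ratio = bank50.exit_radius.mean() / bank100.exit_radius.mean()
        assert ratio == pytest.approx(2.0, rel=0.05)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            hs.simulate_bank(-1.0, 0.9)
        with pytest.raises(ValueError):
            hs.simulate_bank(100.0, 1.5)
        with pytest.raises(ValueError):
            hs.simulate_bank(100.0, 0.9, n_photons=0)

    def test_reservoir_cap_preserves_estimates(self, geom):
        full = hs.simulate_bank(100.0, 0.9, n_photons=20_000, seed=5)
        capped = hs.simulate_bank(100.0, 0.9, n_photons=20_000, seed=5,
                                  max_records=5_000)
        assert len(capped) == 5_000
        assert capped.meta.record_scale == pytest.approx(len(full) / 5_000)
        r_full = hs.probe_collect(hs.scale_bank(full, 1.0, 100.0), geom)
        r_capped = hs.probe_collect(hs.scale_bank(capped, 1.0, 100.0), geom)
        assert r_capped == pytest.approx(r_full, rel=0.1)


class TestScaleBank:
    def test_identity_transform(self, bank100):
        scaled = hs.scale_bank(bank100, 0.0, bank100.meta.mu_s_ref)
        np.testing.assert_array_equal(scaled.exit_radius, bank100.exit_radius)
        np.testing.assert_array_equal(scaled.weight, bank100.weight)

    def test_absorption_strictly_shrinks_weights(self, bank100):
        scaled = hs.scale_bank(bank100, 0.5, bank100.meta.mu_s_ref)
        assert np.all(scaled.weight < bank100.weight)

    def test_g_mismatch_rejected(self, bank100):
        with pytest.raises(ValueError, match="g"):
            hs.scale_bank(bank100, 0.1, 80.0, g=0.5)

    def test_nonpositive_mu_s_rejected(self, bank100):
        with pytest.raises(ValueError):
            hs.scale_bank(bank100, 0.1, 0.0)

    @pytest.mark.parametrize("mu_a", [0.5, 1.5, 3.0])
    @pytest.mark.parametrize("mu_s", [60.0, 100.0, 140.0])
    def test_scaled_matches_fresh_simulation(self, bank100, mu_a, mu_s):
        """Similarity-scaling oracle: rescaled baseline bank vs a fresh
        simulation run directly at the target scattering, over a 3x3 grid."""
        scaled = hs.scale_bank(bank100, mu_a, mu_s)
        fresh_bank = hs.simulate_bank(
            mu_s, bank100.meta.g, n_photons=30_000, seed=int(1000 + mu_s + 10 * mu_a)
        )
        fresh = hs.scale_bank(fresh_bank, mu_a, mu_s)
        bins = np.linspace(0.0, 120.0 / mu_s, 7)
        r1, e1 = binned_reflectance(scaled, bins)
        r2, e2 = binned_reflectance(fresh, bins)
        z = np.abs(r1 - r2) / np.hypot(e1, e2)
        # Bonferroni-corrected family bound: 54 simultaneous bins across the
        # grid at a family-wise 3-sigma level give a per-bin cut of ~3.9
        assert np.all(z < 3.9)
        assert z.mean() < 1.5


class TestProbeCollect:
    def test_far_separation_collects_nothing(self, bank100):
        # separation beyond any possible exit radius (path cap bounds r)
        geom = hs.ProbeGeometry(fiber_core_radius=0.02, center_separation=350.0)
        scaled = hs.scale_bank(bank100, 0.1, 100.0)
        assert hs.probe_collect(scaled, geom) == 0.0

    def test_concentric_equal_fibers_collect_everything_at_zero_radius(self):
        geom = hs.ProbeGeometry(fiber_core_radius=0.02, center_separation=0.0)
        scaled = ScaledBank(np.zeros(100), np.ones(100), n_launched=100)
        assert hs.probe_collect(scaled, geom) == pytest.approx(1.0, abs=1e-9)

    def test_collection_probability_matches_double_integral(self, geom):
        # brute-force oracle: midpoint quadrature over the source disc
        # (area-uniform) and the exit azimuth
        nu, nth, nphi = 200, 200, 200
        rs = geom.fiber_core_radius * np.sqrt((np.arange(nu) + 0.5) / nu)
        th = 2 * np.pi * (np.arange(nth) + 0.5) / nth
        phi = 2 * np.pi * (np.arange(nphi) + 0.5) / nphi
        sx = geom.center_separation + rs[:, None] * np.cos(th)[None, :]
        sy = rs[:, None] * np.sin(th)[None, :]
        for r in (0.01, 0.03, 0.05, 0.07):
            ex = sx[:, :, None] + r * np.cos(phi)[None, None, :]
            ey = sy[:, :, None] + r * np.sin(phi)[None, None, :]
            inside = ex**2 + ey**2 < geom.fiber_core_radius**2
            assert collection_probability(r, geom) == pytest.approx(
                inside.mean(), abs=1e-3
            )

    def test_reflectance_monotone_in_absorption(self, bank100, geom):
        values = [
            hs.probe_collect(hs.scale_bank(bank100, mu_a, 100.0), geom)
            for mu_a in (0.2, 0.8, 1.6, 3.0, 5.0)
        ]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestDiffusionOracle:
    def test_monotone_in_absorption(self):
        r1 = hs.diffusion_reflectance(0.1, 10.0, 1.0)
        r2 = hs.diffusion_reflectance(0.2, 10.0, 1.0)
        assert r2 < r1

    def test_asymptotic_slope_is_mu_eff(self):
        mu_a, mu_sp = 0.1, 10.0
        mu_eff = np.sqrt(3 * mu_a * (mu_a + mu_sp))
        rho = np.linspace(4.0, 6.0, 41)
        y = np.log(rho**2 * hs.diffusion_reflectance(mu_a, mu_sp, rho))
        slope = np.polyfit(rho, y, 1)[0]
        assert slope == pytest.approx(-mu_eff, rel=0.02)

    def test_monte_carlo_agrees_with_dipole_at_1cm(self, bank100):
        mu_a, mu_sp = 0.1, 10.0
        scaled = hs.scale_bank(bank100, mu_a, mu_sp / (1 - bank100.meta.g))
        lo, hi = 0.9, 1.1
        area = np.pi * (hi**2 - lo**2)
        mask = (scaled.exit_radius >= lo) & (scaled.exit_radius < hi)
        r_mc = scaled.weight[mask].sum() / scaled.n_launched / area
        rr = np.linspace(lo, hi, 201)
        r_dipole = np.trapezoid(
            hs.diffusion_reflectance(mu_a, mu_sp, rr) * 2 * np.pi * rr, rr
        ) / area
        assert r_mc == pytest.approx(r_dipole, rel=0.15)


def test_bank_serialization_round_trips_exactly(tmp_path):
    bank = hs.simulate_bank(90.0, 0.9, n_photons=2000, seed=3)
    hs.save_bank(bank, tmp_path / "bank")
    back = hs.load_bank(tmp_path / "bank")
    np.testing.assert_array_equal(back.exit_radius, bank.exit_radius)
    np.testing.assert_array_equal(back.path_length, bank.path_length)
    np.testing.assert_array_equal(back.weight, bank.weight)
    assert back.meta == bank.meta
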