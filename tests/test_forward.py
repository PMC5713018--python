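"""Shallow-water forward model: limits, factors, band integration."""

import numpy as np
import pytest

import shallowsea as ss
from shallowsea.errors import ValidationError


@pytest.fixture()
def pixel(geom):
    wc = ss.WaterColumn(G=0.1, P=0.05, X=0.01)
    return ss.PixelParams(wc=wc, z=3.0, ab=np.array([0.5, 0.3, 0.2]), geom=geom)


class TestDepthLimits:
    def test_zero_depth_returns_albedo_over_pi(self, pixel, lib, grid):
        p0 = ss.PixelParams(wc=pixel.wc, z=0.0, ab=pixel.ab, geom=pixel.geom)
        rrs = ss.rrs_shallow(p0, grid, lib)
        albedo = ss.mix_albedo(pixel.ab, lib.on_grid(grid))
        assert np.allclose(rrs, albedo / np.pi, rtol=1e-12)

    def test_deep_limit_is_deep_water_rrs(self, pixel, lib, grid):
        pinf = ss.PixelParams(wc=pixel.wc, z=1e4, ab=pixel.ab, geom=pixel.geom)
        rrs = ss.rrs_shallow(pinf, grid, lib)
        a = ss.absorption(pixel.wc, grid)
        bb = ss.backscatter(pixel.wc, grid)
        rrs_inf = ss.deep_water_rrs(ss.gordon_u(a, bb), pixel.geom)
        assert np.allclose(rrs, rrs_inf, rtol=1e-12, atol=1e-15)

    def test_mid_depth_term_by_term_oracle(self, pixel, lib):
        """Hand evaluation of every term of the model at one wavelength."""
        lam = np.array([550.0])
        wc, g, z = pixel.wc, pixel.geom, pixel.z
        a = ss.absorption(wc, lam)[0]
        bb = ss.backscatter(wc, lam)[0]
        u = bb / (a + bb)
        rrs_inf = (0.0512 * u * (1 + 4.6659 * u - 7.8387 * u**2 + 5.4571 * u**3)
                   * (1 + 0.1098 / g.mu_s_sw) * (1 + 0.4021 / g.mu_v_sw))
        kd = (a + bb) / g.mu_s_sw
        duc = 1.03 * np.sqrt(1 + 2.4 * u)
        dub = 1.04 * np.sqrt(1 + 5.4 * u)
        alb = ss.mix_albedo(pixel.ab, lib.on_grid(lam))[0]
        expect = (rrs_inf * (1 - np.exp(-(1 / g.mu_s_sw + duc / g.mu_v_sw) * kd * z))
                  + alb / np.pi * np.exp(-(1 / g.mu_s_sw + dub / g.mu_v_sw) * kd * z))
        got = ss.rrs_shallow(pixel, lam, lib)[0]
        assert got == pytest.approx(expect, rel=1e-12)

    def test_monotone_convergence_to_deep_water(self, pixel, lib, grid):
        """|rrs(z) - rrs_inf| shrinks monotonically with depth."""
        a = ss.absorption(pixel.wc, grid)
        bb = ss.backscatter(pixel.wc, grid)
        rrs_inf = ss.deep_water_rrs(ss.gordon_u(a, bb), pixel.geom)
        prev = None
        for z in [0.0, 0.5, 1, 2, 4, 8, 16, 32]:
            p = ss.PixelParams(wc=pixel.wc, z=z, ab=pixel.ab, geom=pixel.geom)
            gap = np.abs(ss.rrs_shallow(p, grid, lib) - rrs_inf).max()
            if prev is not None:
                assert gap <= prev + 1e-15
            prev = gap

    def test_depth_trend_sign_set_by_bottom_vs_water_brightness(self, geom, lib):
        """rrs falls with z when the bottom outshines the deep-water signal
        (clear water over bright sand) and rises when the water outshines a
        dark bottom (turbid water over sediment-rock); checked at the
        abundance-simplex vertices."""
        lam = np.array([490.0])
        cases = [
            (ss.WaterColumn(G=0.05, P=0.02, X=0.005), np.array([1.0, 0, 0])),
            (ss.WaterColumn(G=0.01, P=0.005, X=0.05), np.array([0.0, 0, 1.0])),
        ]
        for wc, ab in cases:
            a = ss.absorption(wc, lam)
            bb = ss.backscatter(wc, lam)
            rrs_inf = ss.deep_water_rrs(ss.gordon_u(a, bb), geom)[0]
            alb = ss.mix_albedo(ab, lib.on_grid(lam))[0]
            sign = np.sign(rrs_inf - alb / np.pi)
            assert sign != 0
            vals = [ss.rrs_shallow(ss.PixelParams(wc=wc, z=z, ab=ab, geom=geom),
                                   lam, lib)[0] for z in (0.5, 1.0, 2.0, 4.0)]
            assert np.all(sign * np.diff(vals) > 0)


class TestDiffusionFactors:
    def test_zero_u_baselines(self):
        df = ss.diffusion_factors(0.0)
        assert df.Duc == pytest.approx(1.03)
        assert df.Dub == pytest.approx(1.04)

    def test_monotone_and_ordering(self):
        u = np.linspace(0.0, 0.999, 500)
        df = ss.diffusion_factors(u)
        assert np.all(np.diff(df.Duc) > 0)
        assert np.all(np.diff(df.Dub) > 0)
        assert np.all(df.Dub >= df.Duc)
        assert np.all(df.Duc >= 1.0)


class TestInterfaceTransfer:
    def test_zero_maps_to_zero(self):
        assert ss.to_above_surface(0.0) == 0.0

    def test_round_trip(self):
        rrs = np.linspace(0.0, 0.2, 50)
        back = ss.from_above_surface(ss.to_above_surface(rrs))
        assert np.allclose(back, rrs, atol=1e-14)

    def test_amplifies_over_half(self):
        rrs = np.linspace(1e-4, 0.2, 20)
        assert np.all(ss.to_above_surface(rrs) > 0.5 * rrs)

    def test_nonphysical_rejected(self):
        with pytest.raises(ValidationError):
            ss.to_above_surface(0.7)


class TestSimulateBands:
    def test_fine_grid_oracle_composition(self, pixel, bands6, lib, grid):
        """Band simulation equals the step-by-step pipeline composition."""
        got = ss.simulate_bands(pixel, bands6, lib)
        rrs = ss.rrs_shallow(pixel, grid, lib)
        expect = ss.band_integrate(ss.to_above_surface(rrs), bands6, grid_nm=grid)
        assert np.allclose(got, expect, rtol=1e-12)

    def test_zero_depth_pure_sand(self, geom, bands6, lib, grid):
        wc = ss.WaterColumn(G=0.05, P=0.02, X=0.01)
        p = ss.PixelParams(wc=wc, z=0.0, ab=np.array([1.0, 0, 0]), geom=geom)
        got = ss.simulate_bands(p, bands6, lib)
        sand = lib.on_grid(grid).matrix[:, 0]
        expect = ss.band_integrate(ss.to_above_surface(sand / np.pi), bands6,
                                   grid_nm=grid)
        assert np.allclose(got, expect, rtol=1e-12)

    def test_forward_model_vectorised_matches_scalar(self, forward6):
        rng = np.random.default_rng(4)
        n = 10
        G = rng.uniform(0.01, 0.3, n)
        P = rng.uniform(0.005, 0.2, n)
        X = rng.uniform(0.001, 0.05, n)
        z = rng.uniform(0.5, 15, n)
        ab = rng.dirichlet([1, 1, 1], n)
        batch = forward6.simulate(G, P, X, z, ab)
        for i in range(n):
            one = forward6.simulate(G[i], P[i], X[i], z[i], ab[i])
            assert np.allclose(batch[i], one, rtol=1e-14)

    def test_continuity_in_parameters(self, forward6):
        """Small parameter steps produce proportionally small band changes."""
        p0 = np.array([0.1, 0.05, 0.01, 3.0])
        ab = np.array([0.4, 0.3, 0.3])
        base = forward6.simulate(*p0, ab)
        for k in range(4):
            for h in (1e-4, 1e-5):
                p = p0.copy()
                p[k] += h
                delta = np.abs(forward6.simulate(*p, ab) - base).max()
                assert delta < 10 * h  # bounded directional derivative

    def test_analytic_jacobian_matches_finite_differences(self, forward6):
        rng = np.random.default_rng(11)
        for _ in range(10):
            p = np.array([rng.uniform(0.01, 0.3), rng.uniform(0.005, 0.2),
                          rng.uniform(0.001, 0.05), rng.uniform(0.5, 15),
                          rng.uniform(0.05, 0.95), rng.uniform(0.05, 0.95)])
            _, J = forward6.simulate_jac(*p)
            for k in range(6):
                h = 1e-6 * max(abs(p[k]), 1e-2)
                pp, pm = p.copy(), p.copy()
                pp[k] += h
                pm[k] -= h
                fd = (forward6.simulate_jac(*pp)[0]
                      - forward6.simulate_jac(*pm)[0]) / (2 * h)
                assert np.allclose(J[:, k], fd, rtol=1e-4, atol=1e-9)
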