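"""Per-pixel and scene inversion: cost, depth init, recovery, determinism."""

import numpy as np
import pytest

import shallowsea as ss
from shallowsea.errors import ValidationError
from shallowsea.invert import FLAG_Z_AT_MAX


class TestCost:
    def test_perfect_match_zero(self):
        o = np.full(6, 0.05)
        assert ss.cost(o, o) == 0.0

    def test_single_band_mismatch_forced_arithmetic(self):
        """One band off by d on a flat observation o: cost = d^2/o."""
        o = np.full(6, 0.04)
        m = o.copy()
        m[2] += 0.01
        assert ss.cost(o, m) == pytest.approx(0.01 ** 2 / 0.04, rel=1e-12)

    def test_formula_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            o = rng.uniform(0.01, 0.2, 6)
            m = rng.uniform(0.01, 0.2, 6)
            expect = 6 * np.sum((m - o) ** 2) / np.sum(o)
            assert ss.cost(o, m) == pytest.approx(expect, rel=1e-12)

    def test_zero_observation_rejected(self):
        with pytest.raises(ValidationError):
            ss.cost(np.zeros(6), np.ones(6))


class TestDepthInit:
    def test_equal_bands_give_gain_minus_offset(self):
        rc = ss.RatioCoefficients(m0=4.0, m1=8.0, n=1000.0)
        z0, bad = ss.init_depth(0.05, 0.05, rc)
        assert not bad
        assert z0 == pytest.approx(8.0 - 4.0)

    def test_gain_linearity(self):
        rc1 = ss.RatioCoefficients(m0=0.0, m1=10.0, n=1000.0)
        rc2 = ss.RatioCoefficients(m0=0.0, m1=20.0, n=1000.0)
        z1, _ = ss.init_depth(0.03, 0.05, rc1, z_max=1e6)
        z2, _ = ss.init_depth(0.03, 0.05, rc2, z_max=1e6)
        assert z2 == pytest.approx(2 * z1)

    def test_log_domain_fallback(self):
        rc = ss.RatioCoefficients()
        z0, bad = ss.init_depth(1e-9, 0.05, rc)
        assert bad and z0 == pytest.approx(2.0)

    def test_calibrated_ratio_ranks_depth(self):
        """Calibrated on truth points over a uniform sandy bottom in clear
        water (the heuristic's domain of validity), the blue/green log
        ratio ranks scene depths almost perfectly."""
        from scipy.stats import spearmanr
        cfg = ss.SceneConfig(
            shape=(16, 16), seed=7, cover_kind="mosaic",
            classes=(ss.CoverClass("sand", (0.8, 0.1, 0.1), 0.0, (0.5, 8.0)),),
            iop_kind="constant", g_range=(0.02, 0.02), p_range=(0.01, 0.01),
            x_range=(0.005, 0.005))
        t = ss.generate(cfg)
        blue, green = t.observed[1].ravel(), t.observed[2].ravel()
        rc = ss.calibrate_ratio(blue[::7], green[::7], t.z.ravel()[::7])
        z0, _ = ss.init_depth(t.observed[1], t.observed[2], rc)
        rho = spearmanr(z0.ravel(), t.z.ravel()).statistic
        assert rho > 0.9


class TestPixelInversion:
    def test_noiseless_recovery(self, forward6):
        """Construct-then-recover at z=3 m: depth within 5%, abundances
        within 0.05."""
        truth = dict(G=0.08, P=0.04, X=0.008, z=3.0)
        ab = np.array([0.5, 0.2, 0.3])
        obs = forward6.simulate(truth["G"], truth["P"], truth["X"], truth["z"], ab)
        sol = ss.invert_pixel(obs, forward6)
        assert abs(sol.z - truth["z"]) / truth["z"] < 0.05
        assert np.abs(sol.ab - ab).max() < 0.05
        assert sol.cost < 1e-12

    def test_deep_water_hits_bound_iops_still_recovered(self, forward6):
        truth = dict(G=0.08, P=0.04, X=0.008)
        ab = np.array([0.4, 0.3, 0.3])
        obs = forward6.simulate(truth["G"], truth["P"], truth["X"], 1e3, ab)
        sol = ss.invert_pixel(obs, forward6, z0=20.0)
        assert sol.flag & FLAG_Z_AT_MAX
        assert abs(sol.G - truth["G"]) / truth["G"] < 0.10
        assert abs(sol.P - truth["P"]) / truth["P"] < 0.10
        assert abs(sol.X - truth["X"]) / truth["X"] < 0.10

    def test_cost_never_above_initialisation(self, forward6):
        rng = np.random.default_rng(1)
        for _ in range(5):
            obs = forward6.simulate(rng.uniform(0.01, 0.3),
                                    rng.uniform(0.005, 0.2),
                                    rng.uniform(0.001, 0.05),
                                    rng.uniform(0.5, 15),
                                    rng.dirichlet([1, 1, 1]))
            noisy = obs * (1 + 0.05 * rng.standard_normal(6))
            z0 = 2.0
            sol = ss.invert_pixel(np.abs(noisy), forward6, z0=z0)
            opts = ss.InversionOptions()
            init_model = forward6.simulate(opts.init_G, opts.init_P, opts.init_X,
                                           z0, np.full(3, 1 / 3))
            assert sol.cost <= ss.cost(np.abs(noisy), init_model) + 1e-15

    def test_library_permutation_permutes_abundances(self, bands6, lib, geom):
        perm = ["algae", "sediment", "sand"]
        fm1 = ss.ForwardModel(bands6, lib, geom)
        fm2 = ss.ForwardModel(bands6, lib.reorder(perm), geom)
        ab = np.array([0.6, 0.1, 0.3])
        obs = fm1.simulate(0.05, 0.03, 0.01, 2.0, ab)
        s1 = ss.invert_pixel(obs, fm1)
        s2 = ss.invert_pixel(obs, fm2)
        idx = [lib.names.index(n) for n in perm]
        assert np.allclose(s2.ab, s1.ab[idx], atol=1e-4)

    def test_invalid_observation_rejected(self, forward6):
        with pytest.raises(ValidationError):
            ss.invert_pixel(np.full(6, np.nan), forward6)
        with pytest.raises(ValidationError):
            ss.invert_pixel(np.zeros(6), forward6)


class TestSceneInversion:
    def test_constant_scene_identical_solutions(self, bands6, lib, geom):
        fm = ss.ForwardModel(bands6, lib, geom)
        obs = fm.simulate(0.06, 0.03, 0.01, 4.0, np.array([0.5, 0.25, 0.25]))
        cube = np.tile(obs[:, None, None], (1, 6, 6))
        res = ss.invert_scene(cube, geom, lib, bands6)
        for k in ("G", "P", "X", "z"):
            assert np.ptp(res[k]) == 0.0

    def test_depth_gradient_monotone_and_deterministic(self, small_scene):
        t = small_scene
        b6 = t.bands.subset(6)
        res1 = ss.invert_scene(t.observed[:6], t.config.geometry, t.lib, b6)
        res2 = ss.invert_scene(t.observed[:6], t.config.geometry, t.lib, b6)
        assert np.array_equal(res1["z"], res2["z"], equal_nan=True)
        # retrieved depth follows the truth gradient (column means increase)
        col_means = np.nanmean(res1["z"], axis=0)
        assert (np.diff(col_means) > 0).mean() > 0.9
        rel = (res1["z"] - t.z) / t.z
        assert np.sqrt(np.mean(rel ** 2)) < 0.05
        assert np.sqrt(np.mean((res1["abundance"] - t.abundance) ** 2)) < 0.05

    def test_mask_respected(self, small_scene):
        t = small_scene
        b6 = t.bands.subset(6)
        mask = np.zeros(t.z.shape, bool)
        mask[:4, :4] = True
        res = ss.invert_scene(t.observed[:6], t.config.geometry, t.lib, b6,
                              mask=mask)
        assert np.all(np.isnan(res["z"][~mask]))
        assert np.all(res["flags"][~mask] == 255)
        assert np.all(np.isfinite(res["z"][mask]))

    def test_mask_geometry_mismatch(self, small_scene):
        t = small_scene
        with pytest.raises(ValidationError):
            ss.invert_scene(t.observed[:6], t.config.geometry, t.lib,
                            t.bands.subset(6), mask=np.ones((3, 3), bool))


def test_deeper_water_degrades_albedo_recovery(bands6, lib, geom):
    """Abundance error grows with depth (rank test over 2-m bins)."""
    fm = ss.ForwardModel(bands6, lib, geom)
    rng = np.random.default_rng(4)
    bin_errs = []
    for z_lo in (1, 3, 5, 7, 9, 11):
        errs = []
        for _ in range(6):
            ab = rng.dirichlet([1, 1, 1])
            z = z_lo + rng.uniform(0, 2)
            obs = fm.simulate(0.06, 0.03, 0.01, z, ab)
            noisy = np.abs(obs * (1 + 0.01 * rng.standard_normal(6)))
            sol = ss.invert_pixel(noisy, fm, z0=z)
            errs.append(np.abs(sol.ab - ab).mean())
        bin_errs.append(np.mean(errs))
    from scipy.stats import spearmanr
    rho = spearmanr(np.arange(len(bin_errs)), bin_errs).statistic
    assert rho > 0.5
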