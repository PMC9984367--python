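import numpy as np
import pytest

from grainmorph import fractal_texture as ft
from grainmorph.image_io import HeightField
from grainmorph.synthetic_data import (
    SyntheticTextureSpec,
    generate_anisotropic_field,
    generate_fbm_surface,
)


def brute_force_acf(z):
    """Circular autocorrelation by direct summation over all lags."""
    z = z - z.mean()
    rows, cols = z.shape
    out = np.zeros_like(z)
    for dy in range(rows):
        for dx in range(cols):
            out[dy, dx] = np.sum(z * np.roll(np.roll(z, -dy, 0), -dx, 1))
    return np.fft.fftshift(out / out[0, 0])


def brute_force_structure_function(z, max_lag):
    """Axis-aligned mean squared difference by explicit loops."""
    z = z - z.mean()
    out = []
    for lag in range(1, max_lag + 1):
        total, count = 0.0, 0
        for i in range(z.shape[0]):
            for j in range(z.shape[1] - lag):
                total += (z[i, j + lag] - z[i, j]) ** 2
                count += 1
        for i in range(z.shape[0] - lag):
            for j in range(z.shape[1]):
                total += (z[i + lag, j] - z[i, j]) ** 2
                count += 1
        out.append(total / count)
    return np.array(out)


class TestAutocorrelation:
    def test_matches_brute_force_on_small_fields(self, rng):
        for _ in range(3):
            z = rng.standard_normal((16, 18))
            acf = ft.autocorrelation(HeightField(z, 1.0))
            assert np.allclose(acf.R, brute_force_acf(z), atol=1e-10)

    def test_center_is_one_and_bounded(self, rng):
        acf = ft.autocorrelation(HeightField(rng.standard_normal((32, 32)), 1.0))
        assert acf.R[acf.center] == pytest.approx(1.0)
        assert np.all(np.abs(acf.R) <= 1 + 1e-9)

    def test_white_noise_decorrelates_immediately(self):
        n = 64
        vals = []
        for seed in range(5):
            z = np.random.default_rng(seed).standard_normal((n, n))
            acf = ft.autocorrelation(HeightField(z, 1.0))
            cy, cx = acf.center
            vals.extend([acf.R[cy, cx + 5], acf.R[cy + 7, cx]])
        assert np.mean(np.abs(vals)) < 3 / n  # 3/sqrt(N) sampling bound

    def test_invariant_to_constant_offset(self, rng):
        z = rng.standard_normal((24, 24))
        a = ft.autocorrelation(HeightField(z, 1.0))
        b = ft.autocorrelation(HeightField(z + 42.0, 1.0))
        assert np.allclose(a.R, b.R, atol=1e-12)

    def test_constant_field_rejected(self):
        with pytest.raises(ValueError):
            ft.autocorrelation(HeightField(np.ones((8, 8)), 1.0))

    def test_prescribed_decay_lengths_recovered(self):
        """Separable squared-exponential covariance: R hits 0.2 at
        2·l·sqrt(ln 5) pixels along each axis."""
        lengths = (6.0, 14.0)
        errs = []
        for seed in range(3):
            f = generate_anisotropic_field(SyntheticTextureSpec(
                size_px=512, anisotropy_lengths=lengths, seed=seed,
                pixel_scale=1.0))
            _, axes = ft.anisotropy_ratio(ft.autocorrelation(f))
            expected_slow = 2 * max(lengths) * np.sqrt(np.log(5))
            expected_fast = 2 * min(lengths) * np.sqrt(np.log(5))
            errs.append(abs(axes["slow_length"] - expected_slow) / expected_slow)
            errs.append(abs(axes["fast_length"] - expected_fast) / expected_fast)
        assert np.mean(errs) < 0.15


class TestAnisotropyRatio:
    def test_isotropic_field_near_one(self):
        vals = [
            ft.anisotropy_ratio(ft.autocorrelation(generate_anisotropic_field(
                SyntheticTextureSpec(size_px=256, anisotropy_lengths=(3, 3),
                                     seed=s))))[0]
            for s in range(5)
        ]
        assert np.mean(vals) >= 0.9
        assert all(0 < v <= 1 for v in vals)

    def test_one_to_four_ratio_recovered(self):
        vals = [
            ft.anisotropy_ratio(ft.autocorrelation(generate_anisotropic_field(
                SyntheticTextureSpec(size_px=256, anisotropy_lengths=(4, 16),
                                     seed=s))))[0]
            for s in range(5)
        ]
        assert np.mean(vals) == pytest.approx(0.25, abs=0.1)

    def test_rotation_by_90_degrees_preserves_ratio(self):
        f = generate_anisotropic_field(SyntheticTextureSpec(
            size_px=256, anisotropy_lengths=(4, 16), seed=3))
        s1, _ = ft.anisotropy_ratio(ft.autocorrelation(f))
        f90 = HeightField(np.rot90(f.values).copy(), f.pixel_scale)
        s2, _ = ft.anisotropy_ratio(ft.autocorrelation(f90))
        assert s2 == pytest.approx(s1, rel=0.02)

    def test_insufficient_extent_raises(self):
        # long-range correlated field on a tiny map never reaches 0.2
        f = generate_anisotropic_field(SyntheticTextureSpec(
            size_px=64, anisotropy_lengths=(40, 40), seed=0))
        with pytest.raises(ft.InsufficientExtentError):
            ft.anisotropy_ratio(ft.autocorrelation(f))


class TestStructureFunction:
    def test_linear_ramp_square_field(self):
        n = 32
        z = np.tile(np.arange(n, dtype=float), (n, 1))
        sf = ft.structure_function(HeightField(z, 1.0))
        # x-offsets contribute tau^2 exactly, y-offsets 0; equal pair counts
        assert np.allclose(sf.S_tau, sf.tau**2 / 2)

    def test_white_noise_plateaus_at_twice_variance(self):
        z = np.random.default_rng(0).standard_normal((128, 128)) * 3.0
        sf = ft.structure_function(HeightField(z, 1.0))
        assert np.allclose(sf.S_tau, 2 * 9.0, rtol=0.1)
        tau_c, converged = ft.scale_length(sf)
        assert converged and tau_c <= 4.0  # plateau within a few pixels

    def test_matches_brute_force_on_small_fields(self, rng):
        z = rng.standard_normal((20, 24))
        sf = ft.structure_function(HeightField(z, 1.0))
        brute = brute_force_structure_function(z, len(sf.tau))
        assert np.allclose(sf.S_tau, brute, atol=1e-12)

    def test_non_negative_and_increasing_lags(self, rng):
        sf = ft.structure_function(HeightField(rng.standard_normal((64, 64)), 0.3))
        assert np.all(sf.S_tau >= 0)
        assert np.all(np.diff(sf.tau) > 0)

    def test_height_scaling_moves_s_and_k_not_d(self):
        f = generate_fbm_surface(SyntheticTextureSpec(size_px=256, hurst=0.5,
                                                      seed=1))
        sf1 = ft.structure_function(f)
        sf2 = ft.structure_function(HeightField(3.0 * f.values, f.pixel_scale))
        assert np.allclose(sf2.S_tau, 9.0 * sf1.S_tau, rtol=1e-10)
        fit1, fit2 = ft.fit_fractal(sf1), ft.fit_fractal(sf2)
        assert fit2.D == pytest.approx(fit1.D, abs=1e-9)
        assert fit2.K == pytest.approx(9.0 * fit1.K, rel=1e-6)


class TestFitFractal:
    def test_pure_power_law_recovered_exactly(self):
        tau = np.arange(1.0, 33.0)
        sf = ft.StructureFunction(tau=tau, S_tau=4.0 * tau**1.0, Sq=1e6)
        fit = ft.fit_fractal(sf)
        assert fit.alpha == pytest.approx(1.0, abs=1e-12)
        assert fit.D == pytest.approx(2.5, abs=1e-12)
        assert fit.K == pytest.approx(4.0, rel=1e-12)
        assert fit.accepted and fit.r_squared == pytest.approx(1.0)

    def test_hard_cultivar_regime_anchor(self):
        """H = 0.41 fields sit in the hard-endosperm regime D ≈ 2.59."""
        ds = [
            ft.fit_fractal(ft.structure_function(generate_fbm_surface(
                SyntheticTextureSpec(size_px=512, hurst=0.41, seed=s)))).D
            for s in range(3)
        ]
        assert np.mean(ds) == pytest.approx(2.59, abs=0.1)

    def test_too_few_lags_rejected(self):
        tau = np.arange(1.0, 5.0)
        sf = ft.StructureFunction(tau=tau, S_tau=tau, Sq=1e6)
        with pytest.raises(ValueError, match="lags"):
            ft.fit_fractal(sf)


class TestScaleLength:
    def test_joint_scaling_leaves_tau_c_unchanged(self):
        tau = np.arange(1.0, 65.0)
        s = 1 - np.exp(-tau / 10)
        sf1 = ft.StructureFunction(tau=tau, S_tau=s, Sq=np.sqrt(0.45))
        sf2 = ft.StructureFunction(tau=tau, S_tau=4 * s, Sq=np.sqrt(4 * 0.45))
        assert ft.scale_length(sf1)[0] == pytest.approx(ft.scale_length(sf2)[0])

    def test_smoother_fields_have_larger_corner_lag(self):
        for seed in range(3):
            taus = []
            for h in (0.3, 0.7):
                sf = ft.structure_function(generate_fbm_surface(
                    SyntheticTextureSpec(size_px=512, hurst=h, seed=seed)),
                    max_lag_fraction=0.5)
                tau_c, converged = ft.scale_length(sf)
                assert converged
                taus.append(tau_c)
            assert taus[1] > taus[0]

    def test_unreached_plateau_flagged(self):
        tau = np.arange(1.0, 33.0)
        sf = ft.StructureFunction(tau=tau, S_tau=tau * 1e-6, Sq=1.0)
        tau_c, converged = ft.scale_length(sf)
        assert not converged and tau_c == tau[-1]


class TestMonofractalCheck:
    def test_pure_power_law_is_monofractal(self):
        tau = np.arange(1.0, 33.0)
        sf = ft.StructureFunction(tau=tau, S_tau=2 * tau**1.2, Sq=1e6)
        fit = ft.fit_fractal(sf)
        ok, resid = ft.monofractal_check(sf, fit)
        assert ok and resid == pytest.approx(0.0, abs=1e-12)

    def test_two_regime_mixture_is_not_monofractal(self):
        tau = np.arange(1.0, 129.0)
        sf = ft.StructureFunction(
            tau=tau, S_tau=0.05 * tau**1.6 + tau**0.4, Sq=1e6
        )
        fit = ft.fit_fractal(sf)
        ok, _ = ft.monofractal_check(sf, fit)
        assert not ok

    def test_self_affine_fields_are_monofractal(self):
        for seed in range(3):
            sf = ft.structure_function(generate_fbm_surface(
                SyntheticTextureSpec(size_px=512, hurst=0.5, seed=seed)))
            fit = ft.fit_fractal(sf)
            ok, _ = ft.monofractal_check(sf, fit)
            assert ok


class TestAnalyzeTexture:
    def test_full_summary_on_synthetic_field(self):
        f = generate_anisotropic_field(SyntheticTextureSpec(
            size_px=256, anisotropy_lengths=(6, 6), seed=2))
        metrics = ft.analyze_texture(f)
        assert 0 < metrics.Str <= 1
        assert metrics.tau_c > 0
        assert metrics.Sq == pytest.approx(1.0, rel=1e-6)
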