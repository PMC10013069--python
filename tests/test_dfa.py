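"""DFA engine: profile, fluctuation function, two-regime fits."""

import numpy as np
import pytest

from physiofluct import dfa
from physiofluct.synth import gen_scaling_noise


class TestProfile:
    def test_constant_input_gives_zero_profile(self):
        assert np.allclose(dfa.profile(np.full(16, 3.2)), 0.0)

    def test_alternating_series(self):
        assert np.allclose(dfa.profile(np.array([1.0, -1, 1, -1])),
                           [1, 0, 1, 0])

    def test_final_value_is_zero(self, rng):
        x = rng.normal(size=501)
        assert abs(dfa.profile(x)[-1]) < 1e-9 * np.abs(x).sum()

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dfa.profile(np.ones(3))


class TestDfaFluct:
    def test_quadratic_profile_in_detrending_nullspace(self):
        # a linear ramp integrates to a quadratic profile, removed exactly
        # by order-2 detrending
        x = np.linspace(0, 5, 512)
        F = dfa.dfa_fluct(x, scales=[8, 16, 32], order=2)
        assert np.all(F.F < 1e-8)

    def test_matches_naive_reference(self, rng, naive_dfa_fn):
        for _ in range(20):
            n = int(rng.integers(64, 257))
            x = rng.normal(size=n)
            scales = [8, 16, n // 4]
            F = dfa.dfa_fluct(x, scales=scales, order=2)
            ref = naive_dfa_fn(x, F.scales.tolist(), order=2)
            np.testing.assert_allclose(F.F, ref, rtol=1e-10)

    def test_scale_invariance(self, rng):
        x = rng.normal(size=1024)
        F1 = dfa.dfa_fluct(x)
        F2 = dfa.dfa_fluct(3.7 * x)
        np.testing.assert_allclose(F2.F, 3.7 * F1.F, rtol=1e-10)
        a1 = dfa.fit_exponent(F1, 8, 64).alpha
        a2 = dfa.fit_exponent(F2, 8, 64).alpha
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_polynomial_trend_in_input_leaves_F_unchanged(self, rng):
        x = rng.normal(size=2048)
        t = np.linspace(0, 1, x.size)
        trend = 5.0 + 3.0 * t  # degree <= order-1 on the input
        F0 = dfa.dfa_fluct(x, scales=[8, 32, 128])
        F1 = dfa.dfa_fluct(x + trend, scales=[8, 32, 128])
        np.testing.assert_allclose(F1.F, F0.F, rtol=1e-7)

    def test_unusable_scales_dropped_and_error_when_none(self, rng):
        x = rng.normal(size=64)
        F = dfa.dfa_fluct(x, scales=[2, 8, 500])  # 2 < order+2, 500 > n
        assert F.scales.tolist() == [8]
        with pytest.raises(ValueError):
            dfa.dfa_fluct(x, scales=[500])


class TestFitExponent:
    def test_exact_power_law(self):
        s = np.array([8, 16, 32, 64, 128])
        F = dfa.FluctuationFunction(s, 0.3 * s**0.8)
        fit = dfa.fit_exponent(F, 8, 128)
        assert fit.alpha == pytest.approx(0.8, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.accepted

    def test_flat_F_gets_zero_r2_and_fails_gate(self):
        s = np.array([8, 16, 32])
        F = dfa.FluctuationFunction(s, np.full(3, 2.0))
        fit = dfa.fit_exponent(F, 8, 32)
        assert fit.alpha == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == 0.0
        assert not fit.accepted

    def test_jittered_power_law_recovered(self, rng):
        s = np.unique(np.round(np.geomspace(6, 200, 20)).astype(int))
        alphas = []
        for _ in range(20):
            noise = 1.0 + 0.05 * rng.uniform(-1, 1, s.size)
            F = dfa.FluctuationFunction(s, 0.2 * s**0.9 * noise)
            alphas.append(dfa.fit_exponent(F, 6, 200).alpha)
        assert np.mean(alphas) == pytest.approx(0.9, abs=0.05)

    def test_too_few_points_flagged_invalid(self):
        F = dfa.FluctuationFunction(np.array([8, 100]), np.array([1.0, 2.0]))
        fit = dfa.fit_exponent(F, 6, 16)
        assert not fit.valid and not fit.accepted

    def test_scaling_relation_accessors(self):
        fit = dfa.ScalingFit(0.8, 6, 16, 0.99, regime="short")
        assert fit.beta == pytest.approx(2 * 0.8 - 1)
        assert fit.gamma == pytest.approx(2 * (1 - 0.8))


class TestStageFluct:
    def test_single_fragment_identical_to_own_F(self, rng):
        x = rng.normal(size=600)
        scales = np.array([8, 16, 32, 64])
        F_own = dfa.dfa_fluct(x, scales)
        F_st = dfa.stage_fluct([x], [300.0], scales)
        np.testing.assert_allclose(F_st.F, F_own.F, rtol=1e-12)

    def test_two_identical_fragments_any_weights(self, rng):
        x = rng.normal(size=400)
        scales = np.array([8, 32])
        F1 = dfa.stage_fluct([x], [60.0], scales)
        F2 = dfa.stage_fluct([x, x], [30.0, 90.0], scales)
        np.testing.assert_allclose(F2.F, F1.F, rtol=1e-12)

    def test_duration_weighted_combination_arithmetic(self, monkeypatch):
        # F^2 = 1 with weight 30 and F^2 = 4 with weight 90 must combine to
        # sqrt((1*30 + 4*90)/120)
        frags = [np.zeros(40), np.zeros(40)]
        fake = iter([
            dfa.FluctuationFunction(np.array([8]), np.array([1.0])),
            dfa.FluctuationFunction(np.array([8]), np.array([2.0])),
        ])
        monkeypatch.setattr(dfa, "dfa_fluct",
                            lambda *a, **k: next(fake))
        F = dfa.stage_fluct(frags, [30.0, 90.0], np.array([8]))
        assert F.F[0] == pytest.approx(np.sqrt((1 * 30 + 4 * 90) / 120.0))

    def test_short_fragments_excluded_per_scale(self, rng):
        long_frag = rng.normal(size=300)
        short_frag = rng.normal(size=20)  # enters s=8 but not s=64
        scales = np.array([8, 64])
        F = dfa.stage_fluct([long_frag, short_frag], [100.0, 100.0], scales)
        F_long = dfa.dfa_fluct(long_frag, np.array([64]))
        idx = np.where(F.scales == 64)[0][0]
        assert F.F[idx] == pytest.approx(F_long.F[0], rel=1e-12)

    def test_no_usable_fragment_gives_empty_function(self):
        F = dfa.stage_fluct([np.zeros(4)], [30.0], np.array([8, 16]))
        assert F.scales.size == 0


class TestAlpha12:
    def test_recovers_single_regime_noise(self):
        x = gen_scaling_noise(alpha=0.7, n=2**14, seed=5)
        F = dfa.dfa_fluct(x, np.unique(np.round(
            np.geomspace(4, 220, 26)).astype(int)))
        f1, f2 = dfa.alpha12(F, "RRI")
        assert f1.alpha == pytest.approx(0.7, abs=0.1)
        assert f2.alpha == pytest.approx(0.7, abs=0.1)

    def test_bbi_uses_breath_windows(self):
        s = np.unique(np.round(np.geomspace(4, 80, 18)).astype(int))
        F = dfa.FluctuationFunction(s, 0.1 * s**0.6)
        f1, f2 = dfa.alpha12(F, "BBI")
        assert (f1.s_lo, f1.s_hi) == (4, 16)
        assert (f2.s_lo, f2.s_hi) == (12, 50)

    def test_unknown_kind_rejected(self):
        F = dfa.FluctuationFunction(np.array([8, 16, 32]), np.ones(3))
        with pytest.raises(ValueError):
            dfa.alpha12(F, "XYZ")

    def test_missing_regime_coverage_flagged(self):
        s = np.array([6, 8, 10, 12, 16])  # no long-regime scales
        F = dfa.FluctuationFunction(s, 0.1 * s**0.8)
        f1, f2 = dfa.alpha12(F, "RRI")
        assert f1.valid and not f2.valid
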