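import numpy as np
import pytest

from eegsel.nonlinear import (NonlinearParams, hjorth, hurst_exponent,
                              lempel_ziv_complexity, lyapunov_exponent,
                              lz76_phrase_count, phase_amplitude_coupling,
                              shannon_entropy)
from eegsel.spectral import DegenerateSignalError
from eegsel.synthetic import fractional_gaussian_noise

FS = 250.0


def pac_signal(depth, rng, seconds=5.0, fs=FS, f_low=6.0, f_high=24.0):
    """Theta-phase-modulated high-beta carrier plus the theta component."""
    t = np.arange(int(seconds * fs)) / fs
    phase = 2 * np.pi * f_low * t + rng.uniform(0, 2 * np.pi)
    envelope = (1 + depth * np.cos(phase)) / 2
    carrier = 3 * envelope * np.sin(2 * np.pi * f_high * t + rng.uniform(0, 2 * np.pi))
    return 3 * np.sin(phase) + carrier + rng.standard_normal(t.size)


class TestPAC:
    THETA, BETA_H = (4.0, 8.0), (18.0, 30.0)

    def test_bounded(self, rng):
        v = phase_amplitude_coupling(rng.standard_normal(1250), FS,
                                     self.THETA, self.BETA_H)
        assert 0.0 <= v <= 1.0

    def test_modulated_exceeds_unmodulated(self):
        mod, unmod = [], []
        for s in range(30):
            rng = np.random.default_rng(s)
            mod.append(phase_amplitude_coupling(
                pac_signal(1.0, rng), FS, self.THETA, self.BETA_H))
            rng = np.random.default_rng(1000 + s)
            unmod.append(phase_amplitude_coupling(
                pac_signal(0.0, rng), FS, self.THETA, self.BETA_H))
        assert np.mean(mod) > np.mean(unmod) + 0.3

    def test_white_noise_near_floor(self):
        vals = [phase_amplitude_coupling(
            np.random.default_rng(s).standard_normal(1250), FS,
            self.THETA, self.BETA_H) for s in range(20)]
        assert np.mean(vals) < 0.25

    def test_constant_errors(self):
        with pytest.raises(DegenerateSignalError):
            phase_amplitude_coupling(np.ones(1250), FS, self.THETA, self.BETA_H)

    def test_monotone_in_depth(self):
        from scipy.stats import spearmanr
        depths = [0.0, 0.25, 0.5, 0.75, 1.0]
        means = []
        for d in depths:
            vals = [phase_amplitude_coupling(
                pac_signal(d, np.random.default_rng(200 + 17 * s)), FS,
                self.THETA, self.BETA_H) for s in range(20)]
            means.append(np.mean(vals))
        rho, _ = spearmanr(depths, means)
        assert rho > 0.9


class TestShannonEntropy:
    def test_constant_zero(self):
        assert shannon_entropy(np.full(100, 3.0)) == 0.0

    def test_uniform_bins_max_entropy(self):
        x = np.repeat(np.arange(64, dtype=float), 10)
        assert shannon_entropy(x, bins=64) == pytest.approx(np.log(64), rel=1e-9)

    def test_uniform_beats_gaussian(self, rng):
        n = 5000
        u = rng.uniform(-3, 3, n)
        g = np.clip(rng.standard_normal(n), -3, 3)
        assert shannon_entropy(u, 64) > shannon_entropy(g, 64)

    def test_bounds(self, rng):
        v = shannon_entropy(rng.standard_normal(500), bins=32)
        assert 0.0 <= v <= np.log(32)


class TestHjorth:
    def test_alternating_activity(self):
        x = np.tile([1.0, -1.0], 50)
        activity, _, _ = hjorth(x)
        assert activity == pytest.approx(1.0)

    def test_activity_is_variance(self, rng):
        x = rng.standard_normal(1000)
        activity, _, _ = hjorth(x)
        assert activity == pytest.approx(x.var(), rel=1e-12)

    def test_sinusoid_mobility(self):
        f, fs = 10.0, 250.0
        x = np.sin(2 * np.pi * f * np.arange(5000) / fs)
        _, mobility, complexity = hjorth(x)
        assert mobility == pytest.approx(2 * np.sin(np.pi * f / fs), rel=1e-3)
        assert complexity == pytest.approx(1.0, rel=1e-3)

    def test_constant_errors(self):
        with pytest.raises(DegenerateSignalError):
            hjorth(np.ones(100))

    def test_scale_invariance_except_activity(self, rng):
        x = rng.standard_normal(1000)
        a1, m1, c1 = hjorth(x)
        a2, m2, c2 = hjorth(7.0 * x)
        assert a2 == pytest.approx(49.0 * a1, rel=1e-12)
        assert m2 == pytest.approx(m1, rel=1e-12)
        assert c2 == pytest.approx(c1, rel=1e-12)


class TestLyapunov:
    def test_logistic_map(self):
        x = np.empty(5000)
        x[0] = 0.3
        for i in range(4999):
            x[i + 1] = 4 * x[i] * (1 - x[i])
        lam = lyapunov_exponent(x, fs=1.0, embed_dim=5, fit_steps=4)
        assert lam == pytest.approx(np.log(2), abs=0.05)

    def test_sinusoid_near_zero(self):
        x = np.sin(2 * np.pi * 10 * np.arange(2500) / 250.0)
        lam = lyapunov_exponent(x, fs=250.0)
        # chaotic signals at this sampling rate produce |lambda| of tens 1/s
        assert abs(lam) < 1.0

    def test_constant_errors(self):
        with pytest.raises(DegenerateSignalError):
            lyapunov_exponent(np.ones(1000))


class TestHurst:
    def test_white_noise(self):
        ests = [hurst_exponent(np.random.default_rng(s).standard_normal(4096))
                for s in range(20)]
        assert np.mean(ests) == pytest.approx(0.5, abs=0.08)

    def test_fgn_08(self):
        ests = [hurst_exponent(fractional_gaussian_noise(
            4096, 0.8, np.random.default_rng(s))) for s in range(20)]
        assert np.mean(ests) == pytest.approx(0.8, abs=0.08)

    def test_constant_errors(self):
        with pytest.raises(DegenerateSignalError):
            hurst_exponent(np.ones(1024))

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(2048)
        assert hurst_exponent(x) == pytest.approx(hurst_exponent(5 * x), rel=1e-9)


class TestLempelZiv:
    def test_constant_sequence_parsing(self):
        # hand parse of 0^64: phrases '0' then the rest -> c = 2
        assert lz76_phrase_count(np.zeros(64, dtype=np.uint8)) == 2
        v = lempel_ziv_complexity(np.zeros(64) + 5.0)
        assert v == pytest.approx(2 * np.log2(64) / 64)

    def test_alternating_exceeds_constant(self):
        alt = np.tile([0.0, 1.0], 32)
        # hand parse of (01)^32: '0', '1', '01...1' -> c = 3
        assert lz76_phrase_count((alt > 0.5).astype(np.uint8)) == 3
        assert lempel_ziv_complexity(alt) > lempel_ziv_complexity(np.zeros(64) + 1)

    def test_random_bits_near_one(self, rng):
        x = rng.standard_normal(4096)
        assert lempel_ziv_complexity(x) == pytest.approx(1.0, abs=0.15)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(512)
        assert lempel_ziv_complexity(x) == lempel_ziv_complexity(3.0 * x)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            lempel_ziv_complexity(np.arange(8.0))


class TestScaleInvarianceSuite:
    """PAC, SE, HE, KC, mobility, complexity invariant under x -> a*x."""

    def test_all_invariant(self, rng):
        x = rng.standard_normal(1250) + np.sin(2 * np.pi * 10 * np.arange(1250) / FS)
        a = 4.2
        assert phase_amplitude_coupling(x, FS, (4, 8), (18, 30)) == pytest.approx(
            phase_amplitude_coupling(a * x, FS, (4, 8), (18, 30)), rel=1e-9)
        assert shannon_entropy(x) == pytest.approx(shannon_entropy(a * x), rel=1e-9)
        assert hurst_exponent(x) == pytest.approx(hurst_exponent(a * x), rel=1e-9)
        assert lempel_ziv_complexity(x) == lempel_ziv_complexity(a * x)


class TestParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            NonlinearParams(entropy_bins=1)
        with pytest.raises(ValueError):
            NonlinearParams(lyap_embed_dim=1)
        with pytest.raises(ValueError):
            NonlinearParams(lz_binarize="quantile")
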