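import numpy as np
import pytest

from oracles import apen_bruteforce
from swaylab import (
    ApEnSpec,
    COPTrajectory,
    ConfidenceEllipse,
    PsdEstimate,
    ValidationError,
    approximate_entropy,
    confidence_ellipse,
    fractal_dimension,
    mean_power_frequency,
    multitaper_psd,
    structure_set,
    sway_path_2d,
)


class TestApproximateEntropy:
    def test_periodic_motif_with_period_equal_to_lag_is_regular(self, rng):
        motif = rng.standard_normal(10)
        x = np.tile(motif, 1000)  # 10,000 samples, period == lag
        assert approximate_entropy(x, ApEnSpec(lag=10)) <= 0.02

    def test_noise_more_irregular_than_slow_sine(self, rng):
        t = np.arange(10_000) / 200.0
        sine = np.sin(2 * np.pi * 0.3 * t)
        noise = rng.standard_normal(10_000)
        assert approximate_entropy(noise) > approximate_entropy(sine)

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(2000)
        a = approximate_entropy(x)
        b = approximate_entropy(3.5 * x - 12.0)
        assert b == pytest.approx(a, abs=1e-9)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(5):
            x = rng.standard_normal(500)
            got = approximate_entropy(x)
            want = apen_bruteforce(x)
            assert got == pytest.approx(want, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            approximate_entropy(np.ones(1000))

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            approximate_entropy(np.arange(30), ApEnSpec(m=2, lag=10))


def _ellipse(a, b):
    return ConfidenceEllipse(a=a, b=b, theta=0.0, area=np.pi * a * b)


class TestFractalDimension:
    def test_line_limit_is_one(self):
        # planar extent equal to the path length: d = 2*sqrt(a*b) = sp
        sp = 8.0
        assert fractal_dimension(1000, _ellipse(sp / 2, sp / 2), sp) == pytest.approx(1.0)

    def test_scale_invariance(self, rng):
        ml, ap = rng.standard_normal((2, 2000))
        for c in (1.0, 2.0):
            t = COPTrajectory(ml=ml * c, ap=ap * c, fs=200.0)
            e = confidence_ellipse(t)
            fd = fractal_dimension(len(t), e, sway_path_2d(t))
            if c == 1.0:
                ref = fd
        assert fd == pytest.approx(ref, rel=1e-12)

    def test_matches_formula_transcription(self, rng):
        t = COPTrajectory(ml=rng.standard_normal(10_000),
                          ap=rng.standard_normal(10_000), fs=200.0)
        e = confidence_ellipse(t)
        sp = sway_path_2d(t)
        d = 2.0 * np.sqrt(e.a * e.b)
        with pytest.warns(RuntimeWarning):
            # raw white noise is rougher than physiological sway: FD > 2
            got = fractal_dimension(10_000, e, sp)
        assert got == pytest.approx(np.log(10_000) / np.log(10_000 * d / sp),
                                    abs=1e-12)

    def test_full_axes_convention_doubles_extent(self):
        e = _ellipse(2.0, 1.0)
        semi = fractal_dimension(100, e, 50.0, d_convention="semi_axes")
        full = fractal_dimension(100, e, 50.0, d_convention="full_axes")
        assert full < semi  # larger d -> larger log denominator -> smaller FD


class TestMultitaperPsd:
    def test_sine_power_concentrated_at_its_frequency(self):
        fs, dur, f0, nw = 200.0, 50.0, 0.5, 3.0
        t = np.arange(int(fs * dur)) / fs
        psd = multitaper_psd(np.sin(2 * np.pi * f0 * t), fs, nw=nw)
        half_bw = nw / dur
        near = np.abs(psd.freqs - f0) <= half_bw + 0.0125
        assert psd.power[near].sum() / psd.power.sum() >= 0.95

    def test_white_noise_band_roughly_flat(self, rng):
        acc = None
        for _ in range(10):
            psd = multitaper_psd(rng.standard_normal(10_000), 200.0)
            acc = psd.power if acc is None else acc + psd.power
        assert acc.max() / acc.min() < 10.0

    def test_default_grid_excludes_first_bin_past_dc(self, rng):
        psd = multitaper_psd(rng.standard_normal(10_000), 200.0)
        assert psd.freqs[0] == pytest.approx(0.05)
        assert psd.freqs[-1] == pytest.approx(1.5)
        included = multitaper_psd(rng.standard_normal(10_000), 200.0,
                                  include_first_bin=True)
        assert included.freqs[0] == pytest.approx(0.025)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValidationError):
            multitaper_psd(np.zeros(10_000), 200.0)


class TestMeanPowerFrequency:
    def test_point_mass(self):
        psd = PsdEstimate(freqs=[0.3, 0.5, 0.7], power=[0.0, 2.0, 0.0],
                          band=(0.3, 0.7))
        assert mean_power_frequency(psd) == pytest.approx(0.5)

    def test_equal_masses_average(self):
        psd = PsdEstimate(freqs=[0.2, 0.3, 0.4], power=[1.0, 0.0, 1.0],
                          band=(0.2, 0.4))
        assert mean_power_frequency(psd) == pytest.approx(0.3)

    def test_bounded_by_band(self, rng):
        p = rng.random(59)
        f = 0.05 + 0.025 * np.arange(59)
        mpf = mean_power_frequency(PsdEstimate(freqs=f, power=p, band=(f[0], f[-1])))
        assert f[0] <= mpf <= f[-1]

    def test_shifting_mass_upward_increases_mpf(self):
        f = [0.2, 0.4, 0.6]
        low = mean_power_frequency(PsdEstimate(freqs=f, power=[2, 1, 0], band=(0.2, 0.6)))
        high = mean_power_frequency(PsdEstimate(freqs=f, power=[0, 1, 2], band=(0.2, 0.6)))
        assert high > low


class TestStructureSet:
    def test_components_match_standalone_calls(self, rng):
        import warnings

        ml = np.cumsum(rng.standard_normal(2000)) * 0.01 + rng.standard_normal(2000)
        ap = np.cumsum(rng.standard_normal(2000)) * 0.01 + rng.standard_normal(2000)
        t = COPTrajectory(ml=ml, ap=ap, fs=40.0)
        spec = ApEnSpec()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            bundle = structure_set(t, t, apen_spec=spec)
            e = confidence_ellipse(t)
            fd = fractal_dimension(len(t), e, sway_path_2d(t))
        assert bundle.apen_ap == pytest.approx(approximate_entropy(t.ap, spec))
        assert bundle.apen_ml == pytest.approx(approximate_entropy(t.ml, spec))
        assert bundle.fd == pytest.approx(fd)
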