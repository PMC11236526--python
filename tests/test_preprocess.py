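"""Signal conditioning: dilation, regional means, de-noising, derivatives,
resampling, and bulk alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cvrflow as cf
from cvrflow.containers import BoldSeries, MaskVolume
from cvrflow.errors import EmptyRegionError, UndefinedCorrelationError

from conftest import brute_force_best_lag


def single_label_masks(shape=(7, 7, 7)):
    z = np.zeros(shape, dtype=bool)
    brain = np.ones(shape, dtype=bool)
    return MaskVolume(brain=brain, gm=z.copy(), wm=z.copy(), csf=z.copy(),
                      edema=z.copy())


class TestDilateMask:
    def test_single_voxel_six_connectivity_gives_cross(self):
        masks = single_label_masks()
        edema = np.zeros((7, 7, 7), dtype=bool)
        edema[3, 3, 3] = True
        masks = masks.with_label("edema", edema)
        out = cf.dilate_mask(masks, "edema", 1)
        assert out.edema.sum() == 7  # voxel + 6 faces

    def test_zero_iterations_is_identity(self):
        masks = single_label_masks()
        edema = np.zeros((7, 7, 7), dtype=bool)
        edema[2:4, 2:4, 2] = True
        masks = masks.with_label("edema", edema)
        out = cf.dilate_mask(masks, "edema", 0)
        assert np.array_equal(out.edema, edema)

    def test_empty_mask_stays_empty(self):
        masks = single_label_masks()
        out = cf.dilate_mask(masks, "edema", 3)
        assert not out.edema.any()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            cf.dilate_mask(single_label_masks(), "tumour", 1)


class TestExtractRegionalMean:
    def make_bold(self, data):
        return BoldSeries(data=data, tr=1.0)

    def test_uniform_region_gives_constant(self):
        shape = (4, 4, 2)
        data = np.zeros(shape + (5,))
        gm = np.zeros(shape, dtype=bool)
        gm[1:3, 1:3, 0] = True
        data[gm] = 7.5
        masks = single_label_masks(shape).with_label("gm", gm)
        trace = cf.extract_regional_mean(self.make_bold(data), masks, "gm")
        assert np.allclose(trace, 7.5)

    def test_two_voxel_arithmetic_mean(self):
        shape = (2, 1, 1)
        data = np.zeros(shape + (2,))
        data[0, 0, 0] = [1.0, 3.0]
        data[1, 0, 0] = [3.0, 5.0]
        gm = np.ones(shape, dtype=bool)
        masks = single_label_masks(shape).with_label("gm", gm)
        trace = cf.extract_regional_mean(self.make_bold(data), masks, "gm")
        assert np.allclose(trace, [2.0, 4.0])

    def test_fully_excluded_region_raises(self):
        shape = (3, 3, 3)
        gm = np.ones(shape, dtype=bool)
        masks = single_label_masks(shape).with_label("gm", gm)
        masks = masks.with_label("edema", gm.copy())
        bold = self.make_bold(np.zeros(shape + (4,)))
        with pytest.raises(EmptyRegionError):
            cf.extract_regional_mean(bold, masks, "gm", exclude="edema")


class TestDenoiseWavelet:
    def test_zero_input_zero_output(self):
        out = cf.denoise_wavelet(np.zeros(256))
        assert np.allclose(out, 0.0)

    def test_white_noise_variance_reduced(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            x = rng.normal(0.0, 1.0, 1024)
            y = cf.denoise_wavelet(x)
            assert np.var(y) < np.var(x)

    def test_length_preserved_odd_length(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=501)
        assert cf.denoise_wavelet(x).size == 501

    def test_near_idempotent(self):
        # a second pass may only touch coefficients near the noise floor
        rng = np.random.default_rng(1)
        x = np.sin(np.linspace(0, 20, 1000)) * 10 + rng.normal(0, 1, 1000)
        once = cf.denoise_wavelet(x)
        twice = cf.denoise_wavelet(once)
        lam = cf.universal_threshold(1.0, 1000)  # noise scale sigma ~ 1
        assert np.max(np.abs(twice - once)) < lam

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError):
            cf.denoise_wavelet(np.ones(3), level=2)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            cf.denoise_wavelet(np.ones(64), threshold_rule="sure")


class TestTemporalDerivative:
    def test_linear_trace_constant_slope(self):
        trace = 3.0 * np.arange(50)
        d = cf.temporal_derivative(trace, tr=1.05)
        assert np.allclose(d, 3.0 / 1.05)

    def test_constant_trace_zero(self):
        assert np.allclose(cf.temporal_derivative(np.full(20, 5.0), 2.0), 0.0)

    def test_sine_matches_analytic_derivative(self):
        f = 0.05  # Hz
        tr = 0.05
        t = np.arange(0, 40, tr)
        d = cf.temporal_derivative(np.sin(2 * np.pi * f * t), tr)
        analytic = 2 * np.pi * f * np.cos(2 * np.pi * f * t)
        assert np.max(np.abs(d[1:-1] - analytic[1:-1])) < 2 * np.pi * f * 1e-3


class TestResampleTrace:
    def test_identity_when_already_on_grid(self):
        tr = 1.05
        values = np.array([40.0, 42.0, 45.0, 41.0])
        trace = cf.PhysioTrace(times=np.arange(4) * tr, values=values)
        assert np.allclose(cf.resample_trace(trace, tr, 4), values)

    def test_linear_midpoint(self):
        trace = cf.PhysioTrace(times=np.array([0.0, 10.5]),
                               values=np.array([40.0, 50.0]))
        out = cf.resample_trace(trace, 1.05, 10)
        assert out[5] == pytest.approx(45.0)

    def test_edge_hold_beyond_support(self):
        trace = cf.PhysioTrace(times=np.array([0.0, 1.0]),
                               values=np.array([40.0, 44.0]))
        out = cf.resample_trace(trace, 1.0, 5)
        assert np.allclose(out[2:], 44.0)


class TestBulkAlign:
    def test_identical_signals_zero_lag(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=200)
        aligned, lag = cf.bulk_align(x, x.copy(), max_lag=20)
        assert lag == 0
        assert np.array_equal(aligned, x)

    def test_recovers_constructed_delay(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=300)
        bold = base
        co2 = np.roll(base, 7)  # co2 delayed by 7 volumes
        co2[:7] = base[0]
        aligned, lag = cf.bulk_align(bold, co2, max_lag=20)
        assert lag == 7
        assert np.allclose(aligned[: 300 - 7], bold[: 300 - 7])

    def test_constant_input_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            cf.bulk_align(np.ones(100), np.random.default_rng(0).normal(size=100),
                          max_lag=10)

    def test_sign_respected_for_anticorrelated_signals(self):
        # maximum of signed r, not |r|: oracle agreement on an anticorrelated pair
        rng = np.random.default_rng(2)
        x = rng.normal(size=250)
        y = -np.roll(x, 4) + 0.1 * rng.normal(size=250)
        _, lag = cf.bulk_align(x, y, max_lag=15)
        oracle_lag, _ = brute_force_best_lag(x, y, 15)
        assert lag == oracle_lag

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), delay=st.integers(-10, 10))
    def test_matches_brute_force_oracle(self, seed, delay):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=120)
        y = np.roll(x, delay) + 0.3 * rng.normal(size=120)
        _, lag = cf.bulk_align(x, y, max_lag=15)
        oracle_lag, _ = brute_force_best_lag(x, y, 15)
        assert lag == oracle_lag
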