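"""Inflow-voxel selection, skew-normal peak fitting, right-sided HWHM."""

import numpy as np
import pytest
from scipy.stats import skewnorm

import cvrflow as cf
from cvrflow.containers import BoldSeries
from cvrflow.errors import UndefinedWidthError
from cvrflow.inflow import InflowPeakFit


def dense_grid_hwhm_oracle(omega, alpha, n_points=100_000):
    """Right HWHM of the Azzalini skew-normal via a dense scipy.stats grid.

    Independent of the package's bisection path: peak from a parabolic
    refinement of the grid argmax, half-crossing by linear interpolation.
    """
    t = np.linspace(-6 * omega, 10 * omega, n_points)
    y = skewnorm.pdf(t, alpha, loc=0.0, scale=omega)
    i = int(np.argmax(y))
    # parabolic refinement of the peak position
    ym, y0, yp = y[i - 1], y[i], y[i + 1]
    dt = t[1] - t[0]
    t_peak = t[i] + 0.5 * dt * (ym - yp) / (ym - 2 * y0 + yp)
    y_peak = skewnorm.pdf(t_peak, alpha, loc=0.0, scale=omega)
    half = 0.5 * y_peak
    right = np.flatnonzero((t > t_peak) & (y <= half))[0]
    frac = (y[right - 1] - half) / (y[right - 1] - y[right])
    t_half = t[right - 1] + frac * dt
    return t_half - t_peak


class TestSkewNormalModel:
    def test_gaussian_peak_value(self):
        val = cf.skew_normal_model(10.0, amplitude=3.0, xi=10.0, omega=4.0,
                                   alpha=0.0, a=0.0, b=0.0)
        assert val == pytest.approx(3.0 / (4.0 * np.sqrt(2 * np.pi)))

    def test_symmetric_when_alpha_zero(self):
        t = np.linspace(-20, 20, 401)
        y = cf.skew_normal_model(5.0 + t, 2.0, 5.0, 3.0, 0.0, 0.0, 0.0)
        assert np.allclose(y, y[::-1], atol=1e-12)

    def test_zero_amplitude_is_pure_line(self):
        t = np.linspace(0, 10, 50)
        y = cf.skew_normal_model(t, 0.0, 5.0, 2.0, 1.0, 3.0, 0.5)
        assert np.allclose(y, 3.0 + 0.5 * t)

    def test_matches_scipy_skewnorm_density(self):
        t = np.linspace(-10, 30, 200)
        y = cf.skew_normal_model(t, 1.0, 5.0, 4.0, 3.0, 0.0, 0.0)
        assert np.allclose(y, skewnorm.pdf(t, 3.0, loc=5.0, scale=4.0),
                           atol=1e-12)

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(ValueError):
            cf.skew_normal_model(0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0)


class TestSelectInflowVoxels:
    def make_bold(self, data):
        return BoldSeries(data=data, tr=1.05, slice_axis=2)

    def test_peaked_voxel_ranks_first(self):
        rng = np.random.default_rng(0)
        data = rng.normal(0.0, 0.01, (4, 4, 3, 400))
        data[2, 1, 0, 180:220] += 10.0  # strong peak in bottom slice
        bold = self.make_bold(data)
        voxels, trace = cf.select_inflow_voxels(
            bold, n_bottom_slices=1, contrast_window=(100, 300), k_voxels=1,
            denoise=False,
        )
        assert voxels == [(2, 1, 0)]
        assert trace[200] > 5.0

    def test_average_of_both_slice_traces(self):
        data = np.zeros((3, 3, 2, 300))
        peak = np.exp(-0.5 * ((np.arange(300) - 150) / 10.0) ** 2)
        data[0, 0, 0] = 4.0 * peak
        data[1, 1, 1] = 8.0 * peak
        bold = self.make_bold(data)
        _, trace = cf.select_inflow_voxels(
            bold, n_bottom_slices=2, contrast_window=(50, 250), k_voxels=1,
            denoise=False,
        )
        assert np.allclose(trace, 6.0 * peak)

    def test_flat_data_deterministic_tie_break(self):
        data = np.zeros((3, 3, 2, 100))
        bold = self.make_bold(data)
        voxels_a, _ = cf.select_inflow_voxels(
            bold, contrast_window=(10, 90), k_voxels=2, denoise=False
        )
        voxels_b, _ = cf.select_inflow_voxels(
            bold, contrast_window=(10, 90), k_voxels=2, denoise=False
        )
        assert voxels_a == voxels_b
        assert voxels_a[0] == (0, 0, 0)  # index order on ties

    def test_regional_input_rejected(self):
        with pytest.raises(ValueError):
            cf.select_inflow_voxels(BoldSeries(data=np.ones(100), tr=1.0))

    def test_oversized_k_clipped_with_warning(self):
        data = np.random.default_rng(1).normal(size=(2, 2, 2, 64))
        with pytest.warns(UserWarning):
            voxels, _ = cf.select_inflow_voxels(
                self.make_bold(data), n_bottom_slices=1,
                contrast_window=(4, 60), k_voxels=10, denoise=False,
            )
        assert len(voxels) == 4


class TestFitInflowPeak:
    @pytest.mark.parametrize("alpha", [-2.0, 0.0, 2.0])
    @pytest.mark.parametrize("omega", [5.0, 15.0, 30.0])
    def test_noiseless_parameter_recovery(self, alpha, omega):
        tr = 1.05
        window = (250, 525)
        t = np.arange(600) * tr
        truth = dict(amplitude=200.0, xi=320.0, omega=omega, alpha=alpha,
                     a=100.0, b=0.02)
        y = cf.skew_normal_model(t, **truth)
        fit = cf.fit_inflow_peak(y, tr, window=window)
        assert fit.amplitude == pytest.approx(truth["amplitude"], rel=0.01)
        assert fit.xi == pytest.approx(truth["xi"], rel=0.01)
        assert fit.omega == pytest.approx(truth["omega"], rel=0.01)
        assert fit.alpha == pytest.approx(truth["alpha"], rel=0.01, abs=0.02)
        assert fit.a == pytest.approx(truth["a"], rel=0.01)
        assert fit.b == pytest.approx(truth["b"], rel=0.01, abs=1e-4)

    def test_pure_line_gives_negligible_amplitude(self):
        tr = 1.05
        t = np.arange(600) * tr
        y = 50.0 + 0.1 * t
        fit = cf.fit_inflow_peak(y, tr, window=(250, 525))
        peak_height = fit.amplitude / (fit.omega * np.sqrt(2 * np.pi))
        assert peak_height < 1e-3  # invisible against the line
        assert fit.a == pytest.approx(50.0, abs=0.1)
        assert fit.b == pytest.approx(0.1, abs=1e-3)

    def test_default_window_end_is_volume_525(self):
        assert cf.inflow.DEFAULT_INFLOW_WINDOW == (250, 525)

    def test_short_window_rejected(self):
        with pytest.raises(ValueError):
            cf.fit_inflow_peak(np.ones(600), 1.05, window=(10, 14))


class TestHwhmRight:
    def make_fit(self, amplitude=1.0, omega=10.0, alpha=0.0):
        return InflowPeakFit(amplitude=amplitude, xi=0.0, omega=omega,
                             alpha=alpha, a=0.0, b=0.0, hwhm_right=np.nan,
                             rss=0.0, window=(0, 1))

    @pytest.mark.parametrize("omega", [5.0, 15.0, 30.0])
    def test_gaussian_closed_form(self, omega):
        width = cf.hwhm_right(self.make_fit(omega=omega))
        assert width == pytest.approx(omega * np.sqrt(2 * np.log(2)), abs=1e-3)

    def test_skew_narrows_right_width_at_fixed_scale(self):
        # at fixed omega the Gaussian (alpha = 0) has the widest right side;
        # left skew narrows it more than the mirrored right skew
        gauss = cf.hwhm_right(self.make_fit(omega=10.0, alpha=0.0))
        right = cf.hwhm_right(self.make_fit(omega=10.0, alpha=3.0))
        left = cf.hwhm_right(self.make_fit(omega=10.0, alpha=-3.0))
        assert left < right < gauss

    def test_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            omega = float(rng.uniform(2.0, 40.0))
            alpha = float(rng.uniform(-5.0, 5.0))
            width = cf.hwhm_right(self.make_fit(omega=omega, alpha=alpha))
            oracle = dense_grid_hwhm_oracle(omega, alpha)
            assert width == pytest.approx(oracle, abs=1e-3)

    def test_scale_equivariance(self):
        w1 = cf.hwhm_right(self.make_fit(omega=8.0, alpha=1.5))
        w2 = cf.hwhm_right(self.make_fit(omega=16.0, alpha=1.5))
        assert w2 == pytest.approx(2.0 * w1, rel=1e-6)

    def test_baseline_never_enters_width(self):
        tr = 1.05
        t = np.arange(600) * tr
        base = cf.skew_normal_model(t, 150.0, 330.0, 12.0, 1.0, 0.0, 0.0)
        fit0 = cf.fit_inflow_peak(base, tr, window=(250, 525))
        fit1 = cf.fit_inflow_peak(base + 40.0 - 0.05 * t, tr, window=(250, 525))
        assert fit1.hwhm_right == pytest.approx(fit0.hwhm_right, abs=1e-3)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(UndefinedWidthError):
            cf.hwhm_right(self.make_fit(amplitude=0.0))
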