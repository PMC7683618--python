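"""Spectrum processing: ToF calibration, smoothing, linearization,
background-subtracted peak areas and the % ssDNA statistic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lilbid.spectra import (
    CalibratedSpectrum,
    RawTrace,
    SpectrumParams,
    calibrate_two_point,
    find_peak_bounds,
    integrate_peak,
    linearize,
    measure_percent_ssdna,
    mz_of,
    percent_ssdna,
    process_trace,
    smooth_moving_average,
)
from lilbid.synthetic import SyntheticConfig, calibration_points, synth_spectrum


def flat_spectrum(lo=1.0, hi=101.0, step=1.0, value=0.0):
    mz = np.arange(lo, hi + step / 2, step)
    return CalibratedSpectrum(mz=mz, intensity=np.full_like(mz, value), step=step)


class TestCalibration:
    def test_recovers_generating_law(self):
        t = np.linspace(5.0, 40.0, 36)
        trace = RawTrace(x=t, intensity=np.ones_like(t), abscissa="tof")
        out = calibrate_two_point(trace, (10.0, 100.0), (20.0, 400.0))
        # law a=1, t0=0: every time maps to t^2
        assert out.abscissa == "mz"
        np.testing.assert_allclose(out.x, t**2, rtol=1e-12)

    def test_equal_times_raise(self):
        t = np.linspace(5, 40, 10)
        trace = RawTrace(x=t, intensity=np.ones_like(t), abscissa="tof")
        with pytest.raises(ValueError):
            calibrate_two_point(trace, (10.0, 100.0), (10.0, 400.0))

    def test_inverted_points_imply_bad_constant(self):
        t = np.linspace(5, 40, 10)
        trace = RawTrace(x=t, intensity=np.ones_like(t), abscissa="tof")
        with pytest.raises(ValueError, match="a <= 0"):
            calibrate_two_point(trace, (10.0, 400.0), (20.0, 100.0))

    def test_apex_alignment_after_linearization(self):
        """Calibrating on the synthetic peak apexes puts each apex on the
        theoretical m/z within one grid step."""
        cfg = SyntheticConfig(noise_sd=0.0)
        trace = synth_spectrum(50.0, cfg, width=800.0, seed=0)
        cal1, cal2 = calibration_points(cfg)
        spec = linearize(smooth_moving_average(calibrate_two_point(trace, cal1, cal2)), 1.0)
        for mass in (cfg.ss_mass, cfg.ds_mass):
            target = mz_of(mass, 1)
            sel = np.abs(spec.mz - target) < 300
            apex = spec.mz[sel][np.argmax(spec.intensity[sel])]
            assert abs(apex - target) <= spec.step


class TestSmoothing:
    def test_constant_unchanged(self):
        x = np.arange(0.0, 101.0)
        tr = RawTrace(x=x, intensity=np.full_like(x, 3.3), abscissa="mz")
        np.testing.assert_allclose(smooth_moving_average(tr, 20.0).intensity, 3.3)

    def test_unit_impulse_becomes_boxcar(self):
        x = np.arange(0.0, 101.0)
        y = np.zeros_like(x)
        y[50] = 1.0
        out = smooth_moving_average(RawTrace(x=x, intensity=y, abscissa="mz"), 20.0)
        inside = np.abs(x - 50) <= 10
        np.testing.assert_allclose(out.intensity[inside], 1 / 21, atol=1e-12)
        np.testing.assert_allclose(out.intensity[~inside], 0.0, atol=1e-12)

    def test_interior_mass_conserved(self, rng):
        x = np.arange(0.0, 201.0)
        y = np.zeros_like(x)
        y[50:150] = rng.random(100)
        out = smooth_moving_average(RawTrace(x=x, intensity=y, abscissa="mz"), 20.0)
        assert out.intensity.sum() == pytest.approx(y.sum(), rel=1e-9)

    def test_nonpositive_window_raises(self):
        x = np.arange(0.0, 10.0)
        tr = RawTrace(x=x, intensity=x, abscissa="mz")
        with pytest.raises(ValueError):
            smooth_moving_average(tr, 0.0)


class TestLinearize:
    def test_exact_for_linear_intensity(self, rng):
        x = np.sort(rng.uniform(10, 90, 40))
        tr = RawTrace(x=x, intensity=2.0 * x + 1.0, abscissa="mz")
        out = linearize(tr, 1.0)
        np.testing.assert_allclose(out.intensity, 2.0 * out.mz + 1.0, rtol=1e-12)

    def test_grid_inside_input_range(self, rng):
        x = np.sort(rng.uniform(10, 90, 30))
        out = linearize(RawTrace(x=x, intensity=x, abscissa="mz"), 1.7)
        assert out.mz[0] >= x[0] and out.mz[-1] <= x[-1]

    def test_idempotent_at_same_step(self, rng):
        x = np.sort(rng.uniform(10, 90, 50))
        tr = RawTrace(x=x, intensity=np.sin(x), abscissa="mz")
        once = linearize(tr, 0.5)
        twice = linearize(RawTrace(x=once.mz, intensity=once.intensity, abscissa="mz"), 0.5)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-12)

    def test_nonpositive_step_raises(self):
        x = np.arange(1.0, 10.0)
        with pytest.raises(ValueError):
            linearize(RawTrace(x=x, intensity=x, abscissa="mz"), 0.0)


class TestPeakBounds:
    def test_isolated_gaussian_brackets_peak(self):
        mz = np.arange(1.0, 202.0)
        y = np.exp(-0.5 * ((mz - 100) / 8) ** 2)
        spec = CalibratedSpectrum(mz=mz, intensity=y, step=1.0)
        left, right = find_peak_bounds(spec, 100.0, 50.0)
        assert left < 100.0 - 3 * 8 and right > 100.0 + 3 * 8

    def test_overlapping_peaks_share_valley(self):
        mz = np.arange(1.0, 242.0)
        y = np.exp(-0.5 * ((mz - 100) / 15) ** 2) + np.exp(-0.5 * ((mz - 140) / 15) ** 2)
        spec = CalibratedSpectrum(mz=mz, intensity=y, step=1.0)
        _, right_of_left = find_peak_bounds(spec, 100.0, 35.0)
        left_of_right, _ = find_peak_bounds(spec, 140.0, 35.0)
        assert right_of_left == left_of_right == pytest.approx(120.0)

    def test_edge_truncation_warns(self):
        spec = flat_spectrum(1, 101, 1.0, 1.0)
        with pytest.warns(UserWarning, match="truncated"):
            find_peak_bounds(spec, 5.0, 20.0)


class TestIntegratePeak:
    def triangle(self, base=20.0, height=10.0, offset=0.0):
        mz = np.arange(1.0, 102.0)
        y = np.maximum(0.0, height * (1 - np.abs(mz - 50) / (base / 2))) + offset
        return CalibratedSpectrum(mz=mz, intensity=y, step=1.0)

    def test_triangle_area(self):
        res = integrate_peak(self.triangle(), (40.0, 60.0))
        assert res.net_area == pytest.approx(100.0)  # b*h/2

    def test_constant_offset_removed_by_chord(self):
        a = integrate_peak(self.triangle(), (40.0, 60.0)).net_area
        b = integrate_peak(self.triangle(offset=25.0), (40.0, 60.0)).net_area
        assert a == pytest.approx(b)

    def test_gaussian_closed_form_within_1pct(self):
        amp, sigma = 7.0, 6.0
        mz = np.arange(1.0, 202.0)
        y = amp * np.exp(-0.5 * ((mz - 100) / sigma) ** 2)
        spec = CalibratedSpectrum(mz=mz, intensity=y, step=1.0)
        res = integrate_peak(spec, (100 - 8 * sigma, 100 + 8 * sigma))
        assert res.net_area == pytest.approx(amp * sigma * np.sqrt(2 * np.pi), rel=0.01)

    def test_bounds_outside_grid_raise(self):
        with pytest.raises(ValueError):
            integrate_peak(self.triangle(), (-5.0, 60.0))

    def test_monotone_segment_gives_zero_net_area(self):
        mz = np.arange(1.0, 102.0)
        spec = CalibratedSpectrum(mz=mz, intensity=mz * 0.5, step=1.0)
        res = integrate_peak(spec, (20.0, 60.0))
        assert res.net_area == pytest.approx(0.0, abs=1e-9)


class TestPercentSsdna:
    @pytest.mark.parametrize(
        "ss, ds, expected",
        [([0.0], [5.0], 0.0), ([3.0], [3.0], 50.0), ([2.0, 1.0], [2.0, 1.0], 50.0)],
    )
    def test_examples(self, ss, ds, expected):
        assert percent_ssdna(ss, ds) == pytest.approx(expected)

    def test_all_zero_raises(self):
        with pytest.raises(ValueError, match="no signal"):
            percent_ssdna([0.0], [0.0])

    @settings(deadline=None, derandomize=True)
    @given(
        ss=st.lists(st.floats(0, 1e6), min_size=1, max_size=3),
        ds=st.lists(st.floats(0, 1e6), min_size=1, max_size=3),
        k=st.floats(1e-3, 1e3),
    )
    def test_in_range_and_scale_invariant(self, ss, ds, k):
        if sum(ss) + sum(ds) == 0:
            return
        p = percent_ssdna(ss, ds)
        assert 0.0 <= p <= 100.0
        assert percent_ssdna([k * v for v in ss], [k * v for v in ds]) == pytest.approx(p)


class TestComposedPipeline:
    """The stages compose in the fixed order calibrate -> smooth ->
    linearize -> integrate and recover the generating dissociation level."""

    @pytest.mark.parametrize("pct", [12.5, 50.0, 88.0])
    def test_recovers_pct_noiseless(self, pct, cal_points):
        cfg = SyntheticConfig(noise_sd=0.0)
        trace = synth_spectrum(pct, cfg, width=900.0, seed=3)
        params = SpectrumParams(
            ss_mass_da=cfg.ss_mass, ds_mass_da=cfg.ds_mass,
            cal1=cal_points[0], cal2=cal_points[1],
        )
        spec = process_trace(trace, params)
        measured, peaks = measure_percent_ssdna(spec, params)
        assert measured == pytest.approx(pct, abs=0.5)
        assert len(peaks) == 2

    def test_recovers_pct_default_noise(self, cal_points):
        cfg = SyntheticConfig()
        params = SpectrumParams(
            ss_mass_da=cfg.ss_mass, ds_mass_da=cfg.ds_mass,
            cal1=cal_points[0], cal2=cal_points[1],
        )
        trace = synth_spectrum(40.0, cfg, width=900.0, seed=11)
        measured, _ = measure_percent_ssdna(process_trace(trace, params), params)
        assert measured == pytest.approx(40.0, abs=3.0)
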