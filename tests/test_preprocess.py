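"""Slicing, averaging, baseline subtraction and smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fabprofile import (
    PipelineConfig,
    Run,
    Spectrum,
    SimulationParams,
    make_slices,
    average_slice,
    render_run,
    smooth,
    subtract_baseline,
)
from fabprofile.errors import ConfigError
from fabprofile.preprocess import _baseline_length_scale, estimate_baseline

from .oracles import slice_windows_by_enumeration


class TestMakeSlices:
    def test_published_roi_gives_160_windows(self):
        windows = make_slices(10.0, 50.0, 0.3, 0.05)
        assert len(windows) == 160
        assert windows[0].rt_start == pytest.approx(10.0)
        assert windows[0].rt_end == pytest.approx(10.3)
        assert windows[-1].rt_end == pytest.approx(50.0)
        # stride 0.25, overlap exactly 0.05 between consecutive windows
        for a, b in zip(windows, windows[1:]):
            assert b.rt_start - a.rt_start == pytest.approx(0.25, abs=1e-9)
            assert a.rt_end - b.rt_start == pytest.approx(0.05, abs=1e-9)

    def test_matches_enumeration_oracle(self):
        windows = make_slices(10.0, 50.0, 0.3, 0.05)
        expected = slice_windows_by_enumeration(10.0, 50.0, 0.3, 0.05)
        assert len(windows) == len(expected)
        for w, (s, e) in zip(windows, expected):
            assert w.rt_start == pytest.approx(s, abs=1e-9)
            assert w.rt_end == pytest.approx(e, abs=1e-9)

    def test_roi_of_one_slice_width(self):
        windows = make_slices(0.0, 0.3, 0.3, 0.05)
        assert len(windows) == 1
        assert (windows[0].rt_start, windows[0].rt_end) == (0.0, 0.3)

    def test_roi_shorter_than_window_is_clipped(self):
        windows = make_slices(0.0, 0.2, 0.3, 0.05)
        assert len(windows) == 1
        assert windows[0].rt_end == 0.2

    def test_invalid_overlap(self):
        with pytest.raises(ConfigError):
            make_slices(0.0, 1.0, 0.3, 0.3)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        roi_len=st.floats(0.5, 60.0),
        width=st.floats(0.1, 1.0),
        frac=st.floats(0.05, 0.45),
    )
    def test_coverage_property(self, roi_len, width, frac):
        """Every RT in the ROI falls in >=1 window; overlap strips in exactly
        2 (guaranteed whenever the overlap is below half the width, as in the
        published geometry)."""
        overlap = width * frac
        windows = make_slices(0.0, roi_len, width, overlap)
        assert windows[-1].rt_end == pytest.approx(min(roi_len, windows[-1].rt_end))
        for rt in np.linspace(0.0, roi_len * 0.999, 200):
            hits = sum(w.contains(rt) for w in windows)
            assert hits >= 1
            assert hits <= 2


class TestAverageSlice:
    def _run(self, rts, values, config):
        from fabprofile.io import mz_grid
        grid = mz_grid(config)
        scans = [Spectrum(rt=t, mz=grid, intensity=np.full(grid.size, v))
                 for t, v in zip(rts, values)]
        return Run(run_id="r", scans=scans)

    def test_identical_scans_average_to_themselves(self, small_config):
        from fabprofile.preprocess import SliceWindow
        run = self._run([10.05, 10.10], [7.0, 7.0], small_config)
        w = SliceWindow(index=0, rt_start=10.0, rt_end=10.3)
        avg = average_slice(run, w, small_config)
        assert np.all(avg.intensity == 7.0)
        assert avg.rt == pytest.approx(10.15)

    def test_mean_of_zero_and_ten(self, small_config):
        from fabprofile.preprocess import SliceWindow
        run = self._run([10.05, 10.10], [0.0, 10.0], small_config)
        w = SliceWindow(index=0, rt_start=10.0, rt_end=10.3)
        assert np.all(average_slice(run, w, small_config).intensity == 5.0)

    def test_empty_window_flagged_zero(self, small_config):
        from fabprofile.preprocess import SliceWindow, preprocess_slice
        run = self._run([12.0], [3.0], small_config)
        w = SliceWindow(index=0, rt_start=10.0, rt_end=10.3)
        avg = average_slice(run, w, small_config)
        assert not np.any(avg.intensity)
        assert preprocess_slice(run, w, small_config) is None

    def test_scale_equivariance(self, small_config):
        from fabprofile.preprocess import SliceWindow
        run1 = self._run([10.05, 10.1, 10.2], [1.0, 2.0, 3.0], small_config)
        run2 = self._run([10.05, 10.1, 10.2], [2.5, 5.0, 7.5], small_config)
        w = SliceWindow(index=0, rt_start=10.0, rt_end=10.3)
        a1 = average_slice(run1, w, small_config).intensity
        a2 = average_slice(run2, w, small_config).intensity
        np.testing.assert_allclose(a2, 2.5 * a1)


def _grid():
    return 500.0 + 0.1 * np.arange(25001)


class TestBaseline:
    def test_constant_spectrum_is_removed(self):
        grid = _grid()
        s = Spectrum(rt=0.0, mz=grid, intensity=np.full(grid.size, 1000.0))
        out = subtract_baseline(s, 0.8)
        assert out.intensity.max() < 0.05 * 1000.0

    def test_zero_spectrum_stays_zero(self):
        grid = _grid()
        s = Spectrum(rt=0.0, mz=grid, intensity=np.zeros(grid.size))
        assert not np.any(subtract_baseline(s, 0.8).intensity)

    def test_narrow_peak_on_broad_hump_preserved(self):
        """Peak FWHM 0.2 Th on a hump FWHM 800 Th: apex kept within 5%."""
        grid = _grid()
        mu = 1500.0
        peak = 5000.0 * np.exp(-0.5 * ((grid - mu) / (0.2 / 2.3548)) ** 2)
        hump = 3000.0 * np.exp(-0.5 * ((grid - 1500.0) / (800.0 / 2.3548)) ** 2)
        out = subtract_baseline(Spectrum(rt=0.0, mz=grid, intensity=peak + hump), 0.8)
        apex = out.intensity[np.argmin(np.abs(grid - mu))]
        assert apex == pytest.approx(5000.0, rel=0.05)

    def test_flatness_monotone_in_length_scale(self):
        scales = [_baseline_length_scale(f) for f in (0.1, 0.4, 0.8, 1.0)]
        assert scales == sorted(scales)
        assert scales[0] >= 10.0 and scales[-1] <= 1000.0

    def test_higher_flatness_gives_flatter_baseline(self):
        """A stiffer baseline follows a mid-width bump less closely."""
        grid = _grid()
        bump = 1000.0 * np.exp(-0.5 * ((grid - 1500.0) / (120.0 / 2.3548)) ** 2)
        s = Spectrum(rt=0.0, mz=grid, intensity=bump)
        residual = []
        for f in (0.2, 0.6, 1.0):
            b = estimate_baseline(s, f)
            residual.append(float(np.abs(bump - b).max()))
        assert residual == sorted(residual)

    def test_flatness_out_of_range(self):
        grid = _grid()
        s = Spectrum(rt=0.0, mz=grid, intensity=np.ones(grid.size))
        with pytest.raises(ConfigError):
            subtract_baseline(s, 1.5)


class TestSmooth:
    def test_zero_iterations_is_identity(self):
        grid = _grid()
        rng = np.random.default_rng(1)
        y = rng.uniform(0, 10, grid.size)
        s = Spectrum(rt=0.0, mz=grid, intensity=y)
        np.testing.assert_array_equal(smooth(s, 0.2, 0).intensity, y)

    def test_delta_becomes_gaussian_of_same_area(self):
        grid = _grid()
        y = np.zeros(grid.size)
        y[grid.size // 2] = 100.0
        out = smooth(Spectrum(rt=0.0, mz=grid, intensity=y), 0.2, 1)
        assert out.intensity.sum() == pytest.approx(100.0, rel=1e-3)
        # FWHM of the result matches the requested smoothing width
        apex = out.intensity.max()
        above = grid[out.intensity >= apex / 2.0]
        assert above[-1] - above[0] == pytest.approx(0.2, abs=0.1)

    def test_white_noise_variance_shrinks(self):
        grid = _grid()
        rng = np.random.default_rng(2)
        y = rng.uniform(0, 100, grid.size)
        out = smooth(Spectrum(rt=0.0, mz=grid, intensity=y), 0.2, 1)
        assert out.intensity.var() < y.var()

    def test_repeated_iterations_widen(self):
        grid = _grid()
        y = np.zeros(grid.size)
        y[grid.size // 2] = 100.0
        one = smooth(Spectrum(rt=0.0, mz=grid, intensity=y), 0.2, 1).intensity
        three = smooth(Spectrum(rt=0.0, mz=grid, intensity=y), 0.2, 3).intensity
        assert three.max() < one.max()
        assert three.sum() == pytest.approx(one.sum(), rel=1e-3)


class TestPipelineOrder:
    def test_average_baseline_smooth_order(self, small_config):
        """preprocess_slice applies average -> baseline -> smooth."""
        from fabprofile.preprocess import (SliceWindow, preprocess_slice)
        from fabprofile import SimulatedClone
        clone = SimulatedClone(true_mass=48000.0, rt_center=10.05, rt_sigma=0.1,
                               abundance=1e5)
        params = SimulationParams(n_clones=1, seed=0, rt_start=10.0, rt_end=10.3,
                                  baseline_amplitude=500.0)
        run = render_run([clone], params, small_config)
        w = SliceWindow(index=0, rt_start=10.0, rt_end=10.3)
        out = preprocess_slice(run, w, small_config)
        # the broad hump is mostly gone while envelope peaks survive
        from fabprofile.preprocess import average_slice as avg_fn
        raw = avg_fn(run, w, small_config)
        mu30 = (48000.0 + 30 * small_config.proton_mass) / 30
        trough = np.abs(raw.mz - (mu30 + 20.0)) < 5.0  # between charge peaks
        assert out.intensity[trough].mean() < 0.2 * raw.intensity[trough].mean()
        peak_sel = np.abs(raw.mz - mu30) < 0.5
        assert out.intensity[peak_sel].max() > 0.5 * raw.intensity[peak_sel].max()
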