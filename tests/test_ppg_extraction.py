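"""ROI waveforms, floating-window DC, AC/DC normalization, filtering."""

import numpy as np
import pytest

from ippgmap import (CardiacCycles, VideoSequence, build_roi_grid, dc_component,
                     lowpass, normalize_invert, roi_waveforms)
from ippgmap.errors import FilterError, SizeError
from ippgmap.ppg_extraction import DcSeries, PpgWaveform


def _waveform(values, fps=39.0, state="stabilized"):
    return PpgWaveform(values=np.asarray(values, float), state=state, fps=fps)


class TestRoiGrid:
    @pytest.mark.parametrize("h, w, r, expected", [
        (480, 752, 2, (240, 376)),  # full camera frame
        (4, 4, 2, (2, 2)),
        (5, 7, 2, (2, 3)),
    ])
    def test_lattice_shape(self, h, w, r, expected):
        assert build_roi_grid(h, w, r).shape == expected

    def test_physical_size_from_pixel_pitch(self):
        grid = build_roi_grid(480, 752, 2, pixel_pitch_mm=0.02)
        assert grid.physical_size_mm == pytest.approx(0.04)  # 40 um ROI side

    def test_too_small_image_raises(self):
        with pytest.raises(SizeError):
            build_roi_grid(1, 10, 2)


class TestRoiWaveforms:
    def test_roi_mean_is_arithmetic_mean(self):
        frames = np.zeros((2, 2, 2))
        frames[0] = [[10, 20], [30, 40]]
        frames[1] = [[1, 1], [1, 1]]
        video = VideoSequence(frames=frames, fps=39.0)
        w = roi_waveforms(video, build_roi_grid(2, 2, 2))
        assert w.state == "raw"
        np.testing.assert_allclose(w.values[:, 0, 0], [25.0, 1.0])

    def test_constant_frames_give_constant_waveform(self):
        video = VideoSequence(frames=np.full((5, 4, 4), 100.0), fps=39.0)
        w = roi_waveforms(video, build_roi_grid(4, 4, 2))
        np.testing.assert_array_equal(w.values, 100.0)


class TestDcComponent:
    def _cycles_and_times(self, n, fps, period_frames):
        times = np.arange(n) / fps
        period = period_frames / fps
        r = np.arange(0.0, times[-1] + period, period)
        return CardiacCycles(r_times=r), times

    def test_constant_waveform_gives_constant_dc(self):
        cycles, times = self._cycles_and_times(200, 39.0, 31)
        dc = dc_component(_waveform(np.full(200, 7.0)), cycles, times)
        np.testing.assert_allclose(dc.values, 7.0)

    def test_sinusoid_at_cardiac_frequency_integrates_out(self):
        # window = one period: any contiguous whole period of a sampled
        # sinusoid sums to zero, so DC is exactly the mean level
        n, period = 200, 25  # odd fps-free construction: period in frames
        cycles, times = self._cycles_and_times(n, 39.0, period)
        x = 5.0 + 0.3 * np.sin(2 * np.pi * np.arange(n) / period)
        dc = dc_component(_waveform(x), cycles, times)
        sel = dc.full_window & dc.in_cycle
        np.testing.assert_allclose(dc.values[sel], 5.0, atol=1e-9)

    def test_centered_window_tracks_linear_drift(self):
        n, period = 200, 31  # odd window length: exactly centered
        cycles, times = self._cycles_and_times(n, 39.0, period)
        x = 2.0 + 0.05 * np.arange(n)
        dc = dc_component(_waveform(x), cycles, times)
        sel = dc.full_window & dc.in_cycle
        np.testing.assert_allclose(dc.values[sel], x[sel], atol=1e-9)

    def test_nonpositive_dc_flags_roi(self):
        cycles, times = self._cycles_and_times(100, 39.0, 31)
        vals = np.zeros((100, 1, 2))
        vals[:, 0, 0] = 5.0
        vals[:, 0, 1] = -1.0
        dc = dc_component(_waveform(vals), cycles, times)
        assert dc.roi_valid[0, 0]
        assert not dc.roi_valid[0, 1]


class TestNormalizeInvert:
    def test_unity_ratio_maps_to_zero(self):
        w = _waveform(np.full(50, 3.0))
        dc = DcSeries(values=np.full(50, 3.0), window_frames=np.full(50, 31),
                      in_cycle=np.ones(50, bool), full_window=np.ones(50, bool),
                      roi_valid=np.array(True))
        np.testing.assert_array_equal(normalize_invert(w, dc).values, 0.0)

    def test_absorption_dip_becomes_positive_pulse(self):
        t = np.linspace(0, 1, 100)
        m = 0.02
        w = _waveform(10.0 * (1 - m * np.sin(2 * np.pi * t)))
        dc = DcSeries(values=np.full(100, 10.0), window_frames=np.full(100, 31),
                      in_cycle=np.ones(100, bool), full_window=np.ones(100, bool),
                      roi_valid=np.array(True))
        out = normalize_invert(w, dc)
        np.testing.assert_allclose(out.values, m * np.sin(2 * np.pi * t), atol=1e-12)
        assert out.state == "normalized_inverted"

    def test_scale_invariance_of_ac_dc_ratio(self):
        rng = np.random.default_rng(3)
        cycles = CardiacCycles(r_times=np.arange(0.0, 6.0, 0.8))
        times = np.arange(200) / 39.0
        base = 100.0 + rng.normal(0, 1.0, (200, 2, 2)) + 50.0
        w1 = _waveform(base)
        w2 = _waveform(base * 3.7)
        out1 = normalize_invert(w1, dc_component(w1, cycles, times))
        out2 = normalize_invert(w2, dc_component(w2, cycles, times))
        np.testing.assert_allclose(out1.values, out2.values, atol=1e-12)


class TestLowpass:
    def _tone(self, freq, fps=39.0, seconds=15.0):
        t = np.arange(int(seconds * fps)) / fps
        return t, np.sin(2 * np.pi * freq * t)

    def _gain_phase(self, freq, x, y, fps=39.0):
        t = np.arange(x.size) / fps
        sl = slice(int(2 * fps), -int(2 * fps))
        probe = np.exp(-2j * np.pi * freq * t[sl])
        h = np.vdot(probe, y[sl]) / np.vdot(probe, x[sl])
        return abs(h), np.angle(h)

    def test_constant_series_unchanged(self):
        out = lowpass(_waveform(np.full(300, 2.5), state="normalized_inverted"))
        np.testing.assert_allclose(out.values, 2.5, atol=1e-10)
        assert out.state == "filtered"

    def test_passband_tone_amplitude_and_phase(self):
        _, x = self._tone(1.0)
        y = lowpass(_waveform(x, state="normalized_inverted")).values
        gain, phase = self._gain_phase(1.0, x, y)
        assert abs(gain - 1.0) <= 0.01
        assert abs(phase) < 0.01  # zero-phase filtering

    def test_stopband_tone_attenuated(self):
        _, x = self._tone(10.0)
        y = lowpass(_waveform(x, state="normalized_inverted")).values
        gain, _ = self._gain_phase(10.0, x, y)
        assert gain <= 0.10

    def test_near_idempotence_in_passband(self):
        _, x = self._tone(1.0)
        w = _waveform(x, state="normalized_inverted")
        once = lowpass(w)
        twice = lowpass(once)
        g1, _ = self._gain_phase(1.0, x, once.values)
        g2, _ = self._gain_phase(1.0, x, twice.values)
        assert abs(g2 - g1) / g1 < 0.02

    def test_short_series_raises(self):
        with pytest.raises(FilterError):
            lowpass(_waveform(np.zeros(10), state="normalized_inverted"))

    def test_undersampled_video_raises(self):
        with pytest.raises(FilterError):
            lowpass(_waveform(np.zeros(300), fps=7.0, state="normalized_inverted"))
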