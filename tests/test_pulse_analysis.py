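"""Pulse cutting, ensemble averaging, APC, synchronization index."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ippgmap import (CardiacCycles, MeanPulse, PulseSet, compute_apc,
                     ensemble_average, segment_pulses, sync_index,
                     temporal_resolution)
from ippgmap.errors import TimingError
from ippgmap.ppg_extraction import PpgWaveform


def _filtered(values, fps=39.0):
    return PpgWaveform(values=np.asarray(values, float), state="filtered", fps=fps)


def _template(length):
    u = np.arange(length) / length
    f = 1 - np.cos(2 * np.pi * u)
    return f / np.ptp(f)


class TestSegmentPulses:
    def test_regular_cycles_give_31_or_32_samples(self):
        # 0.8 s cycles at 39 fps: 0.8 * 39 = 31.2 -> pulses hold 31 or 32
        # frames depending on where the grid falls against each R-peak
        fps = 39.0
        times = np.arange(int(13 * 0.8 * fps)) / fps
        cycles = CardiacCycles(r_times=np.arange(13) * 0.8)
        w = _filtered(np.zeros(times.size), fps)
        pulses = segment_pulses(w, cycles, times)
        assert pulses.n_pulses == 12
        assert set(p.shape[0] for p in pulses.pulses) <= {31, 32}

    def test_gated_out_cycle_is_excluded(self):
        fps = 39.0
        times = np.arange(500) / fps
        r = np.arange(14) * 0.8
        valid = np.ones(13, bool)
        valid[3] = False
        cycles = CardiacCycles(r_times=r, valid=valid)
        pulses = segment_pulses(_filtered(np.zeros(500), fps), cycles, times)
        assert 3 not in pulses.cycle_ids
        assert pulses.n_pulses == 12

    def test_too_few_cycles_raises(self):
        times = np.arange(200) / 39.0
        cycles = CardiacCycles(r_times=np.arange(6) * 0.8)
        with pytest.raises(TimingError, match="usable"):
            segment_pulses(_filtered(np.zeros(200)), cycles, times)

    def test_unfiltered_waveform_rejected(self):
        cycles = CardiacCycles(r_times=np.arange(14) * 0.8)
        w = PpgWaveform(values=np.zeros(500), state="raw", fps=39.0)
        with pytest.raises(ValueError, match="filtered"):
            segment_pulses(w, cycles, np.arange(500) / 39.0)


class TestEnsembleAverage:
    def test_identical_pulses_average_to_themselves(self):
        template = _template(31)
        pulses = PulseSet(pulses=[template.copy() for _ in range(12)],
                          cycle_ids=list(range(12)))
        mean = ensemble_average(pulses)
        assert mean.n_cycles == 12
        np.testing.assert_allclose(mean.values, template, rtol=0, atol=1e-15)

    def test_noise_shrinks_as_inverse_sqrt_n(self):
        # Monte-Carlo oracle: RMS(mean - template) ~ sigma / sqrt(12)
        rng = np.random.default_rng(42)
        template = _template(31)
        sigma, reps = 0.1, 300
        rms = np.empty(reps)
        for k in range(reps):
            stack = template[None] + sigma * rng.standard_normal((12, 31))
            pulses = PulseSet(pulses=list(stack), cycle_ids=list(range(12)))
            mean = ensemble_average(pulses)
            rms[k] = np.sqrt(np.mean((mean.values - template) ** 2))
        expected = sigma / np.sqrt(12)
        assert abs(rms.mean() - expected) / expected < 0.25

    def test_variable_cycle_lengths_preserve_early_morphology(self):
        # pulses share their early-cycle shape; truncation to the shortest
        # pulse averages the common part coherently
        rng = np.random.default_rng(7)
        template = _template(36)
        lengths = rng.integers(28, 36, size=12)
        pulses = PulseSet(pulses=[template[:n] for n in lengths],
                          cycle_ids=list(range(12)))
        mean = ensemble_average(pulses)
        assert mean.values.shape[0] == lengths.min()
        np.testing.assert_allclose(mean.values, template[: lengths.min()],
                                   atol=1e-12)

    def test_below_min_cycles_raises(self):
        pulses = PulseSet(pulses=[np.zeros(30)] * 5, cycle_ids=list(range(5)))
        with pytest.raises(TimingError):
            ensemble_average(pulses)

    def test_commutes_with_affine_transform(self):
        rng = np.random.default_rng(9)
        stack = rng.standard_normal((12, 31))
        pulses = PulseSet(pulses=list(stack), cycle_ids=list(range(12)))
        mean = ensemble_average(pulses).values
        shifted = PulseSet(pulses=[2.5 * p - 1.0 for p in stack],
                           cycle_ids=list(range(12)))
        np.testing.assert_allclose(ensemble_average(shifted).values,
                                   2.5 * mean - 1.0, atol=1e-12)


class TestApc:
    def test_constant_pulse_has_zero_apc(self):
        mean = MeanPulse(values=np.full(30, 0.4), n_cycles=12, fps=39.0)
        assert compute_apc(mean) == 0.0

    def test_half_percent_sine_gives_one_percent_apc(self):
        u = np.linspace(0, 2 * np.pi, 1000)
        mean = MeanPulse(values=0.005 * np.sin(u), n_cycles=12, fps=39.0)
        assert compute_apc(mean) == pytest.approx(1.0, rel=1e-4)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(-5, 5), st.floats(0.01, 10))
    def test_translation_invariant_and_homogeneous(self, shift, scale):
        values = _template(31)
        base = compute_apc(MeanPulse(values=values, n_cycles=12, fps=39.0))
        shifted = compute_apc(MeanPulse(values=values + shift, n_cycles=12, fps=39.0))
        scaled = compute_apc(MeanPulse(values=values * scale, n_cycles=12, fps=39.0))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-9)
        assert scaled == pytest.approx(base * scale, rel=1e-9)

    def test_apc_sd_shrinks_with_cycle_count(self):
        # SD of APC across noise realizations ~ 1 / sqrt(n_cycles)
        rng = np.random.default_rng(17)
        template = _template(31)
        sigma, reps = 0.05, 400
        sds = {}
        for n in (3, 12, 48):
            apc = np.empty(reps)
            for k in range(reps):
                stack = template[None] + sigma * rng.standard_normal((n, 31))
                apc[k] = compute_apc(MeanPulse(values=stack.mean(axis=0),
                                               n_cycles=n, fps=39.0))
            sds[n] = apc.std(ddof=1)
        assert 1.6 <= sds[3] / sds[12] <= 2.4
        assert 1.6 <= sds[12] / sds[48] <= 2.4


class TestSyncIndex:
    def test_identical_aligned_pulses_give_one(self):
        template = _template(31)
        pulses = PulseSet(pulses=[template.copy() for _ in range(12)],
                          cycle_ids=list(range(12)))
        assert sync_index(pulses) == pytest.approx(1.0)

    def test_phase_scrambled_pulses_match_brute_force(self):
        rng = np.random.default_rng(23)
        template = _template(31)
        stack = np.stack([np.roll(template, rng.integers(0, 31))
                          for _ in range(12)])
        pulses = PulseSet(pulses=list(stack), cycle_ids=list(range(12)))
        got = sync_index(pulses)
        # brute-force evaluation of the same definition
        expected = np.ptp(stack.mean(axis=0)) / np.mean([np.ptp(p) for p in stack])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got < 0.7  # well below the aligned value

    def test_pure_noise_pulses_sit_near_sqrt_n_floor(self):
        rng = np.random.default_rng(29)
        vals = []
        for _ in range(200):
            stack = rng.standard_normal((12, 31))
            pulses = PulseSet(pulses=list(stack), cycle_ids=list(range(12)))
            vals.append(sync_index(pulses))
        # mean-pulse amplitude of incoherent noise scales as 1/sqrt(12)
        assert 0.5 / np.sqrt(12) < np.mean(vals) < 2.0 / np.sqrt(12)

    def test_zero_amplitude_pulses_give_zero(self):
        pulses = PulseSet(pulses=[np.zeros(30)] * 12, cycle_ids=list(range(12)))
        assert sync_index(pulses) == 0.0

    def test_desynchronization_monotonicity(self):
        # larger random per-pulse delays never raise the median index
        rng = np.random.default_rng(31)
        template = _template(64)
        medians = []
        for spread in (0, 4, 10, 24):
            vals = []
            for _ in range(60):
                stack = np.stack([np.roll(template, rng.integers(0, spread + 1))
                                  for _ in range(12)])
                pulses = PulseSet(pulses=list(stack), cycle_ids=list(range(12)))
                vals.append(sync_index(pulses))
            medians.append(np.median(vals))
        assert all(a >= b - 1e-9 for a, b in zip(medians, medians[1:]))


class TestTemporalResolution:
    @pytest.mark.parametrize("period, expected", [
        (0.5, 6.0),        # 120 bpm: fastest stated refresh
        (1.0, 12.0),
        (4.0 / 3.0, 16.0),  # 45 bpm: slowest stated refresh
    ])
    def test_span_of_twelve_cycles(self, period, expected):
        r = np.arange(13) * period
        assert temporal_resolution(CardiacCycles(r_times=r)) == pytest.approx(expected)

    def test_insufficient_cycles_raise(self):
        with pytest.raises(TimingError):
            temporal_resolution(CardiacCycles(r_times=np.arange(5) * 0.8))
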