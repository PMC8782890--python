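"""R-peak detection and the cardiac-cycle timeline.

The ECG is the timing reference for everything downstream: the floating
DC window equals the duration of the enclosing cardiac cycle, and the
waveform is cut into pulses at the R-peaks before ensemble averaging.

The detector is Pan–Tompkins-style: band-pass to the QRS band, squared
derivative, moving-window energy, adaptive threshold, then refinement of
each candidate to the local maximum of the raw signal.  Cycles whose
duration falls outside the physiological gate [0.30, 2.0] s (30–200 bpm)
are flagged invalid; both cycles adjacent to an out-of-gate interval are
excluded from ensemble averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from .errors import TimingError
from .io_sync import EcgRecord

#: physiological gate on cycle duration, seconds (200 bpm .. 30 bpm)
CYCLE_GATE_S = (0.30, 2.0)

#: minimum number of R-peaks: 12 averaged cycles need 13 boundaries
MIN_PEAKS = 13


@dataclass
class CardiacCycles:
    """R-peak instants and the cycles they delimit.

    ``valid[i]`` marks cycle i (the interval ``[r_times[i], r_times[i+1])``)
    as usable for averaging; there are ``len(r_times) - 1`` cycles.
    """

    r_times: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        if self.r_times.size >= 2 and np.any(np.diff(self.r_times) <= 0):
            raise TimingError("r_times must be strictly increasing")
        if self.valid is None:
            d = self.durations
            self.valid = (d >= CYCLE_GATE_S[0]) & (d <= CYCLE_GATE_S[1])
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != (self.n_cycles,):
            raise TimingError(
                f"{self.valid.size} validity flags for {self.n_cycles} cycles"
            )

    @property
    def durations(self) -> np.ndarray:
        """Cycle durations in seconds; always ``diff(r_times)``."""
        return np.diff(self.r_times)

    @property
    def n_cycles(self) -> int:
        return max(self.r_times.size - 1, 0)


def detect_r_peaks(ecg: EcgRecord, min_peaks: int = MIN_PEAKS) -> CardiacCycles:
    """Detect R-peaks and build the cardiac-cycle timeline.

    Raises :class:`TimingError` when fewer than ``min_peaks`` peaks are
    found (12 cycles of ensemble averaging need 13 boundaries).
    """
    x = ecg.samples
    fs = ecg.fs
    if x.size < int(2 * fs):
        raise TimingError("ECG record shorter than 2 s")

    # QRS band-pass; filtfilt keeps peaks in place
    nyq = fs / 2.0
    hi = min(30.0, 0.9 * nyq)
    b, a = sps.butter(3, [5.0 / nyq, hi / nyq], btype="bandpass")
    bp = sps.filtfilt(b, a, x)

    # squared derivative -> moving-window energy (~150 ms)
    energy = uniform_filter1d(np.gradient(bp) ** 2, max(int(0.15 * fs), 1))

    # candidate peaks at least 300 ms apart (200 bpm refractory period)
    cand, props = sps.find_peaks(energy, distance=max(int(0.30 * fs), 1))
    if cand.size == 0:
        raise TimingError("no QRS energy peaks found (flatline or pure noise ECG)")
    heights = energy[cand]
    # adaptive threshold: a fraction of the typical strong-beat energy
    thr = 0.20 * np.median(heights[heights >= np.percentile(heights, 50)])
    if thr <= 0:
        raise TimingError("ECG energy threshold degenerate (flatline record)")
    cand = cand[heights > thr]

    # refine each candidate to the raw-signal local maximum (R apex)
    half = max(int(0.05 * fs), 1)
    peaks = []
    for c in cand:
        lo = max(c - half, 0)
        hi_i = min(c + half + 1, x.size)
        peaks.append(lo + int(np.argmax(x[lo:hi_i])))
    peaks = np.unique(peaks)
    # drop refinement collisions closer than the refractory period
    if peaks.size > 1:
        keep = [0]
        for i in range(1, peaks.size):
            if peaks[i] - peaks[keep[-1]] >= int(0.25 * fs):
                keep.append(i)
            elif x[peaks[i]] > x[peaks[keep[-1]]]:
                keep[-1] = i
        peaks = peaks[keep]

    if peaks.size < min_peaks:
        raise TimingError(
            f"insufficient cardiac cycles: {peaks.size} R-peaks found, "
            f"{min_peaks} required"
        )
    r_times = peaks / fs
    cycles = CardiacCycles(r_times=r_times)
    # an out-of-gate interval invalidates both adjacent cycles
    d = cycles.durations
    bad = (d < CYCLE_GATE_S[0]) | (d > CYCLE_GATE_S[1])
    valid = ~bad
    valid[:-1] &= ~bad[1:]
    valid[1:] &= ~bad[:-1]
    cycles.valid = valid
    return cycles


def cycle_at(cycles: CardiacCycles, t: float) -> int:
    """Index i of the half-open cycle ``[r_times[i], r_times[i+1])`` holding t."""
    r = cycles.r_times
    if not (r[0] <= t < r[-1]):
        raise TimingError(
            f"t={t:.3f} s outside cardiac coverage [{r[0]:.3f}, {r[-1]:.3f}) s"
        )
    return int(np.searchsorted(r, t, side="right") - 1)
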