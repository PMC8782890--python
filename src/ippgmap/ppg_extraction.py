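"""From stabilized pixel signals to normalized, filtered PPG waveforms.

The frame is tiled into 2x2-pixel ROIs sharing borders without overlap;
each ROI's waveform is the frame-by-frame mean pixel value.  The slowly
varying DC baseline is the mean over a floating window whose length
equals the duration of the cardiac cycle containing each sample; the
waveform is divided by it (AC/DC — cancels uneven illumination and
camera gain), unity is subtracted and the sign inverted so that the
output rises with arterial blood volume (blood absorbs the green probe
light, so raw intensity dips during systole).  Finally a zero-phase
low-pass (4th-order Butterworth at 4 Hz, forward-backward) removes
sensor noise above the cardiac band without displacing pulse extrema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ecg_timing import CardiacCycles
from .errors import FilterError, SizeError
from .io_sync import VideoSequence
from .stabilization import StabilizedSignals

STATES = ("raw", "stabilized", "normalized_inverted", "filtered")


@dataclass
class RoiGrid:
    """Lattice of non-overlapping square ROIs, top-left anchored."""

    roi_size: int
    shape: tuple[int, int]
    physical_size_mm: float | None = None  # mm per ROI side

    @property
    def n_rois(self) -> int:
        return self.shape[0] * self.shape[1]


@dataclass
class PpgWaveform:
    """Per-ROI time series through its processing states.

    ``values`` has shape (n_frames, roi_rows, roi_cols) — or any trailing
    layout for single-ROI diagnostics — and ``state`` records where in
    the raw -> stabilized -> normalized_inverted -> filtered chain it is.
    """

    values: np.ndarray
    state: str
    fps: float

    def __post_init__(self) -> None:
        if self.state not in STATES:
            raise ValueError(f"unknown waveform state {self.state!r}")
        self.values = np.asarray(self.values)


@dataclass
class DcSeries:
    """Floating-window DC baseline matched to :class:`PpgWaveform`.

    ``window_frames[t]`` is the window length used at frame t (the
    enclosing cardiac-cycle duration in frames); ``in_cycle[t]`` marks
    frames inside a valid cardiac cycle and ``full_window[t]`` those
    whose centered window fits without clipping — only these enter the
    pulse analysis.  ``roi_valid`` is False where the baseline is not
    strictly positive (division safety).
    """

    values: np.ndarray
    window_frames: np.ndarray
    in_cycle: np.ndarray
    full_window: np.ndarray
    roi_valid: np.ndarray


def build_roi_grid(height: int, width: int, roi_size: int = 2,
                   pixel_pitch_mm: float | None = None) -> RoiGrid:
    if height < roi_size or width < roi_size:
        raise SizeError(f"image {height}x{width} smaller than one ROI of {roi_size} px")
    return RoiGrid(
        roi_size=roi_size,
        shape=(height // roi_size, width // roi_size),
        physical_size_mm=None if pixel_pitch_mm is None else roi_size * pixel_pitch_mm,
    )


def roi_waveforms(signals: StabilizedSignals | VideoSequence,
                  grid: RoiGrid) -> PpgWaveform:
    """Frame-by-frame mean pixel value in every ROI.

    Accepts stabilized signals (the quantitative path) or the raw video
    (for before-stabilization diagnostics).
    """
    if isinstance(signals, StabilizedSignals):
        frames, state, fps = signals.corrected, "stabilized", signals.fps
    else:
        frames, state, fps = signals.frames, "raw", signals.fps
    r = grid.roi_size
    nr, nc = grid.shape
    v = frames[:, : nr * r, : nc * r].astype(np.float64)
    v = v.reshape(frames.shape[0], nr, r, nc, r).mean(axis=(2, 4))
    return PpgWaveform(values=v, state=state, fps=fps)


def _cycle_index_per_frame(cycles: CardiacCycles, frame_times: np.ndarray):
    """Cycle index for each frame; -1 outside coverage or in invalid cycles."""
    idx = np.searchsorted(cycles.r_times, frame_times, side="right") - 1
    inside = (idx >= 0) & (idx < cycles.n_cycles)
    idx_safe = np.clip(idx, 0, max(cycles.n_cycles - 1, 0))
    ok = inside & cycles.valid[idx_safe]
    return np.where(ok, idx_safe, -1)


def dc_component(w: PpgWaveform, cycles: CardiacCycles,
                 frame_times: np.ndarray) -> DcSeries:
    """Floating-window DC: mean over one enclosing-cycle duration, centered.

    The window is centered on each sample (unbiased for linear drifts)
    and clipped at the record edges; frames whose full window does not
    fit are flagged so pulse analysis can trim them.  Frames outside any
    valid cardiac cycle borrow the nearest in-cycle window length, so the
    series stays smooth for filtering, but are excluded downstream.
    """
    vals = w.values
    n = vals.shape[0]
    frame_times = np.asarray(frame_times, dtype=float)
    cyc = _cycle_index_per_frame(cycles, frame_times)
    in_cycle = cyc >= 0

    durations = cycles.durations
    win = np.empty(n)
    if np.any(in_cycle):
        win[in_cycle] = durations[cyc[in_cycle]]
        if np.any(~in_cycle):
            # nearest in-cycle frame lends its window length
            src = np.flatnonzero(in_cycle)
            tgt = np.flatnonzero(~in_cycle)
            nearest = src[np.argmin(np.abs(frame_times[tgt, None] -
                                           frame_times[src][None]), axis=1)]
            win[tgt] = win[nearest]
    else:
        win[:] = np.median(durations) if durations.size else 1.0
    wlen = np.maximum(np.rint(win * w.fps).astype(int), 1)

    t_idx = np.arange(n)
    a = t_idx - wlen // 2
    b = a + wlen  # exclusive
    full = (a >= 0) & (b <= n)
    a = np.clip(a, 0, n)
    b = np.clip(b, 1, n)
    cs = np.concatenate([np.zeros((1, *vals.shape[1:])), np.cumsum(vals, axis=0)])
    dc = (cs[b] - cs[a]) / (b - a).reshape(-1, *([1] * (vals.ndim - 1)))

    consider = in_cycle & full
    if np.any(consider):
        roi_valid = np.all(dc[consider] > 0, axis=0)
    else:
        roi_valid = np.zeros(vals.shape[1:], dtype=bool)
    return DcSeries(values=dc, window_frames=wlen, in_cycle=in_cycle,
                    full_window=full, roi_valid=roi_valid)


def normalize_invert(w: PpgWaveform, dc: DcSeries) -> PpgWaveform:
    """AC/DC normalization: ``out = -(w / DC - 1)``.

    The ratio cancels the incident-illumination level (both AC and DC
    scale with it); subtracting unity and inverting the sign turns the
    systolic absorption dip into a positive pulse that tracks arterial
    blood pressure.  ROIs with a non-positive baseline are zeroed and
    carried as invalid in ``dc.roi_valid``.
    """
    safe = np.where(dc.values > 0, dc.values, 1.0)
    out = -(w.values / safe - 1.0)
    out = np.where(dc.values > 0, out, 0.0)
    return PpgWaveform(values=out, state="normalized_inverted", fps=w.fps)


def lowpass(w: PpgWaveform, cutoff: float = 4.0, order: int = 4) -> PpgWaveform:
    """Zero-phase Butterworth low-pass (forward-backward filtering)."""
    if w.fps <= 2 * cutoff:
        raise FilterError(
            f"fps {w.fps} must exceed twice the {cutoff} Hz cutoff"
        )
    b, a = sps.butter(order, cutoff / (w.fps / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if w.values.shape[0] <= padlen:
        raise FilterError(
            f"series of {w.values.shape[0]} samples too short for "
            f"zero-phase filtering (needs > {padlen})"
        )
    out = sps.filtfilt(b, a, w.values, axis=0)
    return PpgWaveform(values=out, state="filtered", fps=w.fps)
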