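"""End-to-end pipeline: synchronized recording in, perfusion map out.

Stage order follows the processing chain: stream alignment, R-peak
detection, segment-wise motion compensation, ROI waveform extraction,
floating-window AC/DC normalization, zero-phase low-pass, R-gated pulse
cutting, 12-cycle ensemble averaging, APC map assembly.  The analysis
path contains no randomness: identical inputs and config give
bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__ as _pkg_version
from .ecg_timing import CardiacCycles, detect_r_peaks
from .errors import ConfigError
from .io_sync import EcgRecord, SyncedRecording, VideoSequence, align_streams, read_ecg, read_video
from .mapping import (PerfusionMap, RegionStats, aggregate_region, build_map,
                      render_overlay, write_map_csv, write_map_tiff,
                      write_region_stats)
from .ppg_extraction import (DcSeries, PpgWaveform, build_roi_grid, dc_component,
                             lowpass, normalize_invert, roi_waveforms)
from .pulse_analysis import MeanPulse, PulseSet, ensemble_average, segment_pulses
from .stabilization import (StabilizedSignals, build_segment_grid,
                            estimate_offsets, remove_motion_component)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of the analysis, with the standard defaults.

    Defaults mirror the published processing chain: 8x8-px motion
    segments, 2x2-px ROIs, 4 Hz zero-phase low-pass, 12-cycle ensemble
    with an 8-cycle floor.
    """

    video_path: str = ""
    ecg_path: str = ""
    sidecar_path: str | None = None
    out_dir: str = "ippg_out"

    segment_size: int = 8
    roi_size: int = 2
    cutoff_hz: float = 4.0
    filter_order: int = 4
    n_cycles: int = 12
    min_cycles: int = 8
    aggregation_size_px: int = 60
    color_range: tuple[float, float] | None = None
    stabilize: bool = True
    motion_mode: str = "auto"  # offset estimation route
    motion_lowpass_hz: float | None = 1.5  # band limit of the compensator
    motion_subtraction: str = "warp"  # 'warp' (exact) or 'linear' (1st order)
    max_shift_px: float = 16.0
    cond_max: float = 1e3
    overlay_alpha: float = 0.6
    diagnostics_rois: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("segment_size", "roi_size", "n_cycles", "min_cycles",
                     "aggregation_size_px", "filter_order"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be positive")
        if self.min_cycles > self.n_cycles:
            raise ConfigError("min_cycles cannot exceed n_cycles")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "color_range" in raw and raw["color_range"] is not None:
            raw["color_range"] = tuple(raw["color_range"])
        if "diagnostics_rois" in raw:
            raw["diagnostics_rois"] = [tuple(x) for x in raw["diagnostics_rois"]]
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Perfusion map plus the intermediates diagnostics may want."""

    perfusion_map: PerfusionMap
    cycles: CardiacCycles
    synced: SyncedRecording
    waveform_filtered: PpgWaveform
    dc: DcSeries
    pulses: PulseSet
    mean_pulse: MeanPulse
    stabilized: StabilizedSignals | None
    waveform_raw: PpgWaveform


def _reference_frame(video: VideoSequence, cycles: CardiacCycles,
                     frame_times: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    """Temporal mean of the first cardiac cycle's frames (noise-robust ref)."""
    r0, r1 = cycles.r_times[0], cycles.r_times[1]
    sel = np.flatnonzero((frame_times >= r0) & (frame_times < r1))
    if sel.size == 0:
        sel = np.arange(min(video.n_frames, max(int(video.fps), 1)))
    ref = video.frames[sel[0]: sel[-1] + 1].astype(np.float64).mean(axis=0)
    return ref, (int(sel[0]), int(sel[-1] + 1))


def analyze(video: VideoSequence, ecg: EcgRecord,
            config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis on in-memory streams."""
    cfg = config or PipelineConfig()
    if cfg.cutoff_hz >= video.fps / 2:
        raise ConfigError(
            f"cutoff {cfg.cutoff_hz} Hz must be below half the frame rate "
            f"({video.fps / 2:.1f} Hz)"
        )
    synced = align_streams(video, ecg)
    video = synced.video
    frame_times = synced.frame_times_ecg
    logger.info("aligned %d frames over %.1f s", video.n_frames,
                frame_times[-1] - frame_times[0])

    cycles = detect_r_peaks(ecg, min_peaks=cfg.min_cycles + 1)
    logger.info("detected %d R-peaks, %d valid cycles",
                cycles.r_times.size, int(cycles.valid.sum()))

    roi_grid = build_roi_grid(video.height, video.width, cfg.roi_size,
                              pixel_pitch_mm=video.pixel_pitch_mm)
    seg_valid_roi = np.ones(roi_grid.shape, dtype=bool)
    stabilized = None
    if cfg.stabilize:
        seg_grid = build_segment_grid(video.height, video.width, cfg.segment_size)
        ref, span = _reference_frame(video, cycles, frame_times)
        # cap the compensator band below the cardiac fundamental: motion
        # at the heart frequency is indistinguishable from the signal
        f_card = 1.0 / float(np.median(cycles.durations))
        smooth_hz = cfg.motion_lowpass_hz
        if smooth_hz is not None:
            smooth_hz = min(smooth_hz, 0.7 * f_card)
        est = estimate_offsets(video, seg_grid, reference=ref,
                               cond_max=cfg.cond_max, max_shift=cfg.max_shift_px,
                               mode=cfg.motion_mode, ref_span=span,
                               smooth_hz=smooth_hz)
        stabilized = remove_motion_component(video, est, seg_grid, reference=ref,
                                             method=cfg.motion_subtraction)
        seg_valid_roi = _segment_validity_to_rois(
            stabilized.segment_valid, cfg.segment_size, cfg.roi_size, roi_grid.shape
        )
        logger.info("stabilization: %d/%d segments valid in all frames",
                    int(stabilized.segment_valid.sum()), stabilized.segment_valid.size)
        signals = stabilized
    else:
        signals = video

    w_raw = roi_waveforms(video, roi_grid)
    w = roi_waveforms(signals, roi_grid)
    dc = dc_component(w, cycles, frame_times)
    w_norm = normalize_invert(w, dc)
    w_filt = lowpass(w_norm, cutoff=cfg.cutoff_hz, order=cfg.filter_order)

    usable = dc.in_cycle & dc.full_window
    pulses = segment_pulses(w_filt, cycles, frame_times,
                            min_cycles=cfg.min_cycles, valid_frames=usable)
    mean_pulse = ensemble_average(pulses, n=cfg.n_cycles,
                                  min_cycles=cfg.min_cycles, fps=video.fps)

    roi_valid = seg_valid_roi & dc.roi_valid
    reason = np.zeros(roi_grid.shape, dtype=int)
    reason[~dc.roi_valid] = 2
    reason[~seg_valid_roi] = 1
    pmap = build_map(
        mean_pulse, roi_grid, roi_valid=roi_valid, reason=reason,
        meta={
            "n_cycles": mean_pulse.n_cycles,
            "window_s": [float(frame_times[0]), float(frame_times[-1])],
            "config_hash": cfg.config_hash(),
            "stabilized": cfg.stabilize,
            "below_target_cycles": mean_pulse.n_cycles < cfg.n_cycles,
        },
    )
    logger.info("map: %d/%d valid ROIs, %d-cycle ensemble",
                int(pmap.mask.sum()), pmap.mask.size, mean_pulse.n_cycles)
    return PipelineResult(
        perfusion_map=pmap, cycles=cycles, synced=synced,
        waveform_filtered=w_filt, dc=dc, pulses=pulses, mean_pulse=mean_pulse,
        stabilized=stabilized, waveform_raw=w_raw,
    )


def _segment_validity_to_rois(segment_valid: np.ndarray, segment_size: int,
                              roi_size: int, roi_shape: tuple[int, int]) -> np.ndarray:
    """An ROI is valid only if its containing motion segment is."""
    out = np.ones(roi_shape, dtype=bool)
    rr = (np.arange(roi_shape[0]) * roi_size) // segment_size
    cc = (np.arange(roi_shape[1]) * roi_size) // segment_size
    rr = np.clip(rr, 0, segment_valid.shape[0] - 1)
    cc = np.clip(cc, 0, segment_valid.shape[1] - 1)
    out &= segment_valid[np.ix_(rr, cc)]
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-to-file pipeline driver: read inputs, analyze, write outputs."""
    video = read_video(config.video_path, config.sidecar_path)
    ecg = read_ecg(config.ecg_path)
    result = analyze(video, ecg, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    pmap = result.perfusion_map
    write_map_csv(pmap, out / "apc_map.csv")
    write_map_tiff(pmap, out / "apc_map.tif")
    background = result.synced.video.frames[0]
    render_overlay(pmap, background, out / "apc_overlay.png",
                   alpha=config.overlay_alpha, vrange=config.color_range)

    stats = [RegionStats(
        mean=float(np.nanmean(pmap.apc)) if pmap.mask.any() else float("nan"),
        sd=float(np.nanstd(pmap.apc, ddof=1)) if pmap.mask.sum() > 1 else 0.0,
        n_roi=int(pmap.mask.sum()), region="whole_map",
    )]
    write_region_stats(stats, out / "region_stats.json",
                       extra={"n_cycles": result.mean_pulse.n_cycles})

    manifest = {
        "version": _pkg_version,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "n_frames": result.synced.video.n_frames,
        "n_dropped_frames": result.synced.n_dropped_frames,
        "n_r_peaks": int(result.cycles.r_times.size),
        "n_valid_cycles": int(result.cycles.valid.sum()),
        "n_cycles_averaged": result.mean_pulse.n_cycles,
        "n_valid_rois": int(pmap.mask.sum()),
        "n_masked_rois": int((~pmap.mask).sum()),
        "mask_reasons": {name: int((pmap.reason == code).sum())
                         for code, name in [(1, "motion_ill_conditioned"),
                                            (2, "dc_nonpositive")]},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return result


def export_roi_diagnostics(result: PipelineResult, roi: tuple[int, int],
                           out_dir: str | Path) -> list[Path]:
    """Per-ROI CSVs mirroring the diagnostic panels: raw waveform,
    normalized+filtered waveform, ECG, individual pulses + mean pulse."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r, c = roi
    t = result.synced.frame_times_ecg
    paths = []

    def save(name, header, cols):
        p = out / f"roi_{r}_{c}_{name}.csv"
        np.savetxt(p, np.column_stack(cols), delimiter=",", header=header, comments="")
        paths.append(p)

    save("x1_raw", "time_s,value", (t, result.waveform_raw.values[:, r, c]))
    save("x2_filtered", "time_s,value", (t, result.waveform_filtered.values[:, r, c]))
    ecg = result.synced.ecg
    save("x3_ecg", "time_s,mv", (ecg.times, ecg.samples))
    length = result.mean_pulse.values.shape[0]
    cols = [np.arange(length) / result.synced.video.fps]
    header = ["time_s"]
    for k, pulse in enumerate(result.pulses.pulses[: result.mean_pulse.n_cycles]):
        cols.append(pulse[:length, r, c])
        header.append(f"pulse_{k}")
    cols.append(result.mean_pulse.values[:, r, c])
    header.append("mean_pulse")
    save("x4_pulses", ",".join(header), cols)
    return paths
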