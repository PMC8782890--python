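"""Video/ECG input-output and the common time base between the two streams.

The interchange formats are deliberately plain: grayscale multipage TIFF
(or a raw 8-bit frame stack) with a JSON sidecar carrying the frame rate
and timestamps, and a two-column CSV (time in ms, amplitude in mV) for the
single-lead ECG.  Synchronization is modeled as a single constant offset
``t0_offset`` — the ECG-clock time of video frame 0 — matching hardware
that timestamps both streams against one clock to ~1 ms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import AlignmentError, FormatError

logger = logging.getLogger(__name__)

#: maximum tolerated deviation of a frame interval from 1/fps, as a
#: fraction of 1/fps.  Ensemble averaging assumes a regular frame grid,
#: so jittered recordings are rejected rather than resampled.
JITTER_TOLERANCE = 0.25

#: minimum video/ECG overlap (seconds) for any analysis: 12 cardiac
#: cycles at the fastest physiological heart rate span 6 s.
MIN_OVERLAP_S = 6.0


@dataclass
class VideoSequence:
    """A stack of grayscale frames with per-frame timestamps.

    Parameters
    ----------
    frames : ndarray, shape (n_frames, height, width)
        Pixel intensities; 8-bit integer or float.
    fps : float
        Nominal frame rate in frames per second.
    timestamps : ndarray, shape (n_frames,), optional
        Frame times in seconds on the camera clock.  Synthesized as
        ``i / fps`` when omitted.
    pixel_pitch_mm : float, optional
        Physical size of one pixel in the tissue plane, millimetres.
    """

    frames: np.ndarray
    fps: float
    timestamps: np.ndarray | None = None
    pixel_pitch_mm: float | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError(
                f"frames must be 3-D [frame, row, col], got shape {self.frames.shape}"
            )
        if self.fps <= 0:
            raise FormatError(f"fps must be positive, got {self.fps}")
        if self.timestamps is None:
            self.timestamps = np.arange(self.n_frames) / self.fps
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.shape != (self.n_frames,):
            raise FormatError(
                f"{self.timestamps.size} timestamps for {self.n_frames} frames"
            )
        if self.n_frames > 1:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise FormatError("timestamps must be strictly increasing")
            jitter = np.max(np.abs(dt - 1.0 / self.fps)) * self.fps
            if jitter >= JITTER_TOLERANCE:
                raise FormatError(
                    f"frame-interval jitter {jitter:.3f}/fps exceeds "
                    f"{JITTER_TOLERANCE}/fps; irregular recordings are rejected"
                )
        if np.issubdtype(self.frames.dtype, np.integer):
            lo, hi = int(self.frames.min(initial=0)), int(self.frames.max(initial=0))
            if lo < 0 or hi > 255:
                raise FormatError(f"8-bit frames must lie in [0, 255], got [{lo}, {hi}]")
        elif not np.all(np.isfinite(self.frames)):
            raise FormatError("frame intensities must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def height(self) -> int:
        return self.frames.shape[1]

    @property
    def width(self) -> int:
        return self.frames.shape[2]

    @property
    def duration(self) -> float:
        """Time span covered by the frames, seconds."""
        return float(self.timestamps[-1] - self.timestamps[0]) + 1.0 / self.fps


@dataclass
class EcgRecord:
    """Single-lead ECG samples on a uniform grid.

    ``t0_offset`` is the ECG-clock time (seconds) at which video frame 0
    was exposed; it is the whole synchronization model.
    """

    samples: np.ndarray
    fs: float
    t0_offset: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise FormatError(f"ECG sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample instants in seconds on the ECG clock."""
        return np.arange(self.samples.size) / self.fs


@dataclass
class SyncedRecording:
    """A video stream placed on the ECG clock."""

    video: VideoSequence
    ecg: EcgRecord
    frame_times_ecg: np.ndarray
    n_dropped_frames: int = 0

    def __post_init__(self) -> None:
        self.frame_times_ecg = np.asarray(self.frame_times_ecg, dtype=float)
        expected = self.ecg.t0_offset + self.video.timestamps
        if np.max(np.abs(self.frame_times_ecg - expected)) > 1e-3:
            raise AlignmentError("frame times deviate from the ECG clock by > 1 ms")


# ---------------------------------------------------------------------------
# readers / writers


def _sidecar_path(path: Path, sidecar: str | Path | None) -> Path:
    if sidecar is not None:
        return Path(sidecar)
    return path.with_suffix(".json")


def read_video(path: str | Path, sidecar: str | Path | None = None) -> VideoSequence:
    """Read a multipage TIFF or raw 8-bit stack plus its JSON sidecar.

    The sidecar holds ``fps``, ``height``, ``width`` and optionally
    ``timestamps`` (seconds) and ``pixel_pitch_mm``.  No intensity
    rescaling is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"video file not found: {path}")
    meta_path = _sidecar_path(path, sidecar)
    if not meta_path.exists():
        raise FormatError(f"video sidecar not found: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # corrupt container
            raise FormatError(f"cannot read TIFF {path}: {exc}") from exc
        if frames.ndim == 2:
            frames = frames[None]
    else:
        h, w = int(meta["height"]), int(meta["width"])
        flat = np.fromfile(path, dtype=np.uint8)
        if flat.size % (h * w):
            raise FormatError(
                f"{path}: {flat.size} bytes is not a whole number of {h}x{w} frames"
            )
        frames = flat.reshape(-1, h, w)
    if "height" in meta and frames.shape[1:] != (int(meta["height"]), int(meta["width"])):
        raise FormatError(
            f"sidecar declares {meta['height']}x{meta['width']} "
            f"but stack frames are {frames.shape[1]}x{frames.shape[2]}"
        )
    ts = meta.get("timestamps")
    n_meta = meta.get("n_frames")
    if n_meta is not None and int(n_meta) != frames.shape[0]:
        raise FormatError(
            f"sidecar declares {n_meta} frames but stack holds {frames.shape[0]}"
        )
    return VideoSequence(
        frames=frames,
        fps=float(meta["fps"]),
        timestamps=None if ts is None else np.asarray(ts, dtype=float),
        pixel_pitch_mm=meta.get("pixel_pitch_mm"),
    )


def write_video(video: VideoSequence, path: str | Path,
                sidecar: str | Path | None = None) -> None:
    """Write a frame stack as multipage TIFF (or raw) plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, video.frames)
    else:
        np.ascontiguousarray(video.frames, dtype=np.uint8).tofile(path)
    meta = {
        "fps": video.fps,
        "height": video.height,
        "width": video.width,
        "n_frames": video.n_frames,
        "timestamps": video.timestamps.tolist(),
    }
    if video.pixel_pitch_mm is not None:
        meta["pixel_pitch_mm"] = video.pixel_pitch_mm
    _sidecar_path(path, sidecar).write_text(json.dumps(meta))


def read_ecg(path: str | Path) -> EcgRecord:
    """Read a two-column ``time_ms,mv`` CSV into an :class:`EcgRecord`.

    The sampling rate is estimated as ``1 / median(dt)``; an optional
    header comment ``# t0_offset_ms=<float>`` carries the sync offset.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"ECG file not found: {path}")
    t0_offset = 0.0
    skiprows = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "t0_offset_ms" in line:
                    t0_offset = float(line.split("=", 1)[1]) * 1e-3
                skiprows += 1
            else:
                if line.strip() and line.lstrip()[0] not in "0123456789+-.":
                    skiprows += 1  # column-name header line
                break
    df = pd.read_csv(path, header=None, names=["time_ms", "mv"], skiprows=skiprows)
    if len(df) < 2:
        raise FormatError(f"{path}: need at least two ECG samples")
    t_ms = df["time_ms"].to_numpy(dtype=float)
    dt = np.diff(t_ms)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: ECG time column is not strictly increasing")
    dt_med = float(np.median(dt))
    fs = 1000.0 / dt_med
    n_expected = (t_ms[-1] - t_ms[0]) / dt_med + 1
    if len(df) < 0.99 * n_expected:
        raise FormatError(
            f"{path}: more than 1% of samples missing "
            f"({len(df)} present, ~{n_expected:.0f} expected)"
        )
    return EcgRecord(samples=df["mv"].to_numpy(dtype=float), fs=fs, t0_offset=t0_offset)


def write_ecg(ecg: EcgRecord, path: str | Path) -> None:
    """Write an :class:`EcgRecord` as ``time_ms,mv`` CSV with sync header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t_ms = np.arange(ecg.samples.size) * 1000.0 / ecg.fs
    with open(path, "w") as fh:
        fh.write(f"# t0_offset_ms={ecg.t0_offset * 1e3:.6f}\n")
        fh.write("time_ms,mv\n")
        pd.DataFrame({"time_ms": t_ms, "mv": ecg.samples}).to_csv(
            fh, index=False, header=False, float_format="%.9g"
        )


def align_streams(video: VideoSequence, ecg: EcgRecord) -> SyncedRecording:
    """Place video frames on the ECG clock and drop uncovered frames.

    Raises :class:`AlignmentError` when the common interval is shorter
    than :data:`MIN_OVERLAP_S`.
    """
    frame_times = ecg.t0_offset + video.timestamps
    covered = (frame_times >= 0.0) & (frame_times <= ecg.duration)
    n_dropped = int(np.count_nonzero(~covered))
    if n_dropped:
        logger.info("align_streams: dropped %d frames outside ECG coverage", n_dropped)
        video = VideoSequence(
            frames=video.frames[covered],
            fps=video.fps,
            timestamps=video.timestamps[covered],
            pixel_pitch_mm=video.pixel_pitch_mm,
        )
        frame_times = frame_times[covered]
    if frame_times.size == 0 or frame_times[-1] - frame_times[0] < MIN_OVERLAP_S:
        span = 0.0 if frame_times.size == 0 else frame_times[-1] - frame_times[0]
        raise AlignmentError(
            f"video/ECG overlap {span:.2f} s is below the {MIN_OVERLAP_S:.0f} s minimum"
        )
    return SyncedRecording(video=video, ecg=ecg, frame_times_ecg=frame_times,
                           n_dropped_frames=n_dropped)
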