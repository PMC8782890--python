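"""Ground-truthed synthetic recordings: textured tissue video + ECG.

The generator emulates the acquisition the pipeline targets — a diffuse
tissue scene under static (possibly uneven) illumination whose
reflectance is modulated a few percent by cardiac blood volume, breathing
translation of a few pixels, sensor noise, 8-bit quantization, and a
synchronously sampled single-lead ECG with known R-peak times.  Every
frame follows the closed-form generative equation

    frame(p, t) = quantize( [texture * (1 - depth * pulse(t))](p - offset(t))
                            * gain(p) + noise )

so the configured depth map, pulse template, R-times and offsets ARE the
ground truth against which each pipeline stage is checked.

The default pulse template is band-limited (two harmonics of the heart
rate) and normalized to unit peak-to-peak: a cardiac pulse is smooth,
and keeping its spectrum inside the pipeline's 4 Hz analysis band makes
the closed-form expected APC (depth x 100) exact rather than
filter-dependent.  A sharper upstroke+exponential-decay template is
available for qualitative experiments.  Pulses are laid out in absolute
time from each R-peak (nominal-period clock, clamped at cycle end):
pulse extrema positions do not depend on cycle duration, which is what
makes R-gated ensemble averaging robust to heart-rate variability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_sync import EcgRecord, VideoSequence


@dataclass
class SceneConfig:
    """Spatial/acquisition side of the synthetic recording."""

    dims: tuple[int, int] = (128, 128)  # (height, width) px
    fps: float = 39.0
    duration: float = 15.0  # s
    mean_level: float = 180.0  # intensity levels
    texture_contrast: float = 25.0  # spatial SD, levels
    texture_smooth_px: float = 8.0  # correlation length of the texture
    texture_seed: int = 2024
    gain_field: np.ndarray | float | None = None  # static illumination multiplier
    depth_map: np.ndarray | float = 0.02  # peak-to-peak modulation fraction
    bit_depth: str = "float"  # "float" or "8"
    pixel_pitch_mm: float | None = 0.02

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth_map, dtype=float)
        if np.any(depth < 0) or np.any(depth > 0.05):
            raise ValueError("pulsatile depth must lie in [0, 0.05]")
        if self.gain_field is not None and np.any(np.asarray(self.gain_field) <= 0):
            raise ValueError("gain field must be strictly positive")
        if self.bit_depth not in ("float", "8"):
            raise ValueError("bit_depth must be 'float' or '8'")


@dataclass
class PhysioConfig:
    """Physiology and nuisance processes."""

    hr_bpm: float = 70.0
    hrv_frac: float = 0.0  # CV of the cycle duration
    pulse_template: str = "harmonic"  # or "upstroke_decay"
    resp_freq: float = 0.25  # Hz
    motion_amp: float = 0.0  # px, breathing translation amplitude
    motion_mode: str = "translation"
    noise_sigma: float = 0.0  # intensity levels
    ecg_snr_db: float | None = None  # None = clean ECG
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30.0 <= self.hr_bpm <= 200.0:
            raise ValueError("heart rate must lie in [30, 200] bpm")
        if self.motion_amp < 0 or self.hrv_frac < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.motion_mode not in ("translation", "affine"):
            raise ValueError("motion_mode must be 'translation' or 'affine'")


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    r_times: np.ndarray
    depth_map: np.ndarray
    offsets: np.ndarray  # (n_frames, 2): (dy, dx) true scene displacement
    expected_apc_map: np.ndarray  # percent, pixel lattice

    def expected_apc_rois(self, roi_size: int = 2) -> np.ndarray:
        """Ground-truth APC on the ROI lattice (block mean of the pixel map)."""
        h, w = self.expected_apc_map.shape
        nr, nc = h // roi_size, w // roi_size
        v = self.expected_apc_map[: nr * roi_size, : nc * roi_size]
        return v.reshape(nr, roi_size, nc, roi_size).mean(axis=(1, 3))


# ---------------------------------------------------------------------------
# pulse templates


def pulse_template(kind: str = "harmonic", n: int = 512) -> np.ndarray:
    """One-cycle pulse shape on [0, 1), normalized to unit peak-to-peak.

    'harmonic': two-harmonic band-limited pulse (default; spectrum stays
    inside the 4 Hz analysis band at intraoperative heart rates).
    'upstroke_decay': systolic rise over 20% of the cycle followed by an
    exponential decay — sharper, with energy above the analysis band.
    """
    u = np.arange(n) / n
    if kind == "harmonic":
        f = (1 - np.cos(2 * np.pi * u)) + 0.35 * (1 - np.cos(4 * np.pi * u - 0.9))
    elif kind == "upstroke_decay":
        rise = 0.20
        f = np.where(
            u < rise,
            0.5 * (1 - np.cos(np.pi * u / rise)),
            np.exp(-(u - rise) / 0.25) * (1 + (u - 1) * 0),
        )
        # close the cycle continuously back to the foot
        f = f * (1 - u**8)
    else:
        raise ValueError(f"unknown pulse template {kind!r}")
    f = f - f.min()
    return f / (f.max() - f.min())


def _template_lookup(template: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Evaluate the template at clamped phase u (absolute-time clock)."""
    u = np.clip(u, 0.0, 1.0 - 1e-9)
    idx = u * template.size
    i0 = np.floor(idx).astype(int) % template.size
    i1 = (i0 + 1) % template.size
    frac = idx - np.floor(idx)
    return template[i0] * (1 - frac) + template[i1] * frac


# ---------------------------------------------------------------------------
# ECG synthesis


def _draw_r_times(physio: PhysioConfig, duration: float,
                  rng: np.random.Generator) -> np.ndarray:
    t0_period = 60.0 / physio.hr_bpm
    times = [0.05 * t0_period]
    while times[-1] < duration:
        iv = t0_period * (1.0 + physio.hrv_frac * rng.standard_normal())
        iv = float(np.clip(iv, 0.31, 1.99))
        times.append(times[-1] + iv)
    return np.array(times[:-1]) if times[-1] >= duration else np.array(times)


def synth_ecg(
    physio: PhysioConfig,
    duration: float,
    fs: float = 1000.0,
    r_times: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[EcgRecord, np.ndarray]:
    """Synthetic single-lead ECG with known R-peak times.

    Each beat is a P wave, a narrow dominant R wave flanked by Q/S dips,
    and a broad T wave; optional white noise at ``ecg_snr_db`` relative
    to the clean signal RMS.  Returns the record and the true R times.
    """
    if rng is None:
        rng = np.random.default_rng(physio.seed)
    if r_times is None:
        r_times = _draw_r_times(physio, duration, rng)
    t = np.arange(int(round(duration * fs))) / fs
    x = np.zeros_like(t)

    def gauss(center, amp, sigma):
        nonlocal x
        lo = np.searchsorted(t, center - 5 * sigma)
        hi = np.searchsorted(t, center + 5 * sigma)
        x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)

    for r in r_times:
        gauss(r - 0.180, 0.12, 0.025)   # P
        gauss(r - 0.025, -0.12, 0.010)  # Q
        gauss(r, 1.00, 0.008)           # R
        gauss(r + 0.025, -0.20, 0.010)  # S
        gauss(r + 0.300, 0.30, 0.060)   # T
    if physio.ecg_snr_db is not None:
        rms = np.sqrt(np.mean(x**2))
        sigma = rms / 10 ** (physio.ecg_snr_db / 20.0)
        x = x + sigma * rng.standard_normal(x.size)
    return EcgRecord(samples=x, fs=fs, t0_offset=0.0), np.asarray(r_times)


# ---------------------------------------------------------------------------
# scene synthesis


def make_texture(scene: SceneConfig) -> np.ndarray:
    """Smooth positive reflectance texture with the configured statistics."""
    rng = np.random.default_rng(scene.texture_seed)
    base = rng.standard_normal(scene.dims)
    tex = ndimage.gaussian_filter(base, scene.texture_smooth_px, mode="wrap")
    tex = tex / tex.std() * scene.texture_contrast + scene.mean_level
    return np.clip(tex, 0.15 * scene.mean_level, 250.0)


def _phase_from_r_times(frame_times: np.ndarray, r_times: np.ndarray,
                        nominal_period: float) -> np.ndarray:
    """Absolute-time pulse clock: (t - last R) / nominal period, clamped."""
    idx = np.clip(np.searchsorted(r_times, frame_times, side="right") - 1,
                  0, r_times.size - 1)
    u = (frame_times - r_times[idx]) / nominal_period
    before_first = frame_times < r_times[0]
    # before the first beat, run the clock backward from R_0
    u = np.where(before_first, 1.0 + (frame_times - r_times[0]) / nominal_period, u)
    return np.clip(u, 0.0, 1.0)


def generate_recording(
    scene: SceneConfig,
    physio: PhysioConfig,
) -> tuple[VideoSequence, EcgRecord, GroundTruth]:
    """Generate a synchronized video + ECG pair with full ground truth.

    Deterministic under ``physio.seed`` (timing/noise) and
    ``scene.texture_seed`` (reflectance pattern).
    """
    rng = np.random.default_rng(physio.seed)
    h, w = scene.dims
    n_frames = int(round(scene.duration * scene.fps))
    frame_times = np.arange(n_frames) / scene.fps

    texture = make_texture(scene)
    depth = np.broadcast_to(np.asarray(scene.depth_map, dtype=float), scene.dims).copy()
    gain = (np.ones(scene.dims) if scene.gain_field is None
            else np.broadcast_to(np.asarray(scene.gain_field, float), scene.dims))

    if scene.bit_depth == "8":
        swing = depth * texture
        if np.any((swing > 0) & (swing < 1.0)):
            warnings.warn(
                "pulsatile swing below 1 LSB at 8 bits in part of the scene; "
                "recovery there relies entirely on noise dither",
                stacklevel=2,
            )

    r_times = _draw_r_times(physio, scene.duration, rng)
    template = pulse_template(physio.pulse_template)
    u = _phase_from_r_times(frame_times, r_times, 60.0 / physio.hr_bpm)
    pulse = _template_lookup(template, u)  # (n_frames,)

    # static fields that move together with the tissue
    a_field = texture  # baseline reflectance
    b_field = texture * depth  # pulsatile part

    offsets = np.zeros((n_frames, 2))
    if physio.motion_amp > 0:
        ph = 2 * np.pi * physio.resp_freq * frame_times
        offsets[:, 1] = physio.motion_amp * np.sin(ph)  # dx (columns)
        offsets[:, 0] = 0.6 * physio.motion_amp * np.sin(ph + 0.7)  # dy (rows)

    frames = np.empty((n_frames, h, w), dtype=np.float64)
    if physio.motion_amp > 0:
        # spline prefilter once; per-frame evaluation at shifted coordinates
        a_coef = ndimage.spline_filter(a_field, order=3, mode="mirror")
        b_coef = ndimage.spline_filter(b_field, order=3, mode="mirror")
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        for i in range(n_frames):
            coords = np.stack([rows - offsets[i, 0], cols - offsets[i, 1]])
            a_s = ndimage.map_coordinates(a_coef, coords, order=3,
                                          prefilter=False, mode="mirror")
            b_s = ndimage.map_coordinates(b_coef, coords, order=3,
                                          prefilter=False, mode="mirror")
            frames[i] = (a_s - pulse[i] * b_s) * gain
    else:
        frames[:] = (a_field[None] - pulse[:, None, None] * b_field[None]) * gain[None]

    if physio.noise_sigma > 0:
        frames += physio.noise_sigma * rng.standard_normal(frames.shape)
    if scene.bit_depth == "8":
        frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)

    video = VideoSequence(frames=frames, fps=scene.fps, timestamps=frame_times,
                          pixel_pitch_mm=scene.pixel_pitch_mm)
    ecg, _ = synth_ecg(physio, scene.duration, r_times=r_times, rng=rng)
    truth = GroundTruth(
        r_times=r_times,
        depth_map=depth,
        offsets=offsets,
        expected_apc_map=depth * 100.0,  # template has unit peak-to-peak
    )
    return video, ecg, truth
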