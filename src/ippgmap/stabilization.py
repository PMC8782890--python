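"""Segment-wise motion compensation by gradient optical flow.

Tissue in intraoperative video moves heterogeneously (respiration,
peristalsis, handling), so each frame is tiled into small segments
(default 8x8 px) whose motion is compensated independently.  Under
brightness constancy, a scene displaced by (dx, dy) changes pixel
intensity by -(Gx*dx + Gy*dy) to first order, with Gx, Gy the spatial
gradients of the reference image; the implied motion-related intensity
component is subtracted per pixel, leaving the blood-volume signal.

Camera intensity varies for two reasons — motion and blood volume — and
the estimator must not mistake one for the other.  Blood volume
modulates reflectance multiplicatively and near-uniformly within a
small segment, so the default estimator works on log-intensity with a
per-segment uniform-brightness nuisance term: the blood term is
absorbed by the nuisance exactly, and only spatial structure drives the
offset solution.  A pure two-parameter least-squares on raw intensity
(no nuisance term) is kept as an option; it is exact for noiseless
rigid shifts of static scenes but leaks part of any global intensity
modulation into the motion estimate.

Two estimation routes exist: direct frame-to-reference flow (accurate
while displacements stay within the ~2 px linearization range) and
accumulated inter-frame flow for larger excursions; ``mode='auto'``
switches to accumulation when the direct estimate leaves the linear
range anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .errors import SizeError
from .io_sync import VideoSequence

#: displacement (px) beyond which first-order brightness constancy is
#: unreliable and inter-frame accumulation takes over
MAX_LINEAR_PX = 2.0

#: intensity floor before the log transform (half of one 8-bit level)
_LOG_FLOOR = 0.5


@dataclass
class SegmentGrid:
    """Non-overlapping tiling of the frame into square segments.

    Margins not divisible by ``segment_size`` are dropped (top-left
    anchored), matching the ROI lattice convention.
    """

    segment_size: int
    shape: tuple[int, int]  # segments per (row, col)

    @property
    def n_segments(self) -> int:
        return self.shape[0] * self.shape[1]

    @property
    def covered(self) -> tuple[int, int]:
        """Pixel extent (height, width) covered by the tiling."""
        return (self.shape[0] * self.segment_size, self.shape[1] * self.segment_size)

    def origins(self) -> np.ndarray:
        """(n_segments, 2) array of top-left pixel coordinates (row, col)."""
        rr, cc = np.meshgrid(
            np.arange(self.shape[0]) * self.segment_size,
            np.arange(self.shape[1]) * self.segment_size,
            indexing="ij",
        )
        return np.stack([rr.ravel(), cc.ravel()], axis=1)


@dataclass
class MotionEstimate:
    """Per-segment, per-frame lateral offsets relative to the reference.

    ``dx``/``dy`` have shape (n_frames, seg_rows, seg_cols), in pixels;
    ``dx`` is the column (horizontal) displacement of the scene content,
    ``dy`` the row displacement.  ``valid`` flags segments/frames where
    the normal system was well-conditioned and the offset within
    ``max_shift``.
    """

    dx: np.ndarray
    dy: np.ndarray
    valid: np.ndarray


@dataclass
class StabilizedSignals:
    """Motion-corrected per-pixel signals.

    ``corrected + motion_component`` reproduces the raw frames exactly
    (conservation); ``segment_valid`` is True where the motion solution
    was trustworthy in every frame — downstream maps mask the rest.
    """

    corrected: np.ndarray
    motion_component: np.ndarray
    fps: float
    timestamps: np.ndarray
    segment_valid: np.ndarray
    grid: SegmentGrid


def build_segment_grid(height: int, width: int, segment_size: int = 8) -> SegmentGrid:
    if height < segment_size or width < segment_size:
        raise SizeError(
            f"image {height}x{width} smaller than one {segment_size}x{segment_size} segment"
        )
    if segment_size < 2:
        raise SizeError("segment_size must be at least 2")
    return SegmentGrid(segment_size=segment_size,
                       shape=(height // segment_size, width // segment_size))


def _block_sum(img: np.ndarray, grid: SegmentGrid) -> np.ndarray:
    """Sum over each segment; accepts (..., H, W), returns (..., sr, sc)."""
    s = grid.segment_size
    sr, sc = grid.shape
    v = img[..., : sr * s, : sc * s]
    v = v.reshape(*img.shape[:-2], sr, s, sc, s)
    return v.sum(axis=(-3, -1))


def _block_center(img: np.ndarray, grid: SegmentGrid) -> np.ndarray:
    """Subtract each segment's mean from its pixels (offset projection)."""
    s = grid.segment_size
    sr, sc = grid.shape
    out = np.array(img[..., : sr * s, : sc * s], dtype=np.float64)
    v = out.reshape(*img.shape[:-2], sr, s, sc, s)
    v -= v.mean(axis=(-3, -1), keepdims=True)
    return out


def _gradients(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gy, gx = np.gradient(ref.astype(np.float64))
    return gx, gy


def _normal_matrix(gx: np.ndarray, gy: np.ndarray, grid: SegmentGrid, cond_max: float):
    sxx = _block_sum(gx * gx, grid)
    sxy = _block_sum(gx * gy, grid)
    syy = _block_sum(gy * gy, grid)
    tr = sxx + syy
    disc = np.sqrt(np.maximum((sxx - syy) ** 2 + 4 * sxy**2, 0.0))
    lam_min = (tr - disc) / 2.0
    lam_max = (tr + disc) / 2.0
    det = sxx * syy - sxy**2
    ok = (lam_min > 1e-12) & (lam_max <= cond_max * np.maximum(lam_min, 1e-30))
    safe_det = np.where(ok, det, 1.0)
    return safe_det, ok, sxx, sxy, syy


def _solve_offsets(gx, gy, grid, it, cond_max, *, centered):
    """Per-segment LS solution of Gx*dx + Gy*dy [+ e] = -It.

    ``it`` has shape (n_frames, H, W).  With ``centered`` the gradients
    and temporal differences are segment-mean-centered first, which
    projects out a uniform per-segment brightness term.
    """
    if centered:
        gx = _block_center(gx, grid)
        gy = _block_center(gy, grid)
        it = _block_center(it, grid)
    det, ok, sxx, sxy, syy = _normal_matrix(gx, gy, grid, cond_max)
    bx = -_block_sum(gx[None] * it if gx.ndim == 2 else gx * it, grid)
    by = -_block_sum(gy[None] * it if gy.ndim == 2 else gy * it, grid)
    dx = (syy[None] * bx - sxy[None] * by) / det[None]
    dy = (sxx[None] * by - sxy[None] * bx) / det[None]
    dx = np.where(ok[None], dx, 0.0)
    dy = np.where(ok[None], dy, 0.0)
    return dx, dy, ok


def _flow_image(img: np.ndarray, invariant: bool) -> np.ndarray:
    """Domain in which flow is estimated: log-intensity by default."""
    img = np.asarray(img, dtype=np.float64)
    if invariant:
        return np.log(np.maximum(img, _LOG_FLOOR))
    return img


def resolve_reference(video: VideoSequence,
                      reference: int | np.ndarray = 0) -> np.ndarray:
    """Reference image: a frame index or an explicit (already averaged) image."""
    if isinstance(reference, (int, np.integer)):
        return video.frames[int(reference)].astype(np.float64)
    ref = np.asarray(reference, dtype=np.float64)
    if ref.shape != video.frames.shape[1:]:
        raise SizeError("reference image shape does not match the frames")
    return ref


def estimate_offsets(
    video: VideoSequence,
    grid: SegmentGrid,
    reference: int | np.ndarray = 0,
    *,
    cond_max: float = 1e3,
    max_shift: float = 16.0,
    mode: str = "auto",
    ref_span: tuple[int, int] | None = None,
    illumination_invariant: bool = True,
    smooth_hz: float | None = 1.5,
) -> MotionEstimate:
    """Per-segment lateral offsets of every frame relative to the reference.

    Parameters
    ----------
    reference : int or ndarray
        Frame index, or a reference image (e.g. the temporal mean of the
        first cardiac cycle, which is what the pipeline passes).
    mode : {'auto', 'direct', 'accumulate'}
        'direct' solves frame-to-reference flow; 'accumulate' integrates
        inter-frame flow (for displacements beyond the linear range);
        'auto' starts direct and falls back to accumulation when any
        direct offset exceeds the ~2 px linearization range.
    ref_span : (start, stop), optional
        Frame range the reference image was averaged over; accumulated
        offsets are taken relative to the mean position over this span.
        Defaults to frame 0 (or the index given as ``reference``).
    illumination_invariant : bool
        Estimate on log-intensity with a per-segment uniform-brightness
        nuisance term (default).  With False, solve the bare
        two-parameter system on raw intensity — exact for rigid shifts
        of static scenes, but global intensity modulation (blood volume)
        then leaks into the offsets.
    smooth_hz : float or None
        Zero-phase low-pass applied to the offset traces.  Tissue bulk
        motion (respiration, peristalsis, handling) lives well below
        ~1 Hz; band-limiting the compensator passes it with margin while
        rejecting broadband estimator noise, and keeping the band below
        the cardiac fundamental guarantees stabilization cannot subtract
        genuine pulsatile signal.  None disables smoothing.
    """
    if mode not in ("auto", "direct", "accumulate"):
        raise ValueError(f"unknown mode {mode!r}")
    ref = resolve_reference(video, reference)
    fref = _flow_image(ref, illumination_invariant)
    gx, gy = _gradients(fref)
    fframes = _flow_image(video.frames, illumination_invariant)

    if mode in ("auto", "direct"):
        dx, dy, ok = _solve_offsets(gx, gy, grid, fframes - fref[None], cond_max,
                                    centered=illumination_invariant)
        direct_ok = np.max(np.hypot(dx, dy), initial=0.0) <= MAX_LINEAR_PX
        if mode == "direct" or direct_ok:
            dx, dy = _smooth_traces(dx, dy, video.fps, smooth_hz)
            valid = ok[None] & (np.hypot(dx, dy) <= max_shift)
            return MotionEstimate(dx=dx, dy=dy, valid=valid)

    # accumulate inter-frame flow: each step is far inside the linear range
    n = video.n_frames
    sr, sc = grid.shape
    step_dx = np.zeros((n, sr, sc))
    step_dy = np.zeros((n, sr, sc))
    step_ok = np.ones((sr, sc), dtype=bool)
    for t in range(1, n):
        g_img = 0.5 * (fframes[t - 1] + fframes[t])
        gxs, gys = _gradients(g_img)
        d1, d2, okt = _solve_offsets(gxs, gys, grid,
                                     (fframes[t] - fframes[t - 1])[None], cond_max,
                                     centered=illumination_invariant)
        step_dx[t], step_dy[t] = d1[0], d2[0]
        step_ok &= okt
    cum_dx = np.cumsum(step_dx, axis=0)
    cum_dy = np.cumsum(step_dy, axis=0)
    if ref_span is None:
        r0 = int(reference) if isinstance(reference, (int, np.integer)) else 0
        ref_span = (r0, r0 + 1)
    a, b = ref_span
    dx = cum_dx - cum_dx[a:b].mean(axis=0)[None]
    dy = cum_dy - cum_dy[a:b].mean(axis=0)[None]
    dx, dy = _smooth_traces(dx, dy, video.fps, smooth_hz)
    # conditioning of the reference gradients governs where subtraction works
    _, ok_ref, *_ = _normal_matrix(
        *(_block_center(g, grid) for g in (gx, gy)) if illumination_invariant
        else (gx, gy), grid, cond_max
    )
    valid = ok_ref[None] & step_ok[None] & (np.hypot(dx, dy) <= max_shift)
    return MotionEstimate(dx=dx, dy=dy, valid=valid)


def _smooth_traces(dx: np.ndarray, dy: np.ndarray, fps: float,
                   smooth_hz: float | None):
    """Zero-phase low-pass of the per-segment offset traces."""
    if smooth_hz is None or smooth_hz >= fps / 2:
        return dx, dy
    b, a = sps.butter(2, smooth_hz / (fps / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if dx.shape[0] <= padlen:
        return dx, dy
    return (sps.filtfilt(b, a, dx, axis=0), sps.filtfilt(b, a, dy, axis=0))


def remove_motion_component(
    video: VideoSequence,
    estimate: MotionEstimate,
    grid: SegmentGrid,
    reference: int | np.ndarray = 0,
    *,
    method: str = "warp",
) -> StabilizedSignals:
    """Subtract the motion-related intensity component per pixel.

    The motion component at pixel p of segment s in frame t is the
    intensity change the segment's lateral offset (dx, dy) causes there.
    With ``method='warp'`` (default) it is the difference between the
    frame and the frame resampled back to the reference position,
    ``raw(p) - raw(p + d)`` by spline interpolation — segment-wise rigid
    registration expressed as a subtraction, accurate for the
    several-pixel excursions breathing produces and exact in the sense
    that the blood-volume modulation, which moves with the tissue, is
    untouched.  With ``method='linear'`` the first-order form
    ``-(Gx(p) * dx + Gy(p) * dy)`` is used, with Gx, Gy the
    reference-frame gradients (adequate below ~2 px).  Where the
    estimate is invalid the component is zero and the segment is
    flagged for masking.
    """
    if method not in ("warp", "linear"):
        raise ValueError(f"unknown subtraction method {method!r}")
    s = grid.segment_size
    sr, sc = grid.shape

    dx = np.where(estimate.valid, estimate.dx, 0.0)
    dy = np.where(estimate.valid, estimate.dy, 0.0)
    # expand per-segment offsets to pixel resolution
    dx_px = np.repeat(np.repeat(dx, s, axis=1), s, axis=2)
    dy_px = np.repeat(np.repeat(dy, s, axis=1), s, axis=2)
    h_cov, w_cov = sr * s, sc * s

    motion = np.zeros(video.frames.shape, dtype=np.float64)
    if method == "linear":
        ref = resolve_reference(video, reference)
        gx, gy = _gradients(ref)
        motion[:, :h_cov, :w_cov] = -(
            gx[None, :h_cov, :w_cov] * dx_px + gy[None, :h_cov, :w_cov] * dy_px
        )
    else:
        # align to the mean tissue position over the record: the estimate
        # is reference-relative, but the canonical resting position of the
        # scene is its temporal mean (a per-segment constant shift of the
        # target only adds a static field, invisible after AC/DC)
        dx_px = dx_px - dx_px.mean(axis=0, keepdims=True)
        dy_px = dy_px - dy_px.mean(axis=0, keepdims=True)
        rows, cols = np.meshgrid(np.arange(h_cov, dtype=float),
                                 np.arange(w_cov, dtype=float), indexing="ij")
        for t in range(video.n_frames):
            if not (np.any(dx_px[t]) or np.any(dy_px[t])):
                continue
            frame = video.frames[t].astype(np.float64)
            coords = np.stack([rows + dy_px[t], cols + dx_px[t]])
            aligned = ndimage.map_coordinates(frame, coords, order=3,
                                              mode="mirror")
            motion[t, :h_cov, :w_cov] = frame[:h_cov, :w_cov] - aligned
    raw = video.frames.astype(np.float64)
    corrected = raw - motion
    # store the realized difference so corrected + motion_component == raw
    # bit-exactly (the subtraction of two nearby doubles is exact)
    return StabilizedSignals(
        corrected=corrected,
        motion_component=raw - corrected,
        fps=video.fps,
        timestamps=video.timestamps,
        segment_valid=estimate.valid.all(axis=0),
        grid=grid,
    )
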