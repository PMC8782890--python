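"""Perfusion maps: assembly, regional statistics, overlays, serialization.

The per-ROI APC values form a 2-D perfusion map on the ROI lattice.
Regional means over large (default 60x60-pixel) windows mirror the way
perfusion gradients are reported clinically, including the
percent-of-maximum convention; overlays pseudo-color the map (blue =
low, red = high perfusion) on the grayscale tissue frame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib import colormaps

from .errors import ConfigError, ConsistencyError, EmptyRegionError
from .ppg_extraction import RoiGrid
from .pulse_analysis import MeanPulse, compute_apc

#: mask reason codes
REASONS = {0: "valid", 1: "motion_ill_conditioned", 2: "dc_nonpositive",
           3: "insufficient_cycles", 4: "unprocessed"}

DEFAULT_CMAP = "jet"  # blue -> red, low -> high perfusion


@dataclass
class PerfusionMap:
    """APC (percent) on the ROI lattice with a validity mask."""

    apc: np.ndarray
    mask: np.ndarray  # True = valid
    reason: np.ndarray  # int codes per REASONS
    roi_size: int = 2
    sync: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.apc.shape != self.mask.shape or self.apc.shape != self.reason.shape:
            raise ConsistencyError("apc, mask and reason lattices disagree")


@dataclass
class RegionStats:
    """Mean +/- SD of APC over the valid ROIs of a region."""

    mean: float
    sd: float
    n_roi: int
    region: str = ""

    def to_dict(self) -> dict:
        return {"region": self.region, "mean_pct": self.mean,
                "sd_pct": self.sd, "n_roi": self.n_roi}


def build_map(
    mean_pulse: MeanPulse,
    grid: RoiGrid,
    roi_valid: np.ndarray | None = None,
    reason: np.ndarray | None = None,
    meta: dict | None = None,
) -> PerfusionMap:
    """Assemble the APC map from a lattice-shaped mean pulse.

    ``mean_pulse.values`` must have shape (pulse_len, roi_rows, roi_cols)
    matching ``grid.shape``; ``roi_valid`` masks ROIs invalidated
    upstream (motion, non-positive DC).
    """
    if mean_pulse.values.shape[1:] != grid.shape:
        raise ConsistencyError(
            f"mean-pulse lattice {mean_pulse.values.shape[1:]} does not "
            f"match ROI grid {grid.shape}"
        )
    apc = np.asarray(compute_apc(mean_pulse), dtype=float)
    mask = np.ones(grid.shape, dtype=bool) if roi_valid is None else roi_valid.copy()
    rs = np.zeros(grid.shape, dtype=int) if reason is None else reason.copy()
    apc = np.where(mask, apc, np.nan)
    sync = mean_pulse.sync
    if isinstance(sync, np.ndarray):
        sync = np.where(mask, sync, np.nan)
    m = {"n_cycles": mean_pulse.n_cycles}
    m.update(meta or {})
    return PerfusionMap(apc=apc, mask=mask, reason=rs, roi_size=grid.roi_size,
                        sync=sync, meta=m)


def _stats_over(apc: np.ndarray, sel: np.ndarray, region: str) -> RegionStats:
    vals = apc[sel]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise EmptyRegionError(f"region {region or '<mask>'} holds no valid ROI")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return RegionStats(mean=float(np.mean(vals)), sd=sd, n_roi=int(vals.size),
                       region=region)


def aggregate_region(pmap: PerfusionMap, center: tuple[int, int],
                     size_px: int = 60) -> RegionStats:
    """Mean/SD of APC in a square window of ``size_px`` pixels on a side.

    ``center`` is in ROI coordinates (row, col); a 60x60-pixel window is
    30x30 ROIs at the default 2-px ROI size.  SD is the sample standard
    deviation (ddof=1).
    """
    half = max(size_px // pmap.roi_size, 1) // 2
    r0 = max(center[0] - half, 0)
    c0 = max(center[1] - half, 0)
    r1 = min(center[0] + half + (size_px // pmap.roi_size) % 2, pmap.apc.shape[0])
    c1 = min(center[1] + half + (size_px // pmap.roi_size) % 2, pmap.apc.shape[1])
    sel = np.zeros_like(pmap.mask)
    sel[r0:r1, c0:c1] = True
    sel &= pmap.mask
    return _stats_over(pmap.apc, sel, region=f"win{size_px}px@({center[0]},{center[1]})")


def region_report(pmap: PerfusionMap, region: np.ndarray,
                  name: str = "") -> RegionStats:
    """Mean/SD of APC over an arbitrary boolean ROI-lattice mask."""
    region = np.asarray(region, dtype=bool)
    if region.shape != pmap.apc.shape:
        raise ConsistencyError("region mask does not match the map lattice")
    return _stats_over(pmap.apc, region & pmap.mask, region=name)


def relative_percent(stats: list[RegionStats]) -> list[float]:
    """Each region's mean as percent of the maximum region mean.

    Exactly one region reports 100 (ties broken by first occurrence).
    """
    means = np.array([s.mean for s in stats], dtype=float)
    if means.size == 0 or np.max(means) <= 0:
        raise EmptyRegionError("relative percentages need at least one region "
                               "with positive mean APC")
    top = float(np.max(means))
    out = (means / top * 100.0).tolist()
    # pin the first maximal region to exactly 100
    out[int(np.argmax(means))] = 100.0
    return out


def colorize(pmap: PerfusionMap, vrange: tuple[float, float] | None = None,
             cmap: str = DEFAULT_CMAP) -> np.ndarray:
    """RGBA (float, 0-1) rendering of the map at ROI resolution.

    Masked ROIs come out fully transparent.  Exposed separately so
    overlay pixels can be checked against direct colormap evaluation.
    """
    if vrange is None:
        finite = pmap.apc[np.isfinite(pmap.apc)]
        vrange = (0.0, float(finite.max()) if finite.size else 1.0)
    lo, hi = vrange
    if lo >= hi:
        raise ConfigError(f"color range lower bound {lo} must be below upper {hi}")
    norm = np.clip((np.nan_to_num(pmap.apc, nan=lo) - lo) / (hi - lo), 0.0, 1.0)
    rgba = colormaps[cmap](norm)
    rgba[..., 3] = np.where(pmap.mask, 1.0, 0.0)
    return rgba


def render_overlay(
    pmap: PerfusionMap,
    background: np.ndarray,
    path: str | Path,
    *,
    alpha: float = 0.6,
    vrange: tuple[float, float] | None = None,
    cmap: str = DEFAULT_CMAP,
) -> None:
    """Alpha-blend the pseudo-color map on the grayscale frame, save PNG.

    The map is upsampled nearest-neighbor (each ROI an ``roi_size``
    square block) so no fake sub-ROI resolution is painted; a color bar
    spans the configured range.
    """
    background = np.asarray(background)
    nr, nc = pmap.apc.shape
    if background.shape[0] < nr * pmap.roi_size or background.shape[1] < nc * pmap.roi_size:
        raise ConsistencyError("background smaller than the map footprint")
    rgba = colorize(pmap, vrange=vrange, cmap=cmap)
    rgba[..., 3] *= alpha
    up = np.repeat(np.repeat(rgba, pmap.roi_size, axis=0), pmap.roi_size, axis=1)

    if vrange is None:
        finite = pmap.apc[np.isfinite(pmap.apc)]
        vrange = (0.0, float(finite.max()) if finite.size else 1.0)
    fig, ax = plt.subplots(figsize=(6, 6 * background.shape[0] / background.shape[1]))
    ax.imshow(background, cmap="gray", vmin=0,
              vmax=255 if np.issubdtype(background.dtype, np.integer) else None)
    ax.imshow(up, extent=(-0.5, up.shape[1] - 0.5, up.shape[0] - 0.5, -0.5))
    ax.set_axis_off()
    sm = plt.cm.ScalarMappable(cmap=cmap,
                               norm=plt.Normalize(vmin=vrange[0], vmax=vrange[1]))
    fig.colorbar(sm, ax=ax, orientation="horizontal", fraction=0.05, pad=0.02,
                 label="APC, %")
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# serialization


def write_map_csv(pmap: PerfusionMap, path: str | Path) -> None:
    np.savetxt(path, pmap.apc, delimiter=",", fmt="%.6g")


def write_map_tiff(pmap: PerfusionMap, path: str | Path) -> None:
    tifffile.imwrite(path, pmap.apc.astype(np.float32))


def write_region_stats(stats: list[RegionStats], path: str | Path,
                       extra: dict | None = None) -> None:
    payload = {"regions": [s.to_dict() for s in stats]}
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2))
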