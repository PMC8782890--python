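"""Shared fixtures: small ground-truthed synthetic recordings."""

import numpy as np
import pytest

from ippgmap import PhysioConfig, SceneConfig, generate_recording


@pytest.fixture(scope="session")
def small_uniform_recording():
    """64x64, 12 s, uniform 1% depth, float, no motion/noise."""
    scene = SceneConfig(dims=(64, 64), duration=12.0, depth_map=0.01)
    physio = PhysioConfig(hr_bpm=70, seed=11)
    return generate_recording(scene, physio)


@pytest.fixture(scope="session")
def small_motion_recording():
    """64x64, 12 s, uniform 1% depth, 2-px breathing translation."""
    scene = SceneConfig(dims=(64, 64), duration=12.0, depth_map=0.01)
    physio = PhysioConfig(hr_bpm=70, seed=12, motion_amp=2.0)
    return generate_recording(scene, physio)


@pytest.fixture(scope="session")
def static_texture_video():
    """Static textured scene (no pulsation, no motion, no noise)."""
    scene = SceneConfig(dims=(64, 64), duration=8.0, depth_map=0.0)
    physio = PhysioConfig(hr_bpm=70, seed=13)
    video, _, _ = generate_recording(scene, physio)
    return video


def zone_depth_map(dims=(128, 128), depths=(0.005, 0.01, 0.02, 0.03)):
    """Horizontal bands of increasing pulsatile depth."""
    h, w = dims
    band = h // len(depths)
    out = np.zeros(dims)
    for i, d in enumerate(depths):
        out[i * band: (i + 1) * band, :] = d
    return out
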