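"""Shared fixtures: hand-built segments and a small synthetic dataset."""

from __future__ import annotations

import numpy as np
import pytest

from swarmflight.segmentation import Segment
from swarmflight.simulate import ClassParams, SimConfig, simulate


def make_segment(positions, times=None, label="male", segment_id="s0") -> Segment:
    """Wrap raw arrays in a Segment (25 Hz default clock)."""
    positions = np.asarray(positions, dtype=float)
    if times is None:
        times = np.arange(len(positions)) * 0.04
    times = np.asarray(times, dtype=float)
    return Segment(
        segment_id=segment_id,
        track_id="trk0",
        trial_id="tr0",
        label=label,
        positions=positions,
        times=times,
        window_s=float(times[-1] - times[0]),
        overlap_s=0.0,
        start=0,
        stop=len(times),
    )


def circle_segment(radius=0.5, omega=2.5, n=41, dt=0.04, z=0.0) -> Segment:
    """Uniform circular motion in the XY plane."""
    t = np.arange(n) * dt
    pos = np.column_stack(
        [radius * np.cos(omega * t), radius * np.sin(omega * t), np.full(n, z)]
    )
    return make_segment(pos, t)


def small_sim_config(seed=0, **overrides) -> SimConfig:
    """A fast, reduced-size simulation for unit tests."""
    defaults = dict(
        male=ClassParams(4, 4, 10.0, 2.0, 6.0, 0.0),
        couple=ClassParams(3, 5, 6.0, 1.0, 4.0, 1.0),
        female=ClassParams(1, 3, 5.0, 1.0, 4.0, 1.2),
        focal_male=ClassParams(1, 2, 6.0, 1.0, 5.0, 0.0),
    )
    defaults.update(overrides)
    return SimConfig(seed=seed, **defaults)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate(small_sim_config(seed=42))


@pytest.fixture(scope="session")
def small_matrix(small_dataset):
    from swarmflight.features import build_feature_matrix
    from swarmflight.segmentation import window_dataset
    from swarmflight.tracks import filter_short_tracks

    filtered = filter_short_tracks(small_dataset, 1.6)
    return build_feature_matrix(window_dataset(filtered, 1.6, 0.8))
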