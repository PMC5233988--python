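"""Shared fixtures and brute-force reference implementations.

The reference functions are deliberately naive double loops over frames
and particles; they serve as independent oracles for the vectorised
metrics code.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from nkaproton.states import default_registry
from nkaproton.trajectory import MetricWindow, Particle, Trajectory


@pytest.fixture(scope="session")
def registry():
    return default_registry()


def make_traj(ion_frames, water_frames=None, times=None, box=None) -> Trajectory:
    """Build a trajectory from explicit per-frame ion/water coordinates.

    ion_frames: (F, n_ion, 3); water_frames: (F, n_water, 3) or None.
    """
    ion_frames = np.asarray(ion_frames, dtype=float)
    F, n_ion = ion_frames.shape[:2]
    parts = [Particle(f"SOD:{i+1}:NA", "ion") for i in range(n_ion)]
    coords = ion_frames
    if water_frames is not None:
        water_frames = np.asarray(water_frames, dtype=float)
        coords = np.concatenate([ion_frames, water_frames], axis=1)
        parts += [Particle(f"HOH:{k+1}:OH2", "water_oxygen")
                  for k in range(water_frames.shape[1])]
    if times is None:
        times = np.arange(F, dtype=float)
    return Trajectory(coords=coords, times=np.asarray(times, dtype=float),
                      particles=tuple(parts), box=box)


def full_window(traj: Trajectory) -> MetricWindow:
    return MetricWindow(float(traj.times[0]), float(traj.times[-1]))


# ---------------------------------------------------------------------------
# brute-force oracles

def brute_rmsf(traj: Trajectory, window: MetricWindow) -> tuple[list, float]:
    mask = window.frame_mask(traj)
    frames = [f for f, m in enumerate(mask) if m]
    out = []
    for i in traj.ion_indices:
        mean = [sum(traj.coords[f, i, k] for f in frames) / len(frames)
                for k in range(3)]
        acc = 0.0
        for f in frames:
            acc += sum((traj.coords[f, i, k] - mean[k]) ** 2 for k in range(3))
        out.append(math.sqrt(acc / len(frames)))
    return out, sum(out) / len(out)


def _mic_dist(a, b, box):
    d = [a[k] - b[k] for k in range(3)]
    if box is not None:
        d = [d[k] - box[k] * round(d[k] / box[k]) for k in range(3)]
    return math.sqrt(sum(x * x for x in d))


def brute_nwater(traj: Trajectory, cutoff: float,
                 window: MetricWindow) -> tuple[list, float]:
    mask = window.frame_mask(traj)
    counts = []
    box = None if traj.box is None else list(traj.box)
    for f, m in enumerate(mask):
        if not m:
            continue
        n = 0
        for w in traj.water_indices:
            for i in traj.ion_indices:
                if _mic_dist(traj.coords[f, w], traj.coords[f, i], box) <= cutoff:
                    n += 1
                    break
        counts.append(n)
    return counts, sum(counts) / len(counts)
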