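"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cinpop import imaging_events as ie
from cinpop import synthgen as sg


def match_events(truth, raster, tol: int = 1) -> int:
    """Greedy one-to-one matching of inferred to true event frames.

    A true event counts as recovered if an unused inferred event lies within
    ``tol`` frames (a spike near a frame boundary registers its rise one
    frame late).
    """
    tp = 0
    for i in range(truth.n_cells):
        rf = list(raster.event_frames(i))
        for f in truth.event_frames(i):
            hits = sorted((abs(g - f), g) for g in rf if abs(g - f) <= tol)
            if hits:
                tp += 1
                rf.remove(hits[0][1])
    return tp


def resolvable_trains(n_cells: int, rate: float, duration: float, fps: float,
                      seed: int, min_isi: float = 0.25) -> list[sg.SpikeTrain]:
    """Irregular trains thinned to a minimum ISI and snapped to frame
    centres, so every spike is resolvable by the imaging pipeline."""
    return [
        sg.snap_to_frame_centers(
            sg.enforce_min_isi(
                sg.make_spike_train("irregular", rate, 1.0, duration,
                                    seed=seed * 1000 + i), min_isi), fps)
        for i in range(n_cells)
    ]


@pytest.fixture
def noiseless_scenario():
    """10 cells x 100 s at 10 fps, frame-resolvable spikes, no noise."""
    trains = resolvable_trains(10, 1.5, 100.0, 10.0, seed=11)
    return sg.ImagingScenario(10, 100.0, 10.0, trains, noise_sd=0.0, seed=11)


@pytest.fixture
def small_raster():
    """3 cells x 12 frames with a known coactive frame."""
    A = np.zeros((3, 12), dtype=int)
    A[:, 5] = 1
    A[0, 2] = 1
    A[2, 9] = 1
    return ie.EventRaster(A, fps=10.0)


def spontaneous_sweep(p: sg.APShapeParams, spike_times, duration: float,
                      fs: float = 50_000.0):
    ms = sg.MembraneScenario(ap_shape=p)
    return sg.simulate_spontaneous(ms, np.asarray(spike_times), duration, fs)
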