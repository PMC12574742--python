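"""Shared fixtures: simulated walks reused across test modules."""

from dataclasses import replace

import numpy as np
import pytest

import gaitkeo as gk


@pytest.fixture(scope="session")
def quiet_walk():
    """Noiseless 60 s walk, default gait parameters, seed 7."""
    return gk.simulate_gait(gk.GaitSimConfig(seed=7, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_walk():
    """60 s walk at 10 dB SNR, seed 7."""
    base = gk.GaitSimConfig(seed=7)
    sd = gk.noise_sd_for_snr(base, 10.0)
    return gk.simulate_gait(replace(base, noise_sd=sd))


@pytest.fixture(scope="session")
def snr10_noise_sd():
    return gk.noise_sd_for_snr(gk.GaitSimConfig(), 10.0)


def nearest_errors(detected: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """|detected − nearest truth| for each detected time."""
    detected = np.asarray(detected, dtype=float)
    truth = np.asarray(truth, dtype=float)
    return np.array([np.min(np.abs(truth - t)) for t in detected])


def within_truth_span(times, truth, margin_s: float = 0.02):
    """Drop detections outside the scored window.

    Boundary strides that begin before (or end after) the recording produce
    real events near its edges which the ground-truth list of *complete*
    strides does not carry; they are trimmed before scoring, as validation
    protocols do with partial strides.
    """
    times = np.asarray(times, dtype=float)
    lo, hi = np.min(truth) - margin_s, np.max(truth) + margin_s
    return times[(times >= lo) & (times <= hi)]


def recovery_rate(walk, events: gk.EventSeries, side: str, tol_s: float) -> float:
    """Fraction of true IC+FC events matched by a detection within tol_s."""
    hits = total = 0
    for etype, truth in (
        ("IC", walk.truth.ic_times[side]),
        ("FC", walk.truth.fc_times[side]),
    ):
        det = np.array([e.time_s for e in events.events if e.type == etype])
        for t in truth:
            total += 1
            if det.size and np.min(np.abs(det - t)) <= tol_s:
                hits += 1
    return hits / total
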