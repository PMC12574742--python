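"""Coordinate-based gait events from motion capture (the reference arm).

The Zeni coordinate method places initial contact where the foot is most
anterior relative to the pelvis and final contact where it is most
posterior.  Here a single ankle-cluster point per side substitutes for the
classic heel/toe markers for both events — a deliberate simplification that
shifts both events by a roughly constant offset relative to heel/toe timing
but leaves stance-duration differences essentially unbiased.

Because the ankle coordinate is taken relative to the pelvis, overground
walking needs no detrending: forward progression cancels in the relative
coordinate.  Extrema are refined by parabolic interpolation through the
three frames around each peak, since at 120 Hz the frame quantum (8.3 ms)
is not negligible against sub-centisecond timing agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_io import (
    DataError,
    DetectionError,
    EventSeries,
    GaitEvent,
    MarkerTrajectories,
    ParameterError,
)
from .tkeo import compute_stance, estimate_cycle_duration

MAX_INTERP_GAP_FRAMES = 10


@dataclass(frozen=True)
class RelativeApSeries:
    """Ankle minus pelvis anterior-posterior position per frame (meters).

    Positive values mean the ankle is anterior to the pelvis in the walking
    direction.  Frames inside gaps longer than 10 frames are NaN; shorter
    gaps have been linearly interpolated.
    """

    values: np.ndarray
    frame_rate: float
    side: str
    walking_direction_sign: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if not self.frame_rate > 0:
            raise ParameterError("frame rate must be positive")
        if self.walking_direction_sign not in (-1.0, 1.0):
            raise ParameterError("walking_direction_sign must be -1 or +1")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.frame_rate


def _interpolate_short_gaps(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linearly fill gaps of <= MAX_INTERP_GAP_FRAMES frames; longer stay NaN."""
    out = np.where(valid, values, np.nan)
    idx = np.flatnonzero(~valid)
    if idx.size == 0:
        return out
    # contiguous runs of invalid frames
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    for run in np.split(idx, splits):
        a, b = run[0] - 1, run[-1] + 1
        if run.size <= MAX_INTERP_GAP_FRAMES and a >= 0 and b < values.size and valid[a] and valid[b]:
            out[run] = np.interp(run, [a, b], [values[a], values[b]])
    return out


def relative_ap_displacement(
    markers: MarkerTrajectories,
    side: str,
    walking_direction_sign: float | None = None,
) -> RelativeApSeries:
    """Per-frame ankle − pelvis AP displacement along the walking direction.

    The walking axis is the first marker coordinate (fixed by the axis
    mapping at read time); the direction sign is taken from the net pelvis
    displacement unless declared.  With under 1 m of net pelvis travel the
    direction is ambiguous and must be declared.
    """
    if side not in ("left", "right"):
        raise ParameterError(f"side must be 'left' or 'right', got {side!r}")
    ankle_name = f"ankle_{side}"
    pelvis = markers.pelvis[:, 0]
    ankle = markers.marker(ankle_name)[:, 0]
    valid = markers.gap_mask["pelvis"] & markers.gap_mask[ankle_name]
    if valid.sum() < 2:
        raise DataError("fewer than 2 frames with both pelvis and ankle tracked")

    if walking_direction_sign is None:
        good = np.flatnonzero(markers.gap_mask["pelvis"])
        net = pelvis[good[-1]] - pelvis[good[0]]
        if abs(net) < 1.0:
            raise DataError(
                f"net pelvis displacement {net:.2f} m < 1 m: walking direction "
                "is ambiguous, declare walking_direction_sign"
            )
        walking_direction_sign = float(np.sign(net))

    rel = _interpolate_short_gaps(ankle - pelvis, valid) * walking_direction_sign
    return RelativeApSeries(
        values=rel,
        frame_rate=markers.frame_rate,
        side=side,
        walking_direction_sign=walking_direction_sign,
        start_time=markers.start_time,
    )


def _refine_extremum(values: np.ndarray, i: int) -> float:
    """Sub-frame peak location by a parabola through (i−1, i, i+1)."""
    if i <= 0 or i >= values.size - 1:
        return float(i)
    y0, y1, y2 = values[i - 1 : i + 2]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0 or not np.isfinite(denom):
        return float(i)
    delta = 0.5 * (y0 - y2) / denom
    return float(i + np.clip(delta, -0.5, 0.5))


def zeni_events(
    markers: MarkerTrajectories,
    side: str,
    walking_direction_sign: float | None = None,
    min_separation_frac: float = 0.5,
) -> EventSeries:
    """IC/FC events and stances from marker data for one side.

    IC = local maxima of the ankle-relative-to-pelvis AP series (ankle most
    anterior), FC = local minima (most posterior), each refined to sub-frame
    precision.  The minimum peak separation is ``min_separation_frac`` of
    the stride period estimated from the series' own autocorrelation.
    Stance per stride is the ipsilateral IC→FC interval; event times are
    seconds on the shared recording clock.
    """
    rel = relative_ap_displacement(markers, side, walking_direction_sign)
    values = rel.values
    finite = np.isfinite(values)
    if not finite.any():
        raise DataError("relative AP series has no valid frames")
    # treat long-gap NaN frames as the series mean so they host no extrema
    work = np.where(finite, values, np.nanmean(values))
    fr = rel.frame_rate

    class _Wrap:  # adapt to the autocorrelation estimator's trace interface
        samples = work
        ts = 1.0 / fr
        phi = None

    try:
        cycle_s = estimate_cycle_duration(_Wrap)
    except (DataError, DetectionError) as err:
        raise DetectionError(f"no gait periodicity in marker data: {err}") from err
    if work.size / fr < 2 * cycle_s:
        raise DataError("marker series spans fewer than 2 gait cycles")

    distance = max(1, int(round(min_separation_frac * cycle_s * fr)))
    amp = np.nanmax(values) - np.nanmin(values)
    prominence = 0.2 * amp if amp > 0 else None
    ic_idx, _ = sps.find_peaks(work, distance=distance, prominence=prominence)
    fc_idx, _ = sps.find_peaks(-work, distance=distance, prominence=prominence)
    ic_idx = ic_idx[finite[ic_idx]]
    fc_idx = fc_idx[finite[fc_idx]]
    if ic_idx.size < 2:
        raise DetectionError("fewer than 2 anterior extrema: no strides detectable")

    def _events(indices: np.ndarray, etype: str, series: np.ndarray) -> list[GaitEvent]:
        out = []
        for i in indices:
            pos = _refine_extremum(series, int(i))
            out.append(
                GaitEvent(
                    type=etype,
                    side=side,
                    time_s=float(rel.start_time + pos / fr),
                    sample_index=int(i),
                    peak_amplitude=float(values[i]),
                )
            )
        return out

    ics = _events(ic_idx, "IC", work)
    fcs = _events(fc_idx, "FC", -work)

    pairs: list[tuple[GaitEvent, GaitEvent]] = []
    used_fc: set[int] = set()
    for k, ic in enumerate(ics):
        next_ic_t = ics[k + 1].time_s if k + 1 < len(ics) else np.inf
        for j, fc in enumerate(fcs):
            if j in used_fc:
                continue
            if ic.time_s < fc.time_s < next_ic_t:
                pairs.append((ic, fc))
                used_fc.add(j)
                break
    unpaired = [e for e in ics if e not in {p[0] for p in pairs}]
    unpaired += [e for j, e in enumerate(fcs) if j not in used_fc]
    return compute_stance(pairs, params=None, extra_events=unpaired)
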