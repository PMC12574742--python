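"""Domain containers and tabular I/O for the gait pipeline.

Two concurrent measurement streams are handled:

* a single-axis anterior-posterior (AP) thigh acceleration trace per leg,
  nominally sampled at 50 Hz, and
* 3D marker-cluster trajectories (posterior pelvis, both lateral malleoli)
  from optical motion capture, nominally 120 Hz.

Both streams share one clock: sample ``i`` of a trace sits at
``start_time + i * ts`` seconds from recording start.  Any synchronization
offset between the two acquisition systems is expressed through
``start_time`` rather than by resampling.

Canonical acceleration unit is m/s²; inputs declared in g are converted on
read (1 g = 9.80665 m/s²).  Irregularly sampled input is rejected, not
resampled: the discrete energy operator downstream assumes a constant
sampling interval.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

G_TO_MS2 = 9.80665

MARKER_NAMES = ("pelvis", "ankle_left", "ankle_right")


class GaitError(Exception):
    """Base class for all domain errors raised by this package."""


class FormatError(GaitError):
    """Input file does not have the expected columns/structure."""


class DataError(GaitError):
    """Input data violates a precondition (non-monotone time, too short...)."""


class IrregularSamplingError(DataError):
    """Inter-sample gaps deviate too much from a constant rate."""


class ParameterError(GaitError):
    """A parameter value is outside its valid domain."""


class DetectionError(GaitError):
    """An event-detection stage found nothing usable."""


class PairingError(GaitError):
    """No strides could be matched between the two measurement arms."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AccelTrace:
    """Uniformly sampled single-axis acceleration.

    Parameters
    ----------
    samples : array of float, m/s²
        AP acceleration, anterior positive unless ``anterior_positive`` is
        False (then the sign is flipped on construction by callers that
        normalise polarity).
    ts : float
        Sampling interval in seconds (50 Hz -> 0.02).
    side : str
        ``"left"``/``"right"`` or ``"paretic"``/``"nonparetic"``.
    anterior_positive : bool
        Sign convention flag carried as metadata.
    start_time : float
        Seconds from the shared recording start to sample 0.
    """

    samples: np.ndarray
    ts: float
    side: str
    anterior_positive: bool = True
    start_time: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if not self.ts > 0:
            raise ParameterError(f"sampling interval must be positive, got {self.ts}")
        if samples.ndim != 1 or samples.size < 5:
            raise DataError(
                "acceleration trace needs at least 5 samples "
                f"(energy operator stencil), got shape {samples.shape}"
            )
        if not np.all(np.isfinite(samples)):
            raise DataError("acceleration trace contains non-finite samples")
        if not self.side:
            raise ParameterError("side must be set")

    @property
    def n(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        return (self.n - 1) * self.ts

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n) * self.ts

    def with_samples(self, samples: np.ndarray) -> "AccelTrace":
        return replace(self, samples=np.asarray(samples, dtype=float))


@dataclass(frozen=True)
class MarkerTrajectories:
    """Pelvis and bilateral ankle 3D positions over time (meters, lab frame).

    ``gap_mask[name]`` is True where the marker was tracked; gap frames keep
    their (NaN) rows rather than being dropped, so frame indices stay aligned
    with time.  First coordinate is the declared walking (AP) axis.
    """

    frame_rate: float
    pelvis: np.ndarray
    ankle_left: np.ndarray
    ankle_right: np.ndarray
    gap_mask: dict[str, np.ndarray] = field(default_factory=dict)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        if not self.frame_rate > 0:
            raise ParameterError(f"frame rate must be positive, got {self.frame_rate}")
        arrays = {}
        n = None
        for name in MARKER_NAMES:
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise DataError(f"marker '{name}' must be (n_frames, 3), got {arr.shape}")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise DataError("marker trajectories must have equal frame counts")
            arrays[name] = arr
        mask = dict(self.gap_mask) if self.gap_mask else {}
        for name in MARKER_NAMES:
            m = mask.get(name)
            if m is None:
                m = np.all(np.isfinite(arrays[name]), axis=1)
            m = np.asarray(m, dtype=bool)
            if m.shape != (n,):
                raise DataError(f"gap mask for '{name}' must have {n} entries")
            if m.sum() < 2:
                raise DataError(f"marker '{name}' has fewer than 2 valid frames")
            mask[name] = m
            object.__setattr__(self, name, arrays[name])
        object.__setattr__(self, "gap_mask", mask)

    @property
    def n_frames(self) -> int:
        return int(self.pelvis.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_frames) / self.frame_rate

    def marker(self, name: str) -> np.ndarray:
        if name not in MARKER_NAMES:
            raise ParameterError(f"unknown marker '{name}'")
        return getattr(self, name)

    def translated(self, offset: Sequence[float]) -> "MarkerTrajectories":
        """Rigid lab-frame translation of all markers (events are invariant)."""
        off = np.asarray(offset, dtype=float).reshape(1, 3)
        return replace(
            self,
            pelvis=self.pelvis + off,
            ankle_left=self.ankle_left + off,
            ankle_right=self.ankle_right + off,
        )


@dataclass(frozen=True)
class GaitEvent:
    """A single timed gait event: initial contact (IC) or final contact (FC)."""

    type: str  # "IC" | "FC"
    side: str
    time_s: float
    sample_index: int
    peak_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        if self.type not in ("IC", "FC"):
            raise ParameterError(f"event type must be IC or FC, got {self.type!r}")


@dataclass(frozen=True)
class Stride:
    """One gait cycle's contact pair; stance runs from IC to ipsilateral FC."""

    side: str
    ic_time: float
    fc_time: float
    stride_index: int

    @property
    def stance_s(self) -> float:
        return self.fc_time - self.ic_time


@dataclass
class EventSeries:
    """Time-ordered gait events plus the per-stride stance records."""

    events: list[GaitEvent] = field(default_factory=list)
    strides: list[Stride] = field(default_factory=list)
    params_used: object = None

    def __post_init__(self) -> None:
        self.events = sorted(self.events, key=lambda e: (e.time_s, e.type))
        for side in {s.side for s in self.strides}:
            ics = [s.ic_time for s in self.strides if s.side == side]
            if any(b <= a for a, b in zip(ics, ics[1:])):
                raise DataError(f"IC times not strictly increasing on side {side!r}")
        for s in self.strides:
            if not s.stance_s > 0:
                raise DataError(
                    f"stance must be positive (IC {s.ic_time:.3f} s, FC {s.fc_time:.3f} s)"
                )

    def stances(self, side: str | None = None) -> np.ndarray:
        vals = [s.stance_s for s in self.strides if side is None or s.side == side]
        return np.asarray(vals, dtype=float)

    @property
    def sides(self) -> list[str]:
        return sorted({s.side for s in self.strides})

    def summary(self) -> dict[str, dict[str, float]]:
        """Per-side stance mean/SD (ddof=1 where n>1)."""
        out: dict[str, dict[str, float]] = {}
        for side in self.sides:
            v = self.stances(side)
            out[side] = {
                "n": int(v.size),
                "mean_stance_s": float(np.mean(v)) if v.size else float("nan"),
                "sd_stance_s": float(np.std(v, ddof=1)) if v.size > 1 else float("nan"),
            }
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_accel_csv(
    path,
    side: str,
    time_col: str = "time_s",
    acc_col: str = "acc_ap",
    rate_hz: float | None = None,
    units: str = "m/s2",
    anterior_positive: bool = True,
    max_gap_deviation: float = 0.01,
) -> AccelTrace:
    """Read a single-axis acceleration CSV into an :class:`AccelTrace`.

    The sampling interval is taken from ``rate_hz`` if declared, otherwise
    inferred as the median inter-sample gap of ``time_col``.  Time must be
    strictly increasing, and every gap must be within ``max_gap_deviation``
    (relative) of the median gap, else the file is rejected as irregularly
    sampled.  ``units="g"`` converts samples to m/s².
    """
    df = pd.read_csv(path)
    if acc_col not in df.columns:
        raise FormatError(f"missing acceleration column {acc_col!r} in {path}")
    acc = df[acc_col].to_numpy(dtype=float)
    if units in ("g",):
        acc = acc * G_TO_MS2
    elif units not in ("m/s2", "m/s^2", "ms2"):
        raise ParameterError(f"unknown acceleration units {units!r}")

    start_time = 0.0
    if time_col in df.columns:
        t = df[time_col].to_numpy(dtype=float)
        gaps = np.diff(t)
        if np.any(gaps <= 0):
            raise IrregularSamplingError(
                f"time column {time_col!r} is not strictly increasing"
            )
        ts = float(np.median(gaps))
        if np.any(np.abs(gaps - ts) > max_gap_deviation * ts):
            raise IrregularSamplingError(
                "inter-sample gaps deviate more than "
                f"{max_gap_deviation:.0%} from the median ({ts:.6f} s)"
            )
        start_time = float(t[0])
        if rate_hz is not None:
            ts = 1.0 / rate_hz
    elif rate_hz is not None:
        ts = 1.0 / rate_hz
    else:
        raise FormatError(
            f"no time column {time_col!r} and no declared rate for {path}"
        )
    return AccelTrace(
        samples=acc, ts=ts, side=side,
        anterior_positive=anterior_positive, start_time=start_time,
    )


def read_markers_csv(
    path,
    frame_rate: float,
    axis_map: tuple[str, str, str] = ("x", "y", "z"),
    start_time: float = 0.0,
) -> MarkerTrajectories:
    """Read marker trajectories from a wide CSV.

    Expected columns: ``<marker>_x, <marker>_y, <marker>_z`` for each of
    pelvis, ankle_left, ankle_right (a ``frame`` column is allowed and
    ignored).  ``axis_map`` names the source columns in (AP, ML, vertical)
    order, so the declared walking axis lands in the first coordinate.
    Blank/NaN rows are flagged in the gap mask, never dropped.
    """
    df = pd.read_csv(path)
    data: dict[str, np.ndarray] = {}
    mask: dict[str, np.ndarray] = {}
    for name in MARKER_NAMES:
        cols = [f"{name}_{ax}" for ax in axis_map]
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise FormatError(f"marker '{name}' missing columns {missing} in {path}")
        arr = df[cols].to_numpy(dtype=float)
        data[name] = arr
        mask[name] = np.all(np.isfinite(arr), axis=1)
    return MarkerTrajectories(
        frame_rate=frame_rate, gap_mask=mask, start_time=start_time, **data
    )


# ---------------------------------------------------------------------------
# Writers (events CSV / report JSON) and their inverse readers
# ---------------------------------------------------------------------------

EVENT_COLUMNS = ["side", "type", "time_s", "sample_index", "peak_amplitude", "stride_index"]


def write_events(series: EventSeries, path) -> None:
    """Write an :class:`EventSeries` to CSV (one row per event).

    ``stride_index`` is filled for events that belong to a completed stride,
    −1 otherwise; times carry 6 decimals (microsecond precision).
    """
    stride_of: dict[tuple[str, str, float], int] = {}
    for s in series.strides:
        stride_of[(s.side, "IC", round(s.ic_time, 9))] = s.stride_index
        stride_of[(s.side, "FC", round(s.fc_time, 9))] = s.stride_index
    rows = []
    for e in series.events:
        rows.append(
            {
                "side": e.side,
                "type": e.type,
                "time_s": f"{e.time_s:.6f}",
                "sample_index": e.sample_index,
                "peak_amplitude": f"{e.peak_amplitude:.9g}",
                "stride_index": stride_of.get((e.side, e.type, round(e.time_s, 9)), -1),
            }
        )
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> EventSeries:
    df = pd.read_csv(path)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"events file {path} missing columns {missing}")
    events = [
        GaitEvent(
            type=row.type,
            side=row.side,
            time_s=float(row.time_s),
            sample_index=int(row.sample_index),
            peak_amplitude=float(row.peak_amplitude),
        )
        for row in df.itertuples()
    ]
    strides = []
    for (side, idx), grp in df[df.stride_index >= 0].groupby(["side", "stride_index"]):
        ic = grp[grp.type == "IC"]
        fc = grp[grp.type == "FC"]
        if len(ic) == 1 and len(fc) == 1:
            strides.append(
                Stride(
                    side=side,
                    ic_time=float(ic.time_s.iloc[0]),
                    fc_time=float(fc.time_s.iloc[0]),
                    stride_index=int(idx),
                )
            )
    strides.sort(key=lambda s: (s.side, s.stride_index))
    return EventSeries(events=events, strides=strides)


def write_report(report, path) -> None:
    """Serialise an agreement report (any object with ``to_dict``) to JSON."""
    payload = report.to_dict() if hasattr(report, "to_dict") else dict(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
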