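"""Gait-event detection from thigh AP acceleration via the Teager-Kaiser
energy operator (TKEO).

The continuous operator Ψ[x](t) = ẋ(t)² − x(t)ẍ(t) tracks the instantaneous
energy of a signal as a joint function of amplitude and frequency, which
makes it sharply sensitive to the brief high-frequency transients that foot
impacts (initial contact, IC) and push-off (final contact, FC) impose on
thigh acceleration.  The pipeline is:

    high-pass filter (0.5 Hz, 4th-order Butterworth, zero-phase)
      -> discrete TKEO φ_n
      -> stride-period estimate (autocorrelation)
      -> IC detection (largest per-cycle φ peaks)
      -> FC detection (largest remaining peak per IC→IC interval after the
         IC neighbourhoods are masked out and the interval renormalised)
      -> per-stride stance duration = FC − IC.

Two discretisations of Ψ are provided.  With 3-sample symmetric differences
for both derivatives (first over spacing Ts, second over spacing 2·Ts) the
operator becomes

    φ_n = [2·x_n² + (x_{n+1} − x_{n−1})² − x_n·(x_{n+2} + x_{n−2})] / (4·Ts²)

(``variant="consistent"``, the default).  ``variant="literal"`` replaces the
final plus with a minus — a published form of the same expression that does
not follow from the symmetric-difference derivation; it is kept so the two
can be compared.  All detection windows scale with the estimated stride
period rather than using absolute seconds, so very slow hemiplegic gait
(walking speeds down to ~0.1 m/s) is handled by the same defaults.

Detection is fully deterministic: identical input and parameters give
bit-identical events.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy import signal as sps

from .signal_io import (
    AccelTrace,
    DataError,
    DetectionError,
    EventSeries,
    GaitEvent,
    ParameterError,
    Stride,
)

logger = logging.getLogger("gaitkeo")

TKEO_VARIANTS = ("consistent", "literal")

# Stride periods considered physiological, in seconds; the autocorrelation
# search band extends down to a step period (half a stride).
MIN_STRIDE_S = 0.8
MAX_STRIDE_S = 4.0
MIN_ACF_PEAK = 0.2


@dataclass(frozen=True)
class DetectorParams:
    """Tunable constants of the detector.

    hp_cutoff_hz, hp_order
        High-pass Butterworth applied (zero-phase) before the energy
        operator; removes gravity/orientation drift.
    ic_rel_threshold
        IC peaks must reach this fraction of the reference amplitude
        (median of the per-cycle φ maxima).
    ic_min_separation_frac
        Minimum IC-to-IC spacing as a fraction of the estimated stride.
    mask_halfwidth_frac
        Half-width of the region zeroed around each IC before the FC search,
        as a fraction of the stride.
    fc_window_frac
        (lower, upper) bounds of the FC search window inside each IC→IC
        interval, as fractions of that interval; stance typically ends at
        ~60 % of the cycle, so the default window 25–75 % brackets it.
    stride_band_frac
        (lower, upper) admissible IC→IC interval as a fraction of the
        estimated stride period.  An interval far below one stride means a
        duplicate detection inside a cycle (e.g. a push-off transient
        mistaken for a contact); far above one stride means a missed IC, so
        the interval spans two strides and any single FC found in it would
        be mistimed.  Both are rejected rather than turned into strides.
    smooth_window_s
        Width of the centred moving average applied to φ before any peak
        search.  A transient's raw φ peak depends on how the burst carrier
        aligns with the sample grid (at 50 Hz a ~10 Hz impact burst spans
        only a few samples), so peak heights of identical bursts can vary
        severalfold; averaging over roughly one transient width integrates
        the energy envelope and removes that sensitivity without biasing
        peak timing (the window is symmetric).  0 disables smoothing.
    tkeo_variant
        "consistent" (default) or "literal"; see module docstring.
    """

    hp_cutoff_hz: float = 0.5
    hp_order: int = 4
    ic_rel_threshold: float = 0.3
    ic_min_separation_frac: float = 0.5
    mask_halfwidth_frac: float = 0.15
    fc_window_frac: tuple[float, float] = (0.25, 0.75)
    stride_band_frac: tuple[float, float] = (0.7, 1.5)
    smooth_window_s: float = 0.06
    tkeo_variant: str = "consistent"

    def __post_init__(self) -> None:
        fracs = (
            self.ic_rel_threshold,
            self.ic_min_separation_frac,
            self.mask_halfwidth_frac,
            *self.fc_window_frac,
        )
        # ic_rel_threshold may legitimately exceed 1 (then detection fails
        # loudly); the window/mask fractions must lie strictly in (0, 1).
        for f in fracs[1:]:
            if not 0 < f < 1:
                raise ParameterError(f"fractional parameter out of (0,1): {f}")
        if not self.ic_rel_threshold > 0:
            raise ParameterError("ic_rel_threshold must be positive")
        lo, hi = self.fc_window_frac
        if not lo < hi:
            raise ParameterError("fc_window_frac lower bound must be below upper")
        blo, bhi = self.stride_band_frac
        if not 0 < blo < 1 < bhi:
            raise ParameterError("stride_band_frac must bracket 1.0 stride")
        if self.tkeo_variant not in TKEO_VARIANTS:
            raise ParameterError(f"tkeo_variant must be one of {TKEO_VARIANTS}")
        if self.smooth_window_s < 0:
            raise ParameterError("smooth_window_s must be >= 0")
        if self.hp_order < 1:
            raise ParameterError("hp_order must be >= 1")
        if not self.hp_cutoff_hz > 0:
            raise ParameterError("hp_cutoff_hz must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fc_window_frac"] = list(self.fc_window_frac)
        d["stride_band_frac"] = list(self.stride_band_frac)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorParams":
        d = dict(d)
        for key in ("fc_window_frac", "stride_band_frac"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class TkeoSeries:
    """Instantaneous-energy series φ_n aligned sample-for-sample to its trace.

    φ carries units (m/s²)²/s² under the 1/(4·Ts²) scaling.  The 5-point
    stencil leaves φ undefined at the first and last two samples; those are
    set to 0 and excluded from every peak search via ``valid_range``
    (half-open index interval).
    """

    phi: np.ndarray
    ts: float
    side: str
    start_time: float = 0.0
    variant: str = "consistent"

    def __post_init__(self) -> None:
        phi = np.asarray(self.phi, dtype=float)
        object.__setattr__(self, "phi", phi)
        lo, hi = self.valid_range
        if not np.all(np.isfinite(phi[lo:hi])):
            raise DataError("non-finite energy values inside the valid range")

    @property
    def n(self) -> int:
        return int(self.phi.size)

    @property
    def valid_range(self) -> tuple[int, int]:
        return (2, self.n - 2)

    @property
    def duration_s(self) -> float:
        return (self.n - 1) * self.ts

    def time_of(self, index: int | np.ndarray):
        return self.start_time + np.asarray(index) * self.ts


# ---------------------------------------------------------------------------
# Stage 1: filtering
# ---------------------------------------------------------------------------


def highpass_filter(
    trace: AccelTrace, cutoff_hz: float = 0.5, order: int = 4
) -> AccelTrace:
    """Zero-phase high-pass Butterworth filter.

    Applied forward-backward (doubling the effective order) so event timing
    is not biased by filter group delay.  Requires the trace to span at
    least ``3 / cutoff_hz`` seconds so start-up transients cannot dominate.
    """
    nyquist = 0.5 / trace.ts
    if cutoff_hz >= nyquist:
        raise ParameterError(
            f"cutoff {cutoff_hz} Hz is not below the Nyquist frequency {nyquist} Hz"
        )
    min_duration = 3.0 / cutoff_hz
    if trace.duration_s < min_duration:
        raise DataError(
            f"trace of {trace.duration_s:.2f} s is too short for a {cutoff_hz} Hz "
            f"high-pass (needs >= {min_duration:.1f} s)"
        )
    sos = sps.butter(order, cutoff_hz, btype="highpass", fs=1.0 / trace.ts, output="sos")
    filtered = sps.sosfiltfilt(sos, trace.samples)
    return trace.with_samples(filtered)


# ---------------------------------------------------------------------------
# Stage 2: discrete energy operator
# ---------------------------------------------------------------------------


def tkeo_discrete(trace: AccelTrace, variant: str = "consistent") -> TkeoSeries:
    """Discrete Teager-Kaiser energy of an acceleration trace.

    ``variant="consistent"``:
        φ_n = [2x_n² + (x_{n+1}−x_{n−1})² − x_n(x_{n+2}+x_{n−2})] / (4Ts²),
        identical to ẋ² − x·ẍ with the symmetric 3-point first derivative
        (spacing Ts) and the symmetric second derivative over spacing 2Ts.
    ``variant="literal"``:
        same with (x_{n+2} − x_{n−2}) in the last term.

    The first and last two samples are set to 0 and flagged invalid.
    """
    if variant not in TKEO_VARIANTS:
        raise ParameterError(f"variant must be one of {TKEO_VARIANTS}")
    x = trace.samples
    phi = np.zeros_like(x)
    core = 2.0 * x[2:-2] ** 2 + (x[3:-1] - x[1:-3]) ** 2
    if variant == "consistent":
        core -= x[2:-2] * (x[4:] + x[:-4])
    else:
        core -= x[2:-2] * (x[4:] - x[:-4])
    phi[2:-2] = core / (4.0 * trace.ts**2)
    return TkeoSeries(
        phi=phi, ts=trace.ts, side=trace.side,
        start_time=trace.start_time, variant=variant,
    )


def smooth_tkeo(series: TkeoSeries, window_s: float) -> TkeoSeries:
    """Centred moving average of the energy series.

    Integrates φ over roughly one transient width so a burst's detected
    height reflects its envelope energy rather than its carrier-phase
    alignment with the sample grid.  The window is rounded to an odd sample
    count (symmetric, so peak timing is unbiased); ``window_s <= ts``
    returns the series unchanged.
    """
    if window_s <= 0:
        return series
    w = max(1, int(round(window_s / series.ts)))
    if w % 2 == 0:
        w += 1
    if w == 1:
        return series
    lo, hi = series.valid_range
    phi = series.phi.copy()
    phi[lo:hi] = np.convolve(series.phi[lo:hi], np.ones(w) / w, mode="same")
    return replace(series, phi=phi)


# ---------------------------------------------------------------------------
# Stage 3: stride-period estimate
# ---------------------------------------------------------------------------


def estimate_cycle_duration(series: TkeoSeries | AccelTrace) -> float:
    """Dominant stride period (s) from the biased autocorrelation.

    Searches for the strongest local autocorrelation maximum at lags of
    0.4–4.0 s.  The biased estimator (normalised by the full length) decays
    with lag, so the fundamental beats its own multiples.  A peak found
    below 0.8 s is interpreted as a step period and doubled.  Raises
    :class:`DetectionError` if no peak reaches 0.2 of the zero-lag value —
    i.e. no periodic gait is present.
    """
    x = series.phi if isinstance(series, TkeoSeries) else series.samples
    ts = series.ts
    if (x.size - 1) * ts < 3.0:
        raise DataError("need at least 3 s of signal to estimate a stride period")
    x = np.asarray(x, dtype=float) - np.mean(x)
    n = x.size
    # biased ACF via FFT
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    spec = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(spec * np.conj(spec), nfft)[:n]
    if acf[0] <= 0:
        raise DetectionError("no periodic gait found (flat signal)")
    acf = acf / acf[0]

    lo = max(2, int(np.floor(0.4 / ts)))
    hi = min(n - 2, int(np.ceil(MAX_STRIDE_S / ts)))
    if hi <= lo:
        raise DataError("signal too short for the stride-period search band")
    seg = acf[lo : hi + 1]
    peaks, props = sps.find_peaks(seg, height=MIN_ACF_PEAK)
    if peaks.size == 0:
        raise DetectionError("no periodic gait found")
    lags = lo + peaks
    heights = props["peak_heights"]
    # Fundamental selection.  The tallest ACF peak is often a multiple of
    # the stride period (a period of non-integer sample count aligns better
    # with the grid at twice the lag; concatenated cadences reinforce
    # common multiples), so the raw argmax is unreliable.  Neighbouring
    # side-lobes (burst/harmonic interaction) are first merged into one
    # representative peak per lag cluster, then the smallest-lag cluster
    # whose height is comparable to the strongest (>= 0.5x) is taken as the
    # fundamental.
    rep_lags: list[int] = []
    rep_heights: list[float] = []
    for lag, h in zip(lags, heights):
        if rep_lags and lag - rep_lags[-1] <= 0.15 * lag:
            if h > rep_heights[-1]:
                rep_lags[-1], rep_heights[-1] = int(lag), float(h)
        else:
            rep_lags.append(int(lag))
            rep_heights.append(float(h))
    top = max(rep_heights)
    lag = next(
        l for l, h in zip(rep_lags, rep_heights) if h >= 0.5 * top
    )
    period = lag * ts
    if period < MIN_STRIDE_S:
        period *= 2.0  # step-level peak; stride spans two steps
    if not MIN_STRIDE_S <= period <= MAX_STRIDE_S:
        raise DetectionError(
            f"estimated period {period:.2f} s outside the physiological stride band"
        )
    return float(period)


# ---------------------------------------------------------------------------
# Stage 4: IC detection
# ---------------------------------------------------------------------------


def detect_ic(
    series: TkeoSeries, params: DetectorParams, cycle_s: float
) -> list[GaitEvent]:
    """Initial contacts as the large per-cycle peaks of the energy series.

    The reference amplitude is the median of per-cycle φ maxima (the signal
    is tiled into consecutive windows one stride long); candidate peaks must
    reach ``ic_rel_threshold`` times that reference and be separated by at
    least ``ic_min_separation_frac`` strides.  Equal-height peaks within one
    separation window resolve to the earlier sample.
    """
    lo, hi = series.valid_range
    phi = series.phi[lo:hi]
    cycle_samples = max(2, int(round(cycle_s / series.ts)))
    n_cycles = phi.size // cycle_samples
    if n_cycles >= 1:
        tiled = phi[: n_cycles * cycle_samples].reshape(n_cycles, cycle_samples)
        reference = float(np.median(tiled.max(axis=1)))
    else:
        reference = float(np.max(phi))
    height = params.ic_rel_threshold * reference
    distance = max(1, int(round(params.ic_min_separation_frac * cycle_samples)))
    peaks, props = sps.find_peaks(phi, height=height, distance=distance)
    if peaks.size == 0:
        raise DetectionError(
            f"no IC peaks reach the threshold {height:.3g} "
            f"({params.ic_rel_threshold} x reference {reference:.3g})"
        )
    return [
        GaitEvent(
            type="IC",
            side=series.side,
            time_s=float(series.time_of(p + lo)),
            sample_index=int(p + lo),
            peak_amplitude=float(h),
        )
        for p, h in zip(peaks, props["peak_heights"])
    ]


# ---------------------------------------------------------------------------
# Stage 5: FC detection
# ---------------------------------------------------------------------------


def detect_fc(
    series: TkeoSeries,
    ic_events: list[GaitEvent],
    params: DetectorParams,
    cycle_s: float,
) -> list[tuple[GaitEvent, GaitEvent]]:
    """Final contacts inside each consecutive ipsilateral IC→IC interval.

    Per interval: (1) zero φ within ``mask_halfwidth_frac`` strides of each
    bounding IC (removing the impact peaks), (2) rescale the remainder to
    unit maximum (calibrating the surrounding region), (3) take the largest
    remaining local maximum whose time falls inside the fractional window
    ``fc_window_frac`` of the interval.  Intervals with no admissible peak
    are dropped with a warning.  Returns (IC, FC) pairs.
    """
    if len(ic_events) < 2:
        raise DetectionError("FC detection needs at least 2 ICs on the side")
    mask_half = max(0, int(round(params.mask_halfwidth_frac * cycle_s / series.ts)))
    w_lo, w_hi = params.fc_window_frac
    band_lo, band_hi = params.stride_band_frac
    pairs: list[tuple[GaitEvent, GaitEvent]] = []
    for ic_a, ic_b in zip(ic_events, ic_events[1:]):
        interval = ic_b.time_s - ic_a.time_s
        if not band_lo * cycle_s <= interval <= band_hi * cycle_s:
            logger.warning(
                "IC interval %.3f s at IC %.3f s outside the plausible stride "
                "band (%.2f-%.2f strides): not treated as a stride",
                interval, ic_a.time_s, band_lo, band_hi,
            )
            continue
        a, b = ic_a.sample_index, ic_b.sample_index
        seg = series.phi[a : b + 1].copy()
        seg[: mask_half + 1] = 0.0
        if mask_half > 0:
            seg[len(seg) - mask_half - 1 :] = 0.0
        else:
            seg[-1] = 0.0
        peak_val = seg.max()
        if peak_val <= 0:
            logger.warning(
                "stride at IC %.3f s dropped: masking removed the whole interval",
                ic_a.time_s,
            )
            continue
        seg = seg / peak_val  # unit-max calibration of the surrounding region
        j_lo = int(np.ceil(w_lo * (b - a)))
        j_hi = int(np.floor(w_hi * (b - a)))
        cand, props = sps.find_peaks(seg)
        in_window = cand[(cand >= j_lo) & (cand <= j_hi)]
        if in_window.size == 0:
            logger.warning(
                "stride at IC %.3f s dropped: no FC peak inside the "
                "%d-%d%% window", ic_a.time_s, round(w_lo * 100), round(w_hi * 100),
            )
            continue
        heights = seg[in_window]
        j = int(in_window[np.argmax(heights)])  # argmax -> earliest on ties
        fc = GaitEvent(
            type="FC",
            side=series.side,
            time_s=float(series.time_of(a + j)),
            sample_index=int(a + j),
            peak_amplitude=float(seg[j]),
        )
        pairs.append((ic_a, fc))
    return pairs


# ---------------------------------------------------------------------------
# Stage 6: stance assembly
# ---------------------------------------------------------------------------


def compute_stance(
    pairs: list[tuple[GaitEvent, GaitEvent]],
    params: DetectorParams | None = None,
    extra_events: list[GaitEvent] | None = None,
) -> EventSeries:
    """Assemble (IC, FC) pairs into an :class:`EventSeries` with stances.

    Pairs whose FC does not follow its IC are rejected and logged.  Stride
    indices count accepted strides per side from 0.
    """
    strides: list[Stride] = []
    events: list[GaitEvent] = list(extra_events or [])
    counters: dict[str, int] = {}
    for ic, fc in sorted(pairs, key=lambda p: p[0].time_s):
        if fc.time_s <= ic.time_s:
            logger.warning(
                "rejected IC/FC pair with non-positive stance (IC %.3f s, FC %.3f s)",
                ic.time_s, fc.time_s,
            )
            continue
        idx = counters.get(ic.side, 0)
        counters[ic.side] = idx + 1
        strides.append(
            Stride(side=ic.side, ic_time=ic.time_s, fc_time=fc.time_s, stride_index=idx)
        )
        events.extend([ic, fc])
    return EventSeries(events=events, strides=strides, params_used=params)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


def detect_gait_events(
    trace: AccelTrace, params: DetectorParams | None = None
) -> EventSeries:
    """End-to-end detection on one AP acceleration trace.

    filter -> energy operator -> stride-period estimate -> IC -> FC ->
    stance.  Stage failures are re-raised with the stage named.
    """
    params = params or DetectorParams()
    stage = "highpass_filter"
    try:
        filtered = highpass_filter(trace, params.hp_cutoff_hz, params.hp_order)
        stage = "tkeo_discrete"
        series = tkeo_discrete(filtered, params.tkeo_variant)
        series = smooth_tkeo(series, params.smooth_window_s)
        stage = "estimate_cycle_duration"
        cycle_s = estimate_cycle_duration(filtered)
        stage = "detect_ic"
        ics = detect_ic(series, params, cycle_s)
        stage = "detect_fc"
        pairs = detect_fc(series, ics, params, cycle_s)
        stage = "compute_stance"
        unpaired = [ic for ic in ics if ic not in {p[0] for p in pairs}]
        return compute_stance(pairs, params=params, extra_events=unpaired)
    except (DataError, ParameterError, DetectionError) as err:
        err.args = (f"[{stage}] {err.args[0] if err.args else ''}",) + err.args[1:]
        raise
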