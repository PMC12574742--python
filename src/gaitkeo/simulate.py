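"""Synthetic paired gait data with exact ground truth.

Generates the two concurrent measurement streams the pipeline consumes — a
thigh AP acceleration trace per leg and pelvis/ankle marker trajectories —
from one shared event schedule, so every detected event can be scored
against known truth without any recorded data.

Model
-----
Per side, initial contacts (IC) fall every ``cycle_s`` seconds, the two
sides half a cycle out of phase; the final contact (FC) of each stride
follows its IC by ``stance_fraction × cycle_s`` (the paretic side's stance
fraction is shifted by ``asymmetry``).  The acceleration is a sum of

* stride-locked low-frequency harmonics (the smooth thigh swing),
* a Gaussian-windowed ~10 Hz burst at every IC and a smaller one at every
  FC — the energy operator responds to exactly this kind of joint
  amplitude-frequency transient, so the detector's target is physically
  motivated yet fully controlled, and
* white Gaussian sensor noise.

The marker stream is exactly solvable by the coordinate method: the
ankle-minus-pelvis AP displacement is a piecewise-cosine wave whose maxima
sit exactly on the true ICs and minima exactly on the true FCs.

Two fields perturb only the accelerometer arm, for end-to-end
method-comparison experiments: ``accel_stance_offset_s`` shifts every FC
burst (injecting a known systematic stance bias) and ``timing_jitter_sd_s``
jitters every burst centre (injecting known random timing error).  Ground
truth always refers to the unperturbed schedule, which the mocap stream
follows.

Everything is deterministic given the seed; cohort simulations derive
per-walk sub-seeds from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np

from .signal_io import AccelTrace, MarkerTrajectories, ParameterError

SIDES = ("left", "right")


@dataclass(frozen=True)
class GaitSimConfig:
    """Parameters of one simulated walk.

    Defaults emulate comfortable-pace hemiplegic walking: 1.37 s stride,
    stance 62 % of the cycle (≈0.85 s), paretic stance fraction reduced by
    5 percentage points, accelerometer at 50 Hz, mocap at 120 Hz.
    """

    duration_s: float = 60.0
    accel_rate_hz: float = 50.0
    mocap_rate_hz: float = 120.0
    cycle_s: float = 1.37
    stance_fraction: float = 0.62
    asymmetry: float = -0.05
    paretic_side: str = "left"
    ic_transient_amplitude: float = 3.0  # m/s²
    fc_to_ic_amplitude_ratio: float = 0.5
    transient_width_s: float = 0.05
    transient_freq_hz: float = 10.0
    harmonic_amplitudes: tuple[float, ...] = (1.0, 0.5)
    noise_sd: float = 0.3  # m/s²
    walking_speed_ms: float = 0.93
    marker_excursion_m: float = 0.35
    intersystem_offset_s: float = 0.0
    accel_stance_offset_s: float = 0.0
    timing_jitter_sd_s: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.stance_fraction + self.asymmetry < 1:
            raise ParameterError("paretic stance fraction must stay in (0, 1)")
        if not 0 < self.stance_fraction < 1:
            raise ParameterError("stance_fraction must be in (0, 1)")
        for rate in (self.accel_rate_hz, self.mocap_rate_hz):
            if rate <= 2.0 / self.transient_width_s:
                raise ParameterError(
                    f"sampling rate {rate} Hz cannot resolve a "
                    f"{self.transient_width_s * 1000:.0f} ms transient"
                )
        if self.duration_s < 3 * self.cycle_s:
            raise ParameterError("duration must cover at least 3 gait cycles")
        if self.paretic_side not in SIDES:
            raise ParameterError(f"paretic_side must be one of {SIDES}")
        if self.noise_sd < 0 or self.timing_jitter_sd_s < 0:
            raise ParameterError("noise/jitter standard deviations must be >= 0")
        if self.transient_freq_hz >= 0.5 * self.accel_rate_hz:
            raise ParameterError("transient frequency must be below accel Nyquist")

    def stance_fraction_of(self, side: str) -> float:
        frac = self.stance_fraction
        if side == self.paretic_side:
            frac += self.asymmetry
        return frac

    def to_dict(self) -> dict:
        d = asdict(self)
        d["harmonic_amplitudes"] = list(self.harmonic_amplitudes)
        return d


@dataclass(frozen=True)
class GroundTruth:
    """True event times per side, seconds on the shared clock."""

    ic_times: dict[str, np.ndarray]
    fc_times: dict[str, np.ndarray]
    config: GaitSimConfig

    def stances(self, side: str) -> np.ndarray:
        return self.fc_times[side] - self.ic_times[side]

    def all_stances(self) -> np.ndarray:
        return np.concatenate([self.stances(s) for s in SIDES])


@dataclass(frozen=True)
class SimulatedWalk:
    participant_id: str
    walk_index: int
    accel: dict[str, AccelTrace]
    markers: MarkerTrajectories
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Event schedules and waveforms
# ---------------------------------------------------------------------------


def _schedule(config: GaitSimConfig, side: str, margin_cycles: int = 2):
    """IC/FC times for one side, extended ``margin_cycles`` beyond each end."""
    cycle = config.cycle_s
    phase = 0.0 if side == "right" else 0.5 * cycle
    first = 0.5 * cycle + phase
    start = first - margin_cycles * cycle
    n = int(np.ceil((config.duration_s - start) / cycle)) + margin_cycles
    ics = start + np.arange(n) * cycle
    fcs = ics + config.stance_fraction_of(side) * cycle
    return ics, fcs


def _truth_window(ics: np.ndarray, fcs: np.ndarray, duration: float):
    """Keep strides whose IC and FC both fall strictly inside the recording.

    An event at the literal first sample is unattributable by any detector
    and excluded (it only arises from the waveform margin extension).
    """
    keep = (ics > 1e-9) & (fcs <= duration)
    return ics[keep], fcs[keep]


def _burst(t: np.ndarray, center: float, amplitude: float, config: GaitSimConfig) -> np.ndarray:
    sigma = 0.5 * config.transient_width_s
    u = t - center
    env = np.exp(-0.5 * (u / sigma) ** 2)
    return amplitude * env * np.cos(2.0 * np.pi * config.transient_freq_hz * u)


def _accel_waveform(
    t: np.ndarray,
    config: GaitSimConfig,
    side: str,
    ics: np.ndarray,
    fcs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    cycle = config.cycle_s
    phase = 0.0 if side == "right" else 0.5 * cycle
    x = np.zeros_like(t)
    for k, amp in enumerate(config.harmonic_amplitudes, start=1):
        x += amp * np.sin(2.0 * np.pi * k * (t - phase) / cycle)
    jit = config.timing_jitter_sd_s
    for ic in ics:
        c = ic + (rng.normal(0.0, jit) if jit > 0 else 0.0)
        x += _burst(t, c, config.ic_transient_amplitude, config)
    fc_amp = config.ic_transient_amplitude * config.fc_to_ic_amplitude_ratio
    for fc in fcs:
        c = fc + config.accel_stance_offset_s + (rng.normal(0.0, jit) if jit > 0 else 0.0)
        x += _burst(t, c, fc_amp, config)
    return x


def _relative_ap(t: np.ndarray, ics: np.ndarray, fcs: np.ndarray, amplitude: float) -> np.ndarray:
    """Piecewise-cosine ankle-minus-pelvis AP wave.

    Crest exactly at each IC, trough exactly at each FC; C1-continuous at
    the junctions (zero slope at every extremum).
    """
    knots = np.empty(ics.size + fcs.size)
    kinds = np.empty(knots.size, dtype=int)  # +1 crest (IC), -1 trough (FC)
    knots[0::2] = ics
    knots[1::2] = fcs
    kinds[0::2] = 1
    kinds[1::2] = -1
    order = np.argsort(knots)
    knots, kinds = knots[order], kinds[order]

    out = np.empty_like(t)
    seg = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, knots.size - 2)
    t0 = knots[seg]
    t1 = knots[seg + 1]
    frac = (t - t0) / (t1 - t0)
    # from crest to trough: +cos(π·frac); trough to crest: −cos(π·frac)
    out = kinds[seg] * np.cos(np.pi * frac) * amplitude
    return out


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def simulate_gait(
    config: GaitSimConfig, participant_id: str = "p0", walk_index: int = 0
) -> SimulatedWalk:
    """Generate one walk: both acceleration traces, markers and truth."""
    rng = np.random.default_rng(config.seed)
    duration = config.duration_s

    schedules = {side: _schedule(config, side) for side in SIDES}
    truth = GroundTruth(
        ic_times={
            s: _truth_window(*schedules[s], duration)[0] for s in SIDES
        },
        fc_times={
            s: _truth_window(*schedules[s], duration)[1] for s in SIDES
        },
        config=config,
    )

    n_acc = int(round(duration * config.accel_rate_hz)) + 1
    t_acc = np.arange(n_acc) / config.accel_rate_hz
    accel: dict[str, AccelTrace] = {}
    for side in SIDES:
        ics, fcs = schedules[side]
        clean = _accel_waveform(t_acc, config, side, ics, fcs, rng)
        if config.noise_sd > 0:
            clean = clean + rng.normal(0.0, config.noise_sd, size=clean.size)
        accel[side] = AccelTrace(
            samples=clean, ts=1.0 / config.accel_rate_hz, side=side
        )

    n_moc = int(round(duration * config.mocap_rate_hz)) + 1
    t_moc = np.arange(n_moc) / config.mocap_rate_hz
    half_excursion = 0.5 * config.marker_excursion_m
    pelvis = np.column_stack(
        [config.walking_speed_ms * t_moc, np.zeros(n_moc), np.full(n_moc, 1.0)]
    )
    ankles = {}
    for side in SIDES:
        ics, fcs = schedules[side]
        rel = _relative_ap(t_moc, ics, fcs, half_excursion)
        lateral = 0.1 if side == "right" else -0.1
        ankles[side] = pelvis + np.column_stack(
            [rel, np.full(n_moc, lateral), np.full(n_moc, -0.9)]
        )
    markers = MarkerTrajectories(
        frame_rate=config.mocap_rate_hz,
        pelvis=pelvis,
        ankle_left=ankles["left"],
        ankle_right=ankles["right"],
        start_time=config.intersystem_offset_s,
    )
    return SimulatedWalk(
        participant_id=participant_id,
        walk_index=walk_index,
        accel=accel,
        markers=markers,
        truth=truth,
    )


def clean_signal_rms(config: GaitSimConfig) -> float:
    """RMS of the noiseless acceleration waveform (pooled over both sides)."""
    quiet = replace(config, noise_sd=0.0)
    walk = simulate_gait(quiet)
    samples = np.concatenate([walk.accel[s].samples for s in SIDES])
    return float(np.sqrt(np.mean(samples**2)))


def noise_sd_for_snr(config: GaitSimConfig, snr_db: float) -> float:
    """Noise SD giving the requested signal-to-noise ratio in dB."""
    return clean_signal_rms(config) / 10.0 ** (snr_db / 20.0)


@dataclass(frozen=True)
class CohortConfig:
    """Participant-level parameter distributions for a simulated cohort.

    Defaults emulate a small chronic-stroke validation cohort: 13
    participants, two 10 m walks each at self-selected speed, stride and
    stance-fraction variation across (not within) participants, walking
    speeds truncated to a practical 0.25–1.39 m/s band.
    """

    n_participants: int = 13
    walks_per_participant: int = 2
    walk_distance_m: float = 10.0
    cycle_mean_s: float = 1.37
    cycle_sd_s: float = 0.15
    cycle_bounds_s: tuple[float, float] = (0.95, 2.2)
    stance_fraction_mean: float = 0.62
    stance_fraction_sd: float = 0.03
    stance_fraction_bounds: tuple[float, float] = (0.5, 0.72)
    speed_mean_ms: float = 0.93
    speed_sd_ms: float = 0.38
    speed_bounds_ms: tuple[float, float] = (0.25, 1.39)
    duration_bounds_s: tuple[float, float] = (8.0, 45.0)
    base: GaitSimConfig = field(default_factory=GaitSimConfig)

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("cohort needs at least 1 participant")
        for sd in (self.cycle_sd_s, self.stance_fraction_sd, self.speed_sd_ms):
            if sd < 0:
                raise ParameterError("distribution SDs must be >= 0")


def _truncated_normal(rng, mean, sd, bounds):
    if sd == 0:
        return float(np.clip(mean, *bounds))
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if bounds[0] <= v <= bounds[1]:
            return float(v)
    return float(np.clip(mean, *bounds))


def simulate_cohort(cohort: CohortConfig, seed: int) -> list[SimulatedWalk]:
    """Simulate every walk of a cohort; deterministic given the seed.

    Each participant draws a stride period, stance fraction and walking
    speed once (truncated normal); each of their walks then runs long
    enough to cover ``walk_distance_m`` at that speed, clipped to the
    configured duration bounds.  Per-walk RNG sub-seeds derive from the
    master seed, so walks are independent but reproducible.
    """
    master = np.random.default_rng(seed)
    walks: list[SimulatedWalk] = []
    for p in range(cohort.n_participants):
        cycle = _truncated_normal(
            master, cohort.cycle_mean_s, cohort.cycle_sd_s, cohort.cycle_bounds_s
        )
        stance = _truncated_normal(
            master,
            cohort.stance_fraction_mean,
            cohort.stance_fraction_sd,
            cohort.stance_fraction_bounds,
        )
        speed = _truncated_normal(
            master, cohort.speed_mean_ms, cohort.speed_sd_ms, cohort.speed_bounds_ms
        )
        duration = float(
            np.clip(cohort.walk_distance_m / speed, *cohort.duration_bounds_s)
        )
        duration = max(duration, 3.5 * cycle)  # honour the min-cycles invariant
        pid = f"p{p:02d}"
        for w in range(cohort.walks_per_participant):
            sub_seed = int(master.integers(0, 2**31))
            config = replace(
                cohort.base,
                duration_s=duration,
                cycle_s=cycle,
                stance_fraction=stance,
                walking_speed_ms=speed,
                seed=sub_seed,
            )
            walks.append(simulate_gait(config, participant_id=pid, walk_index=w))
    return walks
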