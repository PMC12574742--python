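"""The accelerometer arm: filter, energy operator, period estimate, events."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal as sps

import gaitkeo as gk
from conftest import nearest_errors, recovery_rate, within_truth_span


def trace_of(x, ts=0.02, side="left"):
    return gk.AccelTrace(samples=np.asarray(x, float), ts=ts, side=side)


# ---------------------------------------------------------------------------
# High-pass filter
# ---------------------------------------------------------------------------


class TestHighpass:
    def test_dc_rejection(self):
        trace = trace_of(np.full(3000, 9.81))
        out = gk.highpass_filter(trace, 0.5, 4)
        assert np.max(np.abs(out.samples)) < 1e-6 * 9.81

    def test_passband_rms_matches_analytic_gain(self):
        # 5 Hz sinusoid at 50 Hz sampling; forward-backward filtering applies
        # the squared magnitude response, evaluated here with sosfreqz.
        t = np.arange(0, 60, 0.02)
        trace = trace_of(np.sin(2 * np.pi * 5 * t))
        out = gk.highpass_filter(trace, 0.5, 4)
        sos = sps.butter(4, 0.5, btype="highpass", fs=50.0, output="sos")
        _, h = sps.sosfreqz(sos, worN=[5.0], fs=50.0)
        expected_gain = np.abs(h[0]) ** 2
        core = slice(250, -250)  # clear of edge transients
        ratio = np.sqrt(np.mean(out.samples[core] ** 2) / np.mean(trace.samples[core] ** 2))
        assert ratio == pytest.approx(expected_gain, rel=0.01)
        assert abs(ratio - 1.0) < 0.01  # 5 Hz is deep in the passband

    def test_zero_phase(self):
        t = np.arange(0, 60, 0.02)
        x = np.sin(2 * np.pi * 5 * t)
        out = gk.highpass_filter(trace_of(x), 0.5, 4).samples
        xc = np.correlate(x[500:-500], out[500:-500], mode="full")
        lag = int(np.argmax(xc)) - (len(x[500:-500]) - 1)
        assert lag == 0

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(gk.ParameterError):
            gk.highpass_filter(trace_of(np.zeros(3000)), 25.0, 4)

    def test_short_trace_rejected(self):
        with pytest.raises(gk.DataError):
            gk.highpass_filter(trace_of(np.zeros(100)), 0.5, 4)  # 2 s at 50 Hz


# ---------------------------------------------------------------------------
# Discrete TKEO
# ---------------------------------------------------------------------------


class TestTkeoDiscrete:
    def test_constant_gives_zero(self):
        series = gk.tkeo_discrete(trace_of(np.full(50, 5.0), ts=1.0))
        lo, hi = series.valid_range
        assert series.phi[lo:hi] == pytest.approx(np.zeros(hi - lo), abs=1e-12)

    def test_ramp_consistent_gives_one(self):
        # x=t has continuous energy ẋ² − x·ẍ = 1; the consistent stencil is
        # exact on polynomials of degree <= 2: (2n² + 4 − 2n²)/4 = 1.
        series = gk.tkeo_discrete(trace_of(np.arange(50, dtype=float), ts=1.0))
        lo, hi = series.valid_range
        assert series.phi[lo:hi] == pytest.approx(np.ones(hi - lo), abs=1e-12)

    def test_ramp_literal_differs(self):
        # printed-form operator on the ramp: (2n² + 4 − 4n)/4
        series = gk.tkeo_discrete(
            trace_of(np.arange(50, dtype=float), ts=1.0), variant="literal"
        )
        n = np.arange(2, 48)
        expected = (2 * n.astype(float) ** 2 + 4 - 4 * n) / 4
        assert series.phi[2:48] == pytest.approx(expected, abs=1e-12)

    def test_sinusoid_continuous_limit(self):
        # Ψ of A·cos(ωt) is A²ω²; at Ts=1 ms the discrete error is O(Ts²).
        ts = 0.001
        t = np.arange(0, 2, ts)
        series = gk.tkeo_discrete(trace_of(np.cos(2 * np.pi * t), ts=ts))
        lo, hi = series.valid_range
        target = (2 * np.pi) ** 2
        assert np.max(np.abs(series.phi[lo:hi] - target)) < 1e-3 * target

    def test_continuous_limit_error_order(self):
        # halving Ts shrinks the worst-case sinusoid error ~4x
        errs = []
        for ts in (0.004, 0.002, 0.001):
            t = np.arange(0, 2, ts)
            s = gk.tkeo_discrete(trace_of(np.cos(2 * np.pi * t), ts=ts))
            lo, hi = s.valid_range
            errs.append(np.max(np.abs(s.phi[lo:hi] - (2 * np.pi) ** 2)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.15)
        assert errs[1] / errs[2] == pytest.approx(4.0, rel=0.15)

    def test_edges_zeroed_and_excluded(self):
        series = gk.tkeo_discrete(trace_of(np.arange(10, dtype=float), ts=1.0))
        assert series.phi[[0, 1, -2, -1]] == pytest.approx(np.zeros(4))
        assert series.valid_range == (2, 8)

    @given(scale=st.floats(0.1, 100.0), seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_scale_covariance(self, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=64)
        phi1 = gk.tkeo_discrete(trace_of(x, ts=0.02)).phi
        phi2 = gk.tkeo_discrete(trace_of(scale * x, ts=0.02)).phi
        np.testing.assert_allclose(phi2, scale**2 * phi1, rtol=1e-9, atol=1e-9)

    def test_rejects_unknown_variant(self):
        with pytest.raises(gk.ParameterError):
            gk.tkeo_discrete(trace_of(np.zeros(10)), variant="banana")


# ---------------------------------------------------------------------------
# Stride-period estimate
# ---------------------------------------------------------------------------


class TestCycleEstimate:
    def test_recovers_known_cycle(self):
        walk = gk.simulate_gait(gk.GaitSimConfig(seed=42, cycle_s=1.2))
        filtered = gk.highpass_filter(walk.accel["right"])
        assert gk.estimate_cycle_duration(filtered) == pytest.approx(1.2, abs=0.04)

    def test_white_noise_has_no_gait(self):
        rng = np.random.default_rng(0)
        trace = trace_of(rng.normal(size=3000))
        with pytest.raises(gk.DetectionError, match="no periodic gait"):
            gk.estimate_cycle_duration(trace)

    def test_mixed_cadences_land_between(self):
        # two concatenated walking bouts at different cadences: the estimate
        # must land within the spanned range, not at a common multiple
        wa = gk.simulate_gait(gk.GaitSimConfig(seed=1, cycle_s=1.0, duration_s=30))
        wb = gk.simulate_gait(gk.GaitSimConfig(seed=2, cycle_s=1.4, duration_s=30))
        x = np.concatenate(
            [wa.accel["right"].samples, wb.accel["right"].samples]
        )
        period = gk.estimate_cycle_duration(trace_of(x, ts=0.02, side="right"))
        assert 1.0 - 0.04 <= period <= 1.4 + 0.04

    def test_too_short_signal_rejected(self):
        with pytest.raises(gk.DataError):
            gk.estimate_cycle_duration(trace_of(np.zeros(100), ts=0.02))


# ---------------------------------------------------------------------------
# IC detection
# ---------------------------------------------------------------------------


def _detector_series(trace, params=None):
    params = params or gk.DetectorParams()
    filtered = gk.highpass_filter(trace, params.hp_cutoff_hz, params.hp_order)
    series = gk.tkeo_discrete(filtered, params.tkeo_variant)
    return gk.smooth_tkeo(series, params.smooth_window_s)


class TestDetectIC:
    def test_all_injected_ics_found_at_10db(self, noisy_walk):
        params = gk.DetectorParams()
        for side in ("left", "right"):
            series = _detector_series(noisy_walk.accel[side], params)
            cycle = gk.estimate_cycle_duration(
                gk.highpass_filter(noisy_walk.accel[side])
            )
            ics = gk.detect_ic(series, params, cycle)
            truth = noisy_walk.truth.ic_times[side]
            det = within_truth_span([e.time_s for e in ics], truth)
            assert nearest_errors(det, truth).max() <= 0.04  # no spurious ICs
            hit = sum(np.min(np.abs(det - t)) <= 0.04 for t in truth)
            assert hit >= 0.95 * truth.size

    def test_single_transient_in_flat_signal(self):
        ts = 0.02
        t = np.arange(0, 10, ts)
        u = t - 5.0
        x = 3.0 * np.exp(-0.5 * (u / 0.025) ** 2) * np.cos(2 * np.pi * 10 * u)
        series = gk.smooth_tkeo(gk.tkeo_discrete(trace_of(x, ts=ts)), 0.06)
        ics = gk.detect_ic(series, gk.DetectorParams(), cycle_s=1.37)
        assert len(ics) == 1
        assert ics[0].time_s == pytest.approx(5.0, abs=ts)

    def test_unattainable_threshold_is_detection_error(self):
        params = gk.DetectorParams(ic_rel_threshold=1.1)
        ts = 0.02
        t = np.arange(0, 20, ts)
        # identical sample-aligned bursts: every per-cycle maximum equals the
        # median, so a 1.1x threshold exceeds all peaks
        x = np.zeros_like(t)
        for c in np.arange(1.0, 19.0, 1.0):
            u = t - c
            x += np.exp(-0.5 * (u / 0.025) ** 2)
        series = gk.smooth_tkeo(gk.tkeo_discrete(trace_of(x, ts=ts)), 0.06)
        with pytest.raises(gk.DetectionError):
            gk.detect_ic(series, params, cycle_s=1.0)


class TestDetectFC:
    def test_fc_transients_found_at_10db(self, noisy_walk):
        params = gk.DetectorParams()
        for side in ("left", "right"):
            events = gk.detect_gait_events(noisy_walk.accel[side], params)
            det = np.array([e.time_s for e in events.events if e.type == "FC"])
            errs = nearest_errors(det, noisy_walk.truth.fc_times[side])
            assert np.mean(errs <= 0.04) >= 0.95

    def test_fc_outside_window_drops_stride(self, caplog):
        # FC bumps at 10 % of each cycle sit below the 25 % window edge
        # (and inside the IC mask), so every stride must be dropped
        ts, cycle = 0.02, 1.0
        t = np.arange(0, 12, ts)
        phi = np.zeros_like(t)
        ic_times = np.arange(1.0, 11.0, cycle)
        for c in ic_times:
            phi += 100.0 * np.exp(-0.5 * ((t - c) / 0.02) ** 2)
            phi += 40.0 * np.exp(-0.5 * ((t - c - 0.10 * cycle) / 0.02) ** 2)
        series = gk.TkeoSeries(phi=phi, ts=ts, side="right")
        ics = [
            gk.GaitEvent("IC", "right", c, int(round(c / ts))) for c in ic_times
        ]
        with caplog.at_level("WARNING", logger="gaitkeo"):
            pairs = gk.detect_fc(series, ics, gk.DetectorParams(), cycle)
        assert pairs == []
        assert any(
            "window" in r.message or "whole interval" in r.message
            for r in caplog.records
        )

    def test_mask_covering_cycle_drops_everything(self, quiet_walk):
        params = gk.DetectorParams(mask_halfwidth_frac=0.6)
        events = gk.detect_gait_events(quiet_walk.accel["right"], params)
        assert len(events.strides) == 0

    def test_needs_two_ics(self, quiet_walk):
        series = _detector_series(quiet_walk.accel["right"])
        with pytest.raises(gk.DetectionError):
            gk.detect_fc(series, [], gk.DetectorParams(), 1.37)


class TestComputeStance:
    def test_stance_is_fc_minus_ic(self):
        ic = gk.GaitEvent("IC", "left", 1.00, 50)
        fc = gk.GaitEvent("FC", "left", 1.62, 81)
        series = gk.compute_stance([(ic, fc)])
        assert series.strides[0].stance_s == pytest.approx(0.62)

    def test_rejects_inverted_pair(self, caplog):
        ic = gk.GaitEvent("IC", "left", 2.00, 100)
        fc = gk.GaitEvent("FC", "left", 1.62, 81)
        with caplog.at_level("WARNING", logger="gaitkeo"):
            series = gk.compute_stance([(ic, fc)])
        assert series.strides == []

    def test_no_fcs_is_not_a_crash(self):
        series = gk.compute_stance([])
        assert series.strides == [] and series.events == []

    def test_cohort_stance_in_study_regime(self):
        # comfortable-pace defaults (1.37 s cycle, 62 % stance) should land
        # near the 0.85-0.88 s stance range typical of chronic-stroke walking
        walks = gk.simulate_cohort(gk.CohortConfig(n_participants=5), seed=2)
        pairs = gk.pair_walks(walks, on_error="skip")
        mean_stance = np.mean(pairs.accel())
        assert 0.70 <= mean_stance <= 1.0


class TestEndToEnd:
    def test_detection_is_deterministic(self, noisy_walk):
        a = gk.detect_gait_events(noisy_walk.accel["left"])
        b = gk.detect_gait_events(noisy_walk.accel["left"])
        assert [(e.type, e.time_s, e.sample_index) for e in a.events] == [
            (e.type, e.time_s, e.sample_index) for e in b.events
        ]
        assert [s.stance_s for s in a.strides] == [s.stance_s for s in b.strides]

    def test_most_strides_recovered(self, noisy_walk):
        for side in ("left", "right"):
            events = gk.detect_gait_events(noisy_walk.accel[side])
            n_true = noisy_walk.truth.ic_times[side].size
            assert len(events.strides) >= 0.95 * (n_true - 1)

    def test_event_times_invariant_to_input_scale(self, quiet_walk):
        trace = quiet_walk.accel["right"]
        a = gk.detect_gait_events(trace)
        b = gk.detect_gait_events(trace.with_samples(3.7 * trace.samples))
        assert [e.time_s for e in a.events] == pytest.approx(
            [e.time_s for e in b.events]
        )

    def test_short_trace_fails_in_filter_stage(self):
        trace = trace_of(np.random.default_rng(0).normal(size=100))  # 2 s
        with pytest.raises(gk.DataError, match="highpass_filter"):
            gk.detect_gait_events(trace)

    def test_recovery_monotone_in_noise(self, snr10_noise_sd):
        rates = []
        for noise in (0.5 * snr10_noise_sd, snr10_noise_sd, 3.0 * snr10_noise_sd):
            hits = total = 0
            for seed in range(5):
                walk = gk.simulate_gait(
                    gk.GaitSimConfig(seed=seed, noise_sd=noise)
                )
                for side in ("left", "right"):
                    try:
                        ev = gk.detect_gait_events(walk.accel[side])
                    except gk.GaitError:
                        ev = gk.EventSeries()
                    r = recovery_rate(walk, ev, side, tol_s=0.04)
                    n = (
                        walk.truth.ic_times[side].size
                        + walk.truth.fc_times[side].size
                    )
                    hits += r * n
                    total += n
            rates.append(hits / total)
        assert rates[0] >= rates[1] - 1e-9 >= rates[2] - 2e-9


class TestDetectorParams:
    def test_round_trips_through_dict(self):
        params = gk.DetectorParams(ic_rel_threshold=0.4, fc_window_frac=(0.3, 0.7))
        assert gk.DetectorParams.from_dict(params.to_dict()) == params

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mask_halfwidth_frac": 0.0},
            {"fc_window_frac": (0.7, 0.3)},
            {"tkeo_variant": "nope"},
            {"hp_cutoff_hz": -1.0},
            {"stride_band_frac": (1.2, 1.5)},
            {"smooth_window_s": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(gk.ParameterError):
            gk.DetectorParams(**kwargs)
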