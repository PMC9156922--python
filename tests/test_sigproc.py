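"""Filtering, drift correction, stance detection and leg labelling."""

import numpy as np
import pytest

from rspgait import SimTrialConfig, simulate_trial
from rspgait.sigproc import (
    AFFECTED,
    UNAFFECTED,
    UNKNOWN,
    DriftError,
    GrfTrial,
    MarkerTrial,
    StanceEvent,
    assign_legs,
    correct_drift,
    detect_stance,
    is_saturated,
    lowpass,
    lowpass_trial,
)

FS = 1000.0


def _trial(force, **kw):
    kw.setdefault("sample_rate", FS)
    kw.setdefault("body_mass", 76.0)
    kw.setdefault("belt_speed", 3.0)
    return GrfTrial(force=np.asarray(force, float), **kw)


def _half_sine(peak, t_c, fs=FS, pad=0.5):
    """One symmetric half-sine bump with aerial padding either side."""
    n = int(round((2 * pad + t_c) * fs))
    t = np.arange(n) / fs
    f = np.zeros(n)
    mask = (t >= pad) & (t < pad + t_c)
    f[mask] = peak * np.sin(np.pi * (t[mask] - pad + 0.5 / fs) / t_c)
    return f


class TestLowpass:
    def test_unit_dc_gain_on_constant(self):
        out = lowpass(np.full(4000, 700.0), 30.0, FS)
        assert np.allclose(out, 700.0, atol=1e-9)

    def test_passband_sinusoid_unattenuated_zero_lag(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        y = lowpass(x, 30.0, FS)
        mid = slice(2000, 6000)  # away from filtfilt edge transients
        assert np.abs(y[mid]).max() > 0.99
        # zero phase and <1% attenuation: filtered wave overlays the input
        assert np.allclose(y[mid], x[mid], atol=0.01)

    def test_stopband_sinusoid_strongly_attenuated(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 100.0 * t)
        y = lowpass(x, 30.0, FS)
        assert np.abs(y[2000:6000]).max() < 0.01

    def test_output_length_equals_input(self):
        assert lowpass(np.random.default_rng(0).normal(size=777), 30.0, FS).size == 777

    def test_cutoff_at_or_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(np.zeros(100), 500.0, FS)


class TestCorrectDrift:
    def test_identity_when_baseline_already_zero(self, symmetric_trial):
        _, trial, _, _ = symmetric_trial
        out = correct_drift(trial)
        assert np.abs(out.force - trial.force).max() < 0.5

    def test_linear_ramp_removed(self, symmetric_trial):
        """10 N linear drift: aerial medians back to +/-0.5 N, stance means to 0.5%."""
        cfg, clean, _, truth = symmetric_trial
        ramp = 10.0 * np.arange(clean.force.size) / clean.force.size
        drifted = _trial(clean.force + ramp)
        out = correct_drift(drifted)
        fs = cfg.sample_rate_force
        for _, row in truth.per_step.iterrows():
            a = int(round(row["t_touchdown_s"] * fs))
            b = int(round((row["t_touchdown_s"] + row["t_c"]) * fs))
            assert out.force[a:b].mean() == pytest.approx(
                clean.force[a:b].mean(), rel=0.005
            )
            gap = out.force[b + 30 : a + int(round((row["t_c"] + row["t_a"]) * fs)) - 30]
            if gap.size:
                assert abs(np.median(gap)) < 0.5

    def test_no_aerial_phase_is_an_error(self):
        with pytest.raises(DriftError, match="no aerial baseline"):
            correct_drift(_trial(np.full(3000, 500.0)))


class TestDetectStance:
    def test_empty_and_quiet_signals_give_no_events(self):
        assert detect_stance(_trial(np.zeros(0))) == []
        assert detect_stance(_trial(np.zeros(3000))) == []

    def test_single_bump_matches_analytic_threshold_crossing(self):
        """Detected t_c vs the closed-form 20 N crossing of a 1500 N half-sine."""
        t_c, peak = 0.2, 1500.0
        events = detect_stance(_trial(_half_sine(peak, t_c)))
        assert len(events) == 1
        expected = t_c - 2 * (t_c / np.pi) * np.arcsin(20.0 / peak)
        assert events[0].t_c == pytest.approx(expected, abs=1.0 / FS)

    def test_short_dip_merged_into_one_stance(self):
        f = _half_sine(1500.0, 0.2)
        mid = np.argmax(f)
        f[mid : mid + 5] = 0.0  # 5 ms dropout
        events = detect_stance(_trial(f), min_aerial=0.02)
        assert len(events) == 1

    def test_short_burst_discarded(self):
        f = np.zeros(3000)
        f[1000:1020] = 300.0  # 20 ms blip < min_contact
        assert detect_stance(_trial(f)) == []

    def test_edge_touching_stances_discarded(self):
        f = np.concatenate([np.full(100, 500.0), np.zeros(800), _half_sine(800.0, 0.1, pad=0.2)])
        events = detect_stance(_trial(f))
        assert len(events) == 1
        assert events[0].touchdown > 900

    def test_events_partition_and_aerial_times(self, asymmetric_trial):
        _, trial, _, _ = asymmetric_trial
        events = detect_stance(correct_drift(trial))
        for a, b in zip(events, events[1:]):
            assert a.takeoff <= b.touchdown
            assert a.t_a == pytest.approx((b.touchdown - a.takeoff) / FS)
        assert events[-1].t_a is None

    def test_time_reversed_signal_gives_time_reversed_events(self, asymmetric_trial):
        _, trial, _, _ = asymmetric_trial
        fwd = detect_stance(trial)
        rev = detect_stance(_trial(trial.force[::-1]))
        n = trial.force.size
        assert [(n - e.takeoff, n - e.touchdown) for e in reversed(rev)] == [
            (e.touchdown, e.takeoff) for e in fwd
        ]

    @pytest.mark.parametrize("t_c,t_a,v", [(0.2, 0.12, 3.0), (0.14, 0.11, 7.0)])
    def test_round_trip_against_truth(self, t_c, t_a, v):
        """Detected stance edges within 2 samples per edge of the generator truth."""
        cfg = SimTrialConfig(seed=5, base_t_c=t_c, base_t_a=t_a, belt_speed=v)
        trial, _, truth = simulate_trial(cfg)
        events = detect_stance(correct_drift(trial))
        assert len(events) == cfg.n_steps
        for ev, (_, row) in zip(events, truth.per_step.iterrows()):
            td_true = row["t_touchdown_s"] * FS
            to_true = (row["t_touchdown_s"] + row["t_c"]) * FS
            assert abs(ev.touchdown - td_true) <= 2.0
            assert abs(ev.takeoff - to_true) <= 2.0

    def test_detection_invariant_under_corrected_drift(self, symmetric_trial):
        """Removing a 10 N ramp leaves event count identical and edges within 1 sample."""
        _, clean, _, _ = symmetric_trial
        base = detect_stance(correct_drift(clean))
        ramp = 10.0 * np.arange(clean.force.size) / clean.force.size
        corrected = correct_drift(_trial(clean.force + ramp))
        events = detect_stance(corrected)
        assert len(events) == len(base)
        for a, b in zip(base, events):
            assert abs(a.touchdown - b.touchdown) <= 1
            assert abs(a.takeoff - b.takeoff) <= 1


class TestAssignLegs:
    def test_marker_based_labels_match_generator_truth(self, asymmetric_trial):
        _, trial, markers, truth = asymmetric_trial
        events = detect_stance(correct_drift(trial))
        labelled = assign_legs(events, markers, trial.sample_rate)
        assert [e.leg for e in labelled] == list(truth.per_step["leg"])

    def test_fallback_alternation_without_markers(self):
        events = [StanceEvent(100 * i, 100 * i + 50) for i in range(4)]
        labelled = assign_legs(events, None, FS, fallback_first_leg=AFFECTED)
        assert [e.leg for e in labelled] == [AFFECTED, UNAFFECTED, AFFECTED, UNAFFECTED]

    def test_alternation_violation_labelled_unknown(self):
        # markers always resolve to the affected leg -> every second event unknown
        markers = MarkerTrial(
            affected=np.full(1000, 0.05), unaffected=np.full(1000, 0.15), sample_rate=200.0
        )
        events = [StanceEvent(100 * i, 100 * i + 50) for i in range(3)]
        labelled = assign_legs(events, markers, FS)
        assert [e.leg for e in labelled] == [AFFECTED, UNKNOWN, AFFECTED]

    def test_missing_marker_interval_gives_unknown(self):
        markers = MarkerTrial(
            affected=np.full(10, 0.05), unaffected=np.full(10, 0.15), sample_rate=200.0
        )
        events = [StanceEvent(5000, 5100)]  # beyond marker coverage
        assert assign_legs(events, markers, FS)[0].leg == UNKNOWN


class TestSaturation:
    def test_flags_runs_at_ceiling(self):
        f = np.zeros(1000)
        f[500:504] = 2000.0
        assert is_saturated(f, 2000.0)
        assert not is_saturated(f, 2000.1)
        assert not is_saturated(f, None)

    def test_short_touch_not_flagged(self):
        f = np.zeros(1000)
        f[500:502] = 2000.0
        assert not is_saturated(f, 2000.0, min_run=3)
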