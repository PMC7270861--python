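"""Synthetic cohort generator: trajectories, beats, waveforms, determinism."""
import numpy as np
import pytest
from scipy.integrate import quad

from walkbeat.features import effort
from walkbeat.simulate import (
    CohortSpec,
    GroupProfile,
    beats_from_hr,
    default_high_profile,
    default_low_profile,
    hr_trajectory,
    make_hr_fn,
    simulate_session,
    synth_accel,
    synth_ecg,
    truth_table,
)
from walkbeat.types import PhaseLayout, ValidationError

from conftest import tiny_spec


class TestHrTrajectory:
    def test_flat_when_coefficients_zero(self):
        fn = make_hr_fn(70.0, 0.0, 0.0, 60.0, PhaseLayout())
        t = np.linspace(0, 960, 500)
        assert np.allclose(fn(t), 70.0)

    def test_walk_rise_matches_closed_form(self):
        # low-response baseline kinetics evaluated by direct substitution
        a, b = -0.00013, 0.065
        lay = PhaseLayout()
        fn = make_hr_fn(70.0, a, b, 90.0, lay)
        rise = fn(lay.rest_s + 360.0) - fn(lay.rest_s)
        assert rise == pytest.approx(b * 360 + a * 360**2, abs=1e-9)

    def test_continuity_at_phase_boundaries(self):
        lay = PhaseLayout()
        fn = make_hr_fn(72.0, -1e-4, 0.05, 80.0, lay)
        for t0 in (lay.walk_onset_s, lay.recovery_onset_s):
            assert fn(t0 - 1e-6) == pytest.approx(fn(t0 + 1e-6), abs=1e-3)

    def test_recovery_asymptote_is_rest_hr(self):
        fn = make_hr_fn(68.0, -1e-4, 0.06, 50.0, PhaseLayout())
        assert fn(1e7) == pytest.approx(68.0, abs=1e-6)

    def test_recovery_monotone_toward_rest(self):
        lay = PhaseLayout()
        fn = make_hr_fn(70.0, -1e-4, 0.06, 60.0, lay)
        t = np.linspace(lay.recovery_onset_s, lay.total_s, 200)
        assert np.all(np.diff(fn(t)) <= 0)

    def test_profile_trajectory_session_range(self):
        with pytest.raises(ValidationError):
            hr_trajectory(default_low_profile(), 5)


class TestBeatsFromHr:
    def test_constant_60_bpm(self):
        beats = beats_from_hr(lambda t: 60.0, 60.0)
        assert len(beats) == 61  # 60 intervals of exactly 1.0 s
        assert np.allclose(np.diff(beats), 1.0)

    def test_constant_120_bpm(self):
        beats = beats_from_hr(lambda t: 120.0, 60.0)
        assert np.allclose(np.diff(beats), 0.5)

    def test_ramp_count_matches_quadrature(self):
        hr = lambda t: 60.0 + 60.0 * t / 360.0
        beats = beats_from_hr(hr, 360.0)
        expected, _ = quad(lambda t: hr(t) / 60.0, 0, 360.0)
        assert abs((len(beats) - 1) - expected) <= 1

    def test_nonpositive_hr_rejected(self):
        with pytest.raises(ValidationError):
            beats_from_hr(lambda t: -5.0, 10.0)

    def test_rr_bounds_and_monotone(self, rng):
        beats = beats_from_hr(
            lambda t: 70.0, 120.0, jitter_sd=0.1, rng=rng, hr_noise_sd=5.0
        )
        rr = np.diff(beats)
        assert np.all(rr > 0)
        assert np.all((rr >= 0.3 - 1e-12) & (rr <= 2.0 + 1e-12))

    def test_windowed_hr_recovers_hr_fn(self):
        from walkbeat.features import hr_series
        from walkbeat.types import BeatSeries

        hr = lambda t: 70.0 + 0.05 * t
        beats = BeatSeries.from_times(beats_from_hr(hr, 300.0))
        series = hr_series(beats, 16.0, 4.0, span=(0.0, 300.0))
        assert np.all(np.abs(series.hr - hr(series.times)) < 0.5)


class TestSynthEcg:
    def test_zero_beats_noise_only_length(self):
        sig = synth_ecg(np.array([]), 10.0, fs=512.0)
        assert len(sig) == 5120
        assert np.allclose(sig, 0.0)

    def test_r_peaks_at_beat_times(self):
        beats = np.arange(0.5, 59.5, 1.0)
        sig = synth_ecg(beats, 60.0, fs=512.0)
        for b in beats[:10]:
            i = int(round(b * 512))
            w = sig[i - 10 : i + 11]
            assert abs(np.argmax(w) - 10) <= 1  # peak within one sample

    def test_invalid_fs(self):
        with pytest.raises(ValidationError):
            synth_ecg(np.array([1.0]), 2.0, fs=0)

    def test_saturation_burst_pins_signal(self):
        from walkbeat.simulate import EcgNoise

        sig = synth_ecg(
            np.arange(0.5, 9.5),
            10.0,
            fs=512.0,
            noise=EcgNoise(burst_spans=((4.0, 2.0),), broadband_sd=0.0,
                           baseline_amp=0.0),
        )
        assert np.allclose(sig[int(4.5 * 512) : int(5.5 * 512)], 4.0)


class TestSynthAccel:
    def test_zero_intensity_zero_effort(self):
        acc = synth_accel(1.8, 0.0, 60.0, noise_sd=0.0)
        assert effort(acc) == pytest.approx(0.0, abs=1e-12)

    def test_effort_linear_in_intensity(self, rng):
        a1 = synth_accel(1.8, 1.0, 120.0, noise_sd=0.0)
        a2 = synth_accel(1.8, 2.0, 120.0, noise_sd=0.0)
        assert effort(a2) == pytest.approx(2.0 * effort(a1), rel=1e-9)

    def test_determinism(self):
        a = synth_accel(1.8, 1.0, 30.0, rng=3, noise_sd=0.05)
        b = synth_accel(1.8, 1.0, 30.0, rng=3, noise_sd=0.05)
        assert np.array_equal(a, b)

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValidationError):
            synth_accel(1.8, -1.0, 10.0)


class TestCohort:
    def test_default_low_baseline_mean(self):
        tt = truth_table(CohortSpec(seed=11))
        base = tt[(tt.group == "low") & (tt.session == 0)]
        se = 95.0 / np.sqrt(44)
        assert len(base) == 44
        assert abs(base.distance.mean() - 496.0) < 3 * se

    def test_group_separation_at_threshold(self):
        tt = truth_table(CohortSpec(seed=5))
        per_patient = tt.groupby("patient").agg(
            gain=("total_gain", "first"), group=("group", "first")
        )
        assert (per_patient.loc[per_patient.group == "low", "gain"] < 90).all()
        assert (per_patient.loc[per_patient.group == "high", "gain"] > 90).all()

    def test_distances_interpolate_monotonically(self):
        tt = truth_table(CohortSpec(seed=2))
        for _, sub in tt.groupby("patient"):
            d = sub.sort_values("session")["distance"].to_numpy()
            g = sub["total_gain"].iloc[0]
            assert np.all(np.sign(np.diff(d)) == np.sign(g))
            assert d[-1] - d[0] == pytest.approx(g, abs=1e-9)

    def test_seed_determinism(self):
        spec = tiny_spec(seed=9, n_low=1, n_high=1)
        sr1 = simulate_session(spec, 0, spec.profiles[0], 0, 0)
        sr2 = simulate_session(spec, 0, spec.profiles[0], 0, 0)
        assert np.array_equal(sr1.truth.beat_times, sr2.truth.beat_times)
        assert np.array_equal(sr1.recording.ecg, sr2.recording.ecg)
        spec_b = tiny_spec(seed=10, n_low=1, n_high=1)
        sr3 = simulate_session(spec_b, 0, spec_b.profiles[0], 0, 0)
        assert not np.array_equal(sr1.truth.beat_times, sr3.truth.beat_times)

    def test_noiseless_walk_phase_follows_quadratic(self, noiseless_spec):
        spec = noiseless_spec
        prof = spec.profiles[0]
        sr = simulate_session(spec, 0, prof, 0, 0)
        a, b = prof.walk_kinetics_by_session[0]
        lay = spec.layout
        t = sr.truth.beat_times
        walk = t[(t >= lay.rest_s) & (t < lay.recovery_onset_s - 2.0)]
        rr = np.diff(walk)
        # each RR was generated as exactly 60/hr at the interval onset
        hr_emitted = 60.0 / rr
        u = walk[:-1] - lay.rest_s
        expected = prof.rest_hr_mean + b * u + a * u**2
        assert np.allclose(hr_emitted, expected, atol=1e-9)

    def test_invalid_profile_fields_named(self):
        with pytest.raises(ValidationError, match="n_patients"):
            GroupProfile(
                label="low",
                n_patients=0,
                baseline_distance_mean=500,
                baseline_distance_sd=90,
                total_gain_mean=55,
                total_gain_sd=25,
                walk_kinetics_by_session=tuple([(0.0, 0.0)] * 5),
                recovery_tau_by_session=tuple([90.0] * 5),
            )
        with pytest.raises(ValidationError, match="walk_kinetics_by_session"):
            GroupProfile(
                label="low",
                n_patients=4,
                baseline_distance_mean=500,
                baseline_distance_sd=90,
                total_gain_mean=55,
                total_gain_sd=25,
                walk_kinetics_by_session=((0.0, 0.0),),
                recovery_tau_by_session=tuple([90.0] * 5),
            )
        with pytest.raises(ValidationError, match="n_sessions"):
            CohortSpec(seed=1, n_sessions=1)

    def test_attendance_counts_in_range(self):
        tt = truth_table(CohortSpec(seed=4))
        att = tt.loc[tt.session > 0, "attendance"]
        assert att.between(0, 9).all()
        assert tt.loc[tt.session == 0, "attendance"].isna().all()
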