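"""Synthetic two-group, five-session wearable 6MWT cohort.

The generator emulates a cardiac-rehabilitation cohort followed with a
chest-worn single-lead ECG (512 Hz) and triaxial accelerometer (32 Hz)
during five six-minute walking tests, three weeks apart.  Patients fall
into a low-response and a high-response group according to whether their
total gain in walking distance exceeds 90 m; the groups differ in their
distance trajectories, in the quadratic heart-rate kinetics of the
walking phase, and in how their recovery time constant evolves.

Everything downstream of the patient-level parameters — instantaneous
heart-rate trajectory, beat times, ECG waveform, accelerometer trace —
is generated here together with the ground truth needed to validate the
processing chain.  All randomness is driven by a single integer seed via
`numpy.random.SeedSequence` spawn keys, so the same seed reproduces the
cohort exactly, session by session, in any iteration order.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Callable, Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .types import (
    PhaseLayout,
    Recording,
    RR_MAX_S,
    RR_MIN_S,
    ValidationError,
)

#: Published split threshold on the total distance gain (m).
RESPONSE_THRESHOLD_M = 90.0

#: Expected rehabilitation sessions between consecutive walking tests.
EXPECTED_ATTENDANCE = 9

#: Mean per-interval attendance probability (mean compliance ~86%).
ATTENDANCE_P = 0.86


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one response group.

    ``walk_kinetics_by_session`` holds one (a, b) pair per session: the
    true quadratic walking-phase kinetics HR(t) = rest_hr + b t + a t²
    with t in seconds from walk onset.  ``recovery_tau_by_session`` is
    the exponential recovery time constant (s) per session.  Per-patient
    heterogeneity is multiplicative: each patient carries N(1, coeff sd)
    factors on (a, b) and on tau, constant across sessions.
    """

    label: str
    n_patients: int
    baseline_distance_mean: float
    baseline_distance_sd: float
    total_gain_mean: float
    total_gain_sd: float
    walk_kinetics_by_session: tuple  # 5 (a, b) pairs, bpm/s² and bpm/s
    recovery_tau_by_session: tuple  # 5 time constants, s
    rest_hr_mean: float = 70.0
    rest_hr_sd: float = 3.0
    hr_noise_sd: float = 2.0
    coeff_patient_rel_sd: float = 0.10
    tau_patient_rel_sd: float = 0.10
    gain_side: str = "below"  # truncation side relative to the threshold

    def __post_init__(self) -> None:
        if self.label not in ("low", "high"):
            raise ValidationError("GroupProfile.label must be 'low' or 'high'")
        if self.n_patients <= 0:
            raise ValidationError("GroupProfile.n_patients must be > 0")
        for name in (
            "baseline_distance_sd",
            "total_gain_sd",
            "rest_hr_sd",
            "hr_noise_sd",
            "coeff_patient_rel_sd",
            "tau_patient_rel_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"GroupProfile.{name} must be >= 0")
        if len(self.walk_kinetics_by_session) != 5:
            raise ValidationError(
                "GroupProfile.walk_kinetics_by_session must have 5 entries"
            )
        if len(self.recovery_tau_by_session) != 5:
            raise ValidationError(
                "GroupProfile.recovery_tau_by_session must have 5 entries"
            )
        if self.gain_side not in ("below", "above"):
            raise ValidationError("GroupProfile.gain_side must be below/above")


# Baseline walking-phase kinetics: the low-response group starts with the
# steeper heart-rate rise (a = -1.3e-4 bpm/s², b = 6.5e-2 bpm/s) and keeps
# it; the high-response group starts blunted (-2.7e-5, 2.2e-2) and catches
# up linearly by the final session.
_LOW_KIN = (-1.3e-4, 6.5e-2)
_HIGH_KIN0 = (-2.7e-5, 2.2e-2)


def _interp_kinetics(start, end, n=5):
    return tuple(
        (
            start[0] + (end[0] - start[0]) * s / (n - 1),
            start[1] + (end[1] - start[1]) * s / (n - 1),
        )
        for s in range(n)
    )


def default_low_profile(**overrides) -> GroupProfile:
    """Low-response group: n=44, baseline 496 (95) m, total gain 55 (25) m."""
    base = GroupProfile(
        label="low",
        n_patients=44,
        baseline_distance_mean=496.0,
        baseline_distance_sd=95.0,
        total_gain_mean=55.0,
        total_gain_sd=25.0,
        walk_kinetics_by_session=tuple([_LOW_KIN] * 5),
        recovery_tau_by_session=tuple([90.0] * 5),
        gain_side="below",
    )
    return replace(base, **overrides) if overrides else base


def default_high_profile(**overrides) -> GroupProfile:
    """High-response group: n=45, baseline 473 (97) m, total gain 147 (25) m."""
    base = GroupProfile(
        label="high",
        n_patients=45,
        baseline_distance_mean=473.0,
        baseline_distance_sd=97.0,
        total_gain_mean=147.0,
        total_gain_sd=25.0,
        walk_kinetics_by_session=_interp_kinetics(_HIGH_KIN0, _LOW_KIN),
        recovery_tau_by_session=tuple(np.linspace(90.0, 30.0, 5)),
        gain_side="above",
    )
    return replace(base, **overrides) if overrides else base


@dataclass(frozen=True)
class EcgNoise:
    """Additive disturbances for the synthetic ECG.

    ``burst_spans`` are (onset_s, duration_s) saturation bursts; during a
    burst the trace is pinned at ``burst_level`` (amplifier rail).
    """

    baseline_amp: float = 0.05
    baseline_freq_hz: float = 0.33
    broadband_sd: float = 0.03
    burst_spans: tuple = ()
    burst_level: float = 4.0


@dataclass(frozen=True)
class CohortSpec:
    """Full specification of a synthetic cohort run."""

    profiles: tuple = ()
    n_sessions: int = 5
    seed: int = 0
    layout: PhaseLayout = field(default_factory=PhaseLayout)
    rr_jitter_sd: float = 0.02
    n_artifact_bursts: int = 2
    artifact_burst_s: float = 3.0
    ecg_broadband_sd: float = 0.03
    cadence_hz: float = 1.8
    base_intensity: float = 1.0  # m/s², session 0
    intensity_gain_per_session: float = 0.1  # both groups improve effort alike
    fs_ecg: float = 512.0
    fs_accel: float = 32.0

    def __post_init__(self) -> None:
        if not self.profiles:
            object.__setattr__(
                self, "profiles", (default_low_profile(), default_high_profile())
            )
        if self.n_sessions < 2:
            raise ValidationError("CohortSpec.n_sessions must be >= 2")
        if self.rr_jitter_sd < 0:
            raise ValidationError("CohortSpec.rr_jitter_sd must be >= 0")
        if self.n_artifact_bursts < 0:
            raise ValidationError("CohortSpec.n_artifact_bursts must be >= 0")
        if self.fs_ecg <= 0 or self.fs_accel <= 0:
            raise ValidationError("CohortSpec sampling rates must be > 0")


@dataclass
class GroundTruth:
    """Per patient-session generative truth (the oracle for the pipeline)."""

    patient_id: str
    session: int
    group: str
    beat_times: np.ndarray
    a_true: float
    b_true: float
    rest_hr: float
    tau: float
    distance_m: float
    attendance: float
    artifact_spans: tuple  # (onset_s, duration_s) pairs


@dataclass
class SessionRecord:
    recording: Recording
    truth: GroundTruth


# ---------------------------------------------------------------------------
# Instantaneous heart-rate trajectory


def make_hr_fn(
    rest_hr: float,
    a: float,
    b: float,
    tau: float,
    layout: PhaseLayout,
) -> Callable[[np.ndarray], np.ndarray]:
    """Piecewise instantaneous-HR function over one session.

    Rest: constant ``rest_hr``.  Walk: rest_hr + b u + a u² with u the
    time from walk onset.  Recovery: exponential decay from the end-of-
    walk HR back toward ``rest_hr`` with time constant ``tau``.  The
    function is continuous at both phase boundaries.
    """
    w0 = layout.walk_onset_s
    r0 = layout.recovery_onset_s
    walk_s = layout.walk_s
    hr_end = rest_hr + b * walk_s + a * walk_s**2

    def hr(t):
        t = np.asarray(t, dtype=float)
        u_walk = np.clip(t - w0, 0.0, walk_s)
        out = rest_hr + b * u_walk + a * u_walk**2
        in_rec = t >= r0
        if np.any(in_rec):
            u_rec = np.where(in_rec, t - r0, 0.0)
            rec = rest_hr + (hr_end - rest_hr) * np.exp(-u_rec / tau)
            out = np.where(in_rec, rec, out)
        return out if out.ndim else float(out)

    return hr


def hr_trajectory(
    profile: GroupProfile, session: int, layout: Optional[PhaseLayout] = None
) -> Callable[[np.ndarray], np.ndarray]:
    """Group-level (patient factor = 1) HR trajectory for one session."""
    if not 0 <= session < len(profile.walk_kinetics_by_session):
        raise ValidationError(f"session index {session} out of range")
    layout = layout or PhaseLayout()
    a, b = profile.walk_kinetics_by_session[session]
    tau = profile.recovery_tau_by_session[session]
    return make_hr_fn(profile.rest_hr_mean, a, b, tau, layout)


# ---------------------------------------------------------------------------
# Beats, ECG, accelerometer


def beats_from_hr(
    hr_fn: Callable,
    duration_s: float,
    jitter_sd: float = 0.0,
    rng=None,
    hr_noise_sd: float = 0.0,
) -> np.ndarray:
    """Beat times whose successive intervals follow RR_k = 60 / HR(t_k).

    ``jitter_sd`` is a multiplicative RR jitter (fraction); ``hr_noise_sd``
    adds white per-beat noise (bpm) to the instantaneous HR before it is
    inverted, so it averages out within windows downstream.  RR intervals
    are clipped to the physiological range [0.3, 2.0] s.
    """
    rng = np.random.default_rng(rng)
    beats = [0.0]
    t = 0.0
    while True:
        hr = float(np.asarray(hr_fn(t), dtype=float))
        if hr <= 0:
            raise ValidationError(f"hr_fn must be positive; got {hr} at t={t}")
        if hr_noise_sd > 0:
            hr = max(hr + rng.normal(0.0, hr_noise_sd), 60.0 / RR_MAX_S)
        rr = 60.0 / hr
        if jitter_sd > 0:
            rr *= 1.0 + rng.normal(0.0, jitter_sd)
        rr = min(max(rr, RR_MIN_S), RR_MAX_S)
        t += rr
        if t > duration_s + 1e-9:
            break
        beats.append(t)
    return np.asarray(beats)


# QRS-T template components: (amplitude, offset_s, width_s)
_ECG_COMPONENTS = (
    (-0.10, -0.035, 0.010),  # Q
    (1.00, 0.000, 0.012),  # R
    (-0.12, 0.035, 0.010),  # S
    (0.20, 0.300, 0.070),  # T
)


def _ecg_template(fs: float):
    """Sampled beat template; returns (samples, index of the R peak)."""
    half = int(round(0.5 * fs))
    t = np.arange(-half, half + 1) / fs
    tpl = np.zeros_like(t)
    for amp, mu, sig in _ECG_COMPONENTS:
        tpl += amp * np.exp(-0.5 * ((t - mu) / sig) ** 2)
    return tpl, int(np.argmax(tpl))


def synth_ecg(
    beats: np.ndarray,
    duration_s: float,
    fs: float = 512.0,
    noise: Optional[EcgNoise] = None,
    rng=None,
) -> np.ndarray:
    """Synthetic single-lead ECG: one QRS-T complex per beat time.

    The R peak of each complex lands within one sample of the beat time.
    Optional additive baseline wander, broadband noise and saturation
    bursts come from ``noise``.
    """
    if fs <= 0:
        raise ValidationError("fs must be > 0")
    beats = np.asarray(beats, dtype=float)
    if beats.size and np.any(np.diff(beats) <= 0):
        raise ValidationError("beat times must be strictly increasing")
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * fs))
    sig = np.zeros(n)
    tpl, k_peak = _ecg_template(fs)
    for b in beats:
        i0 = int(round(b * fs)) - k_peak
        lo, hi = max(i0, 0), min(i0 + len(tpl), n)
        if hi > lo:
            sig[lo:hi] += tpl[lo - i0 : hi - i0]
    if noise is not None:
        t = np.arange(n) / fs
        if noise.baseline_amp > 0:
            phase = rng.uniform(0, 2 * np.pi)
            sig += noise.baseline_amp * np.sin(
                2 * np.pi * noise.baseline_freq_hz * t + phase
            )
        if noise.broadband_sd > 0:
            sig += rng.normal(0.0, noise.broadband_sd, n)
        for onset, dur in noise.burst_spans:
            lo = max(int(round(onset * fs)), 0)
            hi = min(int(round((onset + dur) * fs)), n)
            sig[lo:hi] = noise.burst_level
    return sig


def synth_accel(
    cadence_hz: float,
    intensity: float,
    duration_s: float,
    fs: float = 32.0,
    rng=None,
    noise_sd: float = 0.05,
    gravity: float = 9.81,
) -> np.ndarray:
    """Triaxial accelerometer trace: gravity on z + gait oscillation.

    The gait component is sinusoidal at the step cadence with amplitude
    proportional to ``intensity`` (m/s²), so the effort statistic of the
    output scales linearly with intensity.
    """
    if duration_s <= 0:
        raise ValidationError("duration_s must be > 0")
    if intensity < 0:
        raise ValidationError("intensity must be >= 0")
    rng = np.random.default_rng(rng)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    w = 2 * np.pi * cadence_hz
    x = intensity * np.sin(w * t)
    y = 0.3 * intensity * np.sin(2 * w * t + 0.7)
    z = gravity + 0.5 * intensity * np.sin(w * t + 1.2)
    acc = np.stack([x, y, z], axis=1)
    if noise_sd > 0:
        acc = acc + rng.normal(0.0, noise_sd, acc.shape)
    return acc


# ---------------------------------------------------------------------------
# Cohort assembly


@lru_cache(maxsize=None)
def _trunc_loc(mean: float, sd: float, side: str, bound: float) -> float:
    """Location of the one-sided truncated normal whose truncated mean is
    ``mean``.  The group's declared mean gain is the observed mean of a
    group that by definition lies on one side of the split threshold, so
    the sampler is calibrated to reproduce it after truncation."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    def trunc_mean(mu):
        z = (bound - mu) / sd
        if side == "below":  # upper truncation at bound
            return mu - sd * norm.pdf(z) / max(norm.cdf(z), 1e-300)
        return mu + sd * norm.pdf(z) / max(norm.sf(z), 1e-300)

    lo, hi = (mean, mean + 12 * sd) if side == "below" else (mean - 12 * sd, mean)
    return float(brentq(lambda mu: trunc_mean(mu) - mean, lo, hi))


def _truncated_normal(rng, mean, sd, side, bound):
    """One-sided truncated normal draw whose truncated mean equals ``mean``."""
    if sd == 0:
        if (side == "below") != (mean < bound):
            raise ValidationError("degenerate gain mean on the wrong side of the split")
        return mean
    mu = _trunc_loc(mean, sd, side, bound)
    a, b = ((-np.inf, (bound - mu) / sd) if side == "below"
            else ((bound - mu) / sd, np.inf))
    return float(truncnorm.ppf(rng.uniform(), a, b, loc=mu, scale=sd))


def _patient_params(spec: CohortSpec, gi: int, profile: GroupProfile, pi: int):
    """Deterministic per-patient draws (distances, HR traits, attendance)."""
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(gi, pi))
    )
    baseline = max(
        rng.normal(profile.baseline_distance_mean, profile.baseline_distance_sd),
        150.0,
    )
    gain = _truncated_normal(
        rng,
        profile.total_gain_mean,
        profile.total_gain_sd,
        profile.gain_side,
        RESPONSE_THRESHOLD_M,
    )
    # Monotone session fractions with per-session jitter; endpoints exact so
    # the final-minus-baseline distance equals the sampled total gain.
    n = spec.n_sessions
    inner = np.linspace(0.0, 1.0, n)[1:-1]
    inner = np.clip(inner + rng.normal(0.0, 0.05, inner.size), 0.02, 0.98)
    fracs = np.concatenate([[0.0], np.sort(inner), [1.0]])
    distances = baseline + gain * fracs
    rest_hr = rng.normal(profile.rest_hr_mean, profile.rest_hr_sd)
    f_a = max(rng.normal(1.0, profile.coeff_patient_rel_sd), 0.2)
    f_b = max(rng.normal(1.0, profile.coeff_patient_rel_sd), 0.2)
    f_tau = max(rng.normal(1.0, profile.tau_patient_rel_sd), 0.3)
    attendance = np.concatenate(
        [[np.nan], rng.binomial(EXPECTED_ATTENDANCE, ATTENDANCE_P, n - 1)]
    )
    return {
        "distances": distances,
        "gain": gain,
        "rest_hr": rest_hr,
        "f_a": f_a,
        "f_b": f_b,
        "f_tau": f_tau,
        "attendance": attendance,
    }


def _session_index(profile: GroupProfile, session: int) -> int:
    # Profiles describe 5 sessions; clamp for specs with fewer/more.
    return min(session, len(profile.walk_kinetics_by_session) - 1)


def simulate_session(
    spec: CohortSpec,
    gi: int,
    profile: GroupProfile,
    pi: int,
    session: int,
    params: Optional[dict] = None,
) -> SessionRecord:
    """Generate one patient-session recording plus its ground truth."""
    params = params or _patient_params(spec, gi, profile, pi)
    rng = np.random.default_rng(
        np.random.SeedSequence(spec.seed, spawn_key=(gi, pi, session + 1))
    )
    si = _session_index(profile, session)
    a0, b0 = profile.walk_kinetics_by_session[si]
    a, b = a0 * params["f_a"], b0 * params["f_b"]
    tau = profile.recovery_tau_by_session[si] * params["f_tau"]
    layout = spec.layout
    hr_fn = make_hr_fn(params["rest_hr"], a, b, tau, layout)
    beats = beats_from_hr(
        hr_fn,
        layout.total_s,
        jitter_sd=spec.rr_jitter_sd,
        rng=rng,
        hr_noise_sd=profile.hr_noise_sd,
    )
    spans = []
    for _ in range(spec.n_artifact_bursts):
        onset = rng.uniform(10.0, layout.total_s - 10.0 - spec.artifact_burst_s)
        spans.append((onset, spec.artifact_burst_s))
    noise = EcgNoise(broadband_sd=spec.ecg_broadband_sd, burst_spans=tuple(spans))
    ecg = synth_ecg(beats, layout.total_s, fs=spec.fs_ecg, noise=noise, rng=rng)
    intensity = spec.base_intensity + spec.intensity_gain_per_session * session
    accel = synth_accel(
        spec.cadence_hz, intensity, layout.total_s, fs=spec.fs_accel, rng=rng
    )
    pid = f"{profile.label}{pi:03d}"
    rec = Recording(
        ecg=ecg,
        fs_ecg=spec.fs_ecg,
        accel=accel,
        fs_accel=spec.fs_accel,
        phases=layout,
        patient_id=pid,
        session=session,
        distance_m=float(params["distances"][session]),
        attendance=float(params["attendance"][session]),
    )
    truth = GroundTruth(
        patient_id=pid,
        session=session,
        group=profile.label,
        beat_times=beats,
        a_true=a,
        b_true=b,
        rest_hr=params["rest_hr"],
        tau=tau,
        distance_m=float(params["distances"][session]),
        attendance=float(params["attendance"][session]),
        artifact_spans=tuple(spans),
    )
    return SessionRecord(recording=rec, truth=truth)


def iter_cohort(spec: CohortSpec) -> Iterator[SessionRecord]:
    """Stream the cohort one session at a time (constant memory)."""
    for gi, profile in enumerate(spec.profiles):
        for pi in range(profile.n_patients):
            params = _patient_params(spec, gi, profile, pi)
            for session in range(spec.n_sessions):
                yield simulate_session(spec, gi, profile, pi, session, params)


def truth_table(spec: CohortSpec) -> pd.DataFrame:
    """Patient-session ground-truth table (no waveforms, cheap to build)."""
    rows = []
    for gi, profile in enumerate(spec.profiles):
        for pi in range(profile.n_patients):
            params = _patient_params(spec, gi, profile, pi)
            for session in range(spec.n_sessions):
                si = _session_index(profile, session)
                a0, b0 = profile.walk_kinetics_by_session[si]
                rows.append(
                    {
                        "patient": f"{profile.label}{pi:03d}",
                        "session": session,
                        "group": profile.label,
                        "distance": params["distances"][session],
                        "total_gain": params["gain"],
                        "attendance": params["attendance"][session],
                        "rest_hr_true": params["rest_hr"],
                        "a_true": a0 * params["f_a"],
                        "b_true": b0 * params["f_b"],
                        "tau_true": profile.recovery_tau_by_session[si]
                        * params["f_tau"],
                    }
                )
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec):
    """Materialize the whole cohort: (list of SessionRecord, truth table).

    For large cohorts prefer :func:`iter_cohort`, which streams sessions;
    holding all raw waveforms of an 89-patient cohort in memory at once
    is possible but wasteful.
    """
    return list(iter_cohort(spec)), truth_table(spec)
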