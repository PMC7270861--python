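"""Shared domain types for the six-minute-walk-test (6MWT) pipeline.

Time convention: every beat time, window centre and phase onset is in
seconds from the start of the session recording (t = 0 at the start of
the resting phase).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Beat flag vocabulary.
FLAG_DETECTED = "detected"
FLAG_CORRECTED = "corrected"
FLAG_EXCLUDED = "excluded"
BEAT_FLAGS = (FLAG_DETECTED, FLAG_CORRECTED, FLAG_EXCLUDED)

#: Physiological RR-interval range in seconds (30-200 bpm).
RR_MIN_S = 0.3
RR_MAX_S = 2.0


class ValidationError(ValueError):
    """Raised when a domain object violates one of its invariants."""


@dataclass(frozen=True)
class PhaseLayout:
    """Durations of the three 6MWT phases, in seconds.

    The protocol is 5 min seated rest, 6 min walking, 5 min recuperation.
    """

    rest_s: float = 300.0
    walk_s: float = 360.0
    recovery_s: float = 300.0

    def __post_init__(self) -> None:
        for name in ("rest_s", "walk_s", "recovery_s"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"PhaseLayout.{name} must be > 0")

    @property
    def total_s(self) -> float:
        return self.rest_s + self.walk_s + self.recovery_s

    @property
    def walk_onset_s(self) -> float:
        return self.rest_s

    @property
    def recovery_onset_s(self) -> float:
        return self.rest_s + self.walk_s


@dataclass
class Recording:
    """One wearable session: single-lead ECG + triaxial accelerometer.

    ``ecg`` is a 1-D array in device units; ``accel`` is (n, 3) in m/s².
    ``distance_m`` is the distance walked during the 6-minute phase.
    ``attendance`` counts rehabilitation sessions attended since the
    previous test (NaN for the baseline session, which has no interval).
    """

    ecg: np.ndarray
    fs_ecg: float
    accel: np.ndarray
    fs_accel: float
    phases: PhaseLayout
    patient_id: str
    session: int
    distance_m: float
    attendance: float = float("nan")

    def __post_init__(self) -> None:
        self.ecg = np.asarray(self.ecg, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        if not self.fs_ecg > 0:
            raise ValidationError("Recording.fs_ecg must be > 0")
        if not self.fs_accel > 0:
            raise ValidationError("Recording.fs_accel must be > 0")
        if self.accel.ndim != 2 or self.accel.shape[1] != 3:
            raise ValidationError("Recording.accel must have shape (n, 3)")
        if self.distance_m < 0:
            raise ValidationError("Recording.distance_m must be >= 0")
        total = self.phases.total_s
        if abs(len(self.ecg) - total * self.fs_ecg) > self.fs_ecg:
            raise ValidationError(
                f"ECG length {len(self.ecg)} inconsistent with phase total "
                f"{total} s at {self.fs_ecg} Hz"
            )
        if abs(len(self.accel) - total * self.fs_accel) > self.fs_accel:
            raise ValidationError(
                f"accelerometer length {len(self.accel)} inconsistent with "
                f"phase total {total} s at {self.fs_accel} Hz"
            )


@dataclass
class BeatSeries:
    """Ordered R-peak times (seconds from session start) with quality flags.

    Flags: ``detected`` (usable), ``corrected`` (kept in the series but
    removed from heart-rate computation by the automatic correction rule),
    ``excluded`` (inside an artifact window).
    """

    times: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        if self.times.shape != self.flags.shape:
            raise ValidationError("BeatSeries times and flags differ in length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("BeatSeries times must be strictly increasing")
        bad = set(self.flags.tolist()) - set(BEAT_FLAGS)
        if bad:
            raise ValidationError(f"unknown beat flags: {sorted(bad)}")

    @classmethod
    def from_times(cls, times, flag: str = FLAG_DETECTED) -> "BeatSeries":
        times = np.asarray(times, dtype=float)
        return cls(times, np.full(times.shape, flag, dtype=object))

    @property
    def usable_times(self) -> np.ndarray:
        """Times of beats that enter heart-rate computation."""
        return self.times[self.flags == FLAG_DETECTED]

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class HRSeries:
    """Windowed heart-rate series (bpm) over one phase.

    Window centres advance by ``stride_s``; windows with fewer than two
    usable RR intervals are gaps and are simply absent from the arrays.
    ``onset_s`` is the phase onset in session coordinates, so the fitting
    time base is ``times - onset_s``.
    """

    times: np.ndarray
    hr: np.ndarray
    window_s: float
    stride_s: float
    phase: str
    onset_s: float = 0.0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.times.shape != self.hr.shape:
            raise ValidationError("HRSeries times and hr differ in length")
        if self.hr.size and np.any(self.hr <= 0):
            raise ValidationError("HRSeries hr must be positive")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValidationError("HRSeries times must be strictly increasing")

    @property
    def rel_times(self) -> np.ndarray:
        return self.times - self.onset_s

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass
class StaticParams:
    """Static per-session heart-rate parameters plus effort and distance.

    HR_rest: mean HR over the final 20 s of rest; HR_peak: final 10 s of
    walking; HR_rec1..5: each minute of recuperation; HR_peak_dist =
    HR_peak / distance (bpm per metre); effort: mean magnitude of the
    DC-removed triaxial acceleration over the walking phase (m/s²).
    Parameters that cannot be computed are NaN.
    """

    hr_rest: float
    hr_peak: float
    hr_rec: tuple  # (hr_rec1, ..., hr_rec5)
    hr_peak_dist: float
    effort: float
    distance_m: float

    def as_dict(self) -> dict:
        out = {
            "hr_rest": self.hr_rest,
            "hr_peak": self.hr_peak,
            "hr_peak_dist": self.hr_peak_dist,
            "effort": self.effort,
            "distance": self.distance_m,
        }
        for k, v in enumerate(self.hr_rec, start=1):
            out[f"hr_rec{k}"] = v
        return out


@dataclass
class KineticsFit:
    """Result of fitting one candidate model family to an HR series."""

    family: str
    coefficients: dict
    r2: float
    n_points: int
    phase: str
    success: bool = True
    message: str = ""

    def predict(self, t: np.ndarray) -> np.ndarray:
        from . import kinetics  # local import to avoid a cycle

        return kinetics.evaluate_family(self.family, self.coefficients, t)


@dataclass(frozen=True)
class AnovaResult:
    """One effect from a (mixed or repeated-measures) ANOVA.

    partial_eta_sq satisfies df_main*F / (df_main*F + df_error).
    """

    effect: str
    F: float
    df_main: float
    df_error: float
    p: float
    partial_eta_sq: float
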