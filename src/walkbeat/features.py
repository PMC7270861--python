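"""Windowed heart-rate series, static HR parameters and accelerometer effort.

Mean heart rate over a span is computed in the beat domain as
60 / mean(RR intervals fully inside the span), using only beats flagged
``detected``; the short static spans (10-60 s) are therefore resolved
exactly rather than smeared by an analysis window.
"""
from __future__ import annotations

import logging
from typing import Optional, Tuple

import numpy as np

from .types import (
    BeatSeries,
    HRSeries,
    PhaseLayout,
    RR_MAX_S,
    StaticParams,
    ValidationError,
)

log = logging.getLogger(__name__)


def _usable_rr(beats: BeatSeries) -> Tuple[np.ndarray, np.ndarray]:
    """RR intervals between consecutive usable beats.

    Returns (start times, intervals).  Intervals spanning a removed or
    flagged stretch would be inflated, so any interval above the
    physiological maximum is discarded.
    """
    t = beats.usable_times
    if t.size < 2:
        return np.empty(0), np.empty(0)
    rr = np.diff(t)
    ok = rr <= RR_MAX_S + 1e-9
    return t[:-1][ok], rr[ok]


def mean_hr_over_span(beats: BeatSeries, start_s: float, end_s: float) -> float:
    """60 / mean(RR) over intervals fully inside [start_s, end_s]; NaN if none."""
    t0, rr = _usable_rr(beats)
    inside = (t0 >= start_s - 1e-9) & (t0 + rr <= end_s + 1e-9)
    if not inside.any():
        return float("nan")
    return 60.0 / float(rr[inside].mean())


def hr_series(
    beats: BeatSeries,
    window_s: float,
    stride_s: float = 4.0,
    span: Optional[Tuple[float, float]] = None,
    phase: str = "",
) -> HRSeries:
    """Windowed HR series: windows of ``window_s`` advancing by ``stride_s``.

    Per window HR = 60 / mean(RR fully inside the window).  Windows with
    no usable interval are gaps and are omitted.  ``span`` defaults to the
    full beat range; times are window centres in session coordinates.
    """
    if window_s <= 0 or stride_s <= 0:
        raise ValidationError("window_s and stride_s must be > 0")
    t0_all, rr = _usable_rr(beats)
    if span is None:
        if beats.times.size == 0:
            return HRSeries(np.empty(0), np.empty(0), window_s, stride_s, phase)
        span = (float(beats.times[0]), float(beats.times[-1]))
    lo, hi = span
    centers = np.arange(lo + window_s / 2.0, hi - window_s / 2.0 + 1e-9, stride_s)
    times, hrs = [], []
    for c in centers:
        a, b = c - window_s / 2.0, c + window_s / 2.0
        inside = (t0_all >= a - 1e-9) & (t0_all + rr <= b + 1e-9)
        if inside.sum() >= 1:
            times.append(c)
            hrs.append(60.0 / float(rr[inside].mean()))
    return HRSeries(
        np.asarray(times), np.asarray(hrs), window_s, stride_s, phase, onset_s=lo
    )


def effort(accel: np.ndarray) -> float:
    """Mean magnitude of the DC-removed triaxial acceleration (m/s²).

    Gravity (and any constant offset) is removed per axis by mean
    subtraction over the supplied samples, then the Euclidean norm
    sqrt(X² + Y² + Z²) is averaged over all n samples.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.size == 0:
        raise ValidationError("effort: empty accelerometer input")
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValidationError("effort: accel must have shape (n, 3)")
    centered = accel - accel.mean(axis=0, keepdims=True)
    return float(np.linalg.norm(centered, axis=1).mean())


def static_params(
    beats: BeatSeries,
    phases: PhaseLayout,
    distance_m: float,
    accel_walk: Optional[np.ndarray] = None,
) -> StaticParams:
    """All static per-session parameters.

    HR_rest: final 20 s of rest.  HR_peak: final 10 s of walking.
    HR_rec_k: minute k of recuperation (k = 1..5, as far as the recovery
    phase reaches).  HR_peak_dist = HR_peak / distance.  ``accel_walk``
    is the walk-phase accelerometer span (for the effort statistic).
    """
    rest_end = phases.rest_s
    walk_end = phases.rest_s + phases.walk_s
    hr_rest = mean_hr_over_span(beats, rest_end - 20.0, rest_end)
    hr_peak = mean_hr_over_span(beats, walk_end - 10.0, walk_end)
    n_min = int(phases.recovery_s // 60)
    hr_rec = []
    for k in range(5):
        if k < n_min:
            hr_rec.append(
                mean_hr_over_span(beats, walk_end + 60.0 * k, walk_end + 60.0 * (k + 1))
            )
        else:
            hr_rec.append(float("nan"))
    for name, val in (("hr_rest", hr_rest), ("hr_peak", hr_peak)):
        if np.isnan(val):
            log.warning("static_params: no usable beats for %s", name)
    if distance_m > 0 and not np.isnan(hr_peak):
        hr_peak_dist = hr_peak / distance_m
    else:
        hr_peak_dist = float("nan")
    eff = effort(accel_walk) if accel_walk is not None else float("nan")
    return StaticParams(
        hr_rest=hr_rest,
        hr_peak=hr_peak,
        hr_rec=tuple(hr_rec),
        hr_peak_dist=hr_peak_dist,
        effort=eff,
        distance_m=distance_m,
    )
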