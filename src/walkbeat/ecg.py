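"""Raw ECG to clean beat series: segmentation, artifact masking,
R-peak detection (Pan-Tompkins-style) and automatic beat correction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sps

from .types import (
    BeatSeries,
    FLAG_CORRECTED,
    FLAG_DETECTED,
    FLAG_EXCLUDED,
    PhaseLayout,
    Recording,
    RR_MAX_S,
    RR_MIN_S,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class PhaseSpan:
    """One phase of a signal: samples plus the phase offset in seconds."""

    samples: np.ndarray
    offset_s: float
    fs: float


@dataclass
class PhaseSignals:
    rest: PhaseSpan
    walk: PhaseSpan
    recovery: PhaseSpan


def segment_phases(rec: Recording, channel: str = "ecg") -> PhaseSignals:
    """Split a recording into rest / walk / recovery sample spans.

    Offsets are in session coordinates so downstream beat times line up.
    """
    if channel == "ecg":
        sig, fs = rec.ecg, rec.fs_ecg
    elif channel == "accel":
        sig, fs = rec.accel, rec.fs_accel
    else:
        raise ValidationError(f"unknown channel {channel!r}")
    lay = rec.phases
    n = len(sig)
    i_walk = int(round(lay.rest_s * fs))
    i_rec = int(round((lay.rest_s + lay.walk_s) * fs))
    i_end = int(round(lay.total_s * fs))
    if i_end > n + 1:
        raise ValidationError(
            f"phase annotations ({lay.total_s} s) exceed signal length "
            f"({n / fs:.1f} s)"
        )
    i_end = min(i_end, n)
    return PhaseSignals(
        rest=PhaseSpan(sig[:i_walk], 0.0, fs),
        walk=PhaseSpan(sig[i_walk:i_rec], lay.rest_s, fs),
        recovery=PhaseSpan(sig[i_rec:i_end], lay.rest_s + lay.walk_s, fs),
    )


# ---------------------------------------------------------------------------
# Artifact detection


@dataclass
class ArtifactMask:
    """Per-window contamination flags over the whole ECG."""

    flagged: np.ndarray  # bool per window
    window_s: float
    hop_s: float

    def contains(self, t: float) -> bool:
        """True when time ``t`` (s) falls inside a flagged window."""
        if not self.flagged.any():
            return False
        idx = int(t // self.hop_s)
        idx = min(max(idx, 0), len(self.flagged) - 1)
        return bool(self.flagged[idx])

    def flagged_times(self, times: np.ndarray) -> np.ndarray:
        idx = np.clip(
            (np.asarray(times) // self.hop_s).astype(int), 0, len(self.flagged) - 1
        )
        return self.flagged[idx]


def _autocorr_quality(win: np.ndarray, fs: float) -> float:
    """Normalized autocorrelation peak in the physiological RR lag range.

    A quasi-periodic QRS train produces a clear peak; broadband noise or a
    flat trace does not.
    """
    x = win - win.mean()
    denom = float(np.dot(x, x))
    if denom <= 0:
        return 0.0
    ac = sps.correlate(x, x, mode="full")[len(x) - 1 :] / denom
    lo = int(0.25 * fs)
    hi = min(int(1.6 * fs), len(ac) - 1)
    if hi <= lo:
        return 0.0
    return float(ac[lo:hi].max())


def detect_artifacts(
    ecg: np.ndarray,
    fs: float,
    window_s: float = 2.0,
    quality_threshold: float = 0.10,
) -> ArtifactMask:
    """Flag contaminated 2-s windows of the ECG.

    A window is flagged when it is flat (no QRS energy), when its
    amplitude saturates relative to the recording's robust scale, or when
    its autocorrelation quality index falls below threshold.  This is a
    signal-quality stand-in with the contract downstream needs: clean
    synthetic signals yield an all-clear mask, injected saturation bursts
    are flagged.
    """
    ecg = np.asarray(ecg, dtype=float)
    if ecg.size == 0:
        raise ValidationError("ecg must be non-empty")
    w = max(int(round(window_s * fs)), 2)
    n_win = max(int(np.ceil(ecg.size / w)), 1)
    # Robust typical peak amplitude: median over per-window maxima, so a
    # minority of saturated windows cannot inflate the reference.
    dev = np.abs(ecg - np.median(ecg))
    win_max = np.array([dev[k * w : (k + 1) * w].max() for k in range(n_win)])
    typical_peak = float(np.median(win_max))
    sat_level = 1.8 * typical_peak
    flags = np.zeros(n_win, dtype=bool)
    for k in range(n_win):
        win = ecg[k * w : (k + 1) * w]
        if float(np.std(win)) < 1e-8:
            flags[k] = True  # flatline: no QRS energy at all
            continue
        if typical_peak > 0:
            sat_frac = float(np.mean(dev[k * w : (k + 1) * w] > sat_level))
            if sat_frac > 0.05:
                flags[k] = True  # amplitude saturation (also partial windows)
                continue
        if len(win) >= int(0.5 * fs):
            if _autocorr_quality(win, fs) < quality_threshold:
                flags[k] = True
    return ArtifactMask(flagged=flags, window_s=window_s, hop_s=window_s)


# ---------------------------------------------------------------------------
# R-peak detection (Pan-Tompkins-style)


def detect_rpeaks(
    ecg: np.ndarray,
    fs: float,
    mask: Optional[ArtifactMask] = None,
    refractory_s: float = 0.25,
    integration_s: float = 0.150,
) -> BeatSeries:
    """Pan-Tompkins-style R-peak detection.

    Stages: 5-15 Hz band-pass, differentiation, squaring, 150-ms moving
    window integration, then an adaptive signal/noise threshold over the
    candidate peaks with a 250-ms refractory period.  Beat times are
    refined to the maximum of the band-passed signal near each candidate.
    Beats falling inside flagged artifact windows are marked ``excluded``.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 128:
        raise ValidationError("detect_rpeaks requires fs >= 128 Hz")
    if ecg.size < 2 * fs:
        raise ValidationError("signal shorter than 2 s")
    if float(np.ptp(ecg)) < 1e-12:
        return BeatSeries.from_times([])

    nyq = fs / 2.0
    b, a = sps.butter(2, [5.0 / nyq, 15.0 / nyq], btype="band")
    band = sps.filtfilt(b, a, ecg)
    deriv = np.gradient(band)
    sq = deriv**2
    w = max(int(round(integration_s * fs)), 1)
    integ = np.convolve(sq, np.ones(w) / w, mode="same")

    min_dist = max(int(round(refractory_s * fs)), 1)
    cand, _ = sps.find_peaks(integ, distance=min_dist)
    if cand.size == 0:
        return BeatSeries.from_times([])

    # Adaptive thresholds initialized from the first 2 seconds.
    init = integ[: int(2 * fs)]
    spki = 0.25 * float(init.max())
    npki = 0.5 * float(init.mean())
    peaks = []
    for idx in cand:
        pk = integ[idx]
        thr = npki + 0.25 * (spki - npki)
        if pk > thr:
            peaks.append(idx)
            spki = 0.125 * pk + 0.875 * spki
        else:
            npki = 0.125 * pk + 0.875 * npki

    # Refine each detection to the local band-passed maximum (the R wave).
    half = int(round(0.10 * fs))
    times = []
    for idx in peaks:
        lo, hi = max(idx - half, 0), min(idx + half + 1, len(band))
        r = lo + int(np.argmax(band[lo:hi]))
        times.append(r / fs)
    times = np.asarray(sorted(set(times)))
    if times.size == 0:
        return BeatSeries.from_times([])

    flags = np.full(times.shape, FLAG_DETECTED, dtype=object)
    if mask is not None:
        flags[mask.flagged_times(times)] = FLAG_EXCLUDED
    return BeatSeries(times, flags)


# ---------------------------------------------------------------------------
# Automatic beat correction


def correct_beats(
    beats: BeatSeries,
    rr_min: float = RR_MIN_S,
    rr_max: float = RR_MAX_S,
    rel_tol: float = 0.30,
    median_window: int = 7,
) -> BeatSeries:
    """Automatic stand-in for visual beat correction.

    Beats implying an RR interval below ``rr_min`` are dropped as spurious
    extra detections.  Beats implying an RR above ``rr_max`` or deviating
    more than ``rel_tol`` from the running median of recent accepted RR
    intervals are kept in the series but flagged ``corrected`` (no
    interpolation), removing them from heart-rate computation.  The rule
    is deterministic and idempotent.
    """
    times = beats.times
    flags = beats.flags
    if times.size <= 1:
        return BeatSeries(times.copy(), flags.copy())

    out_t, out_f = [times[0]], [flags[0]]
    history: list[float] = []
    last = times[0]
    for t, f in zip(times[1:], flags[1:]):
        rr = t - last
        if rr < rr_min:
            continue  # spurious extra detection: remove outright
        suspicious = rr > rr_max
        if not suspicious and len(history) >= 3:
            med = float(np.median(history[-median_window:]))
            if med > 0 and abs(rr - med) > rel_tol * med:
                suspicious = True
        if suspicious:
            out_f.append(FLAG_CORRECTED if f == FLAG_DETECTED else f)
        else:
            out_f.append(f)
            if f == FLAG_DETECTED:
                history.append(rr)
        out_t.append(t)
        last = t
    n_removed = len(times) - len(out_t)
    n_corr = sum(1 for f in out_f if f == FLAG_CORRECTED)
    if n_removed or n_corr:
        log.debug("correct_beats: removed %d, flagged %d", n_removed, n_corr)
    return BeatSeries(np.asarray(out_t), np.asarray(out_f, dtype=object))


def process_recording(rec: Recording) -> BeatSeries:
    """Artifact masking + detection + correction for one recording."""
    mask = detect_artifacts(rec.ecg, rec.fs_ecg)
    beats = detect_rpeaks(rec.ecg, rec.fs_ecg, mask=mask)
    return correct_beats(beats)
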