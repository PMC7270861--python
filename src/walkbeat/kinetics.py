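"""Heart-rate kinetics: candidate model fits and the digital biomarkers.

Four families are fitted to the within-phase HR series (time in seconds
from phase onset): a one-term exponential a*exp(b t), a two-term
exponential a*exp(b t) + c*exp(d t), a two-term-with-offset exponential
a*exp(b t) + c, and a quadratic polynomial a t² + b t + c.  Goodness of
fit is the coefficient of determination R²; the family with the best
mean R² over a cohort is selected, and the quadratic coefficients
(a_poly, b_poly) are the digital cardiac biomarkers.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .types import HRSeries, KineticsFit, ValidationError

log = logging.getLogger(__name__)

QUADRATIC = "quadratic"
ONE_TERM_EXP = "one_term_exp"
TWO_TERM_EXP = "two_term_exp"
TWO_TERM_EXP_OFFSET = "two_term_exp_offset"

#: family -> (free coefficient names)
FAMILIES = {
    ONE_TERM_EXP: ("alpha", "beta"),
    TWO_TERM_EXP: ("alpha", "beta", "gamma", "delta"),
    TWO_TERM_EXP_OFFSET: ("alpha", "beta", "gamma"),
    QUADRATIC: ("a_poly", "b_poly", "c_poly"),
}

MAX_NFEV = 200  # bounded iterations for the nonlinear fits


def evaluate_family(family: str, coeffs: dict, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    c = coeffs
    if family == QUADRATIC:
        return c["a_poly"] * t**2 + c["b_poly"] * t + c["c_poly"]
    if family == ONE_TERM_EXP:
        return c["alpha"] * np.exp(c["beta"] * t)
    if family == TWO_TERM_EXP:
        return c["alpha"] * np.exp(c["beta"] * t) + c["gamma"] * np.exp(c["delta"] * t)
    if family == TWO_TERM_EXP_OFFSET:
        return c["alpha"] * np.exp(c["beta"] * t) + c["gamma"]
    raise ValidationError(f"unknown family {family!r}")


def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """R² = 1 - SSres/SStot with the degenerate conventions:
    SStot = 0 and SSres = 0 -> 1; SStot = 0 and SSres > 0 -> -inf."""
    y = np.asarray(y, dtype=float)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    tiny = 1e-12 * max(1.0, float(np.sum(y**2)))  # numerically-zero residual
    if ss_tot <= tiny:
        return 1.0 if ss_res <= tiny else float("-inf")
    return 1.0 - ss_res / ss_tot


def _fit_quadratic(t: np.ndarray, y: np.ndarray) -> dict:
    """Closed-form polynomial least squares via the normal equations."""
    X = np.vander(t, 3)  # columns t², t, 1
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return {"a_poly": float(coef[0]), "b_poly": float(coef[1]), "c_poly": float(coef[2])}


def _exp_init(t: np.ndarray, y: np.ndarray) -> Tuple[float, float]:
    """alpha from the first value, beta from a log-linear regression."""
    alpha = float(y[0]) if y[0] != 0 else float(np.mean(y)) or 1.0
    pos = y > 0
    if pos.sum() >= 2 and alpha != 0:
        slope = np.polyfit(t[pos], np.log(y[pos] / abs(alpha) + 1e-12), 1)[0]
        beta = float(np.clip(slope, -1.0, 1.0))
    else:
        beta = 0.0
    return alpha, beta


def fit_family(series: HRSeries, family: str) -> KineticsFit:
    """Least-squares fit of one candidate family to an HR series.

    The quadratic is solved in closed form; the exponential families by
    bounded iterative nonlinear least squares.  Non-convergence yields a
    fit marked failed (with a diagnostic message), never an exception.
    """
    if family not in FAMILIES:
        raise ValidationError(f"unknown family {family!r}")
    t = series.rel_times
    y = series.hr
    n_free = len(FAMILIES[family])
    if len(t) < n_free + 1:
        raise ValidationError(
            f"{family}: need at least {n_free + 1} points, got {len(t)}"
        )
    if len(t) > 1 and np.any(np.diff(t) > 60.0):
        raise ValidationError("HR series has a gap larger than 60 s")

    if family == QUADRATIC:
        coeffs = _fit_quadratic(t, y)
        yhat = evaluate_family(family, coeffs, t)
        return KineticsFit(family, coeffs, r_squared(y, yhat), len(t), series.phase)

    alpha, beta = _exp_init(t, y)
    gamma = float(y[-1])
    if family == ONE_TERM_EXP:
        f = lambda t, a, b: a * np.exp(b * t)
        p0 = (alpha, beta)
    elif family == TWO_TERM_EXP_OFFSET:
        f = lambda t, a, b, c: a * np.exp(b * t) + c
        # start as a decay from the first toward the last value
        t_span = float(t[-1] - t[0]) or 1.0
        p0 = (float(y[0]) - gamma, -2.0 / t_span, gamma)
    else:  # TWO_TERM_EXP
        f = lambda t, a, b, c, d: a * np.exp(b * t) + c * np.exp(d * t)
        p0 = (alpha / 2, beta, alpha / 2, -abs(beta) - 1e-3)
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            popt, _ = curve_fit(f, t, y, p0=p0, maxfev=MAX_NFEV * (n_free + 1))
        coeffs = dict(zip(FAMILIES[family], (float(v) for v in popt)))
        yhat = evaluate_family(family, coeffs, t)
        if not np.all(np.isfinite(yhat)):
            raise RuntimeError("non-finite prediction")
        return KineticsFit(family, coeffs, r_squared(y, yhat), len(t), series.phase)
    except (RuntimeError, ValueError, TypeError) as err:
        log.debug("fit_family(%s) failed: %s", family, err)
        return KineticsFit(
            family,
            {},
            float("-inf"),
            len(t),
            series.phase,
            success=False,
            message=str(err),
        )


def fit_all_families(series: HRSeries) -> dict:
    """Fit every candidate family to one series; returns {family: fit}."""
    return {fam: fit_family(series, fam) for fam in FAMILIES}


def select_best(fits: Iterable[KineticsFit]) -> str:
    """Family with the highest mean R² over all supplied successful fits.

    Ties break toward the family with fewer free coefficients (then by
    name, for determinism).
    """
    by_family: dict = {}
    for fit in fits:
        if fit.success and np.isfinite(fit.r2):
            by_family.setdefault(fit.family, []).append(fit.r2)
    if not by_family:
        raise ValidationError("select_best: all fits failed")
    ranked = sorted(
        by_family.items(),
        key=lambda kv: (-float(np.mean(kv[1])), len(FAMILIES[kv[0]]), kv[0]),
    )
    return ranked[0][0]


def mean_fit_curve(
    fits: Sequence[KineticsFit], timebase: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD of fitted curves on a common timebase.

    Mirrors the published mean-fit-with-SD-shadow figures.  All fits must
    share the same phase.
    """
    fits = [f for f in fits if f.success]
    if len(fits) < 2:
        raise ValidationError("mean_fit_curve: need at least 2 successful fits")
    phases = {f.phase for f in fits}
    if len(phases) > 1:
        raise ValidationError(f"mean_fit_curve: mixed phases {sorted(phases)}")
    timebase = np.asarray(timebase, dtype=float)
    curves = np.stack([f.predict(timebase) for f in fits])
    return curves.mean(axis=0), curves.std(axis=0, ddof=1)
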