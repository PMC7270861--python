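"""Group-level longitudinal statistics for the cohort feature table.

Implements the study's analysis plan: response-group assignment by the
distance-gain split, compliance rates, boxplot-rule outlier removal,
two-way mixed ANOVA (between factor: response group; within factor:
session) with classical sums-of-squares partitioning and partial eta
squared effect sizes, repeated-measures follow-ups within each group,
per-session group contrasts (t / Mann-Whitney), and a Table-1-style
baseline comparison (Shapiro-Wilk gated t / Mann-Whitney for continuous
variables, Fisher exact for categorical ones).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sct

from .types import AnovaResult, ValidationError

ALPHA = 0.05


def partial_eta_sq(df_main: float, df_error: float, F: float) -> float:
    """Effect size: df_main*F / (df_main*F + df_error)."""
    return (df_main * F) / (df_main * F + df_error)


# ---------------------------------------------------------------------------
# Group assignment & compliance


@dataclass
class GroupAssignment:
    table: pd.DataFrame  # index: patient; columns total_gain, group
    threshold: float

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]


def assign_groups(
    gains: Union[pd.Series, dict],
    threshold: Union[float, str] = "median",
) -> GroupAssignment:
    """Split patients into low/high response by total distance gain.

    ``threshold`` is either a number of metres (the published split uses
    90 m) or ``"median"`` for a median split.  Gains strictly above the
    threshold are ``high``; at or below are ``low``.
    """
    gains = pd.Series(gains, dtype=float)
    if len(gains) < 2:
        raise ValidationError("assign_groups needs at least 2 patients")
    thr = float(gains.median()) if threshold == "median" else float(threshold)
    table = pd.DataFrame(
        {
            "total_gain": gains,
            "group": np.where(gains > thr, "high", "low"),
        }
    )
    return GroupAssignment(table=table, threshold=thr)


def compliance_rate(attended: float, expected: int = 9) -> float:
    """Attendance as a percentage of the expected rehabilitation sessions."""
    if expected <= 0:
        raise ValidationError("expected must be > 0")
    if attended < 0:
        raise ValidationError("attended must be >= 0")
    return 100.0 * attended / expected


# ---------------------------------------------------------------------------
# Outliers


def remove_outliers(values: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    """Boxplot rule: drop values > 3 box-lengths beyond the box edges.

    Quartiles use linear interpolation; with IQR = 0 the fences collapse
    onto the quartile value and nothing is removed (equality is not
    'greater than').  Returns (kept values, removed indices).
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        raise ValidationError("remove_outliers needs at least 4 values")
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 3.0 * iqr, q3 + 3.0 * iqr
    removed = np.where((values < lo) | (values > hi))[0]
    kept = np.delete(values, removed)
    return kept, removed


# ---------------------------------------------------------------------------
# ANOVA


def _check_long(long: pd.DataFrame, need_group: bool) -> pd.DataFrame:
    cols = {"patient", "session", "value"} | ({"group"} if need_group else set())
    missing = cols - set(long.columns)
    if missing:
        raise ValidationError(f"long table missing columns {sorted(missing)}")
    long = long.dropna(subset=["value"])
    counts = long.groupby("patient")["session"].nunique()
    n_sessions = long["session"].nunique()
    bad = counts[counts != n_sessions]
    if len(bad):
        raise ValidationError(
            "unbalanced design after deletion; offending patients: "
            + ", ".join(map(str, bad.index.tolist()))
        )
    return long


def listwise_delete(long: pd.DataFrame) -> pd.DataFrame:
    """Drop every patient with any missing session value (per-analysis)."""
    n_sessions = long["session"].nunique()
    ok = (
        long.dropna(subset=["value"])
        .groupby("patient")["session"]
        .nunique()
        .pipe(lambda s: s[s == n_sessions].index)
    )
    return long[long["patient"].isin(ok)].copy()


def _gg_epsilon(wide: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the sample covariance of sessions."""
    S = np.cov(wide, rowvar=False)
    k = S.shape[0]
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * (
        np.sum(S**2) - 2 * k * np.sum(row_means**2) + k**2 * mean_all**2
    )
    if den <= 0:
        return 1.0
    return float(min(max(num / den, 1.0 / (k - 1)), 1.0))


def mixed_anova(
    long: pd.DataFrame, sphericity_correction: bool = False
) -> Dict[str, AnovaResult]:
    """Two-way mixed ANOVA on a long table (patient, group, session, value).

    Between-subjects factor: group; within-subjects factor: session.
    Classical partitioning: between-subjects SS splits into group and
    subjects-within-group; within-subjects SS splits into time,
    time x group, and time x subjects-within-group (the error term for
    both within effects).  No sphericity correction by default (matching
    integer error dfs); Greenhouse-Geisser is available as an option.
    Requires a balanced design after listwise deletion.
    """
    long = _check_long(long, need_group=True)
    gmap = long.groupby("patient")["group"].nunique()
    if (gmap > 1).any():
        raise ValidationError("group label must be constant within patient")

    grand = long["value"].mean()
    T = long["session"].nunique()
    subj_mean = long.groupby("patient")["value"].mean()
    subj_group = long.groupby("patient")["group"].first()
    N = len(subj_mean)
    G = long["group"].nunique()

    # Between-subjects partition
    ss_between_subj = T * float(((subj_mean - grand) ** 2).sum())
    group_means = subj_mean.groupby(subj_group).mean()
    n_per_group = subj_group.value_counts()
    ss_group = T * float(
        (n_per_group * (group_means - grand) ** 2).sum()
    )
    ss_subj_within = ss_between_subj - ss_group

    # Within-subjects partition
    ss_total = float(((long["value"] - grand) ** 2).sum())
    ss_within_subj = ss_total - ss_between_subj
    time_means = long.groupby("session")["value"].mean()
    n_per_time = long.groupby("session")["value"].count()
    ss_time = float((n_per_time * (time_means - grand) ** 2).sum())
    cell = long.groupby(["group", "session"])["value"].agg(["mean", "count"])
    ss_cells = float(
        (cell["count"] * (cell["mean"] - grand) ** 2).sum()
    )
    ss_interaction = ss_cells - ss_group / 1.0 - ss_time
    ss_error_within = ss_within_subj - ss_time - ss_interaction

    df_group, df_subj = G - 1, N - G
    df_time = T - 1
    df_inter = (T - 1) * (G - 1)
    df_err_within = (T - 1) * (N - G)

    eps = 1.0
    if sphericity_correction:
        wide = (
            long.pivot(index="patient", columns="session", values="value")
            .to_numpy()
        )
        eps = _gg_epsilon(wide)

    def result(effect, ss, df_main, ss_err, df_err, scale=1.0):
        df_m, df_e = df_main * scale, df_err * scale
        ms, ms_err = ss / df_main, ss_err / df_err
        F = ms / ms_err if ms_err > 0 else 0.0
        p = float(sct.f.sf(F, df_m, df_e)) if F > 0 else 1.0
        return AnovaResult(
            effect=effect,
            F=float(F),
            df_main=df_m,
            df_error=df_e,
            p=p,
            partial_eta_sq=partial_eta_sq(df_m, df_e, F) if F > 0 else 0.0,
        )

    return {
        "group": result("group", ss_group, df_group, ss_subj_within, df_subj),
        "time": result("time", ss_time, df_time, ss_error_within, df_err_within, eps),
        "interaction": result(
            "interaction", ss_interaction, df_inter, ss_error_within, df_err_within, eps
        ),
    }


def rm_anova_within_group(
    long: pd.DataFrame, sphericity_correction: bool = False
) -> AnovaResult:
    """One-way repeated-measures ANOVA across sessions for one group.

    F = MS_time / MS_(time x subjects); the simple-main-effect follow-up
    run within each response group after a significant interaction.
    """
    long = _check_long(long, need_group=False)
    grand = long["value"].mean()
    T = long["session"].nunique()
    n = long["patient"].nunique()
    subj_mean = long.groupby("patient")["value"].mean()
    time_means = long.groupby("session")["value"].mean()
    ss_total = float(((long["value"] - grand) ** 2).sum())
    ss_subj = T * float(((subj_mean - grand) ** 2).sum())
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_err = ss_total - ss_subj - ss_time
    df_time, df_err = T - 1, (T - 1) * (n - 1)
    eps = 1.0
    if sphericity_correction:
        wide = long.pivot(index="patient", columns="session", values="value").to_numpy()
        eps = _gg_epsilon(wide)
    ms_time, ms_err = ss_time / df_time, ss_err / df_err
    F = ms_time / ms_err if ms_err > 0 else 0.0
    df_m, df_e = df_time * eps, df_err * eps
    p = float(sct.f.sf(F, df_m, df_e)) if F > 0 else 1.0
    return AnovaResult(
        effect="time",
        F=float(F),
        df_main=df_m,
        df_error=df_e,
        p=p,
        partial_eta_sq=partial_eta_sq(df_m, df_e, F) if F > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# Contrasts & baseline table


def group_contrast_at_session(
    values_low: Sequence[float],
    values_high: Sequence[float],
    method: str = "t",
) -> Tuple[float, float]:
    """Two-sample comparison of one parameter at one session.

    ``method="t"`` is the pooled-variance independent t test (two-tailed);
    ``method="mann_whitney"`` is the Mann-Whitney U test.
    """
    a = np.asarray(values_low, dtype=float)
    b = np.asarray(values_high, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("group_contrast needs >= 2 values per group")
    if method == "t":
        if np.var(a) == 0 and np.var(b) == 0:
            if np.mean(a) == np.mean(b):
                return 0.0, 1.0
            raise ValidationError("zero variance in both groups")
        res = sct.ttest_ind(a, b, equal_var=True)
        return float(res.statistic), float(res.pvalue)
    if method == "mann_whitney":
        res = sct.mannwhitneyu(a, b, alternative="two-sided")
        return float(res.statistic), float(res.pvalue)
    raise ValidationError(f"unknown method {method!r}")


def _is_categorical(s: pd.Series) -> bool:
    return (
        s.dtype == bool
        or s.dtype == object
        or isinstance(s.dtype, pd.CategoricalDtype)
        or (s.dropna().nunique() <= 2 and set(s.dropna().unique()) <= {0, 1})
    )


def baseline_table(
    data: pd.DataFrame,
    group_col: str = "group",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Table-1-style baseline comparison of the two response groups.

    Continuous variables: Shapiro-Wilk normality check in each group at
    alpha; normal -> mean (SD) with pooled t test, non-normal ->
    median (IQR) with Mann-Whitney.  Categorical (binary) variables:
    n (%) per group with the Fisher exact test.
    """
    if group_col not in data.columns:
        raise ValidationError(f"missing group column {group_col!r}")
    groups = sorted(data[group_col].dropna().unique())
    if len(groups) != 2:
        raise ValidationError("baseline_table expects exactly 2 groups")
    rows = []
    for col in data.columns:
        if col == group_col:
            continue
        s = data[col]
        a = s[data[group_col] == groups[0]].dropna()
        b = s[data[group_col] == groups[1]].dropna()
        if _is_categorical(s):
            levels = sorted(s.dropna().unique(), key=str)
            if len(levels) != 2:
                continue  # only binary categorical fields are tabulated
            pos = levels[-1]
            tab = [
                [int((a == pos).sum()), int((a != pos).sum())],
                [int((b == pos).sum()), int((b != pos).sum())],
            ]
            _, p = sct.fisher_exact(tab)
            summ = lambda x: f"{int((x == pos).sum())} ({100 * (x == pos).mean():.0f})"
            rows.append(
                {
                    "variable": col,
                    groups[0]: summ(a),
                    groups[1]: summ(b),
                    "p": p,
                    "test": "fisher",
                }
            )
        else:
            a_f, b_f = a.astype(float), b.astype(float)
            normal = all(
                len(x) < 3 or sct.shapiro(x).pvalue > alpha for x in (a_f, b_f)
            )
            if normal:
                stat, p = group_contrast_at_session(a_f, b_f, "t")
                summ = lambda x: f"{x.mean():.1f} ({x.std(ddof=1):.1f})"
                test = "t"
            else:
                stat, p = group_contrast_at_session(a_f, b_f, "mann_whitney")
                summ = (
                    lambda x: f"{x.median():.1f} "
                    f"({x.quantile(0.75) - x.quantile(0.25):.1f})"
                )
                test = "mann_whitney"
            rows.append(
                {
                    "variable": col,
                    groups[0]: summ(a_f),
                    groups[1]: summ(b_f),
                    "p": p,
                    "test": test,
                }
            )
    return pd.DataFrame(rows)
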