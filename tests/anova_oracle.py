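"""Brute-force sums-of-squares ANOVA oracle, independent of the package.

Every sum of squares is accumulated observation by observation from cell
means computed with plain Python loops — a deliberately different
computational route from the implementation's grouped aggregation.
"""
import numpy as np


def _mean(xs):
    return sum(xs) / len(xs)


def mixed_anova_oracle(rows):
    """rows: iterable of (patient, group, session, value); balanced design.

    Returns dict effect -> (F, df_main, df_error).
    """
    rows = list(rows)
    values = [r[3] for r in rows]
    grand = _mean(values)
    patients = sorted({r[0] for r in rows})
    groups = sorted({r[1] for r in rows})
    sessions = sorted({r[2] for r in rows})

    subj_mean = {p: _mean([r[3] for r in rows if r[0] == p]) for p in patients}
    subj_group = {p: next(r[1] for r in rows if r[0] == p) for p in patients}
    group_mean = {g: _mean([r[3] for r in rows if r[1] == g]) for g in groups}
    time_mean = {t: _mean([r[3] for r in rows if r[2] == t]) for t in sessions}
    cell_mean = {
        (g, t): _mean([r[3] for r in rows if r[1] == g and r[2] == t])
        for g in groups
        for t in sessions
    }

    ss_group = sum((group_mean[r[1]] - grand) ** 2 for r in rows)
    ss_subj = sum((subj_mean[r[0]] - group_mean[r[1]]) ** 2 for r in rows)
    ss_time = sum((time_mean[r[2]] - grand) ** 2 for r in rows)
    ss_inter = sum(
        (cell_mean[(r[1], r[2])] - group_mean[r[1]] - time_mean[r[2]] + grand) ** 2
        for r in rows
    )
    ss_err = sum(
        (r[3] - subj_mean[r[0]] - cell_mean[(r[1], r[2])] + group_mean[r[1]]) ** 2
        for r in rows
    )

    G, T, N = len(groups), len(sessions), len(patients)
    df_group, df_subj = G - 1, N - G
    df_time, df_inter, df_err = T - 1, (T - 1) * (G - 1), (T - 1) * (N - G)

    def F(ss, df, ss_e, df_e):
        return (ss / df) / (ss_e / df_e) if ss_e > 0 else 0.0

    return {
        "group": (F(ss_group, df_group, ss_subj, df_subj), df_group, df_subj),
        "time": (F(ss_time, df_time, ss_err, df_err), df_time, df_err),
        "interaction": (F(ss_inter, df_inter, ss_err, df_err), df_inter, df_err),
    }


def rm_anova_oracle(rows):
    """rows: iterable of (patient, session, value); returns (F, df_t, df_e)."""
    rows = list(rows)
    grand = _mean([r[2] for r in rows])
    patients = sorted({r[0] for r in rows})
    sessions = sorted({r[1] for r in rows})
    subj_mean = {p: _mean([r[2] for r in rows if r[0] == p]) for p in patients}
    time_mean = {t: _mean([r[2] for r in rows if r[1] == t]) for t in sessions}
    ss_subj = sum((subj_mean[r[0]] - grand) ** 2 for r in rows)
    ss_time = sum((time_mean[r[1]] - grand) ** 2 for r in rows)
    ss_err = sum(
        (r[2] - subj_mean[r[0]] - time_mean[r[1]] + grand) ** 2 for r in rows
    )
    n, T = len(patients), len(sessions)
    df_time, df_err = T - 1, (T - 1) * (n - 1)
    F = (ss_time / df_time) / (ss_err / df_err) if ss_err > 0 else 0.0
    return F, df_time, df_err


def random_balanced_design(rng, with_effects=True):
    """Small random balanced two-group repeated-measures design."""
    n_per_group = rng.integers(2, 5)
    T = rng.integers(2, 6)
    rows = []
    for gi, g in enumerate(("low", "high")):
        for pi in range(n_per_group):
            pid = f"{g}{pi}"
            subj = rng.normal(0, 2)
            for t in range(T):
                val = rng.normal(0, 1) + subj
                if with_effects:
                    val += 0.5 * t * gi + 0.3 * t
                rows.append((pid, g, t, float(val)))
    return rows
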