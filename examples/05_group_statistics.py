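"""Two-way mixed ANOVA of a heart-rate parameter across the program.

Builds the per-session HR_peak truth values of a simulated cohort
(fast: no waveform synthesis needed for this illustration), adds
measurement-scale noise, and tests whether its progression over the five
sessions differs between the response groups — the time x group
interaction with its partial eta squared effect size, followed by the
within-group repeated-measures follow-ups.
"""
import numpy as np

from walkbeat.simulate import CohortSpec, truth_table
from walkbeat.stats import mixed_anova, rm_anova_within_group

tt = truth_table(CohortSpec(seed=11))
tt["value"] = (
    tt["rest_hr_true"] + tt["b_true"] * 360 + tt["a_true"] * 360**2
    + np.random.default_rng(0).normal(0, 0.6, len(tt))
)
long = tt[["patient", "group", "session", "value"]]

res = mixed_anova(long)
r = res["interaction"]
print("HR_peak, two-way mixed ANOVA (time x group interaction):")
print(f"  F({r.df_main:.0f}, {r.df_error:.0f}) = {r.F:.2f}, "
      f"p = {r.p:.2g}, partial eta^2 = {r.partial_eta_sq:.3f}")
print()
for g, sub in long.groupby("group"):
    fr = rm_anova_within_group(sub)
    print(f"  {g:>4}-response follow-up over time: "
          f"F({fr.df_main:.0f}, {fr.df_error:.0f}) = {fr.F:.2f}, p = {fr.p:.2g}")
print()
print("The high-response group's peak heart rate rises across rehabilitation")
print("while the low-response group's stays flat - hence the interaction.")
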