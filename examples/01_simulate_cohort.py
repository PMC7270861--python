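"""Simulate a small two-group rehabilitation cohort and inspect its truth.

Generates a scaled-down version of the default cohort (6 patients per
response group, five 6MWT sessions each) and prints the group-level
distance structure the generator encodes: the low-response group gains
less than 90 m over the program, the high-response group more.
"""
import numpy as np

from walkbeat.simulate import (
    CohortSpec,
    default_high_profile,
    default_low_profile,
    truth_table,
)

spec = CohortSpec(
    profiles=(
        default_low_profile(n_patients=6),
        default_high_profile(n_patients=6),
    ),
    seed=42,
)
tt = truth_table(spec)

print("patient-session truth table (first rows):")
print(tt.head(5).to_string(index=False))
print()
for g, sub in tt[tt.session == 0].groupby("group"):
    gains = tt.groupby("patient")["total_gain"].first()[sub.patient]
    print(
        f"{g:>4}-response: baseline {sub.distance.mean():6.1f} m, "
        f"total gain {gains.mean():6.1f} m (range {gains.min():.0f}-{gains.max():.0f})"
    )
print()
print("Gains below/above 90 m define the response groups; the same seed")
print("always reproduces the identical cohort, waveforms included.")
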