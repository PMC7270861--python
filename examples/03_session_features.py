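"""Static heart-rate parameters and effort for one simulated session.

Simulates one full 16-minute session (5 min rest / 6 min walk / 5 min
recovery), recovers the beat series from the raw ECG, and prints the
session's static parameters: HR_rest (final 20 s of rest), HR_peak
(final 10 s of walking), HR_rec1..5 (each minute of recuperation),
HR_peak/distance, and the accelerometer effort.
"""
from walkbeat.ecg import segment_phases
from walkbeat.features import static_params
from walkbeat.pipeline import process_session
from walkbeat.simulate import CohortSpec, simulate_session

spec = CohortSpec(seed=7)
sr = simulate_session(spec, 0, spec.profiles[0], 0, 0)
res = process_session(sr.recording, fit_all=False)

row = res.row
print(f"patient {row['patient']}, session {row['session']}, "
      f"distance {row['distance']:.0f} m")
print(f"HR_rest      {row['hr_rest']:6.1f} bpm   (truth rest HR {sr.truth.rest_hr:.1f})")
print(f"HR_peak      {row['hr_peak']:6.1f} bpm")
for k in range(1, 6):
    print(f"HR_rec{k}      {row[f'hr_rec{k}']:6.1f} bpm")
print(f"HR_peak/dist {row['hr_peak_dist']:6.3f} bpm/m")
print(f"effort       {row['effort']:6.2f} m/s^2")
print()
print("HR_peak exceeds HR_rest by the quadratic walking-phase rise; the")
print("recovery minutes decay back toward the resting heart rate.")
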