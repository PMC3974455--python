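"""Quantify evening anticipation under light-dark entrainment.

Compares a normally entrained cohort (activity ramps up over the 3 h before
lights-off) against a clock-null-like cohort that only startles at light
transitions. The anticipation index is the fraction of the 6-h pre-dusk
activity falling in the final 3 h: 0.5 means no anticipation.
"""

import numpy as np

from circatox import anticipation as ant, synthetic_data as sd

entrained = sd.gen_activity(sd.SimulationConfig(seed=7, n_flies=20))
clock_null = sd.gen_activity(
    sd.SimulationConfig(
        seed=8, n_flies=20, evening_ramp_gain=0.0, morning_ramp_gain=0.0
    )
)

groups = {}
for label, cohort in (("entrained", entrained), ("clock-null", clock_null)):
    groups[label] = [ant.series_anticipation(s, range(0, 3)) for s in cohort]
    idx = [r.index for r in groups[label]]
    print(f"{label:>10}: evening index {np.mean(idx):.3f} +/- {np.std(idx):.3f} (n=20)")

report = ant.compare_anticipation(groups)
print(f"\n{report.test}: p = {report.p_value:.2e}")
print(
    "An index above 0.5 means activity is concentrated just before dusk "
    "(anticipation); the clock-null group sits at 0.5 because startles alone "
    "carry no anticipatory information."
)
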