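"""Score circadian rhythmicity of a simulated DD free-run cohort.

Generates a 16-fly cohort entrained for 3 days of 12:12 LD and released
into 7 days of constant darkness, then computes each fly's rhythmicity
statistic (RS = correlogram peak in the 18-30 h window over the 2/sqrt(n)
confidence line) and free-running period, and prints the cohort summary.
An RS at or below 1.5 classifies a fly as arrhythmic.
"""

from circatox import dam_io, rhythmicity as rh, synthetic_data as sd

cfg = sd.SimulationConfig(seed=42, n_flies=16, dd_amplitude=0.8, period_h=24.0)
cohort = sd.gen_activity(cfg)

results = []
for fly in cohort:
    dd = dam_io.slice_segment(fly, "DD")
    results.append(rh.score_series(dd))

for r in results[:4]:
    period = f"{r.period_h:5.2f} h" if r.period_h else "   -  "
    print(f"{r.fly_id}: RS = {r.rs:5.2f}  period = {period}  rhythmic = {r.rhythmic}")
print("...")

summary = rh.summarise_cohort(results, genotype="synthetic", age_group="2-12 dae")
print(
    f"\ncohort: {summary.n} flies, {summary.rhythmic_percent:.0f}% rhythmic, "
    f"mean RS {summary.rs_mean:.2f}, mean period {summary.period_mean_h:.2f} h"
)
print(
    "A rhythmic percentage near 100 with a ~24 h mean period is the healthy-"
    "control signature; amplitude-degraded cohorts lose both."
)
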