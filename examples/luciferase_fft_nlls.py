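"""Fit clock-reporter bioluminescence traces by FFT-NLLS.

Generates damped-cosine luciferase traces with measurement noise, fits the
single-cosine model and prints period, amplitude and the relative amplitude
error; a rel-amp error above 0.7 classifies a trace as arrhythmic.
"""

import numpy as np

from circatox import bioluminescence as bl, synthetic_data as sd

cfg = sd.SimulationConfig(
    seed=5,
    n_flies=6,
    luc=sd.LucParams(a0_cps=100.0, noise_sd=15.0, period_h=24.5, span_h=120.0),
)
traces = sd.gen_luciferase(cfg)

fits = [bl.fft_nlls(t, dd_only=False) for t in traces]
for f in fits:
    print(
        f"{f.fly_id}: period {f.period_h:5.2f} h, amplitude {f.amplitude:6.1f} CPS, "
        f"rel-amp error {f.rel_amp_error:.3f} -> {bl.classify_trace(f)}"
    )

grid, mean, sem = bl.group_profile(traces)
print(
    f"\ngroup profile: {len(grid)} timepoints, peak mean {mean.max():.0f} CPS, "
    f"median s.e.m. {np.median(sem):.1f} CPS"
)
print(
    "Rhythmic traces recover the programmed 24.5 h period; rel-amp error "
    "grows with noise and damping, and >0.7 would mark a trace arrhythmic."
)
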