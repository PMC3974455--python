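# Methods

This note documents the models and numerical choices behind `circatox`: what
each analysis computes, which knobs matter, what the synthetic cohorts do and
do not emulate, and where the design was genuinely open.

## Locomotor rhythmicity (RS statistic)

Activity is recorded as beam crosses summed into fixed bins (30 min by
default), labelled by bin start over half-open intervals. For scoring the
free-running rhythm, only the constant-darkness (DD) segment of the standard
3 d LD + 7 d DD protocol is used: under entrainment the light cycle itself
drives 24-h structure, so DD is where endogenous rhythmicity is measurable.

The correlogram of the mean-subtracted series uses the *biased*
autocovariance estimator (normalising every lag by `n`, not `n − k`). The
biased estimator trades a deterministic taper — a cosine's peak at lag `k`
shrinks by `(1 − k/n)`, about 14% at lag 48 of 336 bins — for lower variance
and a correlogram that cannot diverge at long lags. The rhythmicity
statistic is

    RS = max coefficient at lags in [18 h, 30 h] / (2/√n)

where `2/√n` is the classical large-sample 95% sampling-error line for the
autocorrelation of white noise. RS ≤ 1.5 classifies a fly as arrhythmic;
the threshold is inclusive on the arrhythmic side. A negative window peak
(no circadian recurrence at all) is reported as RS = 0. Both the window and
the confidence-line constant are parameters; results should be reported
with the values used.

The free-running period is the window peak lag refined by three-point
parabolic interpolation, giving sub-bin resolution (the 30-min grid alone
quantises periods to 0.5 h). With the biased estimator the taper also drags
the interpolated peak slightly toward shorter lags (≈ 0.1 h at 7 d / 24 h);
this is far below the Poisson-noise scatter of individual estimates
(≈ ±0.4 h at modulation amplitude 0.8) and is left uncorrected. Period
statistics are reported over rhythmic flies only — arrhythmic correlograms
have no meaningful peak.

Tie-break at the smallest lag; a peak on the window boundary is returned
unrefined with a warning. Constant (zero-variance) series are an error, not
an RS of 0, so silent dead channels cannot pass as scored flies; the
separate dead-fly filter (zero counts over the final 24 h, configurable,
off unless invoked) handles mid-recording deaths explicitly and logs
removals.

## Anticipation index

Entrained flies ramp activity up over ~2–3 h before the light transitions.
Per fly, days within an LD segment are averaged into a daily profile
aligned to ZT0 = lights-on, and the evening index is

    index = Σ activity in [T−3 h, T) / Σ activity in [T−6 h, T)

with `T` the lights-off time. The transition bin itself is excluded from
both windows: the startle response to the light change is visually driven
masking, not anticipation, and including it would inflate the index for any
genotype with intact vision. A flat profile gives 0.5; a linear ramp gives
0.75 (the ratio of ∫₃⁶ t dt to ∫₀⁶ t dt). The index is undefined (reported
as missing, never 0 or imputed) when the 6-h window holds no activity. The
morning index is the symmetric construction before lights-on. Indices are
computed per fly and compared across groups by Kruskal–Wallis with Dunn
post-tests, keeping the fly as the unit of replication.

## FFT-NLLS bioluminescence fitting

Each luciferase trace is detrended by OLS line removal, then fitted with a
single undamped cosine `A·cos(2π(t − φ)/τ)`. The fit is seeded by the
dominant discrete-Fourier component with period inside the circadian window
(18–30 h by default) and refined by Levenberg–Marquardt. One cosine — not
the multi-component decomposition some implementations offer — because the
downstream screen uses only the dominant component's period, amplitude and
amplitude error, and a single component keeps that error interpretable.

Rhythm robustness is the **relative amplitude error**: the half-width of
the amplitude's 95% *joint* confidence region divided by the amplitude,

    rel-amp error = √(3·F(0.95; 3, n−3)) · SE(A) / A,

using the support-plane (simultaneous) bound over the three fitted
parameters rather than the marginal t-interval. The joint bound reflects
that period and phase are estimated, not known: a spurious "rhythm" that
NLLS has freely tuned in period and phase carries much more amplitude
uncertainty than its local covariance suggests, and the marginal interval
under-penalises exactly those fits. With the joint bound, pure-noise traces
exceed the 0.7 arrhythmia cut ~98% of the time while clean rhythmic traces
sit near 0.003–0.06. A trace is rhythmic iff rel-amp error ≤ 0.7 (the cut
itself still counts as rhythmic) *and* the fitted period lies inside the
window. No spectral peak in the window yields an arrhythmic result with an
infinite rel-amp error; non-convergent fits are flagged and excluded from
group summaries.

Damping is deliberately absent from the model even though the generator can
produce damped traces: fitting an undamped cosine to a damping rhythm
inflates the rel-amp error, which is the intended behaviour of the 0.7
screen (a fading reporter rhythm *should* drift toward the arrhythmic
call). Fits run on the DD portion of annotated traces by default.

## Survival analysis

Kaplan–Meier product-limit estimation and the Mantel–Haenszel log-rank test
(via `lifelines`) compare two light conditions on all individuals; the
median is the smallest observed time with S(t) ≤ 0.5 and is undefined
(flagged) if S never reaches 0.5. Deaths are scored in whole days. Because
flies are housed ten per vial, the package also offers the conservative
replicate-level comparison: the median survival of each vial, then a
two-sample test on the ten-vs-ten vial medians. Mann–Whitney is the logged
default (vial medians of n = 10 are coarse and tie-prone); Student's
unpaired t is available. Percent change in median survival is
`100·(median_a − median_b)/median_b`.

## Image quantification

ROI means are plain pixel averages under boolean masks. Background
correction mirrors the manual workflow: the background mask must have
exactly the signal mask's area (the same ROI, moved) and be disjoint from
it; corrected intensity is the difference of the two ROI means, invariant
to additive offsets and linear in gain. Negative corrected values are
possible and flagged rather than clipped.

Soma counting is Gaussian smoothing (σ = 2 px), Otsu thresholding and
connected-component labelling with a minimum-area filter — an automation of
the manual count that is reliable only for bright, well-separated somata
(exact recovery at SNR ≥ 5 on synthetic images); manual counts can be
supplied directly. Per-genotype tallies of hemispheres with the full
complement (normally 4) versus fewer feed a Pearson χ² on the 2×2 table,
1 df, no continuity correction (matching common practice in the field); an
expected cell below 1 triggers a warning recommending an exact test.

## Group statistics

Every dataset is screened with the D'Agostino–Pearson omnibus normality
test; parametric tests (t / one-way ANOVA) are used only when all groups
pass at α = 0.05, otherwise Mann–Whitney / Kruskal–Wallis. Groups below the
omnibus test's n = 8 requirement count as "insufficient" and force the
nonparametric route — the conservative direction. Dunn's post-test is
implemented directly (pooled mid-ranks, tie-corrected variance, two-sided
normal z) with Bonferroni multiplication over all pairs, the adjustment
GraphPad-style workflows use; the adjustment is a parameter. Simulated null
calibration of the routed pipeline keeps the empirical size within ~0.06 at
nominal 0.05.

## Synthetic cohorts

The generators are pure functions of their config (seed included) and
encode the structure each analysis assumes:

* **Activity**: Poisson counts per bin. DD rate
  `baseline·(1 + A·cos(2π(t−φ)/τ))`, with `A` optionally decaying with age
  as `2^(−age/halflife)` — an amyloid-like cohort loses rhythm amplitude
  while its mean activity stays level. LD adds exponential anticipatory
  ramps (time constant 1 h, spanning the 3 h before each transition) and
  one-bin startle spikes at the transitions; LL is flat. Defaults: 8
  counts/30-min bin baseline, A = 0.8, τ = 24 h — a robustly rhythmic young
  control cohort of 16 flies over 3 d LD + 7 d DD.
* **Luciferase**: `baseline + slope·t + A₀·2^(−t/halflife)·cos(...)` plus
  Gaussian noise, clipped at zero CPS; 5-day hourly traces, A₀ = 100 CPS.
  Base-2 damping so half-lives read directly in hours.
* **Lifespan**: Gompertz hazard `a·e^{bt}` sampled by inverse CDF, ceiling
  to whole days, vials of ten, 100 flies per arm. Defaults are calibrated
  analytically so the LD arm's median is 57 dae and the LL arm's 48 dae
  (the published control values), with `a` scaled by the condition effect
  (≈ 4.22) for LL. The steepness b = 0.16/day is the package's choice of a
  realistic demographic slope for flies aged at 29 °C; at this slope the
  KM-median sampling SE at n = 100 is ≈ 0.9 dae, so replicate assays
  reproduce their medians within ±2 dae, consistent with the
  reproducibility the replicate-vial design implies. (A much shallower
  slope, e.g. b = 0.08, would make the median itself irreproducible to ±2
  across identical assays at n = 100.)
* **Images**: Gaussian-profile blobs (peak 200, σ = 3 px) at
  rejection-sampled centres with a minimum separation, on N(20, 5²)
  background, with ground-truth masks (2σ discs) and counts.

What the generators do **not** emulate: bout structure and ultradian
rhythms in activity (real fly activity is burstier than Poisson), masking
beyond a single startle bin, inter-fly period dispersion, plate-position
and luminescence decay artefacts of real reporter assays, age-structured
frailty beyond the Gompertz form, and optical blur/bleed-through in images.
Passing tests therefore demonstrate correctness of the *computations* under
the stated statistical structure, not robustness to every artefact of real
recordings.

## Numerical choices and degenerate inputs

* Re-binning requires an integer width multiple; trailing partial windows
  are dropped and logged, never padded (padding would bias means).
* DAM rows with a non-valid status code are dropped with a warning; counts
  must be integers and non-negative.
* Autocorrelation of a constant series is a "no variance" error; max lag is
  capped at half the span.
* NLLS amplitude sign is canonicalised (A ≥ 0, phase shifted by τ/2);
  phase is reported modulo the period.
* Detrending leaves a cosine untouched exactly only when it is even about
  the sample-grid midpoint (discrete orthogonality); in general the leak is
  a few percent of amplitude and is absorbed by the NLLS refit.
* The acceptance script scales simulation sizes (20 flies per period level,
  30 noise traces, 200 null replicates) to desk-scale runtimes; these sizes
  are the package's reporting defaults.
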