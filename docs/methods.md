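# Methods

## Detection pipeline

The detector consumes three synchronously sampled channels: Earth-frame
horizontal acceleration (`earth_x` east, `earth_y` north, in G with
1 G = 9.80665 m/s²) and heading (`euler_x`, degrees clockwise from due
north, wrapped to [0, 360)). Processing order is smoothing → reprojection
into the runner's antero-posterior/medio-lateral axes → horizontal modulus
→ thresholded peak ("change of inertia", COI) detection → unification of
COIs into change-of-direction (COD) events.

**Smoothing window.** The window is a percentage of one second of samples:
`w = max(1, round(pct/100 · f_s))`, so 30% at 100 Hz is a 30-sample
(0.3 s) window and the physical bandwidth of the filter is independent of
sampling frequency. This is what makes detection counts stable when the
same recording is decimated from 100 Hz to 50 or 20 Hz. The filter is a
centred mean of half-width `⌊w/2⌋`; near the edges the window shrinks
symmetrically rather than padding, so no data is fabricated at the trial
boundaries (which are quiescent in an agility test). Acceleration channels
are averaged arithmetically; the heading channel uses the circular mean
(atan2 of the windowed unit-vector means) because angles cannot be averaged
across the 0/360 seam.

**Axis conventions.** Heading is measured clockwise from north, with
`earth_y` pointing north and `earth_x` east; antero-posterior is positive
forward, medio-lateral positive to the runner's right. Every detection
output except the ML sign is invariant under a joint rotation of the scene
(the test suite asserts this), so the convention only fixes which turns
read as "rightward".

**COI detection.** COIs are strict local maxima of the modulus at or above
the minimum intensity peak (PmI); a plateau of equal values yields one
event at its centre. Of any two peaks closer than
`min_peak_separation_s` (default 0.10 s) only the larger survives, equal
peaks keeping the earlier — one running step takes ≈ 0.3 s at these
speeds, so 0.1 s suppresses jitter twins without eating true steps, and
the tie rule keeps the output order-stable and deterministic.

**COI → COD unification.** A single turn is executed over several braking
and propulsive steps, each of which can produce a COI. Consecutive COIs
with inter-event gaps ≤ `merge_gap_s` (default 0.50 s) merge greedily
left-to-right into one COD. The 0.5 s default spans the 2–3 step cluster
of a cut at 13–18 km/h while separating distinct turns, which in the test
protocol are many seconds apart; it is exposed as a first-class
configuration field because the original system does not document its
unification constant.

**Degenerate inputs.** Empty channels, mismatched lengths, non-positive
sampling rates and unsorted COI sequences raise `ValueError` early;
all-quiet recordings yield an empty event list rather than an error.

## Downsampling

`downsample` is plain sample selection (every k-th sample for integer
ratios, nearest-sample otherwise) with no anti-alias filter. The
percentage-based smoothing stage is the pipeline's low-pass filter, and
selection — unlike averaging — is safe for the circular heading channel.
Decimation slightly re-aligns samples and (without anti-aliasing) leaves
marginally more noise in the smoothed signal, so a peak sitting almost
exactly at threshold can occasionally flip a count between 100 Hz and
50 Hz; across a batch of simulated 13 km/h trials totals agree at 50 Hz
and differ by well under 5% at 20 Hz.

## Trial simulator

The simulator emulates the standard assessment protocol: a 15 m straight
approach at 13 or 18 km/h, hard braking into a single turn of 45, 90, 135
or 180 degrees left or right at a break point, re-acceleration, and a 5 m
run-out, bracketed by a standing start (build-up at 2.5 m/s²), a final
stop, and 0.7 s idle margins so the filter edges see quiescent signal.

**Kinematics.** Speed is piecewise linear: constant approach, braking at
4.0 m/s² down to the turn speed, constant speed through a linear heading
ramp of duration `0.2 + angle/450` s, re-acceleration at 4.0 m/s². The
turn speed scales with angle — `v·(1 − 0.4·angle/180)` — because a
shallow 45° cut barely costs speed while a 180° reversal drops to 60% of
approach speed. This keeps the centripetal + braking acceleration of every
angle/speed combination in the 0.8–2 G band that the PmI grid probes; with
a fixed 60% slowdown a 45° turn at 13 km/h would peak near 0.6 G and be
physically undetectable at a 0.9 G threshold, which contradicts both the
published recovery of all angles and the window-averaged bound
`2·v·sin(θ/2)/w` on detectable direction-change acceleration. The
Earth-frame acceleration is the numerical derivative of the planar
velocity vector, converted to G.

**Gait and noise.** Foot-ground impacts are modelled as a sinusoid at the
step frequency (2.8 Hz) on the body axes, the ML component at 0.6 of the
AP amplitude and 90° out of phase. The amplitude is
`0.4 G · ((v/v₁₃)³ + 12·|a_kin|) · m(t)`: a cruise term growing with
running speed (harder strikes at 18 km/h than 13 km/h) plus a load term
proportional to the instantaneous kinematic acceleration (braking, cutting
and push-off steps strike many times harder than cruise steps — this is
the very structure the COI detector keys on, and without it no smoothing
percentage could separate turn steps from cruise steps). `m(t)` is a
per-step multiplier, normal with CV 0.25 clipped to [0.1, 2.5], giving the
stride-to-stride variability that makes marginal configurations
intermittently over-count. White Gaussian noise (SD 0.05 G per axis) and
heading jitter (SD 1°) complete the signal. All randomness flows through
the integer trial seed; no global random state is touched.

The load gain (12 per G) and cruise exponent (3) were calibrated once so
that the synthetic grid reproduces the published qualitative structure —
near-exact recovery at 30%/0.9 G for 13 km/h and 40%/0.9 G for 18 km/h,
systematic over-counting at 20%/0.8 G (strongest at 18 km/h), and
under-counting at 40%/1.0 G.

**What the simulator does not model.** Multi-segment biomechanics, the
relative oscillation of several stacked devices (between-device
disagreement must be injected explicitly, e.g. by simulating per-device
trials with different seeds), magnetometer disturbance, curved approach
paths, or fatigue; amplitudes are calibrated to the detector's working
range, not to traces from any particular commercial unit. Passing recovery
tests on this generator therefore demonstrates the algorithm's internal
consistency and parameter sensitivity, not field validity on real players.

**Protocol generator.** `generate_protocol` emits the full factorial
(participants × 4 angles × 2 directions × repetitions per speed): 5
participants × 5 repetitions = 200 trials at 13 km/h and, with 4
repetitions, 32 trials per participant at 18 km/h (the per-participant
arithmetic; 5 × 32 = 160 for the group). `drop_trials` removes a seeded
uniform subset, emulating the exclusion of repetitions with inconsistent
approach speed.

## Statistics

Validity of a device × configuration cell against the video criterion uses
the pooled-SD Cohen's d, `d = (m_a − m_b)/s_p` with `(n−1)`-weighted
pooling (for equal n: `s_p = √((s_a² + s_b²)/2)`), classified
trivial/small/medium/long/very long at |d| cut-points 0.2/0.6/1.2/2.0; the
percentage mean difference `100·(m_dev − m_ref)/m_ref`; and the coefficient
of variation `100·s/|m|`. The 95% CI for d uses the large-sample normal
approximation `SE = √((n_a+n_b)/(n_a·n_b) + d²/(2(n_a+n_b)))`; the CIs
printed alongside the published table match no standard closed form we
tried (normal approximation or noncentral-t with n = 5 per group), so CIs
here are informative output and are not golden-tested.

Reproducibility across devices uses the between-device CV (sample SD of
per-device means over their mean; grouped views average per-configuration
CVs) and ICC(2,k): two-way random effects, absolute agreement, average
measures, `(MSR − MSE)/(MSR + (MSC − MSE)/n)` from the two-way ANOVA
decomposition, with the F-based McGraw–Wong interval (single-measures
bounds stepped up by Spearman–Brown). A zero-variance matrix is defined as
perfect agreement (1.0). The implementation is cross-checked against
pingouin's `ICC(A,k)` row in the test suite. The absolute-agreement
variant is deliberate: a constant between-device offset must lower the
coefficient even though rankings are preserved, and a dedicated test
distinguishes it from the consistency variant.

**Published reference values.** The original study's per-participant counts
were never printed, so its headline ICCs (0.94 / 0.96) cannot be
recomputed and are not asserted anywhere. What can be recomputed exactly
are the derived columns of its comparison table from the printed
means/SDs. Doing so revealed nine cells whose printed d or CV disagrees
with their own printed summaries beyond rounding (e.g. a printed d of
−1.69 where the means give −0.54, a printed CV of 23 where sd/mean gives
12); these are frozen in `coddetect.reference` as explicit exclusion lists
with the recomputed values in comments, and golden tests cover every
remaining cell at ±0.01 on d and ±1 on the integer percentage columns
(several printed values are truncated rather than rounded, e.g. 0.867
printed as 0.86).

## Problem sizes

The recovery experiment in the acceptance tests runs the full 200-trial
13 km/h protocol at 100 Hz (≈ 10 s of signal per trial); the sensitivity
and property suites use 48–50 seeded trials. These sizes match the
original protocol and complete in seconds.
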