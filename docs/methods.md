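# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `breathloop`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The closed loop

One tick of the loop (default 10 ticks/s) chains:

    belt sample -> extremum detector -> same-phase rate estimator
                -> trapezoid score -> exponential smoothing
                -> aperture / light representation

In the control condition (`without_feedback`) the chain runs identically —
the score is computed and logged — but the representation is pinned fully
open (aperture 1.0, light 1.0), so sessions with and without feedback are
comparable column-for-column except for the representation.

## Signal model (simulator)

Each breath is an asymmetric raised cosine: from exhalation trough up to
inhalation peak over `inhale_fraction` (default 0.4) of the cycle, back
down over the remainder — exhalation longer than inhalation, as in quiet
human breathing. Breath-by-breath variability is modeled with
multiplicative uniform jitter on period (`cycle_jitter`, default 0.05) and
amplitude (`amplitude_jitter`, default 0.1). On top of the oscillation:

* **baseline drift** — a slow sinusoid (0.005–0.02 Hz, random phase) of
  amplitude `drift_amplitude` (default 0.1 of the unit breathing
  amplitude), standing in for belt slippage and posture change;
* **sensor noise** — white Gaussian, `noise_sd` (default 0.02);
* **movement artifacts** — Hann-windowed sinusoidal bursts with carrier
  frequency drawn per burst from 0.3–1.0 Hz, i.e. deliberately inside the
  fast-breathing band. Burst count is Poisson (default 4/min), durations
  0.5–2 s, amplitude a configurable fraction of the signal's half
  peak-to-trough range. In-band placement is the point: it is what makes
  band-pass filtering useless and forces morphology-based detection.

The default sample rate is 10 samples/s — generous for a sub-1-Hz signal
and cheap. Rates are always breaths/min, times seconds, amplitudes
unitless (stretch belts are uncalibrated). Every generator is a pure
function of its config including the seed.

What the simulator does **not** model: cardiac contamination of the belt
trace, nonlinear belt slippage, posture-specific waveform changes, or any
coupling between task events and breathing. Tests passing on this
generator show the pipeline handles in-band oscillatory interference,
drift, noise and breath variability — not every failure mode of real
field recordings.

### Pilot-study generator

`simulate_pilot` lays out participants × sessions with alternating
with/without-feedback conditions (defaults: 9 participants, 10 sessions of
900 s, starting with feedback). The learning model for the true session
mean rate is deliberately the simplest structure that produces the
qualitative pattern of interest —

    rate(i, j, c) = start_rate + b_i − per_session_drop · j
                    − feedback_offset · [c = with] ,  floored at floor_rate

with participant effects b_i ~ N(0, participant_sd²). Defaults:
start 18 breaths/min (load-elevated), drop 0.6/session, feedback offset
2.0, participant SD 1.2, floor 4.0 — chosen so training starts above the
4–12 band and ends inside it, and so the floor never binds for
realistically sized participant effects. When the floor never binds, the
true condition effect has the closed form
`−feedback_offset + per_session_drop · (mean session index without − with)`
(−1.4 breaths/min for the alternating default), which is what the
bootstrap-coverage experiments check against.

## Extremum detection

In-band artifacts rule out frequency filtering, so detection is
morphological, with three rules:

* **prominence gating** — a candidate extremum is confirmed only once the
  signal has reversed by `prominence_fraction` (default 0.3) of the
  peak-to-trough range over a trailing `rolling_window` (default 20 s);
  the adaptive range makes the threshold scale-free, which matters for an
  uncalibrated belt;
* **refractory merging** — same-kind extrema closer than `refractory`
  (default 1 s) are merged, keeping the more prominent one and dropping
  the shallow opposite extremum between them;
* **retrospective timing** — an emitted event carries the extremum's own
  time; emission happens later, once the event can no longer be revised.

Emission is held while a same-kind rival could still merge with the event
(that is only possible while the current candidate of the same kind sits
before the event's refractory horizon), with `rolling_window` as a hard
latency bound. One corner is deliberately tolerated: if two same-kind
extrema fall within the refractory interval *and* the later one's
confirmation lags beyond the rolling window, the streaming detector keeps
alternation at the expense of the refractory guarantee. Band-limited
breathing plus burst artifacts does not produce this; it would take a
plateau lasting longer than the rolling window straight after a
sub-refractory double bump.

`detect_extrema_offline` applies identical rules non-causally through an
independently written path (pandas time-window rolling statistics and a
separate scan, no emission gating). Mid-signal, the two implementations
must agree exactly; the batch path may additionally report events the
stream was still holding within one `rolling_window` of the end of data.
This two-implementation agreement is the detector's main correctness
check.

Ties in candidate tracking are broken toward the earlier sample (strict
inequality for replacement) in both implementations. Time comparisons
carry a 1 µs slack so window membership cannot flip on float rounding.

## Rate estimation

The instantaneous rate is 60/Δt for the interval Δt between consecutive
same-phase events — troughs by default: exhalation troughs are less
artifact-prone than peaks when the user is standing and moving. The
estimator:

* rejects any interval whose implied rate falls outside `plausible_rate`
  (default 2–60 breaths/min) — the second artifact-rejection stage; the
  anchor still advances, so one bad landmark costs one interval, not two;
* averages the last `window_cycles` accepted **intervals** and inverts the
  mean (default 3). Averaging intervals rather than per-interval rates
  avoids the harmonic/arithmetic ambiguity: the result is the rate of the
  averaged cycle, not the average of rates;
* reports `rate = None` until the first valid interval (warm-up) and sets
  a `stale` flag when no interval has been accepted for
  `staleness_timeout` (default 15 s).

Because every accepted interval implies a rate within bounds, so does the
inverted mean — estimates can never leave `plausible_rate`.

The window trades delay for stability: after a step change the estimate
settles within (window_cycles + 1) new cycles plus detector latency. The
default of 3 keeps the loop responsive (tens of seconds at slow rates)
while averaging out single-cycle jitter.

## Score and representation

The score is a trapezoid: 1.0 on the closed target band (4–12
breaths/min), linear to 0 at `zero_low` (1) and `zero_high` (24), 0
beyond. The plateau rewards the whole band — a broad target keeps
artifact-induced rate wobble from constantly toggling the feedback — and
the ramps give graded guidance outside it. `zero_high = 24` is twice the
band top, so a typically load-elevated rate near 18 scores about 0.5
rather than bottoming out. Band endpoints are inclusive and degenerate
ramps resolve ties toward the better score: boundary cases favor the
user.

The score is exponentially smoothed (time constant `smoothing_time`,
default 2 s) before driving the representation, damping the perceived
variability of the raw estimate; smoothing is a contraction, so it can
never amplify a disturbance. Aperture and light are affine in the
smoothed score with floors 0.25 and 0.3: the worst score still leaves a
quarter of the peripheral field and dim light. During warm-up the loop
assumes a neutral score of 0.5 rather than 0 — a session should not open
at maximal tunnel vision before anything was measured.

The pacer is a piecewise-cosine waveform (rise over the inhale fraction,
fall over the exhale fraction), continuous across segment boundaries, for
guided-breathing tutorials.

## Session logs and replay

Logs are plain text: a `#`-prefixed key=value block echoing the complete
configuration, then CSV rows of (time, raw, rate, score, aperture, light,
stale). Timestamps are rounded to 3 decimals at write time only; every
other value is written with shortest-round-trip float formatting. Because
the loop consumes samples at the tick cadence (zero-order hold), the raw
column alone suffices to recompute every derived column, and `replay`
checks a stored log against that recomputation cell by cell — bit-exact
equality, not tolerance. Replaying with overridden parameters shows
precisely which columns a parameter touches; this reproducible override
mechanism takes the place of a live tuning dashboard.

## Analysis

Session summaries are arithmetic means over ticks with a defined,
non-stale rate; warm-up and stale stretches are excluded because their
logged score is neutral filler, not measured breathing. The fraction of
those ticks inside the band (`time_in_band`) is carried as an auxiliary
column; the primary score summary is the tick-mean of the instantaneous
score.

The score-vs-rate relationship is a degree-2 OLS fit with a pointwise 95%
band from case-resampling bootstrap (resample sessions with replacement,
refit, take 2.5/97.5 percentiles of the predictions on a grid). Bootstrap
refits use batched normal equations; resamples with fewer than three
distinct rates cannot identify a parabola and are redrawn. The band is
widened, if ever necessary, to contain the point prediction, so
`lower ≤ fit ≤ upper` holds by construction.

Condition contrasts are percentile-bootstrap 95% CIs of the mean
difference (with − without). The default pairing is by participant — each
participant contributes the difference of their condition means, and
participants are resampled — since every pilot participant experienced
both conditions; an unpaired variant resamples each condition's sessions
independently. `n_boot` defaults to 5000; seeds are mandatory in the
library so no analysis is silently irreproducible. No hypothesis tests
and no multiplicity control: the output is effect sizes with intervals.

### Known statistical limitation

The percentile bootstrap undercovers for small samples: for a paired mean
of n participants it behaves like a z-interval using the 1/n-divisor
variance estimate, giving roughly 89–91% actual coverage at n ≈ 9–15
instead of the nominal 95% (the t-correction it lacks is
`2·Φ_t(1.96·√((n−1)/n)) − 1`). The package's coverage experiments
therefore run at 50 simulated participants, where the nominal level is
attainable, and CIs computed on a 9-participant pilot should be read as
mildly anticonservative. Bias-corrected variants are out of scope.

## Problem sizes used in tests and the acceptance script

Simulations are scaled to desk size: rate-recovery and step-response runs
use 120–200 s signals; detector-equivalence uses 50 draws of 60 s;
degradation uses 16 base signals of 90 s across four artifact amplitudes;
the coverage experiment runs 200 replications of a 50 × 8 × 45 s design
with 1000 bootstrap draws; the acceptance script's pilot analysis runs the
default 9 × 10 design at 120 s per session. The pilot generator's own
defaults (9 × 10 × 900 s) are unchanged by any of this.
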