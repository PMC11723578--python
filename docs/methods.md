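# Methods

## The statistical problem

Trial-aligned calcium traces are strongly autocorrelated: a single GCaMP
transient spans one to two seconds of 10 Hz samples, so tests that treat
timepoints as independent (t-tests, plain rank-sum tests across samples)
produce badly inflated significance when asking whether a neuron responds
to a stimulus. The package's core test replaces the theoretical null with
an empirical one built by *circular shifting*: rotating a trial's trace by
a random offset preserves transient shape and serial dependence while
destroying alignment to the events, so the distribution of any statistic
computed on rotated traces is a faithful null for "activity unrelated to
the stimulus".

## The permutation test

For one session and one stimulus, each trial trace is first cut to an
isolation window around CS onset (CS tests: [-30, 10) s; US tests:
[-30, 30) s). The per-trial statistic is the Wilcoxon rank-sum value —
the sum of pooled midranks over the post-stimulus samples against the
pre-stimulus samples (CS: [-20, 0) vs [0, 10); food: [-5, 13) vs
[13, 30); shock: [-5, 13) vs [13, 18)) — and the neuron's statistic is
the sum over trials. The null repository holds B = 500 such statistics,
each obtained by drawing one neuron uniformly from the session's full
population (the observed neuron may be drawn; pooling across the
population lets the null carry the heterogeneity of transient shapes),
rotating each of its trials by an independent uniform shift s in [1, N],
and summing the per-trial statistics. Empirical p-values use the add-one
form p+ = (#{W* >= W_obs} + 1)/(B + 1), p- with <=, two-sided
p = 2 min(p+, p-) capped at 1; a neuron with p < 0.05 is excited when
p+ < p-, inhibited when p- < p+. No multiple-testing correction is
applied by default (a Benjamini-Hochberg flag exists downstream of the
results table for users who want one).

Numerical choices: ranks are midranks (ties share their average rank);
no continuity correction or normal approximation is ever used — the
statistic is only compared against its own empirical null, so only its
ordering matters, which also makes the test invariant to any monotone
rescaling of fluorescence. Seconds map to sample indices by
floor(t x rate); all windows are half-open [start, end). The shift range
includes s = N (an identity rotation); a `shift_exclusion` margin can
remove near-identity shifts, but the default keeps the full range. All
random draws come from a single seeded NumPy PCG64 stream in a fixed,
documented order (per null draw: neuron index first, then the per-trial
shift vector), so a (session, windows, B, seed) tuple fixes every p-value
exactly. With p+ = p- (heavy ties) the neuron is not significant
regardless of alpha, and the smallest attainable two-sided p is
2/(B + 1) ≈ 0.004 at B = 500.

## The sign-rank alternative

The conventional comparison method tests each trial separately: a
one-sample Wilcoxon signed-rank test (normal approximation) of the
post-window samples against that trial's pre-window median, then a
cutoff on the number of trials individually significant (two-sided, per
trial alpha = 0.05) in one direction. Two cutoffs are provided. The
binomial cutoff — the smallest k with a Bin(n_trials, alpha/2) upper
tail at or below 0.05 — assumes per-trial tests hold their nominal
level, which autocorrelated traces violate badly (on simulated null
sessions the median neuron shows ~10 of 20 "significant" trials in its
dominant direction). The default in the analysis drivers is therefore a
*null-calibrated* cutoff: the per-trial procedure is run on a simulated
session with no event-locked modulation, and the cutoff is the smallest
count reached by at most 5% of those null neurons. This is this
package's concrete rendering of a distribution-based cutoff; it is a
design choice, clearly exposed as the `trial_count_cutoff` parameter.

## Encoding classification

Neurons registered across the appetitive and fear sessions carry an
ordered label pair (appetitive stimulus first). Both labels significant
in the same direction -> salience; both not significant -> not
significant; every other pair (opposite directions, or exactly one
significant) -> valence. The nine ordered subtypes are retained so
"food-excited only" and "shock-excited only" stay distinct cells.
Category and subtype counts collapse to contingency tables; comparisons
use the Pearson chi-square with no continuity correction (the asymptotic
test, matching how such category tables are conventionally compared).
Percentages are reported to the nearest whole percent (round half away
from zero); counts, not percentages, are the normative output.

## Synthetic data

The generator emulates the paired design: 20 appetitive and 10 fear
trials, 10 s CS at t = 0, US at t = 13 s, traces spanning [-30, 30) s at
10 Hz, with the same neuron IDs in both sessions linked by a registration
map. Baseline activity is shot noise: Poisson events (default 0.4 Hz)
with exponential amplitudes (mean 1.0 dF/F-like units) convolved with a
peak-normalized difference-of-exponentials kernel (rise 0.2 s, decay
1.5 s — GCaMP6m-like), plus Gaussian sensor noise (sd 0.15), a slow
sinusoidal drift (amplitude 0.1, period 40 s, random phase per trial),
and a one-kernel-length burn-in so event tails from before the trace
start are present. Traces are dF/F-like (unconstrained) by default; a
`raw` mode offsets and clips at zero.

Responses modulate the event rate inside a response window with uniform
[0, 0.3] s per-trial latency jitter: excited neurons add events at
`effect_size x baseline_event_rate` (default effect_size 4; with the
default kernel this puts the mean added signal at roughly the same
multiple of the baseline fluctuation); inhibited neurons suppress the
baseline rate multiplicatively (default: complete suppression), because
calcium event rates cannot go negative. Response durations default to
8 s (food, sustained consumption), 2 s (shock, sharp), and 9 s (CS).
Each neuron draws its joint (food, shock) category from a 3x3
probability table whose default equals the proportions observed among
303 cross-registered central-amygdala neurons; CS responses are drawn
conditionally (direction-matched with probability 0.2 given a US
response; 5% spontaneous CS responders otherwise — a stand-in, as no
empirical distribution for this coupling is available). Head-entry times
are US onset plus a lognormal latency (median 1 s, sigma 0.5 ln-units) —
also a stand-in distribution, flagged here. Every neuron has its own
seed substream (`SeedSequence([seed, i])`), so enlarging a population
never perturbs existing neurons.

What the simulation does not capture: correlated noise across neurons,
nonstationary event rates across trials (habituation/satiety), movement
artifacts, crosstalk between nearby cells, and real head-entry behavior.
Passing tests on synthetic data therefore validate the statistical
machinery (calibration, power under known effects, label recovery), not
claims about any particular biological dataset.

## Study conditions used by the test suite

Type-I calibration runs the test on null sessions of 200 neurons x 20
trials at B = 500 over three seeds and checks the pooled rejection
fraction against the exact binomial 99% acceptance band around 0.05.
Category-recovery and method-agreement checks use a "strong" condition —
effect_size 8, baseline event rate 1.0 Hz, noise sd 0.05, shock response
lengthened to 4.5 s, CS coupling off — under which every true effect is
far above noise, so labels are essentially determined and recovered
proportions must match the ground truth within multinomial error. The
analysis drivers under `analysis/` instead use the realistic defaults,
where power is deliberately partial (particularly for shock-inhibited
neurons, whose detectability is bounded by the few baseline events a 5 s
window contains) — mirroring the situation in real recordings.

## Peri-event metrics

z-scoring is per neuron x trial against that trial's own baseline window,
default [-10, 0) s before the alignment event (the pre-event span
conventionally plotted); the normalization window is configurable since
no single standard exists. Zero-variance baselines are flagged and
zero-filled rather than raised, so population averages remain computable.
AUC is the trapezoidal integral of the trial-averaged z trace in
z x seconds over a stated window — [0, 10) s after US delivery and
[0, 5) s after head entry in the drivers. The half-open sampling
convention (samples a .. b - 1/r) is normative: a constant z = 1 over
[0, 5) at 10 Hz gives exactly 4.9. A consequence, documented rather than
hidden: adjacent-window AUCs differ from the merged window's AUC by
exactly the one bridging trapezoid at the shared endpoint. Time-to-peak
and maximum z are read off the same averaged trace, ties resolving to
the earliest sample; early/late comparisons use a half split (first
ceil(n/2) vs last floor(n/2) trials) by default. Group-level inference
on these metrics (ANOVAs, t-tests) is left to general statistics tools;
the package emits the per-neuron values and mean ± s.e.m. summaries.

## Known limitations

* The permutation null is discrete at resolution 1/(B + 1); at B = 500
  the smallest two-sided p is ~0.004, which is ample for alpha = 0.05
  but unsuitable for stringent corrected thresholds without raising B.
* Pooling the null across the whole population means a session dominated
  by strongly responsive neurons widens the null and costs power — a
  property of the method, visible in the simulated analyses.
* The sign-rank alternative's binomial cutoff is anti-conservative on
  autocorrelated data; use the null-calibrated cutoff when comparing
  methods.
* Inhibition detectability is structurally limited by the baseline event
  rate and the post-window length; no analysis choice can recover
  suppression of events that would not have occurred anyway.
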