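# calshift

Statistical analysis of trial-aligned single-cell calcium imaging during
Pavlovian appetitive and fear conditioning: a **circular-shift permutation
test** that classifies neurons as excited, inhibited, or not significantly
responsive to conditioned (CS) and unconditioned (US) stimuli, and a
downstream classifier that partitions cross-session-registered neurons
into **salience-encoding**, **valence-encoding**, and non-significant
categories, with contingency-table comparisons and peri-event response
metrics. A synthetic-data module generates trial-structured GCaMP-like
sessions with known ground truth, so the whole pipeline is testable
without any recording.

## Who this is for

Systems-neuroscience analysts with miniscope/2P calcium data aligned to
behavioral events (e.g. a 10 s CS with food or shock delivered at 13 s
after CS onset, traces spanning −30 s to +30 s at 10 Hz) who need
event-responsiveness calls that respect the strong autocorrelation of
calcium transients.

## The test

Naive p-values across timepoints assume independence, which transients
violate. Instead, for neuron *i* with trials *j*:

1. isolate a window around the event (CS: [−30, 10) s, US: [−30, 30) s);
2. per trial, compute the Wilcoxon rank-sum statistic W<sub>i,j</sub>
   between pre-stimulus and post-stimulus samples (midranks, no
   approximation) and sum across trials: W̃<sub>i</sub> = Σ<sub>j</sub> W<sub>i,j</sub>;
3. build a null of B = 500 statistics W*<sub>b</sub>: draw a random neuron
   from the whole session, circularly shift each of its trials by an
   independent uniform offset s ∈ [1, N] (shape- and
   autocorrelation-preserving), and compute the same summed statistic;
4. p⁺ = (#{W* ≥ W̃} + 1)/(B + 1), p⁻ likewise with ≤, two-sided
   p = 2·min(p⁺, p⁻); at α = 0.05, excited if p⁺ < p⁻, inhibited if
   p⁻ < p⁺.

Registered neurons then get an ordered label pair (appetitive, aversive):
same significant direction → *salience*; both non-significant → *not
significant*; everything else (opposite or one-sided responses) →
*valence*. Category tables are compared with Pearson χ² (no continuity
correction).

## Worked example

```python
import calshift as cs

spec = cs.PopulationSpec(n_registered=303, seed=1)
app, fear, registration, truth = cs.simulate_paired_sessions(spec)

res_food = cs.test_population(app, cs.AnalysisWindows.for_stimulus("food"),
                              B=500, alpha=0.05, seed=11)
res_shock = cs.test_population(fear, cs.AnalysisWindows.for_stimulus("shock"),
                               B=500, alpha=0.05, seed=12)
table = cs.build_encoding_table(res_food, res_shock, registration)
counts = cs.category_counts(table, "us", "category")
print(dict(zip(counts.col_labels, counts.counts[0])), counts.percentages()[0])
```

Running the bundled drivers end to end (`python analysis/01_simulate.py`
… `05_compare_methods.py`) on the default simulated population prints,
step by step:

```
appetitive/food: 88 excited, 82 inhibited of 303 neurons
fear/shock: 79 excited, 14 inhibited of 303 neurons
US encoding: {'salience': '19 (6%)', 'valence': '201 (66%)', 'not_significant': '83 (27%)'}
CS encoding: {'salience': '6 (2%)', 'valence': '80 (26%)', 'not_significant': '217 (72%)'}
CS vs US category proportions: chi2=118.7, df=2, p=1.7e-26
```

i.e. most registered neurons encode valence rather than salience, and CS
encoding is much sparser than US encoding (the χ² compares the two
category distributions over the same 303 neurons). Shock-inhibited
neurons are recovered least often — their detectability is bounded by
the few baseline calcium events a 5 s post-shock window contains — which
is why recovery against ground truth is partial (~70%) at realistic
effect sizes and near-perfect under strong effects (see
`docs/methods.md`). The per-trial sign-rank alternative with a
null-calibrated trial cutoff agrees with the permutation test on 79–94%
of neurons per session.

A `calshift` CLI wraps the same stages (`simulate`, `test`, `classify`,
`metrics`, `run`, `make-fixtures`); sessions persist as HDF5 or long CSV
(documented schema in `calshift.session`).

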