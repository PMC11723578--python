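"""Shared fixtures: handmade tiny sessions and simulated populations.

The "strong" condition used by the end-to-end fixtures makes every true
response essentially noise-free relative to the test's resolution: high
baseline event rate (so inhibition removes many events), low sensor
noise, and a large response gain.  Population-scale fixtures are
session-scoped because simulation and testing dominate suite runtime.
"""

from __future__ import annotations

import numpy as np
import pytest

import calshift as cs


def strong_population_spec(**overrides) -> cs.PopulationSpec:
    """Population with effects far above noise (near-perfect separability)."""
    base = dict(
        n_registered=303,
        seed=7,
        effect_size=8.0,
        cs_response_given_us={"excited": 0.0, "inhibited": 0.0, "none": 0.0},
        response_duration_s={"food": 10.0, "shock": 4.5, "cs": 9.0},
    )
    base.update(overrides)
    return cs.PopulationSpec(**base)


def strong_transient() -> cs.TransientModel:
    return cs.TransientModel(
        baseline_event_rate=1.0, noise_sd=0.05, drift_amplitude=0.05
    )


@pytest.fixture
def tiny_session() -> cs.SessionRecording:
    """3 neurons x 2 trials on the default [-30, 30) s grid.

    Neuron 0 is constant, neuron 1 is a linear ramp, neuron 2 is seeded
    noise — enough structure for window/z-score arithmetic checks.
    """
    n_tp = 600
    rng = np.random.default_rng(42)
    traces = np.empty((3, 2, n_tp))
    traces[0] = 1.0
    traces[1] = np.linspace(0.0, 1.0, n_tp)
    traces[2] = rng.normal(0, 1, (2, n_tp))
    return cs.SessionRecording(
        session_id="tiny",
        paradigm="appetitive",
        traces=traces,
        neuron_ids=["a", "b", "c"],
        events=cs.EventSchedule(head_entry_s=np.array([14.0, np.nan])),
    )


@pytest.fixture(scope="session")
def strong_pair():
    """Simulated registered appetitive/fear pair under the strong condition."""
    spec = strong_population_spec()
    return cs.simulate_paired_sessions(spec, strong_transient())


@pytest.fixture(scope="session")
def strong_pair_results(strong_pair):
    """Circular-shift US responsiveness results for the strong pair."""
    app, fear, registration, truth = strong_pair
    res_food = cs.test_population(
        app, cs.AnalysisWindows.for_stimulus("food"), B=500, seed=21
    )
    res_shock = cs.test_population(
        fear, cs.AnalysisWindows.for_stimulus("shock"), B=500, seed=22
    )
    return res_food, res_shock, registration, truth
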