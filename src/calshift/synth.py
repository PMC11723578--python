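"""Synthetic trial-structured calcium sessions with known ground truth.

The generator emulates the paired-conditioning design the analysis targets:
an appetitive session (20 trials, 10 s CS, food at t = 13 s) and a fear
session (10 trials, 10 s CS, shock at t = 13 s), both sampled at 10 Hz over
[-30, +30) s around CS onset, with the same physical neurons appearing in
both sessions through a registration map.

Baseline activity is a shot-noise process: Poisson calcium events with
exponentially distributed amplitudes, convolved with a peak-normalized
difference-of-exponentials kernel (fast rise, slow decay, GCaMP6m-like),
plus Gaussian sensor noise and a slow sinusoidal drift.  Stimulus
responses modulate the event *rate* inside a response window:

* excited  — extra events at ``effect_size x baseline_event_rate``;
* inhibited — the baseline rate is multiplicatively suppressed (event
  rates cannot go negative, so inhibition is never modeled as negative
  transients).

Each neuron draws its joint (food, shock) response category from a 3 x 3
probability table, and conditionally a direction-matched CS response, so
the downstream permutation test and salience/valence classifier can be
validated against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .session import EventSchedule, RegistrationMap, SessionRecording

RESPONSE_LABELS = ("excited", "inhibited", "none")

#: Joint (food, shock) category probabilities used by default: the observed
#: proportions among 303 cross-registered central-amygdala neurons, rows =
#: food response, columns = shock response, order (excited, inhibited, none).
DEFAULT_JOINT_COUNTS = np.array([
    [36, 16, 60],
    [25, 10, 50],
    [34, 13, 59],
], dtype=float)


@dataclass
class TransientModel:
    """Shape and noise of the simulated calcium signal.

    The kernel is ``exp(-t/tau_decay) - exp(-t/tau_rise)``, peak-normalized;
    event amplitudes are exponential with mean ``event_amplitude_mean``.
    ``mode='dff'`` leaves traces unconstrained (dF/F-like); ``mode='raw'``
    adds ``raw_offset`` and clips at zero (fluorescence-like).
    """

    baseline_event_rate: float = 0.4     # Hz
    kernel_rise_s: float = 0.2
    kernel_decay_s: float = 1.5
    noise_sd: float = 0.15               # fluorescence units
    drift_amplitude: float = 0.1
    drift_period_s: float = 40.0
    event_amplitude_mean: float = 1.0
    mode: str = "dff"
    raw_offset: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.kernel_rise_s < self.kernel_decay_s:
            raise ConfigError("kernel must have 0 < rise < decay")
        for name in ("baseline_event_rate", "noise_sd", "drift_amplitude",
                     "event_amplitude_mean"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.mode not in ("dff", "raw"):
            raise ConfigError(f"mode must be 'dff' or 'raw', got {self.mode!r}")

    def kernel(self, rate: float) -> np.ndarray:
        """Peak-normalized transient kernel sampled at ``rate`` Hz."""
        t = np.arange(0.0, 8.0 * self.kernel_decay_s, 1.0 / rate)
        k = np.exp(-t / self.kernel_decay_s) - np.exp(-t / self.kernel_rise_s)
        return k / k.max()

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "baseline_event_rate", "kernel_rise_s", "kernel_decay_s",
            "noise_sd", "drift_amplitude", "drift_period_s",
            "event_amplitude_mean", "mode", "raw_offset")}

    @classmethod
    def from_dict(cls, d: Mapping) -> "TransientModel":
        return cls(**dict(d))


@dataclass
class PopulationSpec:
    """Ground-truth population structure for paired-session simulation.

    ``joint_category_probabilities`` is the 3 x 3 table over (food, shock)
    responses in the order (excited, inhibited, none); it must sum to 1.
    ``cs_response_given_us`` gives, for a neuron with a significant US
    response, the probability that it also responds to the matching CS in
    the same direction; the ``'none'`` entry is the probability that a
    US-non-responsive neuron responds to the CS anyway (random direction).
    ``effect_size`` is the dimensionless response gain: excited windows add
    events at ``effect_size x baseline_event_rate``.
    """

    n_registered: int = 303
    joint_category_probabilities: np.ndarray = field(
        default_factory=lambda: DEFAULT_JOINT_COUNTS / DEFAULT_JOINT_COUNTS.sum()
    )
    cs_response_given_us: Mapping[str, float] = field(
        default_factory=lambda: {"excited": 0.2, "inhibited": 0.2, "none": 0.05}
    )
    effect_size: float = 4.0
    inhibition_strength: float = 1.0     # fraction of baseline rate removed
    response_latency_s: Mapping[str, float] = field(
        default_factory=lambda: {"food": 0.0, "shock": 0.0, "cs": 0.0}
    )
    response_duration_s: Mapping[str, float] = field(
        default_factory=lambda: {"food": 8.0, "shock": 2.0, "cs": 9.0}
    )
    latency_jitter_s: float = 0.3
    head_entry_lognorm_mu: float = 0.0      # ln-seconds; median latency 1 s
    head_entry_lognorm_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.joint_category_probabilities, dtype=float)
        if p.shape != (3, 3):
            raise ConfigError("joint_category_probabilities must be 3x3 "
                              "(food x shock, order excited/inhibited/none)")
        if (p < 0).any() or (p > 1).any():
            raise ConfigError("category probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"joint category probabilities sum to {p.sum():.12f}, not 1"
            )
        self.joint_category_probabilities = p
        for key, val in self.cs_response_given_us.items():
            if key not in RESPONSE_LABELS:
                raise ConfigError(f"unknown cs_response_given_us key {key!r}")
            if not 0 <= val <= 1:
                raise ConfigError("cs_response_given_us values must lie in [0, 1]")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be non-negative")
        if not 0 <= self.inhibition_strength <= 1:
            raise ConfigError("inhibition_strength must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_registered": self.n_registered,
            "joint_category_probabilities":
                np.asarray(self.joint_category_probabilities).tolist(),
            "cs_response_given_us": dict(self.cs_response_given_us),
            "effect_size": self.effect_size,
            "inhibition_strength": self.inhibition_strength,
            "response_latency_s": dict(self.response_latency_s),
            "response_duration_s": dict(self.response_duration_s),
            "latency_jitter_s": self.latency_jitter_s,
            "head_entry_lognorm_mu": self.head_entry_lognorm_mu,
            "head_entry_lognorm_sigma": self.head_entry_lognorm_sigma,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PopulationSpec":
        d = dict(d)
        if "joint_category_probabilities" in d:
            d["joint_category_probabilities"] = np.asarray(
                d["joint_category_probabilities"], dtype=float
            )
        return cls(**d)


@dataclass
class GroundTruth:
    """True per-neuron response labels and derived encoding categories."""

    table: pd.DataFrame  # neuron_id, label_food, label_shock, label_cs_food,
    #                      label_cs_shock, us_category, cs_category

    def __len__(self) -> int:
        return len(self.table)


# ----------------------------------------------------------------------
# Trace synthesis
# ----------------------------------------------------------------------

def _synth_trial(
    rng: np.random.Generator,
    n_timepoints: int,
    rate: float,
    origin_s: float,
    transient: TransientModel,
    modulations: list[tuple[str, float, float]],
    effect_size: float,
    inhibition_strength: float,
) -> np.ndarray:
    """One trial trace.  ``modulations`` = (kind, start_s, duration_s),
    times relative to CS onset; kind in {'excited', 'inhibited'}."""
    dt = 1.0 / rate
    kernel = transient.kernel(rate)
    burn_in = len(kernel)  # so decay tails from pre-trace events are present
    n_total = n_timepoints + burn_in
    # event-rate profile on the extended grid
    rate_vec = np.full(n_total, transient.baseline_event_rate)
    t_grid = (np.arange(n_total) - burn_in) * dt - origin_s  # rel. CS onset
    for kind, start, dur in modulations:
        sel = (t_grid >= start) & (t_grid < start + dur)
        if kind == "excited":
            rate_vec[sel] += effect_size * transient.baseline_event_rate
        elif kind == "inhibited":
            rate_vec[sel] *= (1.0 - inhibition_strength)
        else:
            raise ConfigError(f"unknown modulation kind {kind!r}")
    counts = rng.poisson(rate_vec * dt)
    # total amplitude in a bin with c events ~ Gamma(c, mean amplitude)
    impulses = rng.gamma(np.maximum(counts, 1e-12), transient.event_amplitude_mean)
    impulses[counts == 0] = 0.0
    signal = np.convolve(impulses, kernel)[burn_in:n_total]
    phase = rng.uniform(0, 2 * np.pi)
    tt = np.arange(n_timepoints) * dt
    drift = transient.drift_amplitude * np.sin(
        2 * np.pi * tt / transient.drift_period_s + phase
    )
    noise = rng.normal(0.0, transient.noise_sd, n_timepoints)
    trace = signal + drift + noise
    if transient.mode == "raw":
        trace = np.maximum(trace + transient.raw_offset, 0.0)
    return trace


def _neuron_rng(seed: int, neuron_index: int) -> np.random.Generator:
    # one substream per neuron: adding neurons never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence([int(seed), neuron_index]))


def _draw_labels(
    rng: np.random.Generator, spec: PopulationSpec
) -> tuple[str, str, str, str]:
    """(food, shock, cs_food, cs_shock) labels for one neuron."""
    p = spec.joint_category_probabilities.ravel()
    cell = rng.choice(9, p=p)
    food = RESPONSE_LABELS[cell // 3]
    shock = RESPONSE_LABELS[cell % 3]
    def cs_label(us_label: str) -> str:
        if us_label != "none":
            if rng.random() < spec.cs_response_given_us.get(us_label, 0.0):
                return us_label
            return "none"
        if rng.random() < spec.cs_response_given_us.get("none", 0.0):
            return "excited" if rng.random() < 0.5 else "inhibited"
        return "none"
    return food, shock, cs_label(food), cs_label(shock)


def _modulations(
    rng: np.random.Generator,
    spec: PopulationSpec,
    us_label: str,
    cs_label: str,
    stimulus: str,
    us_onset_s: float,
) -> list[tuple[str, float, float]]:
    mods = []
    if cs_label != "none":
        lat = spec.response_latency_s["cs"] + rng.uniform(0, spec.latency_jitter_s)
        mods.append(("excited" if cs_label == "excited" else "inhibited",
                     0.0 + lat, spec.response_duration_s["cs"]))
    if us_label != "none":
        lat = (spec.response_latency_s[stimulus]
               + rng.uniform(0, spec.latency_jitter_s))
        mods.append(("excited" if us_label == "excited" else "inhibited",
                     us_onset_s + lat, spec.response_duration_s[stimulus]))
    return mods


def simulate_paired_sessions(
    spec: PopulationSpec,
    transient: TransientModel | None = None,
    assigned_categories: list[tuple[str, str, str, str]] | None = None,
) -> tuple[SessionRecording, SessionRecording, RegistrationMap, GroundTruth]:
    """Simulate registered appetitive (20-trial) and fear (10-trial) sessions.

    ``assigned_categories`` overrides the random per-neuron label draw with
    explicit (food, shock, cs_food, cs_shock) tuples — used e.g. to build
    stratified fixtures guaranteeing every subtype is present.

    Returns the two sessions, the registration map linking them (same
    physical neuron, same ID) and the ground-truth label table.
    """
    if transient is None:
        transient = TransientModel()
    from .encoding import classify_encoding  # avoid import cycle at module load

    rate, origin, span = 10.0, 30.0, 60.0
    n_tp = int(round(span * rate))
    n_app_trials, n_fear_trials = 20, 10
    us_onset = 13.0
    n = spec.n_registered
    if assigned_categories is not None and len(assigned_categories) != n:
        raise ConfigError("assigned_categories length must equal n_registered")

    ids = [f"cell{i:04d}" for i in range(n)]
    app = np.empty((n, n_app_trials, n_tp))
    fear = np.empty((n, n_fear_trials, n_tp))
    rows = []
    for i in range(n):
        rng = _neuron_rng(spec.seed, i)
        if assigned_categories is None:
            food, shock, cs_food, cs_shock = _draw_labels(rng, spec)
        else:
            food, shock, cs_food, cs_shock = assigned_categories[i]
        for j in range(n_app_trials):
            mods = _modulations(rng, spec, food, cs_food, "food", us_onset)
            app[i, j] = _synth_trial(rng, n_tp, rate, origin, transient, mods,
                                     spec.effect_size, spec.inhibition_strength)
        for j in range(n_fear_trials):
            mods = _modulations(rng, spec, shock, cs_shock, "shock", us_onset)
            fear[i, j] = _synth_trial(rng, n_tp, rate, origin, transient, mods,
                                      spec.effect_size, spec.inhibition_strength)
        us_cat, _ = classify_encoding(_to_result_label(food), _to_result_label(shock))
        cs_cat, _ = classify_encoding(_to_result_label(cs_food),
                                      _to_result_label(cs_shock))
        rows.append((ids[i], food, shock, cs_food, cs_shock, us_cat, cs_cat))

    ev_rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 999983]))
    latency = ev_rng.lognormal(
        spec.head_entry_lognorm_mu, spec.head_entry_lognorm_sigma, n_app_trials
    )
    head_entry = np.minimum(us_onset + latency, span - origin - 1.0 / rate)

    app_session = SessionRecording(
        session_id=f"sim-appetitive-seed{spec.seed}",
        paradigm="appetitive",
        traces=app,
        neuron_ids=list(ids),
        events=EventSchedule(head_entry_s=head_entry),
        sampling_rate=rate,
        trial_time_origin=origin,
    )
    fear_session = SessionRecording(
        session_id=f"sim-fear-seed{spec.seed}",
        paradigm="fear",
        traces=fear,
        neuron_ids=list(ids),
        events=EventSchedule(),
        sampling_rate=rate,
        trial_time_origin=origin,
    )
    registration = RegistrationMap([(i, i) for i in ids])
    truth = GroundTruth(pd.DataFrame(rows, columns=[
        "neuron_id", "label_food", "label_shock", "label_cs_food",
        "label_cs_shock", "us_category", "cs_category",
    ]))
    return app_session, fear_session, registration, truth


def _to_result_label(truth_label: str) -> str:
    """Ground-truth 'none' corresponds to the test label 'not_significant'."""
    return "not_significant" if truth_label == "none" else truth_label


def simulate_null_session(
    n_neurons: int,
    n_trials: int,
    transient: TransientModel | None = None,
    seed: int = 0,
    paradigm: str = "baseline",
) -> SessionRecording:
    """A session in which no neuron is modulated by any event.

    Used for type-I-error calibration: every rejection by a downstream
    test is a false positive by construction.
    """
    if transient is None:
        transient = TransientModel()
    rate, origin, span = 10.0, 30.0, 60.0
    n_tp = int(round(span * rate))
    traces = np.empty((n_neurons, n_trials, n_tp))
    for i in range(n_neurons):
        rng = _neuron_rng(seed, i)
        for j in range(n_trials):
            traces[i, j] = _synth_trial(rng, n_tp, rate, origin, transient, [],
                                        0.0, 0.0)
    return SessionRecording(
        session_id=f"sim-null-seed{seed}",
        paradigm=paradigm,
        traces=traces,
        neuron_ids=[f"cell{i:04d}" for i in range(n_neurons)],
        events=EventSchedule(),
        sampling_rate=rate,
        trial_time_origin=origin,
    )
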