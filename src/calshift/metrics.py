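"""Peri-event summary metrics on z-scored activity.

AUC is the trapezoidal integral (in z * seconds) of the trial-averaged
z-scored trace over a stated post-event window; time-to-peak and peak z
locate and measure the maximum of the same averaged trace.  A half-open
window [a, b) at rate r contributes the samples a, a + 1/r, ..., b - 1/r,
so the integral spans b - a - 1/r seconds of trapezoids — the convention
is fixed here and used consistently (AUC over adjacent windows is
additive when they share an endpoint sample).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import BoundsError, DataError, UndefinedMetricError
from .session import (
    SessionRecording,
    ZScoredTensor,
    seconds_to_index,
    window_sample_count,
)

logger = logging.getLogger(__name__)


def _averaged_window(
    z: ZScoredTensor,
    neuron_id: str,
    window_s: tuple[float, float],
    trial_subset: np.ndarray | list[int] | None,
) -> tuple[np.ndarray, float]:
    """Trial-averaged z trace inside the window and its start time (s,
    relative to the alignment event)."""
    i = z.neuron_index(neuron_id)
    trials = (np.arange(z.n_trials) if trial_subset is None
              else np.asarray(trial_subset, dtype=int))
    if trials.size == 0:
        raise DataError("trial subset is empty")
    if trials.min() < 0 or trials.max() >= z.n_trials:
        raise DataError(f"trial subset out of range for {z.n_trials} trials")
    if z.zero_variance[i, trials].all():
        raise UndefinedMetricError(
            f"neuron {neuron_id!r}: all selected trials have zero-variance "
            "baselines; metric undefined"
        )
    count = window_sample_count(window_s, z.sampling_rate)
    n_tp = z.values.shape[2]
    rows = []
    for j in trials:
        start = seconds_to_index(
            z.alignment_times_s[j] + window_s[0], z.sampling_rate
        )
        if start < 0 or start + count > n_tp:
            raise BoundsError(
                f"window {window_s} outside the z tensor span on trial {j}"
            )
        rows.append(z.values[i, j, start:start + count])
    return np.mean(rows, axis=0), window_s[0]


def auc(
    z: ZScoredTensor,
    neuron_id: str,
    window_s: tuple[float, float],
    trial_subset=None,
) -> float:
    """Trapezoidal area under the trial-averaged z trace, in z * seconds."""
    trace, _ = _averaged_window(z, neuron_id, window_s, trial_subset)
    return float(np.trapezoid(trace, dx=1.0 / z.sampling_rate))


def time_to_peak(
    z: ZScoredTensor,
    neuron_id: str,
    window_s: tuple[float, float],
    trial_subset=None,
) -> float:
    """Time (s, relative to the alignment event) of the averaged-trace
    maximum inside the window; ties resolve to the earliest sample."""
    trace, start_s = _averaged_window(z, neuron_id, window_s, trial_subset)
    return float(start_s + np.argmax(trace) / z.sampling_rate)


def peak_z(
    z: ZScoredTensor,
    neuron_id: str,
    window_s: tuple[float, float],
    trial_subset=None,
) -> float:
    """Maximum of the trial-averaged z trace inside the window."""
    trace, _ = _averaged_window(z, neuron_id, window_s, trial_subset)
    return float(trace.max())


def split_trials(
    session: SessionRecording,
    scheme: str = "half",
    k: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic early/late trial split (0-based trial indices).

    ``half``: first ceil(n/2) trials vs last floor(n/2).
    ``first_k_last_k``: first k vs last k, requiring k <= n/2.
    """
    n = session.n_trials
    if scheme == "half":
        cut = (n + 1) // 2
        early, late = np.arange(cut), np.arange(cut, n)
        if late.size == 0:
            logger.warning("late trial subset is empty (n_trials=%d)", n)
        return early, late
    if scheme == "first_k_last_k":
        if k is None or not 1 <= k <= n // 2:
            raise DataError(
                f"first_k_last_k requires 1 <= k <= n_trials/2, got k={k}"
            )
        return np.arange(k), np.arange(n - k, n)
    raise DataError(f"unknown split scheme {scheme!r}")


def metric_report(
    z: ZScoredTensor,
    window_s: tuple[float, float],
    stimulus: str,
    trial_subsets: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """AUC / time-to-peak / peak z for every neuron, per trial subset.

    Neurons whose selected trials are all zero-variance-flagged get NaN
    metrics (with a logged count) rather than aborting the report.
    """
    subsets = trial_subsets or {"all": None}
    rows = []
    n_undefined = 0
    for name, subset in subsets.items():
        n_used = z.n_trials if subset is None else len(subset)
        for nid in z.neuron_ids:
            try:
                rows.append((nid, stimulus, name,
                             auc(z, nid, window_s, subset),
                             time_to_peak(z, nid, window_s, subset),
                             peak_z(z, nid, window_s, subset),
                             n_used))
            except UndefinedMetricError:
                n_undefined += 1
                rows.append((nid, stimulus, name, np.nan, np.nan, np.nan, n_used))
    if n_undefined:
        logger.warning("%d neuron x subset metrics undefined (zero-variance)",
                       n_undefined)
    return pd.DataFrame(rows, columns=[
        "neuron_id", "stimulus", "trial_subset", "auc_zs",
        "time_to_peak_s", "peak_z", "n_trials_used",
    ])
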