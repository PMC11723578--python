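"""Domain types and I/O for trial-aligned calcium imaging sessions.

A session holds a ``neurons x trials x timepoints`` tensor of fluorescence
traces sampled at 10 Hz, together with the event schedule of the Pavlovian
paradigm: a 10 s conditioned stimulus (CS) starting at t = 0, the
unconditioned stimulus (US; food pellet or foot shock) delivered 3 s after
CS offset (t = 13 s), and, for appetitive sessions, per-trial head-entry
times into the food receptacle.  Each trial trace spans [-30, +30) s around
CS onset by default.

Time convention: within a trial, t = 0 is CS onset; the recorded trace
starts at ``-trial_time_origin`` seconds.  Seconds map to sample indices by
``floor(t * rate)`` and all windows are half-open ``[start, end)``, so a
window of length L at rate r always yields ``round(L * r)`` samples.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import (
    BoundsError,
    DataError,
    MissingEventError,
    SchemaError,
    ShapeError,
)

logger = logging.getLogger(__name__)

Paradigm = Literal["appetitive", "fear", "baseline", "post_test"]
PARADIGMS = ("appetitive", "fear", "baseline", "post_test")

Alignment = Literal["cs_onset", "us_onset", "head_entry"]

#: Tolerance used when validating that event times fall inside the span.
_EVENT_TOL = 1e-9


def seconds_to_index(t: float, rate: float) -> int:
    """Map a time in seconds (relative to trace start) to a sample index.

    Uses ``floor(t * rate)`` with a small guard against representation
    error so that grid-aligned times land exactly on their sample.
    """
    return int(np.floor(t * rate + 1e-9))


def window_sample_count(window_s: tuple[float, float], rate: float) -> int:
    """Number of samples a half-open window [start, end) contributes."""
    start, end = window_s
    return int(round((end - start) * rate))


@dataclass
class EventSchedule:
    """Trial event times in seconds relative to CS onset.

    ``head_entry_s`` is a per-trial array (NaN for trials with no head
    entry); it is only meaningful for appetitive sessions, where it records
    the first head entry after food delivery.
    """

    cs_onset_s: float = 0.0
    cs_offset_s: float = 10.0
    us_onset_s: float = 13.0
    head_entry_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (self.cs_onset_s < self.cs_offset_s < self.us_onset_s):
            raise DataError(
                "event schedule must satisfy cs_onset < cs_offset < us_onset, "
                f"got {self.cs_onset_s}, {self.cs_offset_s}, {self.us_onset_s}"
            )
        if self.head_entry_s is not None:
            self.head_entry_s = np.asarray(self.head_entry_s, dtype=float)


@dataclass
class SessionRecording:
    """One recording session: traces, sampling metadata and events."""

    session_id: str
    paradigm: Paradigm
    traces: np.ndarray  # (n_neurons, n_trials, n_timepoints), float64
    neuron_ids: list[str]
    events: EventSchedule = field(default_factory=EventSchedule)
    sampling_rate: float = 10.0
    trial_time_origin: float = 30.0  # seconds of CS onset after trace start

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=np.float64)
        self.neuron_ids = [str(n) for n in self.neuron_ids]
        self.validate()

    # -- basic geometry -------------------------------------------------
    @property
    def n_neurons(self) -> int:
        return self.traces.shape[0]

    @property
    def n_trials(self) -> int:
        return self.traces.shape[1]

    @property
    def n_timepoints(self) -> int:
        return self.traces.shape[2]

    @property
    def trial_span_s(self) -> float:
        """Duration of one trial trace in seconds."""
        return self.n_timepoints / self.sampling_rate

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds relative to CS onset."""
        return (
            np.arange(self.n_timepoints) / self.sampling_rate
            - self.trial_time_origin
        )

    def validate(self) -> None:
        if self.paradigm not in PARADIGMS:
            raise DataError(f"unknown paradigm {self.paradigm!r}")
        if self.traces.ndim != 3:
            raise ShapeError(
                f"traces must be 3-D (neurons, trials, time), got {self.traces.ndim}-D"
            )
        if len(set(self.neuron_ids)) != len(self.neuron_ids):
            raise DataError("neuron_ids contain duplicates")
        if self.traces.shape[0] != len(self.neuron_ids):
            raise ShapeError(
                f"{self.traces.shape[0]} trace rows but {len(self.neuron_ids)} neuron IDs"
            )
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        span = self.trial_span_s
        lo, hi = -self.trial_time_origin, span - self.trial_time_origin
        ev = self.events
        for name, t in (("cs_onset_s", ev.cs_onset_s),
                        ("cs_offset_s", ev.cs_offset_s),
                        ("us_onset_s", ev.us_onset_s)):
            if self.n_timepoints and not (lo - _EVENT_TOL <= t <= hi + _EVENT_TOL):
                raise DataError(
                    f"event {name}={t} s outside recorded span [{lo}, {hi}) s"
                )
        if ev.head_entry_s is not None:
            if len(ev.head_entry_s) != self.n_trials:
                raise ShapeError(
                    f"head_entry_s has {len(ev.head_entry_s)} entries for "
                    f"{self.n_trials} trials"
                )
            finite = ev.head_entry_s[np.isfinite(ev.head_entry_s)]
            if finite.size and (finite.min() < lo or finite.max() > hi):
                raise DataError("head-entry time outside recorded span")

    def neuron_index(self, neuron_id: str) -> int:
        try:
            return self.neuron_ids.index(neuron_id)
        except ValueError:
            raise DataError(f"neuron {neuron_id!r} not in session {self.session_id!r}")

    def alignment_times(self, alignment: Alignment) -> np.ndarray:
        """Per-trial alignment event time in seconds from trace start."""
        if alignment == "cs_onset":
            t = self.trial_time_origin + self.events.cs_onset_s
            return np.full(self.n_trials, t)
        if alignment == "us_onset":
            t = self.trial_time_origin + self.events.us_onset_s
            return np.full(self.n_trials, t)
        if alignment == "head_entry":
            if self.events.head_entry_s is None:
                raise MissingEventError(
                    f"session {self.session_id!r} has no head-entry events"
                )
            return self.trial_time_origin + self.events.head_entry_s
        raise DataError(f"unknown alignment {alignment!r}")


@dataclass(frozen=True)
class AnalysisWindows:
    """Isolation / pre / post windows (seconds relative to CS onset).

    The isolation window is the stretch of trace the permutation test
    rotates; the pre and post windows, both inside it, feed the rank-sum
    comparison.  Defaults follow the testing windows of the conditioning
    paradigm: CS tests compare [-20, 0) vs [0, 10) inside [-30, 10); US
    tests compare [-5, 13) vs the post-delivery window inside [-30, 30)
    (food: [13, 30), shock: [13, 18)).
    """

    stimulus: Literal["cs", "food", "shock", "head_entry"]
    isolation_window_s: tuple[float, float]
    pre_window_s: tuple[float, float]
    post_window_s: tuple[float, float]

    _DEFAULTS = {
        "cs": ((-30.0, 10.0), (-20.0, 0.0), (0.0, 10.0)),
        "food": ((-30.0, 30.0), (-5.0, 13.0), (13.0, 30.0)),
        "shock": ((-30.0, 30.0), (-5.0, 13.0), (13.0, 18.0)),
    }

    def __post_init__(self) -> None:
        iso, pre, post = (
            self.isolation_window_s,
            self.pre_window_s,
            self.post_window_s,
        )
        for name, (a, b) in (("isolation", iso), ("pre", pre), ("post", post)):
            if not a < b:
                raise DataError(f"{name} window {a, b} is empty or reversed")
        if not (iso[0] <= pre[0] and pre[1] <= iso[1]):
            raise DataError("pre window must lie inside the isolation window")
        if not (iso[0] <= post[0] and post[1] <= iso[1]):
            raise DataError("post window must lie inside the isolation window")
        if not (pre[1] <= post[0] or post[1] <= pre[0]):
            raise DataError("pre and post windows must be disjoint")

    @classmethod
    def for_stimulus(cls, stimulus: str) -> "AnalysisWindows":
        """The default window set for ``cs``, ``food`` or ``shock``."""
        try:
            iso, pre, post = cls._DEFAULTS[stimulus]
        except KeyError:
            raise DataError(
                f"no default windows for stimulus {stimulus!r}; "
                f"choose one of {sorted(cls._DEFAULTS)}"
            )
        return cls(stimulus=stimulus, isolation_window_s=iso,
                   pre_window_s=pre, post_window_s=post)


@dataclass
class RegistrationMap:
    """One-to-one partial matching of neuron IDs across two sessions."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        a_side = [a for a, _ in self.pairs]
        b_side = [b for _, b in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise DataError("registration map is not one-to-one")

    def __len__(self) -> int:
        return len(self.pairs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.pairs, columns=["neuron_id_session_a", "neuron_id_session_b"]
                     ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegistrationMap":
        df = pd.read_csv(path, dtype=str)
        required = {"neuron_id_session_a", "neuron_id_session_b"}
        if not required.issubset(df.columns):
            raise SchemaError(
                f"registration CSV missing columns {sorted(required - set(df.columns))}"
            )
        return cls(list(zip(df["neuron_id_session_a"], df["neuron_id_session_b"])))


@dataclass
class ZScoredTensor:
    """Per-trial z-scored traces on the original sample grid.

    z-scoring is per neuron x trial against that trial's own baseline
    window (anchored to ``alignment_event``).  ``zero_variance`` flags
    neuron x trial pairs whose baseline had no variance; their z rows are
    zero-filled so population averages remain computable.
    """

    values: np.ndarray  # (n_neurons, n_trials, n_timepoints)
    alignment_event: Alignment
    baseline_window_s: tuple[float, float]
    sampling_rate: float
    alignment_times_s: np.ndarray  # per trial, seconds from trace start
    neuron_ids: list[str]
    trial_indices: np.ndarray  # indices into the parent session's trials
    zero_variance: np.ndarray  # (n_neurons, n_trials) bool

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    def neuron_index(self, neuron_id: str) -> int:
        try:
            return self.neuron_ids.index(neuron_id)
        except ValueError:
            raise DataError(f"neuron {neuron_id!r} not in z-scored tensor")


# ----------------------------------------------------------------------
# Window extraction and z-scoring
# ----------------------------------------------------------------------

def _window_slices(
    session: SessionRecording,
    align_times_s: np.ndarray,
    window_s: tuple[float, float],
) -> tuple[np.ndarray, int]:
    """Per-trial start index and common sample count for a window."""
    start, end = window_s
    count = window_sample_count(window_s, session.sampling_rate)
    starts = np.array(
        [seconds_to_index(t + start, session.sampling_rate) for t in align_times_s]
    )
    return starts, count


def extract_window(
    session: SessionRecording,
    alignment: Alignment,
    window_s: tuple[float, float],
    allow_missing: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a peri-event window from every neuron and trial.

    Returns ``(tensor, trial_indices)`` where ``tensor`` has shape
    ``(n_neurons, n_trials_used, n_window_samples)``.  With
    ``alignment='head_entry'`` and ``allow_missing=True``, trials lacking a
    head entry are dropped (their indices are omitted from
    ``trial_indices``); otherwise a missing event raises.
    """
    align = session.alignment_times(alignment)
    missing = ~np.isfinite(align)
    if missing.any():
        bad = np.nonzero(missing)[0]
        if not allow_missing:
            raise MissingEventError(
                f"trials {bad.tolist()} lack a {alignment} event in session "
                f"{session.session_id!r}; pass allow_missing to drop them"
            )
        logger.info(
            "dropping %d/%d trials without %s event in session %s",
            len(bad), session.n_trials, alignment, session.session_id,
        )
    keep = np.nonzero(~missing)[0]
    starts, count = _window_slices(session, align[keep], window_s)
    n_tp = session.n_timepoints
    for k, s0 in zip(keep, starts):
        if s0 < 0 or s0 + count > n_tp:
            raise BoundsError(
                f"window {window_s} (aligned to {alignment}) spans samples "
                f"[{s0}, {s0 + count}) outside trace of {n_tp} samples on trial {k}"
            )
    out = np.empty((session.n_neurons, len(keep), count))
    for j, (k, s0) in enumerate(zip(keep, starts)):
        out[:, j, :] = session.traces[:, k, s0:s0 + count]
    return out, keep


def zscore(
    session: SessionRecording,
    alignment: Alignment = "cs_onset",
    baseline_window_s: tuple[float, float] = (-10.0, 0.0),
    allow_missing: bool = False,
) -> ZScoredTensor:
    """z-score every neuron x trial trace against its own baseline window.

    The baseline window is anchored to the alignment event (default
    [-10, 0) s before CS onset).  Trials whose baseline has zero variance
    are flagged and filled with zeros rather than raising, so population
    summaries remain computable.
    """
    baseline, keep = extract_window(
        session, alignment, baseline_window_s, allow_missing=allow_missing
    )
    mu = baseline.mean(axis=2, keepdims=True)
    sd = baseline.std(axis=2, ddof=0, keepdims=True)
    flagged = (sd[..., 0] == 0)
    if flagged.any():
        logger.warning(
            "%d neuron x trial baselines have zero variance; filling z with zeros",
            int(flagged.sum()),
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (session.traces[:, keep, :] - mu) / sd_safe
    z[flagged, :] = 0.0
    return ZScoredTensor(
        values=z,
        alignment_event=alignment,
        baseline_window_s=baseline_window_s,
        sampling_rate=session.sampling_rate,
        alignment_times_s=session.alignment_times(alignment)[keep],
        neuron_ids=list(session.neuron_ids),
        trial_indices=keep,
        zero_variance=flagged,
    )


# ----------------------------------------------------------------------
# File I/O
# ----------------------------------------------------------------------

_CSV_COLUMNS = ["session_id", "paradigm", "neuron_id", "trial", "time_s", "value"]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_session(
    session: SessionRecording,
    path: str | Path,
    format: Literal["csv_long", "hdf5"] = "hdf5",
) -> None:
    """Write a session to disk in the documented HDF5 or long-CSV schema."""
    path = Path(path)
    if format == "hdf5":
        with h5py.File(path, "w") as f:
            f.create_dataset("traces", data=session.traces, dtype="float64")
            f.create_dataset(
                "neuron_ids",
                data=np.array(session.neuron_ids, dtype=h5py.string_dtype()),
            )
            f.attrs["session_id"] = session.session_id
            f.attrs["paradigm"] = session.paradigm
            f.attrs["sampling_rate"] = session.sampling_rate
            f.attrs["trial_time_origin"] = session.trial_time_origin
            ev = f.create_group("events")
            ev.attrs["cs_onset_s"] = session.events.cs_onset_s
            ev.attrs["cs_offset_s"] = session.events.cs_offset_s
            ev.attrs["us_onset_s"] = session.events.us_onset_s
            if session.events.head_entry_s is not None:
                ev.create_dataset("head_entry_s", data=session.events.head_entry_s)
    elif format == "csv_long":
        n, t, tp = session.traces.shape
        time_s = np.arange(tp) / session.sampling_rate
        frames = []
        for i, nid in enumerate(session.neuron_ids):
            for j in range(t):
                frames.append(pd.DataFrame({
                    "session_id": session.session_id,
                    "paradigm": session.paradigm,
                    "neuron_id": nid,
                    "trial": j + 1,
                    "time_s": time_s,
                    "value": session.traces[i, j],
                }))
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=_CSV_COLUMNS))
        df.to_csv(path, index=False, float_format="%.10g")
        meta = {
            "session_id": session.session_id,
            "paradigm": session.paradigm,
            "sampling_rate": session.sampling_rate,
            "trial_time_origin": session.trial_time_origin,
            "n_neurons": n,
            "n_trials": t,
            "n_timepoints": tp,
            "neuron_ids": session.neuron_ids,
            "events": {
                "cs_onset_s": session.events.cs_onset_s,
                "cs_offset_s": session.events.cs_offset_s,
                "us_onset_s": session.events.us_onset_s,
                "head_entry_s": (
                    None if session.events.head_entry_s is None
                    else [None if not np.isfinite(x) else float(x)
                          for x in session.events.head_entry_s]
                ),
            },
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    else:
        raise SchemaError(f"unknown session format {format!r}")


def read_session(
    path: str | Path,
    format: Literal["csv_long", "hdf5"] = "hdf5",
) -> SessionRecording:
    """Read a session written by :func:`write_session`."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"session file {path} does not exist")
    if format == "hdf5":
        with h5py.File(path, "r") as f:
            for name in ("traces", "neuron_ids"):
                if name not in f:
                    raise SchemaError(f"HDF5 session missing dataset '{name}'")
            for attr in ("sampling_rate", "trial_time_origin", "paradigm"):
                if attr not in f.attrs:
                    raise SchemaError(f"HDF5 session missing attribute '{attr}'")
            if "events" not in f:
                raise SchemaError("HDF5 session missing 'events' group")
            ev = f["events"]
            head = (np.asarray(ev["head_entry_s"])
                    if "head_entry_s" in ev else None)
            return SessionRecording(
                session_id=str(f.attrs.get("session_id", path.stem)),
                paradigm=str(f.attrs["paradigm"]),
                traces=np.asarray(f["traces"], dtype=np.float64),
                neuron_ids=[s.decode() if isinstance(s, bytes) else str(s)
                            for s in f["neuron_ids"][()]],
                events=EventSchedule(
                    cs_onset_s=float(ev.attrs["cs_onset_s"]),
                    cs_offset_s=float(ev.attrs["cs_offset_s"]),
                    us_onset_s=float(ev.attrs["us_onset_s"]),
                    head_entry_s=head,
                ),
                sampling_rate=float(f.attrs["sampling_rate"]),
                trial_time_origin=float(f.attrs["trial_time_origin"]),
            )
    if format == "csv_long":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise SchemaError(
                f"csv_long session requires sidecar {sidecar.name} "
                "(sampling_rate, events, ...)"
            )
        meta = json.loads(sidecar.read_text())
        for key in ("sampling_rate", "trial_time_origin", "events", "neuron_ids"):
            if key not in meta:
                raise SchemaError(f"sidecar JSON missing field '{key}'")
        df = pd.read_csv(path)
        missing = set(_CSV_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"csv_long missing columns {sorted(missing)}")
        neuron_ids = [str(n) for n in meta["neuron_ids"]]
        n_tp = int(meta["n_timepoints"])
        n_trials = int(meta["n_trials"])
        traces = np.zeros((len(neuron_ids), n_trials, n_tp))
        if len(df):
            df["neuron_id"] = df["neuron_id"].astype(str)
            for (nid, trial), g in df.groupby(["neuron_id", "trial"], sort=False):
                if len(g) != n_tp:
                    raise ShapeError(
                        f"neuron {nid} trial {trial} has {len(g)} rows, "
                        f"expected {n_tp} (ragged trials)"
                    )
                i = neuron_ids.index(nid)
                g = g.sort_values("time_s")
                traces[i, int(trial) - 1, :] = g["value"].to_numpy()
        evm = meta["events"]
        head = evm.get("head_entry_s")
        if head is not None:
            head = np.array([np.nan if x is None else float(x) for x in head])
        return SessionRecording(
            session_id=str(meta.get("session_id", path.stem)),
            paradigm=str(meta.get("paradigm", df["paradigm"].iloc[0] if len(df) else "baseline")),
            traces=traces,
            neuron_ids=neuron_ids,
            events=EventSchedule(
                cs_onset_s=float(evm["cs_onset_s"]),
                cs_offset_s=float(evm["cs_offset_s"]),
                us_onset_s=float(evm["us_onset_s"]),
                head_entry_s=head,
            ),
            sampling_rate=float(meta["sampling_rate"]),
            trial_time_origin=float(meta["trial_time_origin"]),
        )
    raise SchemaError(f"unknown session format {format!r}")
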