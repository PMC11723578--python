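"""End-to-end orchestration: simulate or load, test, classify, report.

One :func:`run` call executes the full analysis a conditioning experiment
needs: per-stimulus responsiveness tests on both sessions, the
salience/valence encoding classification over registered neurons,
contingency tables with chi-square tests, peri-event metrics with
early/late trial splits, and a structured run log.  Identical config +
seed reproduces every output exactly.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .config import RunConfig
from .encoding import (
    ContingencyTable,
    build_encoding_table,
    category_counts,
    chi_square_independence,
)
from .errors import DataError
from .metrics import metric_report, split_trials
from .responsiveness import signrank_responsiveness, test_population
from .session import (
    RegistrationMap,
    SessionRecording,
    read_session,
    write_session,
    zscore,
)
from .synth import (
    GroundTruth,
    PopulationSpec,
    TransientModel,
    simulate_paired_sessions,
)

logger = logging.getLogger(__name__)

#: Stimuli tested per paradigm.
SESSION_STIMULI = {"appetitive": ("food", "cs"), "fear": ("shock", "cs")}


def derive_seed(master: int, label: str) -> int:
    """A stable per-stage sub-seed below 2**31."""
    h = 0
    for ch in label:
        h = (h * 131 + ord(ch)) % 1_000_000_007
    return int((master * 1_000_003 + h) % (2 ** 31))


def _sessions_from_config(config: RunConfig):
    if config.mode == "simulate":
        spec = PopulationSpec.from_dict(
            {**config.population.to_dict(), "seed": config.seed}
        )
        app, fear, registration, truth = simulate_paired_sessions(
            spec, config.transient
        )
        return app, fear, registration, truth
    fmt = config.session_format
    app = read_session(config.load_paths["appetitive"], fmt)
    fear = read_session(config.load_paths["fear"], fmt)
    registration = RegistrationMap.from_csv(config.load_paths["registration"])
    return app, fear, registration, None


def _test_session(session: SessionRecording, config: RunConfig,
                  method: str) -> pd.DataFrame:
    frames = []
    for stimulus in SESSION_STIMULI[session.paradigm]:
        windows = config.analysis_windows(stimulus)
        seed = derive_seed(config.seed, f"{session.paradigm}:{stimulus}")
        if method == "circular_shift":
            frames.append(test_population(
                session, windows, B=config.B, alpha=config.alpha, seed=seed
            ))
        else:
            frames.append(signrank_responsiveness(
                session, windows, per_trial_alpha=config.alpha
            ))
    return pd.concat(frames, ignore_index=True)


def _agreement_matrix(res_a: pd.DataFrame, res_b: pd.DataFrame) -> pd.DataFrame:
    merged = res_a.merge(res_b, on=["neuron_id", "stimulus"],
                         suffixes=("_circ", "_sign"))
    return pd.crosstab(merged["label_circ"], merged["label_sign"])


def _calibration_check(results: pd.DataFrame, alpha: float) -> dict:
    """Exact-binomial 99% acceptance band check on the rejection fraction."""
    from scipy.stats import binom
    n = len(results)
    rejected = int((results["label"] != "not_significant").sum())
    lo = int(binom.ppf(0.005, n, alpha))
    hi = int(binom.ppf(0.995, n, alpha))
    return {
        "n_neurons": n,
        "n_rejected": rejected,
        "rejection_fraction": rejected / n if n else float("nan"),
        "band_99pct": [lo / n, hi / n] if n else None,
        "pass": bool(lo <= rejected <= hi) if n else None,
    }


def run(config: RunConfig) -> dict:
    """Execute the configured pipeline; write outputs; return the report."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    app, fear, registration, truth = _sessions_from_config(config)

    report: dict = {
        "seed": config.seed,
        "B": config.B,
        "alpha": config.alpha,
        "method": config.method,
        "windows": {
            s: {
                "isolation_window_s": list(config.analysis_windows(s).isolation_window_s),
                "pre_window_s": list(config.analysis_windows(s).pre_window_s),
                "post_window_s": list(config.analysis_windows(s).post_window_s),
            } for s in ("cs", "food", "shock")
        },
        "versions": {
            "calshift": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
        "sessions": {
            "appetitive": {"id": app.session_id, "n_neurons": app.n_neurons,
                           "n_trials": app.n_trials},
            "fear": {"id": fear.session_id, "n_neurons": fear.n_neurons,
                     "n_trials": fear.n_trials},
        },
    }

    methods = (["circular_shift", "sign_rank"] if config.method == "both"
               else [config.method])
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for method in methods:
        results[method] = {}
        for session in (app, fear):
            res = _test_session(session, config, method)
            results[method][session.paradigm] = res
            path = out / f"responsiveness_{session.paradigm}_{method}.csv"
            res.to_csv(path, index=False)

    primary = methods[0]
    if config.method == "both":
        agreement = {}
        for paradigm in ("appetitive", "fear"):
            m = _agreement_matrix(results["circular_shift"][paradigm],
                                  results["sign_rank"][paradigm])
            agreement[paradigm] = m.to_dict()
            overall = results["circular_shift"][paradigm].merge(
                results["sign_rank"][paradigm], on=["neuron_id", "stimulus"],
                suffixes=("_circ", "_sign"))
            agreement[f"{paradigm}_fraction_agree"] = float(
                (overall["label_circ"] == overall["label_sign"]).mean())
        report["method_agreement"] = agreement

    # encoding classification over registered neurons
    enc = build_encoding_table(results[primary]["appetitive"],
                               results[primary]["fear"], registration)
    enc.to_csv(out / "encoding_table.csv", index=False)
    contingency: dict = {}
    if len(enc):
        for pair in ("us", "cs"):
            cat = category_counts(enc, pair, "category")
            sub = category_counts(enc, pair, "subtype")
            contingency[pair] = {
                "categories": cat.to_dict(),
                "category_percent": cat.percentages()[0].tolist(),
                "subtypes": sub.to_dict(),
            }
        us_ct = category_counts(enc, "us", "category")
        cs_ct = category_counts(enc, "cs", "category")
        counts = np.vstack([cs_ct.counts[0], us_ct.counts[0]])
        nonzero = counts.sum(axis=0) > 0  # empty categories carry no information
        cs_vs_us = ContingencyTable(
            counts[:, nonzero], ["cs", "us"],
            [lab for lab, keep in zip(us_ct.col_labels, nonzero) if keep],
        )
        entry = {"table": cs_vs_us.to_dict()}
        if cs_vs_us.counts.shape[1] >= 2 and (cs_vs_us.counts.sum(axis=1) > 0).all():
            stat, dof, p = chi_square_independence(cs_vs_us)
            entry.update({"statistic": stat, "df": dof, "p": p})
        else:
            entry["statistic"] = None
            logger.warning("cs-vs-us table too degenerate for a chi-square test")
        contingency["cs_vs_us"] = entry
    report["contingency"] = contingency
    (out / "contingency.json").write_text(json.dumps(contingency, indent=1))

    # ground-truth bookkeeping (simulate mode only)
    if truth is not None:
        truth.table.to_csv(out / "ground_truth.csv", index=False)
        if (truth.table[["label_food", "label_shock",
                         "label_cs_food", "label_cs_shock"]] == "none").all().all():
            checks = {}
            for method in methods:
                for paradigm in ("appetitive", "fear"):
                    checks[f"{method}:{paradigm}"] = _calibration_check(
                        results[method][paradigm], config.alpha)
            report["calibration_check"] = checks

    # peri-event metrics with early/late splits
    metric_frames = []
    for session, stim in ((app, "food"), (fear, "shock")):
        z = zscore(session, "cs_onset", (-10.0, 0.0))
        early, late = split_trials(session, "half")
        subsets = {"all": None, "early": early, "late": late}
        us_window = (13.0, 23.0)  # 0-10 s after US delivery
        metric_frames.append(metric_report(z, us_window, stim, subsets))
    metrics = pd.concat(metric_frames, ignore_index=True)
    metrics.to_csv(out / "metrics.csv", index=False)

    (out / "run_log.json").write_text(json.dumps(report, indent=1))
    logger.info("run complete; outputs in %s", out)
    return report


def make_fixtures(output_dir: str | Path, seed: int = 0) -> dict:
    """Write a small deterministic paired-session fixture (30 registered
    neurons) whose first nine neurons cover all nine (food, shock)
    response subtypes by stratified assignment."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = ("excited", "inhibited", "none")
    assigned = [(f, s, "none", "none") for f in labels for s in labels]
    # a few CS-responsive cells and a direction-matched tail
    assigned += [
        ("excited", "excited", "excited", "excited"),
        ("inhibited", "inhibited", "inhibited", "inhibited"),
        ("excited", "none", "excited", "none"),
    ]
    rng = np.random.default_rng(seed)
    spec0 = PopulationSpec()
    flat = spec0.joint_category_probabilities.ravel()
    while len(assigned) < 30:
        cell = int(rng.choice(9, p=flat))
        assigned.append((labels[cell // 3], labels[cell % 3], "none", "none"))
    spec = PopulationSpec(n_registered=30, seed=seed)
    app, fear, registration, truth = simulate_paired_sessions(
        spec, TransientModel(), assigned_categories=assigned
    )
    write_session(app, out / "appetitive.h5", "hdf5")
    write_session(fear, out / "fear.h5", "hdf5")
    registration.to_csv(out / "registration.csv")
    truth.table.to_csv(out / "ground_truth.csv", index=False)
    return {"n_registered": 30, "paths": sorted(p.name for p in out.iterdir())}
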