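#!/usr/bin/env python
"""Peri-event response metrics by encoding category.

z-scores each session against a [-10, 0) s pre-CS baseline, computes AUC
(0-10 s after US delivery, z*seconds), time-to-peak and maximum z per
neuron with early/late trial splits, and summarizes (mean +/- s.e.m.) by
US response label.  Full per-neuron tables go to scratch/; group
summaries to results/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import calshift as cs

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    scratch = ROOT / "scratch"
    frames = []
    for paradigm, stim in (("appetitive", "food"), ("fear", "shock")):
        session = cs.read_session(scratch / "sessions" / f"{paradigm}.h5", "hdf5")
        z = cs.zscore(session, "cs_onset", (-10.0, 0.0))
        early, late = cs.split_trials(session, "half")
        rep = cs.metric_report(z, (13.0, 23.0), stim,
                               {"all": None, "early": early, "late": late})
        frames.append(rep)
    metrics = pd.concat(frames, ignore_index=True)
    metrics.to_csv(scratch / "metrics_per_neuron.csv", index=False,
                   float_format="%.5g")

    labels = pd.concat([
        pd.read_csv(results / "responsiveness_appetitive.csv"),
        pd.read_csv(results / "responsiveness_fear.csv"),
    ])
    labels = labels[labels["stimulus"].isin(["food", "shock"])]
    merged = metrics.merge(labels[["neuron_id", "stimulus", "label"]],
                           on=["neuron_id", "stimulus"])
    summary = (
        merged.groupby(["stimulus", "label", "trial_subset"])
        .agg(n=("auc_zs", "size"),
             auc_mean=("auc_zs", "mean"),
             auc_sem=("auc_zs", "sem"),
             ttp_mean=("time_to_peak_s", "mean"),
             peak_z_mean=("peak_z", "mean"))
        .reset_index()
    )
    summary.to_csv(results / "metrics_summary.csv", index=False,
                   float_format="%.4g")
    show = summary[summary["trial_subset"] == "all"]
    for _, r in show.iterrows():
        print(f"{r['stimulus']:5s} {r['label']:16s} n={int(r['n']):3d} "
              f"AUC={r['auc_mean']:7.2f}+/-{r['auc_sem']:.2f} z*s  "
              f"t_peak={r['ttp_mean']:.1f} s  max_z={r['peak_z_mean']:.1f}")
    print(f"-> {results / 'metrics_summary.csv'}")


if __name__ == "__main__":
    sys.exit(main())
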