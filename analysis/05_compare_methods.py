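#!/usr/bin/env python
"""Cross-method check: circular-shift test vs per-trial sign-rank.

Runs the conventional per-trial Wilcoxon sign-rank alternative (with a
null-calibrated trial-count cutoff, since autocorrelated traces inflate
per-trial significance) on the simulated sessions and measures per-label
agreement with the permutation test's US classifications.
"""

import json
import sys
from pathlib import Path

import pandas as pd

import calshift as cs
from calshift.responsiveness import null_calibrated_cutoff

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    report = {}
    for paradigm, stim in (("appetitive", "food"), ("fear", "shock")):
        session = cs.read_session(
            ROOT / "scratch" / "sessions" / f"{paradigm}.h5", "hdf5")
        windows = cs.AnalysisWindows.for_stimulus(stim)
        null = cs.simulate_null_session(150, session.n_trials,
                                        seed=SEED + 9000 + session.n_trials)
        cutoff = null_calibrated_cutoff(null, windows)
        sign = cs.signrank_responsiveness(session, windows,
                                          trial_count_cutoff=cutoff)
        circ = pd.read_csv(results / f"responsiveness_{paradigm}.csv")
        circ = circ[circ["stimulus"] == stim]
        m = circ.merge(sign, on=["neuron_id", "stimulus"],
                       suffixes=("_circ", "_sign"))
        agree = float((m["label_circ"] == m["label_sign"]).mean())
        crosstab = pd.crosstab(m["label_circ"], m["label_sign"])
        report[paradigm] = {
            "stimulus": stim,
            "trial_count_cutoff": int(cutoff),
            "fraction_agree": agree,
            "crosstab": crosstab.to_dict(),
        }
        print(f"{paradigm}/{stim}: cutoff={cutoff} trials, "
              f"agreement {agree:.1%}")
        print(crosstab, "\n")
    (results / "method_agreement.json").write_text(json.dumps(report, indent=1))
    print(f"-> {results / 'method_agreement.json'}")


if __name__ == "__main__":
    sys.exit(main())
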