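#!/usr/bin/env python
"""Run the circular-shift permutation test on the simulated sessions.

For each session x stimulus (appetitive: food, CS; fear: shock, CS) this
builds a B = 500 population-pooled null repository and classifies every
neuron as excited / inhibited / not significant at alpha = 0.05, writing
one CSV per session to results/.
"""

import sys
from pathlib import Path

import calshift as cs
from calshift.pipeline import derive_seed

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
STIMULI = {"appetitive": ("food", "cs"), "fear": ("shock", "cs")}


def main() -> None:
    scratch = ROOT / "scratch" / "sessions"
    results = ROOT / "results"
    import pandas as pd

    for paradigm in ("appetitive", "fear"):
        session = cs.read_session(scratch / f"{paradigm}.h5", "hdf5")
        frames = []
        for stimulus in STIMULI[paradigm]:
            windows = cs.AnalysisWindows.for_stimulus(stimulus)
            res = cs.test_population(
                session, windows, B=500, alpha=0.05,
                seed=derive_seed(SEED, f"{paradigm}:{stimulus}"),
            )
            frames.append(res)
            n_exc = int((res["label"] == "excited").sum())
            n_inh = int((res["label"] == "inhibited").sum())
            print(f"{paradigm}/{stimulus}: {n_exc} excited, {n_inh} inhibited "
                  f"of {len(res)} neurons")
        out = results / f"responsiveness_{paradigm}.csv"
        pd.concat(frames, ignore_index=True).to_csv(
            out, index=False, float_format="%.6g")
        print(f"-> {out}")


if __name__ == "__main__":
    sys.exit(main())
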