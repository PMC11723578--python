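#!/usr/bin/env python
"""Simulate the paired-conditioning dataset the downstream analyses use.

Generates one appetitive session (303 registered neurons, 20 trials) and
one fear session (10 trials) under the default population structure —
joint (food, shock) response categories drawn with the proportions
observed among cross-registered central-amygdala neurons — and writes the
sessions (HDF5) to scratch/sessions/ plus the registration map and
ground-truth labels to results/.
"""

import sys
from pathlib import Path

import calshift as cs

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    scratch = ROOT / "scratch" / "sessions"
    results = ROOT / "results"
    scratch.mkdir(parents=True, exist_ok=True)
    results.mkdir(parents=True, exist_ok=True)

    spec = cs.PopulationSpec(n_registered=303, seed=SEED)
    app, fear, registration, truth = cs.simulate_paired_sessions(spec)

    cs.write_session(app, scratch / "appetitive.h5", "hdf5")
    cs.write_session(fear, scratch / "fear.h5", "hdf5")
    registration.to_csv(scratch / "registration.csv")
    truth.table.to_csv(results / "ground_truth.csv", index=False)

    counts = truth.table["us_category"].value_counts()
    print(f"simulated {app.n_neurons} registered neurons "
          f"({app.n_trials} appetitive / {fear.n_trials} fear trials)")
    print("true US encoding categories:",
          {k: int(v) for k, v in counts.items()})
    print(f"sessions -> {scratch}")


if __name__ == "__main__":
    sys.exit(main())
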