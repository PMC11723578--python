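#!/usr/bin/env python
"""Partition registered neurons into salience / valence / NS categories.

Joins the per-session responsiveness labels across the registration map,
derives the encoding category for the US pair (food, shock) and the CS
pair, tabulates counts and percentages, tests CS-vs-US category
proportions with a Pearson chi-square, and scores recovery against the
simulation's ground truth.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

import calshift as cs
from calshift.encoding import ContingencyTable

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    res_app = pd.read_csv(results / "responsiveness_appetitive.csv")
    res_fear = pd.read_csv(results / "responsiveness_fear.csv")
    registration = cs.RegistrationMap.from_csv(
        ROOT / "scratch" / "sessions" / "registration.csv")
    truth = pd.read_csv(results / "ground_truth.csv")

    table = cs.build_encoding_table(res_app, res_fear, registration)
    table.to_csv(results / "encoding_table.csv", index=False)

    report = {}
    for pair in ("us", "cs"):
        ct = cs.category_counts(table, pair, "category")
        pct = ct.percentages()[0]
        report[pair] = {
            "counts": dict(zip(ct.col_labels, ct.counts[0].astype(int).tolist())),
            "percent": dict(zip(ct.col_labels, pct.tolist())),
            "subtypes": cs.category_counts(table, pair, "subtype").to_dict(),
        }
        print(f"{pair.upper()} encoding:",
              {k: f"{v} ({p}%)" for (k, v), p in
               zip(report[pair]["counts"].items(), pct)})

    cs_vs_us = ContingencyTable(
        np.vstack([
            cs.category_counts(table, "cs", "category").counts[0],
            cs.category_counts(table, "us", "category").counts[0],
        ]),
        ["cs", "us"], list(cs.encoding.CATEGORIES),
    )
    stat, dof, p = cs.chi_square_independence(cs_vs_us)
    report["cs_vs_us_chi_square"] = {"statistic": stat, "df": dof, "p": p}
    print(f"CS vs US category proportions: chi2={stat:.1f}, df={dof}, p={p:.2g}")

    # recovery against ground truth (simulation only)
    merged = table.merge(truth, left_on="neuron_id_a", right_on="neuron_id")
    agree = (merged["us_category_x"] == merged["us_category_y"]).mean()
    report["us_category_recovery_fraction"] = float(agree)
    print(f"US category agreement with ground truth: {agree:.1%}")

    (results / "contingency.json").write_text(json.dumps(report, indent=1))
    print(f"-> {results / 'encoding_table.csv'}, {results / 'contingency.json'}")


if __name__ == "__main__":
    sys.exit(main())
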