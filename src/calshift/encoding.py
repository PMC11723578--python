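"""Salience / valence encoding classification of cross-registered neurons.

A neuron recorded in both the appetitive and the fear session carries a
pair of response labels (one per stimulus).  The pair maps onto one of
three encoding categories:

* **salience** — significant in the *same* direction to both stimuli
  (both excited or both inhibited), i.e. tracking stimulus strength;
* **valence** — responses differ: opposite directions, or significant to
  exactly one stimulus;
* **not_significant** — responsive to neither.

The 9 ordered (appetitive, aversive) label pairs are kept as subtypes so
the full response-type breakdown and its contingency tables can be
reproduced and compared across stimulus pairs or conditioning-order groups
with Pearson chi-square tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, JoinError
from .session import RegistrationMap

LABELS = ("excited", "inhibited", "not_significant")
CATEGORIES = ("salience", "valence", "not_significant")

#: Ordered subtype cells, role A = appetitive stimulus, role B = aversive.
SUBTYPES = tuple(f"{a}/{b}" for a in LABELS for b in LABELS)

ENCODING_COLUMNS = [
    "neuron_id_a", "neuron_id_b",
    "label_food", "label_shock", "us_category", "us_subtype",
    "label_cs_food", "label_cs_shock", "cs_category", "cs_subtype",
]


def classify_encoding(label_a: str, label_b: str) -> tuple[str, str]:
    """Map an ordered (appetitive, aversive) label pair to (category, subtype).

    Same significant direction -> salience; both not significant ->
    not_significant; every other pair -> valence.
    """
    for lab in (label_a, label_b):
        if lab not in LABELS:
            raise DataError(f"invalid response label {lab!r}; expected one of {LABELS}")
    subtype = f"{label_a}/{label_b}"
    if label_a == label_b == "not_significant":
        return "not_significant", subtype
    if label_a == label_b:
        return "salience", subtype
    return "valence", subtype


@dataclass
class ContingencyTable:
    """Labelled non-negative integer count matrix."""

    counts: np.ndarray
    row_labels: list[str]
    col_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DataError("contingency table must be 2-D")
        if (self.counts < 0).any():
            raise DataError("contingency counts must be non-negative")
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise DataError("label lengths do not match the count matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def percentages(self) -> np.ndarray:
        """Whole-number percentages, round half away from zero."""
        frac = 100.0 * self.counts / self.total
        return np.floor(frac + 0.5).astype(int)

    def to_dict(self) -> dict:
        return {
            "rows": self.row_labels,
            "cols": self.col_labels,
            "counts": self.counts.astype(int).tolist(),
        }


def _joined_labels(results: pd.DataFrame, ids: list[str], side: str,
                   stimulus: str | None = None) -> pd.Series:
    df = results
    if stimulus is not None and "stimulus" in df.columns:
        df = df[df["stimulus"] == stimulus]
    lookup = df.set_index("neuron_id")["label"]
    if lookup.index.has_duplicates:
        raise JoinError(
            f"results table for side {side} has duplicate neuron IDs; "
            "pass a single-stimulus table or include a 'stimulus' column"
        )
    missing = [i for i in ids if i not in lookup.index]
    if missing:
        raise JoinError(
            f"registered neuron(s) {missing[:5]} not found in the "
            f"{side} results table"
        )
    return lookup.loc[ids].reset_index(drop=True)


def build_encoding_table(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    registration: RegistrationMap,
    us_stimuli: tuple[str, str] = ("food", "shock"),
    cs_stimulus: str = "cs",
) -> pd.DataFrame:
    """Join per-session responsiveness labels across registered neurons.

    ``results_a`` holds the appetitive session's results (stimuli 'food'
    and optionally 'cs'), ``results_b`` the fear session's ('shock' and
    optionally 'cs').  Returns one row per registered pair with the joint
    labels and the derived US and (where available) CS categories.
    """
    ids_a = [a for a, _ in registration.pairs]
    ids_b = [b for _, b in registration.pairs]
    if not ids_a:
        return pd.DataFrame(columns=ENCODING_COLUMNS)

    label_food = _joined_labels(results_a, ids_a, "appetitive", us_stimuli[0])
    label_shock = _joined_labels(results_b, ids_b, "fear", us_stimuli[1])

    has_cs = ("stimulus" in results_a.columns
              and (results_a["stimulus"] == cs_stimulus).any()
              and "stimulus" in results_b.columns
              and (results_b["stimulus"] == cs_stimulus).any())
    if has_cs:
        label_cs_food = _joined_labels(results_a, ids_a, "appetitive", cs_stimulus)
        label_cs_shock = _joined_labels(results_b, ids_b, "fear", cs_stimulus)
    else:
        label_cs_food = pd.Series([None] * len(ids_a))
        label_cs_shock = pd.Series([None] * len(ids_b))

    rows = []
    for k in range(len(ids_a)):
        us_cat, us_sub = classify_encoding(label_food[k], label_shock[k])
        if has_cs:
            cs_cat, cs_sub = classify_encoding(label_cs_food[k], label_cs_shock[k])
        else:
            cs_cat = cs_sub = None
        rows.append((ids_a[k], ids_b[k], label_food[k], label_shock[k],
                     us_cat, us_sub, label_cs_food[k], label_cs_shock[k],
                     cs_cat, cs_sub))
    return pd.DataFrame(rows, columns=ENCODING_COLUMNS)


def category_counts(
    table: pd.DataFrame,
    stimulus_pair: str = "us",
    detail: str = "category",
) -> ContingencyTable:
    """Count encoding categories (1x3) or response subtypes (1x9)."""
    if len(table) == 0:
        raise DataError("encoding table is empty")
    if stimulus_pair not in ("us", "cs"):
        raise DataError("stimulus_pair must be 'us' or 'cs'")
    col = f"{stimulus_pair}_{'category' if detail == 'category' else 'subtype'}"
    labels = CATEGORIES if detail == "category" else SUBTYPES
    values = table[col]
    if values.isna().any():
        raise DataError(f"{col} is unavailable for some neurons")
    counts = np.array([[int((values == lab).sum()) for lab in labels]])
    return ContingencyTable(counts, [stimulus_pair], list(labels))


def chi_square_independence(table: ContingencyTable
                            ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, upper-tail p).  Requires at
    least a 2x2 table with strictly positive margins, matching the
    asymptotic test's validity conditions.
    """
    counts = table.counts
    r, c = counts.shape
    if r < 2 or c < 2:
        raise DataError("chi-square requires at least a 2x2 table")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise DataError("chi-square requires all row and column sums > 0")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def compare_order_groups(
    table: pd.DataFrame,
    group_assignment: pd.Series | dict,
) -> dict:
    """Compare encoding-category proportions between conditioning-order groups.

    ``group_assignment`` maps each registered neuron (appetitive-side ID)
    to 'appetitive_first' or 'fear_first'.  Builds a 2x3 (group x
    category) table for the US pair and, when available, the CS pair, and
    tests each with the Pearson chi-square.
    """
    if isinstance(group_assignment, dict):
        groups = table["neuron_id_a"].map(group_assignment)
    else:
        groups = pd.Series(group_assignment).reset_index(drop=True)
    if groups.isna().any():
        raise DataError("every registered neuron needs a group assignment")
    valid = {"appetitive_first", "fear_first"}
    bad = set(groups.unique()) - valid
    if bad:
        raise DataError(f"unknown group label(s) {sorted(bad)}")

    out = {}
    for pair in ("us", "cs"):
        col = f"{pair}_category"
        if col not in table.columns or table[col].isna().any():
            continue
        counts = np.array([
            [int(((groups == g) & (table[col] == cat)).sum())
             for cat in CATEGORIES]
            for g in ("appetitive_first", "fear_first")
        ])
        ct = ContingencyTable(counts, ["appetitive_first", "fear_first"],
                              list(CATEGORIES))
        stat, dof, p = chi_square_independence(ct)
        out[pair] = {"table": ct, "statistic": stat, "df": dof, "p": p}
    return out
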