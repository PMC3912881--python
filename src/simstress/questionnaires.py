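"""Scoring for the two study instruments.

* STAI Form Y1 (state anxiety): 20 items answered on a 4-point scale
  (1 = "almost never" ... 4 = "almost always").  Positively worded items are
  reverse-scored (r -> 5 - r) before summation, giving a total from 20 (low
  anxiety) to 80 (high anxiety).  The published instrument does not ship with
  this package, so the reverse-keyed set is a configuration input; the
  default is the conventional Y1 set of ten positively worded items.

* Simulation evaluation questionnaire: 19 statements about the realism and
  usefulness of a simulated performance environment, each rated on a 5-point
  Likert scale (1 = "strongly disagree" ... 5 = "strongly agree").  Per-item
  descriptives (median with the midpoint convention, mean, n-1 SD) reproduce
  the shape of the study's published summary table, and a packaged copy of
  that table's printed values supports significance counting against the
  scale midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_STAI_REVERSE_ITEMS",
    "STAI_N_ITEMS",
    "SEQ_N_ITEMS",
    "ItemSummary",
    "score_stai",
    "seq_descriptives",
    "load_table1_fixture",
    "count_significant",
]

STAI_N_ITEMS = 20
SEQ_N_ITEMS = 19

#: Conventional reverse-keyed (positively worded, e.g. "I feel calm") items
#: of STAI Form Y1.  Override if your licensed form is keyed differently.
DEFAULT_STAI_REVERSE_ITEMS = frozenset({1, 2, 5, 8, 10, 11, 15, 16, 19, 20})


@dataclass(frozen=True)
class ItemSummary:
    """Descriptive statistics for one Likert item."""

    item: int
    median: float
    mean: float
    sd: float
    n: int


def score_stai(
    items: Sequence[int],
    reverse_items: Iterable[int] = DEFAULT_STAI_REVERSE_ITEMS,
) -> int:
    """Score a 20-item STAI-Y1 response vector.

    Each reverse-keyed item ``r`` is mapped to ``5 - r`` and the 20
    transformed responses are summed; the result lies in [20, 80].  Item
    indices in ``reverse_items`` are 1-based.  Missing or out-of-range
    responses raise (no imputation).
    """
    arr = np.asarray(items)
    if arr.shape != (STAI_N_ITEMS,):
        raise ValueError(f"expected exactly {STAI_N_ITEMS} items, got shape {arr.shape}")
    if np.any(pd.isna(arr)):
        raise ValueError("missing STAI item response; no imputation is performed")
    arr = arr.astype(int)
    if np.any((arr < 1) | (arr > 4)):
        raise ValueError("STAI responses must be integers in [1, 4]")
    reverse = set(int(i) for i in reverse_items)
    if not reverse <= set(range(1, STAI_N_ITEMS + 1)):
        raise ValueError("reverse_items must be 1-based indices in 1..20")
    transformed = arr.copy()
    for idx in reverse:
        transformed[idx - 1] = 5 - arr[idx - 1]
    return int(transformed.sum())


def seq_descriptives(table: pd.DataFrame, condition: str) -> list[ItemSummary]:
    """Per-item descriptives for one condition of the evaluation questionnaire.

    ``table`` is long-format with columns ``participant_id``, ``condition``,
    ``item`` (1..19) and ``response`` (1..5).  For each item: sample median
    (midpoint of the two central order statistics for even n — this is what
    produces half-point medians such as 4.5), mean, SD with the n-1
    denominator, and n.
    """
    required = {"participant_id", "condition", "item", "response"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"questionnaire table missing columns: {sorted(missing)}")
    sub = table[table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"no responses for condition {condition!r}")
    resp = sub["response"].to_numpy()
    if np.any((resp < 1) | (resp > 5)) or not np.allclose(resp, np.round(resp)):
        raise ValueError("responses must be integers in [1, 5]")
    items_present = set(sub["item"].unique())
    expected = set(range(1, SEQ_N_ITEMS + 1))
    if items_present != expected:
        raise ValueError(
            f"expected items 1..{SEQ_N_ITEMS}, got {sorted(items_present)}"
        )
    out: list[ItemSummary] = []
    for item, grp in sub.groupby("item"):
        values = grp["response"].to_numpy(dtype=float)
        out.append(
            ItemSummary(
                item=int(item),
                median=float(np.median(values)),
                mean=float(np.mean(values)),
                sd=float(np.std(values, ddof=1)) if values.size >= 2 else 0.0,
                n=int(values.size),
            )
        )
    return sorted(out, key=lambda s: s.item)


def summaries_to_frame(summaries: list[ItemSummary]) -> pd.DataFrame:
    """Tabulate :class:`ItemSummary` records as a DataFrame."""
    return pd.DataFrame(
        [(s.item, s.median, s.mean, s.sd, s.n) for s in summaries],
        columns=["item", "median", "mean", "sd", "n"],
    )


def load_table1_fixture() -> pd.DataFrame:
    """Load the packaged printed summary table of the evaluation questionnaire.

    Columns: ``item``, ``label``, then ``{condition}_{median,mean,sd,p}`` for
    conditions ``recital`` and ``audition``.  The ``p`` columns hold the
    printed Wilcoxon p-values as strings; non-significant entries are the
    literal ``ns``.
    """
    with resources.files("simstress.data").joinpath("table1_fixture.csv").open() as fh:
        df = pd.read_csv(fh, dtype={"recital_p": str, "audition_p": str})
    return df


def count_significant(
    fixture: pd.DataFrame,
    condition: str,
    alpha: float = 0.05,
    item_range: tuple[int, int] = (1, SEQ_N_ITEMS),
) -> tuple[int, float]:
    """Count items whose printed p-value is numeric and below ``alpha``.

    ``item_range`` is an inclusive 1-based interval.  ``ns`` literals count as
    non-significant.  Returns ``(count, percentage)`` with the percentage of
    the items in range, rounded to one decimal.
    """
    col = f"{condition}_p"
    if col not in fixture.columns:
        raise ValueError(f"unknown condition {condition!r}")
    lo, hi = item_range
    sub = fixture[(fixture["item"] >= lo) & (fixture["item"] <= hi)]
    if sub.empty:
        raise ValueError(f"empty item range {item_range}")
    count = 0
    for raw in sub[col]:
        text = str(raw).strip()
        if text.lower() == "ns":
            continue
        p = float(text)
        if p < alpha:
            count += 1
    pct = round(100.0 * count / len(sub), 1)
    return count, pct
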