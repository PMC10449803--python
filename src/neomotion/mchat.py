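"""M-CHAT scoring and high/low ASD-risk group assignment.

The Modified Checklist for Autism in Toddlers is a 23-item caregiver
questionnaire; each item is scored here as a binary failure indicator.
An infant is assigned to the **high-risk** group by the first-stage
screening cut-offs: a total of three or more failed items, or one or
more failures among the ten critical items.  Everyone else is low risk.

Item wording is deliberately not encoded (the instrument is licensed and
only counts matter here): items are anonymous indices 1..23 and the
critical set is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MChatResponse",
    "RiskLabel",
    "score_mchat",
    "group_table",
    "load_mchat_table",
    "high_risk_proportion",
    "N_ITEMS",
    "DEFAULT_CRITICAL_SET",
    "TOTAL_CUTOFF",
    "CRITICAL_CUTOFF",
]

N_ITEMS = 23
#: Anonymous stand-in for the instrument's ten critical items.
DEFAULT_CRITICAL_SET = frozenset({2, 5, 7, 9, 13, 14, 15, 20, 21, 23})
TOTAL_CUTOFF = 3      # criterion (i): >= 3 of 23 items failed
CRITICAL_CUTOFF = 1   # criterion (ii): >= 1 critical item failed


@dataclass(frozen=True)
class MChatResponse:
    """One caregiver's complete 23-item response (1 = item failed)."""

    items: tuple[int, ...]
    critical_set: frozenset[int] = DEFAULT_CRITICAL_SET

    def __post_init__(self) -> None:
        if len(self.items) != N_ITEMS:
            raise ValueError(
                f"expected {N_ITEMS} items, got {len(self.items)} "
                "(all items must be answered)"
            )
        if any(v not in (0, 1) for v in self.items):
            raise ValueError("items must be binary 0/1 failure indicators")
        if len(self.critical_set) != 10 or not self.critical_set <= set(range(1, 24)):
            raise ValueError("critical_set must be 10 item indices in 1..23")


@dataclass(frozen=True)
class RiskLabel:
    """High/low risk label with the scores that produced it."""

    label: str
    total_score: int
    critical_score: int

    @property
    def is_high(self) -> bool:
        return self.label == "high"


def score_mchat(resp: MChatResponse) -> RiskLabel:
    """Apply the dual cut-off: total >= 3 failures, or >= 1 critical failure."""
    total = sum(resp.items)
    critical = sum(resp.items[i - 1] for i in resp.critical_set)
    high = total >= TOTAL_CUTOFF or critical >= CRITICAL_CUTOFF
    return RiskLabel("high" if high else "low", total, critical)


def group_table(
    labels: Sequence[RiskLabel | str],
    sex: Sequence[int],
) -> np.ndarray:
    """2x2 contingency table of risk group by sex.

    Rows are (high, low), columns (male, female); ``sex`` is coded
    1 = male, 0 = female.
    """
    if len(labels) != len(sex):
        raise ValueError("labels and sex differ in length")
    table = np.zeros((2, 2), dtype=int)
    for lab, s in zip(labels, sex):
        name = lab.label if isinstance(lab, RiskLabel) else str(lab)
        row = 0 if name == "high" else 1
        col = 0 if int(s) == 1 else 1
        table[row, col] += 1
    return table


def load_mchat_table(
    path: str | Path,
    critical_set: Iterable[int] = DEFAULT_CRITICAL_SET,
) -> pd.DataFrame:
    """Score a CSV of responses (columns ``infant_id, item_1..item_23``).

    Returns one row per infant with total/critical scores and the risk
    label.
    """
    df = pd.read_csv(path)
    cset = frozenset(critical_set)
    records = []
    for _, row in df.iterrows():
        items = tuple(int(row[f"item_{i}"]) for i in range(1, N_ITEMS + 1))
        lab = score_mchat(MChatResponse(items, cset))
        records.append({
            "infant_id": row["infant_id"],
            "total_score": lab.total_score,
            "critical_score": lab.critical_score,
            "risk": lab.label,
        })
    return pd.DataFrame(records)


def high_risk_proportion(n_high: int, n_total: int) -> float:
    """High-risk share of a dataset, in percent."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return 100.0 * n_high / n_total
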