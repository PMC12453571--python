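"""System Usability Scale (SUS) scoring, cohort summary, and percentile
interpretation.

The SUS is a 10-item questionnaire rated 1-5, scored with Brooke's scheme:
odd items (positively worded) contribute ``rating - 1``, even items
(negatively worded) contribute ``5 - rating``, and the summed contributions
are multiplied by 2.5, giving a 0-100 score in steps of 2.5. A raw score is
interpreted against the distribution of scores across published studies via
the Sauro-Lewis curved grading scale, bundled here as anchor points of the
score-to-percentile curve (``data/sus_percentiles.csv``; e.g. a score of 68
sits at the 50th percentile, 80.8+ reaches the 90th). Interpolation between
anchors is linear, so the mapping is monotone non-decreasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateStatisticError

__all__ = ["SusResponse", "SusSummary", "sus_score", "sus_summary", "sus_percentile"]


@dataclass(frozen=True)
class SusResponse:
    """One participant's 10 item ratings, in standard SUS item order."""

    participant_id: str
    items: Sequence[int]

    def __post_init__(self) -> None:
        items = tuple(int(v) for v in self.items)
        if len(items) != 10:
            raise ValueError(f"SUS has exactly 10 items, got {len(items)}")
        if any(not 1 <= v <= 5 for v in items):
            raise ValueError(f"SUS items must lie in [1, 5], got {items}")
        object.__setattr__(self, "items", items)


@dataclass(frozen=True)
class SusSummary:
    """Cohort SUS summary; ``sd`` is None for a single respondent."""

    mean: float
    sd: Optional[float]
    min: float
    max: float
    n: int
    percentile: int


def sus_score(resp: "SusResponse | Sequence[int]") -> float:
    """Brooke SUS score in [0, 100]; always a multiple of 2.5."""
    items = resp.items if isinstance(resp, SusResponse) else SusResponse("", resp).items
    odd = sum(items[i] - 1 for i in range(0, 10, 2))
    even = sum(5 - items[i] for i in range(1, 10, 2))
    return 2.5 * (odd + even)


_table_cache: Optional[pd.DataFrame] = None


def _percentile_table() -> pd.DataFrame:
    global _table_cache
    if _table_cache is None:
        with resources.files("stsbalance.data").joinpath("sus_percentiles.csv").open() as fh:
            _table_cache = pd.read_csv(fh)
    return _table_cache


def sus_percentile(score: float) -> float:
    """Percentile rank of a SUS score against published-study norms.

    Linear interpolation on the bundled Sauro-Lewis anchor table; clipped to
    [0, 100] at the table's ends.
    """
    if not 0 <= score <= 100:
        raise ValueError(f"SUS score must lie in [0, 100], got {score}")
    tab = _percentile_table()
    return float(np.interp(score, tab["sus"], tab["percentile"]))


def sus_summary(scores: Iterable[float]) -> SusSummary:
    """Mean/SD/range of participant scores plus the percentile of the mean.

    SD uses the n-1 denominator; a single score yields ``sd=None``.
    """
    arr = np.asarray(list(scores), dtype=float)
    if arr.size == 0:
        raise DegenerateStatisticError("no SUS scores to summarise")
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("SUS scores must lie in [0, 100]")
    mean = float(np.mean(arr))
    return SusSummary(
        mean=mean,
        sd=float(np.std(arr, ddof=1)) if arr.size > 1 else None,
        min=float(np.min(arr)),
        max=float(np.max(arr)),
        n=int(arr.size),
        percentile=int(round(sus_percentile(mean))),
    )
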