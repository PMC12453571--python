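"""Cohort adherence analytics: upload-validity accounting, per-participant
engagement summaries, and one-sample t-tests against protocol targets.

A remote-assessment trial asks each participant to complete every activity
once a week for a set number of weeks. Adherence is summarised per
participant as the number of sessions per activity, the mean gap in days
between consecutive session days, and the span from first to last session;
cohort rows report mean/SD/min/max across participants and are compared to
the protocol targets (4 sessions, 7-day gap, 21-day span for a 4-week
schedule) with two-sided one-sample t-tests. Upload quality is reported as
the percentage of recordings the detection algorithms could analyse.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .errors import DegenerateStatisticError

__all__ = [
    "AdherenceSummary",
    "TTestResult",
    "DEFAULT_TARGETS",
    "validity_rate",
    "summarize_adherence",
    "one_sample_t",
    "engagement_report",
]

#: Protocol targets for a 4-week, once-weekly schedule.
DEFAULT_TARGETS: Dict[str, float] = {
    "trial_span_days": 21.0,
    "mean_gap_days": 7.0,
    "n_sessions_sts": 4.0,
    "n_sessions_slb": 4.0,
}


def validity_rate(n_valid: int, n_total: int) -> float:
    """Percentage of analyzable uploads, to one decimal (round half up).

    E.g. 142 valid of 192 uploads -> 74.0; 81 of 127 -> 63.8.
    """
    if n_total <= 0:
        raise DegenerateStatisticError("validity rate undefined for zero uploads")
    if not 0 <= n_valid <= n_total:
        raise ValueError("need 0 <= n_valid <= n_total")
    pct = Decimal(100 * n_valid) / Decimal(n_total)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TTestResult:
    """Two-sided one-sample t-test of a cohort mean against a target."""

    t_statistic: float
    df: int
    p_two_sided: float
    target: float
    mean: float
    sd: float
    n: int


def one_sample_t(mean: float, sd: float, n: int, target: float) -> TTestResult:
    """t = (mean - target) / (sd / sqrt(n)), p from Student's t with n-1 df.

    Computed from summary statistics so published cohort rows (mean, SD, n)
    can be tested without the underlying raw data.
    """
    if n < 2:
        raise DegenerateStatisticError("one-sample t-test needs n >= 2")
    if not sd > 0:
        raise DegenerateStatisticError("one-sample t-test needs sd > 0")
    t = (mean - target) / (sd / np.sqrt(n))
    df = n - 1
    p = float(2.0 * spstats.t.sf(abs(t), df))
    return TTestResult(
        t_statistic=float(t), df=df, p_two_sided=p,
        target=float(target), mean=float(mean), sd=float(sd), n=int(n),
    )


@dataclass
class AdherenceSummary:
    """Per-participant metrics plus cohort mean/SD/min/max rows.

    ``per_participant`` columns: n_sessions_sts, n_sessions_slb,
    mean_gap_days (NaN when fewer than two distinct session days — those
    participants are excluded from the gap aggregation and flagged via
    ``gap_defined``), trial_span_days. ``cohort`` is indexed by metric with
    columns mean/sd/min/max/n.
    """

    per_participant: pd.DataFrame
    cohort: pd.DataFrame


def summarize_adherence(log: pd.DataFrame) -> AdherenceSummary:
    """Engagement summary from a session log.

    The log needs columns ``participant_id``, ``activity`` (``sts``/``slb``;
    a balance session counts once even though it holds two leg recordings)
    and ``session_datetime``. Session totals count log rows; gap and span
    statistics use distinct calendar days (same-day repeats collapse).
    Cohort statistics are unweighted across participants. Row order is
    irrelevant.
    """
    if log.empty:
        raise DegenerateStatisticError("cannot summarise an empty session log")
    df = log.copy()
    df["session_datetime"] = pd.to_datetime(df["session_datetime"])
    df["day"] = df["session_datetime"].dt.normalize()

    rows = []
    for pid, grp in df.groupby("participant_id", sort=True):
        days = np.sort(grp["day"].unique())
        gaps = np.diff(days).astype("timedelta64[D]").astype(float)
        rows.append(
            {
                "participant_id": pid,
                "n_sessions_sts": int((grp["activity"] == "sts").sum()),
                "n_sessions_slb": int((grp["activity"] == "slb").sum()),
                "mean_gap_days": float(np.mean(gaps)) if gaps.size else np.nan,
                "gap_defined": bool(gaps.size),
                "trial_span_days": float(
                    (days[-1] - days[0]).astype("timedelta64[D]").astype(float)
                ),
            }
        )
    per = pd.DataFrame(rows).set_index("participant_id")

    metrics = ["n_sessions_sts", "n_sessions_slb", "mean_gap_days", "trial_span_days"]
    cohort_rows = {}
    for m in metrics:
        vals = per[m].dropna().to_numpy(dtype=float)
        cohort_rows[m] = {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            "min": float(np.min(vals)),
            "max": float(np.max(vals)),
            "n": int(vals.size),
        }
    cohort = pd.DataFrame(cohort_rows).T[["mean", "sd", "min", "max", "n"]]
    return AdherenceSummary(per_participant=per, cohort=cohort)


def engagement_report(
    summary: AdherenceSummary,
    validity_counts: Optional[Mapping[str, "tuple[int, int]"]] = None,
    targets: Mapping[str, float] = DEFAULT_TARGETS,
) -> pd.DataFrame:
    """Cohort engagement table: target/mean/SD/min/max per metric, plus the
    t-test p-value against the target and (optionally) validity-rate rows.

    ``validity_counts`` maps labels (e.g. ``"sts"``, ``"slb"``, ``"overall"``)
    to ``(n_valid, n_total)``; each adds a row whose ``mean`` column holds
    the percentage. Cohorts of a single participant carry NaN SD and no
    t-test (flagged by a NaN p-value).
    """
    if summary.cohort.empty:
        raise DegenerateStatisticError("empty adherence summary")

    rows = []
    for metric, target in targets.items():
        if metric not in summary.cohort.index:
            continue
        c = summary.cohort.loc[metric]
        if c["n"] >= 2 and np.isfinite(c["sd"]) and c["sd"] > 0:
            p = one_sample_t(c["mean"], c["sd"], int(c["n"]), target).p_two_sided
        else:
            p = np.nan
        rows.append(
            {
                "metric": metric, "target": target, "mean": c["mean"],
                "sd": c["sd"], "min": c["min"], "max": c["max"],
                "n": int(c["n"]), "p_vs_target": p,
            }
        )
    if validity_counts:
        for label, (nv, nt) in validity_counts.items():
            rows.append(
                {
                    "metric": f"valid_uploads_pct_{label}", "target": np.nan,
                    "mean": validity_rate(nv, nt), "sd": np.nan,
                    "min": np.nan, "max": np.nan, "n": nt, "p_vs_target": np.nan,
                }
            )
    return pd.DataFrame(rows).set_index("metric")
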