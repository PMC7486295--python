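"""Kaplan-Meier estimation per patient group and the log-rank test.

Both are standard right-censored survival procedures and are computed with
``lifelines``; this module adapts them to the package's survival-table
contract and exposes the risk sets explicitly.  Censored observations tied
with an event time are counted as at risk through the event (censoring after
deaths at equal times), the conventional product-limit tie rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .errors import ValidationError
from .io_catalog import SurvivalTable


@dataclass
class KMCurve:
    """Product-limit estimate at the group's event times."""

    group: str
    event_times: np.ndarray      # distinct times with >= 1 event
    n_risk: np.ndarray           # at risk just before each event time
    n_events: np.ndarray         # events at each time
    survival: np.ndarray         # S(t_i)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "n_risk": self.n_risk,
                "n_event": self.n_events,
                "survival": self.survival,
            }
        )


@dataclass
class LogrankResult:
    chi_square: float
    df: int
    p: float

    def stars(self) -> str:
        """Significance annotation: *, **, ***, **** for p <= 0.05, 0.01, 0.001, 0.0001."""
        for stars, cutoff in (("****", 1e-4), ("***", 1e-3), ("**", 1e-2), ("*", 0.05)):
            if self.p <= cutoff:
                return stars
        return "ns"


def km_estimate(table: SurvivalTable, group: str | int | None = None) -> KMCurve:
    """Kaplan-Meier curve for one group (or the whole table)."""
    t = table.table
    if group is not None:
        t = t[t["group"] == group]
    if len(t) == 0:
        raise ValidationError(f"no subjects in group {group!r}")
    kmf = KaplanMeierFitter()
    kmf.fit(t["time"].to_numpy(dtype=float), t["event"].to_numpy(dtype=int))
    et = kmf.event_table
    ev = et[et["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(times).to_numpy(dtype=float)
    return KMCurve(
        group=str(group),
        event_times=times,
        n_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
        survival=surv,
    )


def logrank_test(table: SurvivalTable) -> LogrankResult:
    """Mantel-Cox log-rank test across all groups in the table."""
    t = table.table
    groups = t["group"].dropna().unique()
    if len(groups) < 2:
        raise ValidationError("log-rank needs at least two non-empty groups")
    sub = t[t["group"].notna()]
    if int(sub["event"].sum()) == 0:
        raise ValidationError("log-rank undefined with zero events")
    res = multivariate_logrank_test(
        sub["time"].to_numpy(dtype=float),
        sub["group"].to_numpy(),
        sub["event"].to_numpy(dtype=int),
    )
    return LogrankResult(
        chi_square=float(res.test_statistic),
        df=len(groups) - 1,
        p=float(res.p_value),
    )


def group_median_survival(table: SurvivalTable) -> pd.DataFrame:
    """Median survival time (and event counts) per group, for reporting."""
    rows = []
    for g in sorted(table.table["group"].dropna().unique()):
        sub = table.table[table.table["group"] == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"].to_numpy(dtype=float), sub["event"].to_numpy(dtype=int))
        rows.append(
            {
                "group": g,
                "n": len(sub),
                "n_events": int(sub["event"].sum()),
                "median_survival": float(kmf.median_survival_time_),
            }
        )
    return pd.DataFrame(rows)
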