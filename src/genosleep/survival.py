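"""Kaplan-Meier estimation and two-group log-rank testing.

Input tables follow the SurvivalData dialect: one row per subject with
columns ``time`` (>= 0), ``event`` (1 = death observed, 0 = censored) and
optionally ``subject_id`` and ``group``.

Tie convention: deaths and censorings recorded at the same time are handled
with deaths first, i.e. a subject censored at t is still at risk for the
deaths at t.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["LogRankResult", "kaplan_meier", "logrank_test"]


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    pval: float
    observed: tuple[float, float]
    expected: tuple[float, float]


def _validate(data: pd.DataFrame, label: str = "survival table") -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in data.columns:
            raise ValueError(f"{label} lacks column {col!r}")
    if len(data) == 0:
        raise ValueError(f"{label} is empty")
    if (data["time"] < 0).any():
        raise ValueError(f"{label} contains negative times")
    if not data["event"].isin((0, 1)).all():
        raise ValueError(f"{label}: event must be 0 or 1")
    return data


def kaplan_meier(data: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate with Greenwood variance.

    Returns one row per distinct event (death) time with columns ``time``,
    ``n_risk``, ``n_events``, ``n_censored`` (censorings in (previous event
    time, this one]), ``survival``, ``var_greenwood`` and ``se``.
    """
    _validate(data)
    times = data["time"].to_numpy(dtype=float)
    events = data["event"].to_numpy(dtype=int)
    n = len(times)

    event_times = np.unique(times[events == 1])
    rows = []
    surv = 1.0
    greenwood_sum = 0.0
    prev = -math.inf
    for t in event_times:
        # deaths first at ties: censored-at-t subjects still count as at risk
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        c = int(((times > prev) & (times <= t) & (events == 0)).sum())
        surv *= 1.0 - d / n_risk
        if n_risk > d:
            greenwood_sum += d / (n_risk * (n_risk - d))
        var = surv**2 * greenwood_sum
        rows.append(
            {
                "time": float(t),
                "n_risk": n_risk,
                "n_events": d,
                "n_censored": c,
                "survival": surv,
                "var_greenwood": var,
                "se": math.sqrt(var),
            }
        )
        prev = t
    return pd.DataFrame(
        rows,
        columns=["time", "n_risk", "n_events", "n_censored", "survival", "var_greenwood", "se"],
    )


def logrank_test(a: pd.DataFrame, b: pd.DataFrame) -> LogRankResult:
    """Two-group Mantel-Haenszel log-rank test.

    At each distinct death time, the expected deaths in group a come from
    the hypergeometric mean d * n_a / n and the variance from
    d (n-d) n_a n_b / (n^2 (n-1)); the statistic (O_a - E_a)^2 / V is
    referred to chi-square with 1 df.
    """
    _validate(a, "group a")
    _validate(b, "group b")
    ta, ea = a["time"].to_numpy(dtype=float), a["event"].to_numpy(dtype=int)
    tb, eb = b["time"].to_numpy(dtype=float), b["event"].to_numpy(dtype=int)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")

    all_times = np.concatenate([ta, tb])
    all_events = np.concatenate([ea, eb])
    event_times = np.unique(all_times[all_events == 1])

    obs_a = 0.0
    exp_a = 0.0
    var = 0.0
    for t in event_times:
        na = int((ta >= t).sum())
        nb = int((tb >= t).sum())
        ntot = na + nb
        da = int(((ta == t) & (ea == 1)).sum())
        db = int(((tb == t) & (eb == 1)).sum())
        d = da + db
        obs_a += da
        exp_a += d * na / ntot
        if ntot > 1:
            var += d * (ntot - d) * na * nb / (ntot**2 * (ntot - 1))

    total_events = float(all_events.sum())
    if var == 0.0:
        chi2 = 0.0
    else:
        chi2 = (obs_a - exp_a) ** 2 / var
    pval = float(stats.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return LogRankResult(
        chi_square=float(chi2),
        pval=pval,
        observed=(obs_a, total_events - obs_a),
        expected=(exp_a, total_events - exp_a),
    )
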