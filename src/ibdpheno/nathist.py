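"""Natural-history summaries: Kaplan-Meier curves, log-rank tests, and
behaviour-prevalence-over-time curves.

Survival machinery wraps lifelines (product-limit estimator with Greenwood
confidence bands; standard log-rank statistic).  Behaviour prevalence uses a
risk-set denominator: at each grid time t the proportions of B1/B2/B3 are
computed among patients still under follow-up at t, optionally smoothed by a
centred moving average.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class SurvivalCurve:
    stratum: str
    times: np.ndarray
    survival: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    at_risk: np.ndarray

    def __post_init__(self):
        s = self.survival
        if s.size and (s[0] > 1 + 1e-9 or np.any(np.diff(s) > 1e-12)
                       or np.any((s < -1e-12) | (s > 1 + 1e-12))):
            raise ValueError("invalid survival step function")

    def at(self, t: float) -> float:
        """Step-function value S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "S": self.survival,
                             "ci_low": self.ci_low, "ci_high": self.ci_high,
                             "at_risk": self.at_risk,
                             "stratum": self.stratum})


def km_estimate(time, event, strata=None) -> dict[str, SurvivalCurve]:
    """Product-limit survival estimate per stratum with Greenwood 95% bands."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    if np.any(t[~np.isnan(t)] < 0):
        raise ValueError("negative time")
    if strata is None:
        strata = np.array(["all"] * t.size, dtype=object)
    strata = np.asarray(strata, dtype=object)
    out = {}
    for s in pd.unique(strata[~pd.isna(strata)]):
        m = (strata == s) & ~np.isnan(t) & ~np.isnan(e)
        kmf = KaplanMeierFitter()
        kmf.fit(t[m], e[m], label=str(s))
        sf = kmf.survival_function_
        ci = kmf.confidence_interval_
        times = sf.index.to_numpy(dtype=float)
        ev = kmf.event_table
        out[str(s)] = SurvivalCurve(
            stratum=str(s), times=times,
            survival=sf.iloc[:, 0].to_numpy(),
            ci_low=ci.iloc[:, 0].to_numpy(),
            ci_high=ci.iloc[:, 1].to_numpy(),
            at_risk=ev["at_risk"].reindex(sf.index).to_numpy(dtype=float))
    return out


def logrank_test(time, event, strata) -> dict:
    """Standard log-rank chi-square across strata (df = strata - 1)."""
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=float)
    g = np.asarray(strata, dtype=object)
    ok = ~np.isnan(t) & ~np.isnan(e) & ~pd.isna(g)
    groups = pd.unique(g[ok])
    if len(groups) < 2:
        raise ValueError("log-rank needs >= 2 strata")
    res = multivariate_logrank_test(t[ok], g[ok], e[ok])
    return {"chi2": float(res.test_statistic), "df": len(groups) - 1,
            "p": float(res.p_value)}


def behaviour_prevalence(P, event_log: pd.DataFrame,
                         time_grid=None, smooth_years: float = 2.0
                         ) -> pd.DataFrame:
    """Proportion of CD patients in B1/B2/B3 at each time since diagnosis.

    ``event_log`` holds per-sample true transition times (columns
    ``t_b1_to_b2`` and ``t_b2_to_b3``); at grid time t the risk set is the
    patients whose follow-up reaches t (post-surgery patients remain in the
    risk set).  A centred moving-average window (default 2 years) smooths
    the curves; ``smooth_years=0`` disables smoothing.
    """
    df = P.df.merge(event_log, on="sample_id")
    cd = df[df["diagnosis"] == "CD"]
    fu = cd["followup_years"].to_numpy(float)
    t12 = cd["t_b1_to_b2"].to_numpy(float)
    t23 = cd["t_b2_to_b3"].to_numpy(float)
    if time_grid is None:
        time_grid = np.arange(0.0, np.nanmax(fu), 0.5)
    time_grid = np.asarray(time_grid, dtype=float)
    time_grid = time_grid[time_grid <= np.nanmax(fu)]  # truncate empty risk sets
    rows = []
    for t in time_grid:
        at_risk = fu >= t
        n = int(at_risk.sum())
        if n == 0:
            continue
        b3 = at_risk & (t23 <= t)
        b2 = at_risk & (t12 <= t) & ~b3
        b1 = at_risk & ~b2 & ~b3
        rows.append({"time": t, "pB1": b1.sum() / n, "pB2": b2.sum() / n,
                     "pB3": b3.sum() / n, "n_at_risk": n})
    out = pd.DataFrame(rows)
    if smooth_years > 0 and len(out) > 1:
        step = float(np.median(np.diff(out["time"])))
        w = max(int(round(smooth_years / step)) | 1, 1)  # odd window
        for c in ("pB1", "pB2", "pB3"):
            out[c + "_smooth"] = out[c].rolling(
                w, center=True, min_periods=1).mean()
    return out
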