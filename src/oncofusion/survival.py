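"""Kaplan–Meier survival estimation and the Wilcoxon–Mann–Whitney test.

The product-limit estimate (with right-censoring, Greenwood variance and a
log-scale 95% band) is computed through lifelines; this module's surface
adds at-risk counts, censoring marks, right-continuous lookup and the
deaths-before-censorings tie convention that lifelines shares.  The
rank-sum test uses midranks for ties, an exact permutation p-value for
small samples (total n <= 12) and the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["KMCurve", "km_estimate", "survival_at", "mwu_test"]


@dataclass
class KMCurve:
    """Product-limit survival estimate with censoring marks and at-risk counts."""

    times: np.ndarray           # distinct event/censor times, ascending (with t=0)
    survival: np.ndarray        # S(t) step values, S(0) = 1
    at_risk: np.ndarray         # number at risk just before each time
    censor_times: np.ndarray    # times of censoring marks
    ci_lower: np.ndarray
    ci_upper: np.ndarray

    @property
    def final_time(self) -> float:
        return float(self.times[-1])


def km_estimate(times, events, alpha: float = 0.05) -> KMCurve:
    """Kaplan–Meier estimate from per-patient follow-up times and event flags.

    ``events[i] == 1`` means the event (death) was observed at ``times[i]``;
    0 means the patient was censored then.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0 or times.size != events.size:
        raise ValueError("times and events must be non-empty and aligned")
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")

    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    grid = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
        surv = np.concatenate([[1.0], surv])
    ci = kmf.confidence_interval_
    lo = np.interp(grid, ci.index.to_numpy(dtype=float), ci.iloc[:, 0].to_numpy())
    hi = np.interp(grid, ci.index.to_numpy(dtype=float), ci.iloc[:, 1].to_numpy())
    table = kmf.event_table
    at_risk = np.interp(grid, table.index.to_numpy(dtype=float),
                        table["at_risk"].to_numpy(dtype=float))
    return KMCurve(times=grid, survival=surv, at_risk=at_risk,
                   censor_times=np.sort(times[events == 0]),
                   ci_lower=lo, ci_upper=hi)


def survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step lookup S(t); beyond the last observed time the
    last value is carried forward (extrapolation)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.survival[max(idx, 0)])


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann–Whitney U for group a with midrank ties."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    return float(r_a - a.size * (a.size + 1) / 2.0)


def mwu_test(group_a, group_b) -> dict[str, float]:
    """Two-sided Wilcoxon–Mann–Whitney test.

    Returns ``{"U": ..., "p_two_sided": ...}``.  For total sample size
    <= 12 the p-value is exact, by enumeration of all group assignments
    (handles ties through midranks); otherwise the tie-corrected normal
    approximation with continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(a, b)
    n_tot = a.size + b.size
    if n_tot <= 12:
        pooled = np.concatenate([a, b])
        mu = a.size * b.size / 2.0
        dev_obs = abs(u_obs - mu)
        hits = 0
        total = 0
        for combo in itertools.combinations(range(n_tot), a.size):
            mask = np.zeros(n_tot, dtype=bool)
            mask[list(combo)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
            total += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
    return {"U": u_obs, "p_two_sided": float(min(p, 1.0))}
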