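"""Treatment-failure survival statistics.

Kaplan-Meier product-limit estimation, the one-degree-of-freedom log-rank
test, and the Mantel-Haenszel hazard ratio (O_A/E_A)/(O_B/E_B) computed from
the pooled log-rank risk sets, with CI exp(log HR +/- 1.96*sqrt(1/E_A+1/E_B)).
These are implemented from the risk-set definitions (and cross-checked in
the test suite against an independent survival library); the reported CI
lower bound may be clipped at 0 for table formatting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["SurvivalCurve", "HRResult", "km_estimate", "logrank", "hazard_ratio"]


@dataclass
class SurvivalCurve:
    """Product-limit estimate: event times, risk sets, events, survival."""

    times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class HRResult:
    hr: float
    ci_low: float
    ci_high: float
    logrank_chi2: float
    p: float


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any():
        raise ValueError("times must be >= 0")
    if t.shape != e.shape:
        raise ValueError("times and event flags must have equal length")
    return t, e


def km_estimate(times, event_flags) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator with right censoring.

    Ties are handled by the simultaneous-event convention: all events at a
    distinct time share one risk set.
    """
    t, e = _clean(times, event_flags)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    uniq = np.unique(t[e])
    n = len(t)
    at_risk = np.empty(len(uniq))
    events = np.empty(len(uniq))
    surv = np.empty(len(uniq))
    s = 1.0
    for i, u in enumerate(uniq):
        r = int(np.sum(t >= u))
        d = int(np.sum((t == u) & e))
        s *= 1.0 - d / r
        at_risk[i], events[i], surv[i] = r, d, s
    return SurvivalCurve(times=uniq, at_risk=at_risk, events=events, survival=surv)


def _risk_table(groupA, groupB):
    """Pooled risk-set tabulation over distinct event times.

    Returns per-event-time arrays (nA, nB, dA, dB)."""
    tA, eA = _clean(*groupA)
    tB, eB = _clean(*groupB)
    all_t = np.concatenate([tA[eA], tB[eB]])
    uniq = np.unique(all_t)
    nA = np.array([(tA >= u).sum() for u in uniq], dtype=float)
    nB = np.array([(tB >= u).sum() for u in uniq], dtype=float)
    dA = np.array([((tA == u) & eA).sum() for u in uniq], dtype=float)
    dB = np.array([((tB == u) & eB).sum() for u in uniq], dtype=float)
    return nA, nB, dA, dB


def _logrank_quantities(groupA, groupB):
    nA, nB, dA, dB = _risk_table(groupA, groupB)
    if len(nA) == 0:
        return 0.0, 0.0, 0.0, 0.0, 0.0
    n = nA + nB
    d = dA + dB
    eA = d * nA / n
    eB = d * nB / n
    with np.errstate(invalid="ignore", divide="ignore"):
        var = d * (nA / n) * (nB / n) * (n - d) / np.where(n > 1, n - 1, 1.0)
    return float(dA.sum()), float(dB.sum()), float(eA.sum()), float(eB.sum()), float(var.sum())


def logrank(groupA, groupB) -> tuple[float, float]:
    """One-degree-of-freedom log-rank test between two (times, events) groups.

    Returns (chi2, p).  With no events in either group, p = 1 by convention.
    """
    oA, oB, eA, eB, var = _logrank_quantities(groupA, groupB)
    if oA + oB == 0 or var == 0:
        return 0.0, 1.0
    chi2 = (oA - eA) ** 2 / var
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def hazard_ratio(groupA, groupB, clip_ci_low: bool = True) -> HRResult:
    """Mantel-Haenszel hazard ratio of group A relative to group B."""
    oA, oB, eA, eB, var = _logrank_quantities(groupA, groupB)
    if oA == 0 or oB == 0 or eA == 0 or eB == 0:
        raise ValueError(
            "degenerate comparison: each group needs at least one event "
            f"(observed A={oA}, B={oB})"
        )
    hr = (oA / eA) / (oB / eB)
    se = np.sqrt(1.0 / eA + 1.0 / eB)
    lo = hr * np.exp(-1.96 * se)
    hi = hr * np.exp(1.96 * se)
    if clip_ci_low:
        lo = max(lo, 0.0)
    chi2, p = logrank(groupA, groupB)
    return HRResult(
        hr=float(hr), ci_low=float(lo), ci_high=float(hi), logrank_chi2=chi2, p=p
    )
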