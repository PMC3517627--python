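"""Pulmonary function, behavioral thresholds, and care-seeking.

Pulmonary function Q maps impairment I and the bronchodilator factor sigma
onto (0, 1]: Q = 1 is the individual's best achievable function (I = 0) and
Q -> 0 the worst.  We use Q = exp(-I / sigma): strictly decreasing in I,
non-decreasing in sigma, and — because sigma is piecewise constant and I
falls only at trigger jumps — downward threshold crossings can occur only at
jump or episode-expiry instants, which is what makes the event-driven engine
exact.

Behavior is threshold-driven: a patient initiates relief medication when Q
falls below their personal relief threshold, seeks unscheduled physician
care below the immediate-care threshold, and emergency care below the
emergency threshold.  Treatment failure is the first passage of Q below the
immediate-care threshold.  Emergency presentations are admitted with a fixed
probability irrespective of Q at presentation; length of stay is geometric
on whole days; pulmonary function is held stable while inpatient, and every
discharge is followed by a short oral-steroid course.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BehaviorProfile",
    "HospitalPolicy",
    "LungAnchors",
    "pulmonary_function",
    "impairment_threshold",
    "fev1_of",
    "classify_zone",
    "handle_ed_visit",
    "detect_treatment_failure",
]

ZONES = ("well", "relief", "md_care", "emergency")

# Event-log types that imply Q has crossed the immediate-care threshold.
FAILURE_EVENTS = ("md_visit", "ed_visit", "failure")


@dataclass(frozen=True)
class BehaviorProfile:
    """Personal care-seeking thresholds on the Q scale.

    q_relief: start relief medication below this.
    q_md: seek immediate (unscheduled physician) care below this; also the
        treatment-failure threshold.
    q_ed: seek emergency care below this.
    washout: days of recovery above a threshold before the same encounter
        type can recur.
    Ordering 0 < q_ed < q_md < q_relief < 1 (emergency is the worst function).
    """

    q_relief: float
    q_md: float
    q_ed: float
    washout: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 < self.q_ed < self.q_md < self.q_relief < 1.0):
            raise ValueError(
                "thresholds must satisfy 0 < q_ed < q_md < q_relief < 1, got "
                f"q_ed={self.q_ed}, q_md={self.q_md}, q_relief={self.q_relief}"
            )
        if self.washout < 0:
            raise ValueError("washout must be >= 0")


@dataclass(frozen=True)
class HospitalPolicy:
    """Admission probability from the ED and mean inpatient length of stay."""

    p_admit: float = 0.268
    los_mean: float = 3.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_admit <= 1.0):
            raise ValueError("p_admit must be in [0, 1]")
        if self.los_mean < 1.0:
            raise ValueError("los_mean must be >= 1 day (geometric on days)")


@dataclass(frozen=True)
class LungAnchors:
    """FEV1 (liters) at the ends of the Q scale."""

    fev1_best: float
    fev1_floor: float

    def __post_init__(self) -> None:
        if not (0 < self.fev1_floor < self.fev1_best):
            raise ValueError("need 0 < fev1_floor < fev1_best")


def pulmonary_function(I: float, sigma: float = 1.0) -> float:
    """Q = exp(-I / sigma), in (0, 1]; Q = 1 iff I = 0."""
    if I < 0:
        raise ValueError("impairment level must be >= 0")
    if sigma < 1.0:
        raise ValueError("sigma must be >= 1")
    return float(np.exp(-I / sigma))


def impairment_threshold(q: float, sigma: float = 1.0) -> float:
    """Inverse of the Q form: the impairment level at which Q equals q.

    Q < q  <=>  I > sigma * (-ln q); the engine works on the I scale.
    """
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    return float(-sigma * np.log(q))


def fev1_of(Q: float, anchors: LungAnchors) -> float:
    """Linear map from Q in [0, 1] to FEV1 in liters."""
    if not (0.0 <= Q <= 1.0):
        raise ValueError("Q must be in [0, 1]")
    return anchors.fev1_floor + Q * (anchors.fev1_best - anchors.fev1_floor)


def classify_zone(Q: float, profile: BehaviorProfile) -> str:
    """Behavioral zone for a pulmonary-function value; lowest crossed wins."""
    if Q < profile.q_ed:
        return "emergency"
    if Q < profile.q_md:
        return "md_care"
    if Q < profile.q_relief:
        return "relief"
    return "well"


def handle_ed_visit(
    policy: HospitalPolicy, rng: np.random.Generator
) -> tuple[str, int]:
    """Dispose an ED presentation: ('discharged', 0) or ('admitted', los_days).

    Admission is Bernoulli(p_admit) regardless of function at presentation;
    length of stay is geometric on whole days with mean los_mean (support
    >= 1 day).
    """
    if rng.random() < policy.p_admit:
        los = int(rng.geometric(1.0 / policy.los_mean))
        return "admitted", los
    return "discharged", 0


def detect_treatment_failure(event_log, profile: BehaviorProfile = None):
    """First time Q dropped below the immediate-care threshold, or None.

    Works on an event log (iterable of (time, event_type, ...) rows or a
    DataFrame with 'time' and 'event' columns).  Any md-care-or-worse entry
    counts — an excursion straight into the emergency zone implies failure
    because q_ed < q_md.
    """
    try:
        times = event_log["time"].to_numpy()
        kinds = event_log["event"].to_numpy()
    except (TypeError, IndexError, AttributeError):
        rows = list(event_log)
        times = np.array([r[0] for r in rows], dtype=float)
        kinds = np.array([r[1] for r in rows], dtype=object)
    mask = np.isin(kinds, FAILURE_EVENTS)
    if not mask.any():
        return None
    return float(times[mask].min())
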