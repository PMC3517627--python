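"""Medication pharmacodynamics.

Two mechanistically distinct drug actions are modeled:

* beta-2 agonists (SABA, LABA) act through the bronchodilator factor sigma:
  while an episode is active it contributes an additive strength
  ``broncho_beta`` to sigma, lifting pulmonary function Q immediately without
  touching the inflammation level I.
* corticosteroids (ICS, OCS) act on the dynamics of I: an active episode
  multiplies the recovery rate gamma by ``gamma_mult`` (>= 1) and the mean
  trigger effect size by ``sens_mult`` (<= 1).  They never change I itself,
  so starting or stopping a corticosteroid leaves the trajectory continuous.

Effects switch on instantly when a dose is taken and hold constant for the
drug's duration of action.  Adherence is the fraction of scheduled dose-days
actually taken; it is realized as one Bernoulli coin per day (both doses of a
twice-daily controller share the day's flip), matching the survey definition
of adherence as "fraction of days of use".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MedicationSpec",
    "MedicationEpisode",
    "Prescription",
    "MedicationCatalog",
    "bronchodilator_factor",
    "inflammation_modifiers",
    "schedule_controller_doses",
    "start_ocs_course",
    "default_catalog",
]

BRONCHODILATORS = ("SABA", "LABA")
CORTICOSTEROIDS = ("ICS", "OCS")
MED_CLASSES = BRONCHODILATORS + CORTICOSTEROIDS


@dataclass(frozen=True)
class MedicationSpec:
    """Effect parameters for one medication class.

    broncho_beta: additive bronchodilator strength (SABA/LABA only).
    gamma_mult: multiplier on recovery rate, >= 1 (ICS/OCS only).
    sens_mult: multiplier on mean trigger effect size, in (0, 1] (ICS/OCS only).
    duration: effect duration in hours.
    schedule: scheduled doses per day (0 for as-needed SABA).
    """

    med_class: str
    broncho_beta: float = 0.0
    gamma_mult: float = 1.0
    sens_mult: float = 1.0
    duration: float = 24.0
    schedule: int = 0

    def __post_init__(self) -> None:
        if self.med_class not in MED_CLASSES:
            raise ValueError(f"unknown medication class {self.med_class!r}")
        if self.duration <= 0:
            raise ValueError("duration must be > 0 hours")
        if self.med_class in BRONCHODILATORS:
            if self.gamma_mult != 1.0 or self.sens_mult != 1.0:
                raise ValueError(
                    f"{self.med_class} is a bronchodilator; gamma_mult and "
                    "sens_mult must be 1"
                )
            if self.broncho_beta < 0:
                raise ValueError("broncho_beta must be >= 0")
        else:
            if self.broncho_beta != 0.0:
                raise ValueError(
                    f"{self.med_class} is a corticosteroid; broncho_beta must be 0"
                )
            if self.gamma_mult < 1.0:
                raise ValueError("gamma_mult must be >= 1")
            if not (0 < self.sens_mult <= 1):
                raise ValueError("sens_mult must be in (0, 1]")

    @property
    def duration_days(self) -> float:
        return self.duration / 24.0


@dataclass(frozen=True)
class MedicationEpisode:
    """An active drug-effect window [start, end) in days; immutable."""

    spec: MedicationSpec
    start: float
    end: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.end is None:
            object.__setattr__(self, "end", self.start + self.spec.duration_days)

    def active_at(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class Prescription:
    """A standing prescription: class, dose level, and adherence fraction."""

    med_class: str
    dose_level: str = "medium"
    adherence: float = 1.0

    def __post_init__(self) -> None:
        if self.med_class not in MED_CLASSES:
            raise ValueError(f"unknown medication class {self.med_class!r}")
        if self.dose_level not in ("low", "medium", "high"):
            raise ValueError(f"unknown dose level {self.dose_level!r}")
        if not (0.0 <= self.adherence <= 1.0):
            raise ValueError("adherence must be in [0, 1]")


class MedicationCatalog(dict):
    """Mapping med_class -> MedicationSpec with attribute-style access."""

    def __init__(self, specs):
        super().__init__({s.med_class: s for s in specs})

    def replace(self, med_class: str, **changes) -> "MedicationCatalog":
        """Return a new catalog with one spec's fields changed."""
        from dataclasses import replace as _replace

        specs = [
            _replace(s, **changes) if cls == med_class else s
            for cls, s in self.items()
        ]
        return MedicationCatalog(specs)


def default_catalog() -> MedicationCatalog:
    """Shipped medication-effect catalog.

    Bronchodilator strengths and corticosteroid multipliers are
    conventional-magnitude starting values for the population-level
    treatment-effect tuning procedure (see
    :func:`asthmasim.calibrate.calibrate_treatment_effects`); durations are
    conventional durations of action.
    """
    from .config import load_medication_catalog

    return load_medication_catalog(None)


def bronchodilator_factor(
    active_episodes, I: float, kappa: float = 0.0
) -> float:
    """Bronchodilator factor sigma >= 1 given the active episode set.

    sigma = 1 + sum_over_active_bronchodilators beta / (1 + kappa * I).
    kappa (default 0) is a configurable attenuation hook letting severe
    inflammation blunt bronchodilation; at kappa = 0 the effect is
    inflammation-independent.  Absent medication sigma = 1.
    """
    if I < 0:
        raise ValueError("impairment level must be >= 0")
    total = 0.0
    for ep in active_episodes:
        if ep.spec.med_class in BRONCHODILATORS:
            total += ep.spec.broncho_beta / (1.0 + kappa * I)
    return 1.0 + total


def inflammation_modifiers(active_episodes) -> tuple[float, float]:
    """(gamma_mult_total, sens_mult_total) over active corticosteroid episodes.

    Multiplicative composition; (1, 1) when none is active.  Corticosteroids
    alter only the rate of change of I, never I itself.
    """
    g, s = 1.0, 1.0
    for ep in active_episodes:
        if ep.spec.med_class in CORTICOSTEROIDS:
            g *= ep.spec.gamma_mult
            s *= ep.spec.sens_mult
    return g, s


def schedule_controller_doses(
    prescription: Prescription,
    spec: MedicationSpec,
    horizon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Dose times (days) for a scheduled controller over [0, horizon).

    Each calendar day is taken with probability ``prescription.adherence``
    (one coin per day; all of that day's doses follow it).  Doses are evenly
    spaced within the day: 1/day at noon; 2/day at 06:00 and 18:00, etc.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    per_day = spec.schedule
    if per_day <= 0:
        return np.empty(0)
    n_days = int(np.ceil(horizon))
    taken = taken_day_mask(prescription.adherence, n_days, rng)
    offsets = (np.arange(per_day) + 0.5) / per_day
    days = np.nonzero(taken)[0]
    times = (days[:, None] + offsets[None, :]).ravel()
    return times[times < horizon]


def taken_day_mask(
    adherence: float, n_days: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of dose-days under per-day Bernoulli adherence."""
    if adherence >= 1.0:
        return np.ones(n_days, dtype=bool)
    if adherence <= 0.0:
        return np.zeros(n_days, dtype=bool)
    return rng.random(n_days) < adherence


def start_ocs_course(
    t: float, spec: MedicationSpec, course_days: int = 5
) -> list[MedicationEpisode]:
    """Consecutive daily oral-steroid episodes covering [t, t + course_days).

    Issued at hospital discharge (and, configurably, after urgent visits).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    return [
        MedicationEpisode(spec, start=t + k, end=t + k + 1)
        for k in range(int(course_days))
    ]
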