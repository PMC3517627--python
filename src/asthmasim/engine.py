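"""Event-driven simulation of one virtual patient.

The engine advances a patient's impairment level I analytically between
discrete events — trigger jumps, controller-coverage boundaries, hospital
discharges — rather than stepping time.  Under the chosen forms
(Q = exp(-I/sigma), piecewise-constant sigma and gamma) pulmonary function
can fall only at jump or coverage-expiry instants, so threshold crossings
are detected exactly with closed-form crossing times and the simulation is
exact up to floating point.  A brute-force fixed-step reference engine
(:mod:`asthmasim.reference`) mirrors the same rules for testing.

Relief-medication cascades: once Q drops below the relief threshold the
patient takes a short-acting bronchodilator immediately, and again at each
expiry of the previous dose while still below the threshold.  Within an
inter-event interval the number and times of these doses have closed form,
so heavy reliever users cost no more than light ones.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import rng as rngmod
from .behavior import BehaviorProfile, HospitalPolicy, LungAnchors, impairment_threshold
from .dynamics import PhysiologyParams
from .meds import (
    MedicationCatalog,
    Prescription,
    taken_day_mask,
)

__all__ = [
    "VirtualPatient",
    "OutcomeSummary",
    "EventLog",
    "EngineOptions",
    "SimInputs",
    "make_streams",
    "prepare_inputs",
    "simulate_patient",
    "summarize",
]

# event kinds, processed in this priority order at equal times
EVT_COV_ON = 0
EVT_COV_OFF = 1
EVT_OCS_OFF = 2
EVT_DISCHARGE = 3
EVT_STIM = 4
EVT_RECHECK = 5  # washout expiry: re-present if still below threshold
EVT_END = 9


@dataclass
class VirtualPatient:
    """One simulated individual: demographics, physiology, behavior, meds.

    ``physiology`` and ``behavior`` are None until calibration assigns them;
    ``targets`` carries the individual's past-year utilization rates (the
    calibration targets).  ``z`` is the latent severity score used by the
    population generator.
    """

    id: int
    age: float
    sex: str
    smoker: bool = False
    physiology: Optional[PhysiologyParams] = None
    anchors: Optional[LungAnchors] = None
    behavior: Optional[BehaviorProfile] = None
    prescriptions: list = field(default_factory=list)
    targets: object = None
    fev1_pct_pred: float = float("nan")
    z: float = 0.0
    calibration_distance: float = float("nan")

    @property
    def adolescent(self) -> bool:
        return 12 <= self.age < 18

    @property
    def calibrated(self) -> bool:
        return self.physiology is not None and self.behavior is not None

    def prescription_for(self, med_class: str) -> Optional[Prescription]:
        for p in self.prescriptions:
            if p.med_class == med_class:
                return p
        return None

    def has_controller(self) -> bool:
        return any(p.med_class in ("ICS", "LABA") for p in self.prescriptions)


@dataclass
class OutcomeSummary:
    """Annualized per-patient outcome rates (Table-style row)."""

    reliever_uses_per_day: float
    controller_use_days_per_day: float
    md_visits_per_year: float
    ed_visits_per_year: float
    hospitalizations_per_year: float
    failure_time: Optional[float]

    def __post_init__(self) -> None:
        if self.hospitalizations_per_year > self.ed_visits_per_year + 1e-12:
            raise ValueError("hospitalizations cannot exceed ED visits")


@dataclass
class EventLog:
    """Counters plus (optionally) the full timestamped event list."""

    horizon: float
    reliever_uses: int = 0
    md_visits: int = 0
    ed_visits: int = 0
    hospitalizations: int = 0
    controller_use_days: int = 0
    failure_time: Optional[float] = None
    final_I: float = 0.0
    rows: Optional[list] = None  # (time, event, value) when collected

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows or [], columns=["time", "event", "value"]
        ).sort_values("time", kind="stable", ignore_index=True)


@dataclass(frozen=True)
class EngineOptions:
    """Behavioral/care policy knobs shared by a whole run."""

    ocs_after_md: bool = True
    ocs_after_ed: bool = True
    ocs_course_days: int = 5
    collect_log: bool = True
    initial_condition: str = "stationary"  # "stationary" or "zero"
    initial_I: float | None = None  # overrides initial_condition when set


@dataclass
class SimInputs:
    """Pre-sampled stochastic inputs shared by the event-driven engine and
    the fixed-step reference engine (common random numbers)."""

    stim_times: np.ndarray
    stim_units: np.ndarray  # unit-exponential draws, scaled at jump time
    cov_runs: dict  # med_class -> (starts, ends) arrays in days
    controller_dose_days: np.ndarray  # sorted day indices with >=1 controller dose
    care_rng: np.random.Generator


def make_streams(
    master_seed: int, patient_id: int, scenario: str | None = None
) -> dict:
    """Named substream bundle for one patient in one scenario.

    Physiological streams (stimuli, effect sizes) ignore the scenario so all
    four scenarios share them (common random numbers); adherence coins are
    scenario-keyed (scenarios change how they are consumed).  The care stream
    (admission coin, length of stay) is also patient-keyed only: the k-th ED
    presentation draws the k-th disposition in every scenario, so a scenario
    with fewer ED visits can never record more admissions.
    """
    return {
        "stimuli": rngmod.substream(master_seed, patient_id, "stimuli"),
        "effects": rngmod.substream(master_seed, patient_id, "effect_sizes"),
        "adherence": rngmod.substream(master_seed, patient_id, "adherence", scenario),
        "care": rngmod.substream(master_seed, patient_id, "care"),
    }


def _mask_to_runs(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge a boolean day mask into (starts, ends) of consecutive runs."""
    if not mask.any():
        return np.empty(0), np.empty(0)
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0].astype(float)
    ends = np.nonzero(d == -1)[0].astype(float)
    return starts, ends


def prepare_inputs(
    patient: VirtualPatient,
    horizon: float,
    catalog: MedicationCatalog,
    streams: dict,
) -> SimInputs:
    """Sample every exogenous random input for one simulation up front."""
    phys = patient.physiology
    stim_times = np.sort(streams["stimuli"].uniform(0.0, horizon, size=streams["stimuli"].poisson(phys.lam * horizon)))
    stim_units = streams["effects"].standard_exponential(size=len(stim_times))
    n_days = int(np.ceil(horizon))
    cov_runs = {}
    masks = []
    for p in patient.prescriptions:
        if p.med_class in ("ICS", "LABA"):
            spec = catalog[p.med_class]
            if spec.schedule <= 0:
                continue
            mask = taken_day_mask(p.adherence, n_days, streams["adherence"])
            masks.append(mask)
            cov_runs[p.med_class] = _mask_to_runs(mask)
    if masks:
        union = np.zeros(n_days, dtype=bool)
        for m in masks:
            union |= m
        dose_days = np.nonzero(union)[0]
        dose_days = dose_days[dose_days < horizon]
    else:
        dose_days = np.empty(0, dtype=int)
    return SimInputs(
        stim_times=stim_times,
        stim_units=stim_units,
        cov_runs=cov_runs,
        controller_dose_days=dose_days,
        care_rng=streams["care"],
    )


class _EventEngine:
    def __init__(
        self,
        patient: VirtualPatient,
        horizon: float,
        catalog: MedicationCatalog,
        inputs: SimInputs,
        policy: HospitalPolicy,
        options: EngineOptions,
    ):
        if not patient.calibrated:
            raise ValueError(
                f"patient {patient.id} has no physiology/behavior parameters; "
                "calibrate before simulating"
            )
        self.p = patient
        self.horizon = float(horizon)
        self.cat = catalog
        self.inp = inputs
        self.policy = policy
        self.opt = options

        phys = patient.physiology
        beh = patient.behavior
        self.gamma0 = phys.gamma
        self.mean_alpha = phys.mean_alpha
        self.I_rel = impairment_threshold(beh.q_relief)
        self.I_md = impairment_threshold(beh.q_md)
        self.I_ed = impairment_threshold(beh.q_ed)
        self.washout = beh.washout

        self.g_ics = catalog["ICS"].gamma_mult
        self.s_ics = catalog["ICS"].sens_mult
        self.g_ocs = catalog["OCS"].gamma_mult
        self.s_ocs = catalog["OCS"].sens_mult
        self.b_laba = catalog["LABA"].broncho_beta
        self.dur_saba = catalog["SABA"].duration_days

        self.log = EventLog(
            horizon=self.horizon,
            controller_use_days=int(len(inputs.controller_dose_days)),
            rows=[] if options.collect_log else None,
        )

        # dynamic state
        self.t = 0.0
        if options.initial_I is not None:
            self.I = float(options.initial_I)
        elif options.initial_condition == "stationary":
            self.I = phys.stationary_mean
        else:
            self.I = 0.0
        self.ics_on = False
        self.laba_on = False
        self.ocs_until = -math.inf
        self.hosp_until: Optional[float] = None
        self.next_saba: Optional[float] = None
        self.rearm_at = {"md": -math.inf, "ed": -math.inf}
        self.rearm_pending = {"md": False, "ed": False}
        self._seq = 0
        self.heap: list = []

    # -- bookkeeping -------------------------------------------------------

    @property
    def gamma_eff(self) -> float:
        g = self.gamma0
        if self.ics_on:
            g *= self.g_ics
        if self.t < self.ocs_until:
            g *= self.g_ocs
        return g

    @property
    def sens_now(self) -> float:
        s = 1.0
        if self.ics_on:
            s *= self.s_ics
        if self.t < self.ocs_until:
            s *= self.s_ocs
        return s

    @property
    def sigma_ctrl(self) -> float:
        return 1.0 + (self.b_laba if self.laba_on else 0.0)

    def _push(self, t: float, kind: int, a: float = 0.0):
        self._seq += 1
        heapq.heappush(self.heap, (t, kind, self._seq, a))

    def _emit(self, t: float, event: str, value) -> None:
        if self.log.rows is not None:
            self.log.rows.append((t, event, value))

    # -- time advance ------------------------------------------------------

    def _advance(self, t1: float) -> None:
        t0 = self.t
        if t1 <= t0:
            # stale event (e.g. a washout re-check scheduled inside an
            # interval that was already advanced past): never rewind time
            return
        if self.hosp_until is not None and t0 < self.hosp_until:
            # inpatient: pulmonary function held stable, no reliever use
            self.t = t1
            return
        g = self.gamma_eff
        I0 = self.I
        thr_rel = self.sigma_ctrl * self.I_rel
        # relief-medication cascade within (t0, t1]
        if self.next_saba is not None:
            if I0 > thr_rel:
                t_exit = t0 + math.log(I0 / thr_rel) / g
            else:
                t_exit = t0
            limit = min(t1, t_exit)
            tau = self.next_saba
            if tau <= limit:
                n = int(math.floor((limit - tau) / self.dur_saba)) + 1
                taus = tau + self.dur_saba * np.arange(n)
                taus = taus[taus < t_exit]
                n = len(taus)
                if n:
                    self.log.reliever_uses += n
                    if self.log.rows is not None:
                        for x in taus:
                            self.log.rows.append((float(x), "reliever_use", "SABA"))
                    self.next_saba = float(taus[-1]) + self.dur_saba
            if t_exit <= t1:
                self.next_saba = None
        # threshold re-arming after an encounter: the encounter type becomes
        # available again ``washout`` days after I recovers above->below its
        # threshold
        for typ, I_q in (("md", self.I_md), ("ed", self.I_ed)):
            if self.rearm_pending[typ]:
                thr = self.sigma_ctrl * I_q
                if I0 <= thr:
                    tc = t0
                else:
                    tc = t0 + math.log(I0 / thr) / g
                if tc <= t1:
                    self.rearm_at[typ] = tc + self.washout
                    self.rearm_pending[typ] = False
                    # if the patient is back below threshold when the washout
                    # expires, they re-present then rather than waiting for
                    # the next trigger
                    self._push(tc + self.washout, EVT_RECHECK)
        self.I = I0 * math.exp(-g * (t1 - t0))
        self.t = t1

    # -- encounter logic ---------------------------------------------------

    def _disarm(self, typ: str) -> None:
        self.rearm_at[typ] = math.inf
        self.rearm_pending[typ] = True

    def _armed(self, typ: str) -> bool:
        return self.t >= self.rearm_at[typ]

    def _start_ocs(self) -> None:
        end = self.t + self.opt.ocs_course_days
        if end > self.ocs_until:
            self.ocs_until = end
            self._push(end, EVT_OCS_OFF)
        if self.log.rows is not None:
            for k in range(self.opt.ocs_course_days):
                self.log.rows.append((self.t + k, "dose", "OCS"))

    def _check_thresholds(self) -> None:
        """Evaluate zones after any event that can lower Q; trigger care.

        Care-seeking is evaluated against the controller-adjusted
        bronchodilator factor only: an active relief dose eases symptoms but
        does not mask the decision to seek care.  (It also keeps downward
        threshold crossings confined to jump/coverage instants, which the
        event queue observes.)
        """
        if self.hosp_until is not None and self.t < self.hosp_until:
            return
        sig = self.sigma_ctrl
        I = self.I
        t = self.t
        if I > sig * self.I_md and self.log.failure_time is None:
            self.log.failure_time = t
            self._emit(t, "failure", "")
        if I > sig * self.I_ed and self._armed("ed"):
            self._ed_visit()
        elif I > sig * self.I_md and self._armed("md"):
            self.log.md_visits += 1
            self._emit(t, "md_visit", "")
            self._disarm("md")
            if self.opt.ocs_after_md:
                self._start_ocs()
        # relief cascade start
        if (
            self.next_saba is None
            and (self.hosp_until is None or self.t >= self.hosp_until)
            and I > self.sigma_ctrl * self.I_rel
        ):
            self.log.reliever_uses += 1
            self._emit(t, "reliever_use", "SABA")
            self.next_saba = t + self.dur_saba

    def _ed_visit(self) -> None:
        t = self.t
        self.log.ed_visits += 1
        self._emit(t, "ed_visit", "")
        self._disarm("ed")
        self._disarm("md")  # one excursion: the ED visit subsumes md care
        if self.inp.care_rng.random() < self.policy.p_admit:
            los = int(self.inp.care_rng.geometric(1.0 / self.policy.los_mean))
            self.log.hospitalizations += 1
            self._emit(t, "admit", los)
            self.hosp_until = t + los
            self.next_saba = None
            self._push(self.hosp_until, EVT_DISCHARGE)
        else:
            if self.opt.ocs_after_ed:
                self._start_ocs()

    # -- main loop ---------------------------------------------------------

    def run(self) -> EventLog:
        for i, s in enumerate(self.inp.stim_times):
            self._push(float(s), EVT_STIM, float(self.inp.stim_units[i]))
        for cls, (starts, ends) in self.inp.cov_runs.items():
            code = 0 if cls == "ICS" else 1
            for s, e in zip(starts, ends):
                if s < self.horizon:
                    self._push(float(s), EVT_COV_ON, code)
                    self._push(float(min(e, self.horizon)), EVT_COV_OFF, code)
        if self.log.rows is not None:
            for d in self.inp.controller_dose_days:
                self.log.rows.append((float(d) + 0.25, "dose", "controller"))
        self._push(self.horizon, EVT_END)

        self._check_thresholds()  # initial condition may already be symptomatic
        while self.heap:
            t_ev, kind, _, a = heapq.heappop(self.heap)
            if t_ev > self.horizon:
                break
            self._advance(t_ev)
            if kind == EVT_END:
                break
            if kind == EVT_STIM:
                if self.hosp_until is not None and self.t < self.hosp_until:
                    continue  # inpatient: function held stable
                alpha = a * self.mean_alpha * self.sens_now
                self.I += alpha
                self._emit(t_ev, "stimulus", alpha)
                self._check_thresholds()
            elif kind == EVT_COV_ON:
                if a == 0:
                    self.ics_on = True
                else:
                    self.laba_on = True
            elif kind == EVT_COV_OFF:
                if a == 0:
                    self.ics_on = False
                else:
                    self.laba_on = False
                    self._check_thresholds()  # sigma dropped; Q fell
            elif kind == EVT_OCS_OFF:
                pass  # gamma_eff/sens_now read ocs_until directly
            elif kind == EVT_RECHECK:
                self._check_thresholds()
            elif kind == EVT_DISCHARGE:
                if self.hosp_until is not None and t_ev >= self.hosp_until:
                    self.hosp_until = None
                    self._emit(t_ev, "discharge", "")
                    self._start_ocs()
                    # function resumes at the (still elevated) frozen level:
                    # restart the relief cascade if warranted
                    self._check_thresholds()
        self.log.final_I = self.I
        return self.log


def simulate_patient(
    patient: VirtualPatient,
    horizon: float,
    catalog: MedicationCatalog,
    streams: dict,
    policy: HospitalPolicy | None = None,
    options: EngineOptions | None = None,
    inputs: SimInputs | None = None,
) -> EventLog:
    """Simulate one calibrated patient over ``horizon`` days.

    ``streams`` is the substream bundle from :func:`make_streams`; passing
    pre-built ``inputs`` lets callers reuse a sampled input set (e.g. the
    fixed-step reference comparison).
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    if not patient.calibrated:
        raise ValueError(
            f"patient {patient.id} has no physiology/behavior parameters; "
            "calibrate before simulating"
        )
    policy = policy or HospitalPolicy()
    options = options or EngineOptions()
    if inputs is None:
        inputs = prepare_inputs(patient, horizon, catalog, streams)
    eng = _EventEngine(patient, horizon, catalog, inputs, policy, options)
    return eng.run()


def summarize(log: EventLog, horizon: float | None = None) -> OutcomeSummary:
    """Annualized outcome rates from an event log."""
    T = float(horizon if horizon is not None else log.horizon)
    if T <= 0:
        raise ValueError("horizon must be > 0")
    years = T / 365.0
    return OutcomeSummary(
        reliever_uses_per_day=log.reliever_uses / T,
        controller_use_days_per_day=log.controller_use_days / T,
        md_visits_per_year=log.md_visits / years,
        ed_visits_per_year=log.ed_visits / years,
        hospitalizations_per_year=log.hospitalizations / years,
        failure_time=log.failure_time,
    )
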