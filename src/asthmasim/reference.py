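"""Brute-force fixed-step reference simulator.

An independent re-implementation of the patient simulation as a plain
time-stepping state machine: impairment decays by the per-step factor
exp(-gamma_eff*dt), trigger jumps land on their nearest grid point, and
every behavioral rule (relief cascade, care thresholds, washout re-arming,
inpatient freezing, discharge steroids) is evaluated step by step instead of
with closed-form crossing times.  It consumes the same pre-sampled inputs
(:class:`asthmasim.engine.SimInputs`) as the event-driven engine, so the two
can be compared trajectory-for-trajectory; agreement validates the
event-driven engine's closed-form event logic.

Intended for tests and small runs only — cost scales with horizon/dt.
"""

from __future__ import annotations

import math

import numpy as np

from .behavior import HospitalPolicy, impairment_threshold
from .engine import EngineOptions, EventLog, SimInputs, VirtualPatient
from .meds import MedicationCatalog

__all__ = ["simulate_patient_fixed_step"]


def simulate_patient_fixed_step(
    patient: VirtualPatient,
    horizon: float,
    catalog: MedicationCatalog,
    inputs: SimInputs,
    policy: HospitalPolicy | None = None,
    options: EngineOptions | None = None,
    dt: float = 1e-3,
) -> EventLog:
    policy = policy or HospitalPolicy()
    options = options or EngineOptions(collect_log=False)

    phys = patient.physiology
    beh = patient.behavior
    I_rel = impairment_threshold(beh.q_relief)
    I_md = impairment_threshold(beh.q_md)
    I_ed = impairment_threshold(beh.q_ed)
    g_ics, s_ics = catalog["ICS"].gamma_mult, catalog["ICS"].sens_mult
    g_ocs, s_ocs = catalog["OCS"].gamma_mult, catalog["OCS"].sens_mult
    b_laba = catalog["LABA"].broncho_beta
    dur_saba = catalog["SABA"].duration_days

    n_steps = int(round(horizon / dt))
    # each jump is applied at its exact time within the enclosing step
    # (decay split around it); behavior rules are still evaluated per step
    stim_steps = np.minimum(
        np.ceil(inputs.stim_times / dt).astype(int), n_steps
    )
    order = np.argsort(stim_steps, kind="stable")
    stim_steps = stim_steps[order]
    stim_times = inputs.stim_times[order]
    stim_units = inputs.stim_units[order]

    # per-day coverage masks
    n_days = int(np.ceil(horizon))
    cov = {}
    for cls, (starts, ends) in inputs.cov_runs.items():
        mask = np.zeros(n_days + 1, dtype=bool)
        for s, e in zip(starts, ends):
            mask[int(s) : int(e)] = True
        cov[cls] = mask

    log = EventLog(
        horizon=horizon,
        controller_use_days=int(len(inputs.controller_dose_days)),
        rows=[] if options.collect_log else None,
    )

    def emit(t_, kind, val=""):
        if log.rows is not None:
            log.rows.append((t_, kind, val))

    if options.initial_I is not None:
        I = float(options.initial_I)
    elif options.initial_condition == "stationary":
        I = phys.stationary_mean
    else:
        I = 0.0
    t = 0.0
    hosp_until = None
    next_saba = None
    rearm_at = {"md": -math.inf, "ed": -math.inf}
    rearm_pending = {"md": False, "ed": False}
    ocs_until = -math.inf
    ptr = 0
    n_stim = len(stim_steps)

    def cov_at(day: int, cls: str) -> bool:
        m = cov.get(cls)
        return bool(m[day]) if (m is not None and day < len(m)) else False

    def start_ocs(now: float):
        nonlocal ocs_until
        ocs_until = max(ocs_until, now + options.ocs_course_days)

    for k in range(n_steps + 1):
        t = k * dt
        day = min(int(t), n_days - 1) if n_days else 0
        ics_on = cov_at(day, "ICS")
        laba_on = cov_at(day, "LABA")
        gamma_eff = phys.gamma * (g_ics if ics_on else 1.0) * (
            g_ocs if t < ocs_until else 1.0
        )
        sens_now = (s_ics if ics_on else 1.0) * (s_ocs if t < ocs_until else 1.0)
        sigma_ctrl = 1.0 + (b_laba if laba_on else 0.0)

        inpatient = hosp_until is not None and t < hosp_until
        if hosp_until is not None and t >= hosp_until:
            hosp_until = None
            start_ocs(t)

        if k > 0 and not inpatient:
            # decay across the step, split exactly at any jumps inside it
            t_prev = (k - 1) * dt
            while ptr < n_stim and stim_steps[ptr] == k:
                s = stim_times[ptr]
                I *= math.exp(-gamma_eff * (s - t_prev))
                I += stim_units[ptr] * phys.mean_alpha * sens_now
                t_prev = s
                ptr += 1
            I *= math.exp(-gamma_eff * (t - t_prev))
        elif k > 0:
            while ptr < n_stim and stim_steps[ptr] == k:
                ptr += 1  # inpatient: function held stable, triggers ignored

        if inpatient:
            continue

        # washout re-arming
        for typ, I_q in (("md", I_md), ("ed", I_ed)):
            if rearm_pending[typ] and I <= sigma_ctrl * I_q:
                rearm_at[typ] = t + beh.washout
                rearm_pending[typ] = False

        # care thresholds use the controller-adjusted factor only (an active
        # relief dose does not mask care-seeking)
        if I > sigma_ctrl * I_md and log.failure_time is None:
            log.failure_time = t
        if I > sigma_ctrl * I_ed and t >= rearm_at["ed"]:
            log.ed_visits += 1
            rearm_at["ed"] = math.inf
            rearm_pending["ed"] = True
            rearm_at["md"] = math.inf
            rearm_pending["md"] = True
            emit(t, "ed_visit")
            if inputs.care_rng.random() < policy.p_admit:
                los = int(inputs.care_rng.geometric(1.0 / policy.los_mean))
                log.hospitalizations += 1
                emit(t, "admit", los)
                hosp_until = t + los
                next_saba = None
            else:
                if options.ocs_after_ed:
                    start_ocs(t)
        elif I > sigma_ctrl * I_md and t >= rearm_at["md"]:
            log.md_visits += 1
            emit(t, "md_visit")
            rearm_at["md"] = math.inf
            rearm_pending["md"] = True
            if options.ocs_after_md:
                start_ocs(t)

        # relief cascade (not while being admitted this very step)
        if hosp_until is not None:
            continue
        if next_saba is None:
            if I > sigma_ctrl * I_rel:
                log.reliever_uses += 1
                emit(t, "reliever_use", "SABA")
                next_saba = t + dur_saba
        elif t >= next_saba:
            if I > sigma_ctrl * I_rel:
                log.reliever_uses += 1
                emit(t, "reliever_use", "SABA")
                next_saba = next_saba + dur_saba
            else:
                next_saba = None

    log.final_I = I
    return log
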