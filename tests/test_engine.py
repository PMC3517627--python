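"""Event-driven patient engine: construction cases, pairing properties,
inpatient freezing, and the fixed-step brute-force oracle."""

import dataclasses

import numpy as np
import pytest

from asthmasim.behavior import BehaviorProfile, HospitalPolicy, LungAnchors
from asthmasim.dynamics import PhysiologyParams
from asthmasim.engine import (
    EngineOptions,
    EventLog,
    SimInputs,
    VirtualPatient,
    make_streams,
    prepare_inputs,
    simulate_patient,
    summarize,
)
from asthmasim.meds import Prescription
from asthmasim.reference import simulate_patient_fixed_step

from conftest import make_patient


def forced_inputs(times, units, care_seed=0):
    """Inputs with hand-chosen trigger times/sizes and no controller use."""
    return SimInputs(
        stim_times=np.asarray(times, dtype=float),
        stim_units=np.asarray(units, dtype=float),
        cov_runs={},
        controller_dose_days=np.empty(0, dtype=int),
        care_rng=np.random.default_rng(care_seed),
    )


class TestConstruction:
    def test_no_stimuli_stays_well(self, catalog):
        p = make_patient(lam=0.0)
        log = simulate_patient(p, 365, catalog, make_streams(0, 0))
        assert log.reliever_uses == 0
        assert log.md_visits == log.ed_visits == log.hospitalizations == 0
        assert log.failure_time is None
        assert log.final_I == 0.0  # stationary mean is 0 at lam=0

    def test_uncalibrated_patient_rejected(self, catalog):
        p = VirtualPatient(id=9, age=30, sex="male")
        with pytest.raises(ValueError, match="calibrate"):
            simulate_patient(p, 10, catalog, make_streams(0, 9))

    def test_single_relief_excursion(self, catalog):
        # jump lands between the relief and immediate-care thresholds:
        # exactly one reliever cascade, no encounters
        p = make_patient(lam=0.01, mean_alpha=1.0)
        I_relief = -np.log(p.behavior.q_relief)  # 0.1625
        I_md = -np.log(p.behavior.q_md)  # 0.5108
        alpha = 0.5 * (I_relief + I_md)
        opts = EngineOptions(collect_log=True, initial_condition="zero")
        inputs = forced_inputs([10.0], [alpha / p.physiology.mean_alpha])
        log = simulate_patient(
            p, 60, catalog, make_streams(0, 0), options=opts, inputs=inputs
        )
        assert log.reliever_uses >= 1
        assert log.md_visits == 0 and log.ed_visits == 0
        assert log.failure_time is None
        first_dose = min(t for t, k, v in log.rows if k == "reliever_use")
        assert first_dose == pytest.approx(10.0)

    def test_deep_excursion_fails_and_seeks_care(self, catalog):
        p = make_patient(lam=0.01, mean_alpha=1.0)
        I_ed = -np.log(p.behavior.q_ed)
        opts = EngineOptions(collect_log=True, initial_condition="zero")
        inputs = forced_inputs([5.0], [2.0 * I_ed / p.physiology.mean_alpha])
        log = simulate_patient(
            p, 30, catalog, make_streams(0, 0),
            policy=HospitalPolicy(p_admit=0.0), options=opts, inputs=inputs,
        )
        assert log.ed_visits == 1
        assert log.failure_time == pytest.approx(5.0)

    def test_bit_identical_reruns(self, catalog, treated_patient):
        a = simulate_patient(treated_patient, 365, catalog, make_streams(8, 1))
        b = simulate_patient(treated_patient, 365, catalog, make_streams(8, 1))
        assert a.rows == b.rows
        assert a.final_I == b.final_I


class TestPairing:
    def test_controller_never_hurts(self, catalog):
        """With common trigger streams, adding a fully adherent controller
        cannot increase reliever use or encounters."""
        worse = 0
        for seed in range(20):
            base = make_patient(pid=seed, lam=0.4, mean_alpha=0.4)
            treated = dataclasses.replace(
                base, prescriptions=[Prescription("ICS", "medium", 1.0)]
            )
            la = simulate_patient(base, 365, catalog, make_streams(seed, seed))
            lb = simulate_patient(treated, 365, catalog, make_streams(seed, seed))
            enc_a = la.md_visits + la.ed_visits + la.hospitalizations
            enc_b = lb.md_visits + lb.ed_visits + lb.hospitalizations
            if enc_b > enc_a or lb.reliever_uses > la.reliever_uses:
                worse += 1
        assert worse == 0


class TestInpatientFreezing:
    def test_function_held_stable_during_stay(self, catalog):
        p = make_patient(lam=0.3, mean_alpha=1.2)
        opts = EngineOptions(collect_log=True)
        log = simulate_patient(
            p, 730, catalog, make_streams(5, 0),
            policy=HospitalPolicy(p_admit=1.0, los_mean=3.0), options=opts,
        )
        assert log.hospitalizations >= 1
        admits = [(t, v) for t, k, v in log.rows if k == "admit"]
        discharges = [t for t, k, v in log.rows if k == "discharge"]
        for (t_in, los), t_out in zip(admits, discharges):
            assert t_out == pytest.approx(t_in + los)
            # no reliever use while inpatient
            assert not any(
                t_in < t < t_out
                for t, k, v in log.rows
                if k in ("reliever_use", "stimulus")
            )
            # a discharge steroid course follows
            assert any(
                t == pytest.approx(t_out) and v == "OCS"
                for t, k, v in log.rows
                if k == "dose"
            )


class TestSummarize:
    def test_empty_log_is_all_zero(self):
        s = summarize(EventLog(horizon=365.0))
        assert s.md_visits_per_year == 0 and s.reliever_uses_per_day == 0

    def test_annualization(self):
        log = EventLog(horizon=365.0, ed_visits=3, hospitalizations=1)
        s = summarize(log)
        assert s.ed_visits_per_year == pytest.approx(3.0)
        assert s.hospitalizations_per_year == pytest.approx(1.0)

    def test_controller_use_days_fraction(self):
        log = EventLog(horizon=365.0, controller_use_days=294)
        s = summarize(log)
        assert s.controller_use_days_per_day == pytest.approx(0.805, abs=5e-4)

    def test_hospitalizations_cannot_exceed_ed(self):
        with pytest.raises(ValueError):
            summarize(EventLog(horizon=365.0, ed_visits=1, hospitalizations=2))


class TestFixedStepOracle:
    def test_event_engine_matches_brute_force(self, catalog):
        """Event-driven simulation agrees with per-step brute force on
        encounter counts (exactly), reliever uses, and final impairment."""
        rng = np.random.default_rng(42)
        pol = HospitalPolicy(p_admit=0.3, los_mean=3.0)
        opts = EngineOptions(collect_log=False)
        for i in range(50):
            phys = PhysiologyParams(
                gamma=float(rng.uniform(0.1, 0.8)),
                lam=float(rng.uniform(0.05, 1.0)),
                mean_alpha=float(rng.uniform(0.05, 0.6)),
            )
            q = (
                float(rng.uniform(0.8, 0.9)),
                float(rng.uniform(0.55, 0.7)),
                float(rng.uniform(0.35, 0.5)),
            )
            rx = []
            if rng.random() < 0.5:
                rx.append(Prescription("ICS", "medium", float(rng.uniform(0.5, 1.0))))
            if rng.random() < 0.3:
                rx.append(Prescription("LABA", "medium", float(rng.uniform(0.5, 1.0))))
            p = make_patient(
                pid=i, gamma=phys.gamma, lam=phys.lam, mean_alpha=phys.mean_alpha,
                q=q, prescriptions=rx,
            )
            ev = simulate_patient(p, 60.0, catalog, make_streams(7, i), pol, opts)
            inputs = prepare_inputs(p, 60.0, catalog, make_streams(7, i))
            fs = simulate_patient_fixed_step(
                p, 60.0, catalog, inputs, pol, opts, dt=1e-3
            )
            assert (ev.md_visits, ev.ed_visits, ev.hospitalizations) == (
                fs.md_visits, fs.ed_visits, fs.hospitalizations,
            ), f"encounter mismatch for patient {i}"
            assert abs(ev.reliever_uses - fs.reliever_uses) <= max(
                3, 0.03 * fs.reliever_uses
            )
            assert ev.final_I == pytest.approx(
                fs.final_I, rel=5e-3, abs=1e-4
            )
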