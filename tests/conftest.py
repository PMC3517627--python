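"""Shared fixtures: medication catalog, small calibrated population, and the
end-to-end pipeline used by the acceptance tests.

The pipeline fixture is session-scoped and deliberately smaller than a full
survey-scale run (calibration dominates the cost); sizes are chosen so the
whole suite stays well inside a routine CI budget while population means
remain statistically meaningful.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from asthmasim.behavior import BehaviorProfile, HospitalPolicy, LungAnchors
from asthmasim.calibrate import (
    TreatmentEffectTargets,
    calibrate_population,
    calibrate_treatment_effects,
    default_effect_grid,
)
from asthmasim.config import load_config
from asthmasim.dynamics import PhysiologyParams
from asthmasim.engine import EngineOptions, VirtualPatient
from asthmasim.meds import Prescription
from asthmasim.population import generate_population
from asthmasim.scenarios import population_outcomes


@pytest.fixture(scope="session")
def catalog():
    return load_config(None).catalog


@pytest.fixture(scope="session")
def run_config():
    return load_config(None)


def make_patient(
    pid=0,
    gamma=0.4,
    lam=0.3,
    mean_alpha=0.3,
    q=(0.85, 0.6, 0.4),
    prescriptions=(),
) -> VirtualPatient:
    return VirtualPatient(
        id=pid,
        age=40.0,
        sex="female",
        physiology=PhysiologyParams(gamma=gamma, lam=lam, mean_alpha=mean_alpha),
        anchors=LungAnchors(fev1_best=2.7, fev1_floor=0.7),
        behavior=BehaviorProfile(*q),
        prescriptions=list(prescriptions),
    )


@pytest.fixture
def simple_patient():
    return make_patient()


@pytest.fixture
def treated_patient():
    return make_patient(
        pid=1,
        prescriptions=[
            Prescription("ICS", "medium", 0.8),
            Prescription("LABA", "medium", 0.85),
        ],
    )


@pytest.fixture(scope="session")
def pipeline(run_config):
    """Generate, calibrate, tune and simulate a reduced population once.

    Returns a dict with the calibrated population, fitted admission policy,
    shipped and tuned catalogs, and population outcome rates per scenario.
    """
    cfg = run_config
    from asthmasim.population import default_marginals

    marg = dataclasses.replace(default_marginals(), n=450)
    pop = generate_population(marg, seed=202)
    cal, report = calibrate_population(
        pop, cfg.calibration, cfg.catalog, master_seed=31
    )
    policy = HospitalPolicy(p_admit=report["p_admit"])
    options = EngineOptions(collect_log=False)
    oo = population_outcomes(cal, cfg.catalog, 57, "OO", policy=policy, options=options)
    targets = TreatmentEffectTargets(1.06, 0.29, 0.09, 1.09)
    tuned, tune_report = calibrate_treatment_effects(
        cal, targets, default_effect_grid(), 57, cfg.catalog, policy=policy,
        options=options,
    )
    out = {
        "population": pop,
        "calibrated": cal,
        "policy": policy,
        "report": report,
        "catalog": cfg.catalog,
        "tuned": tuned,
        "OO": oo,
    }
    for scen in ("OP", "EO", "EP"):
        out[scen] = population_outcomes(
            cal, tuned, 57, scen, policy=policy, options=options
        )
    out["OO_tuned"] = population_outcomes(
        cal, tuned, 57, "OO", policy=policy, options=options
    )
    return out
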