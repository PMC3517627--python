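"""Clinical-trial harness: run-in plus randomized-arm protocols.

Simulates controller-trial designs of the run-in/randomize/follow-up form:
a calibrated population is resampled with replacement to the trial size,
each sampled participant is simulated through a run-in period under their
own observed medications (so the state at randomization reflects usual
care), then through the assigned arm's phase schedule.  Treatment failure
is the first passage of pulmonary function below the participant's
immediate-care threshold during follow-up; participants without failure are
censored at the end of follow-up.

Two classic designs are provided as builders: a three-arm
placebo/long-acting-bronchodilator/inhaled-corticosteroid substitution
design, and a two-arm salmeterol +/- triamcinolone design whose follow-up
splits into a corticosteroid-reduction phase (half-strength) and an
elimination phase.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import HospitalPolicy
from .engine import EngineOptions, VirtualPatient, make_streams, simulate_patient
from .meds import MedicationCatalog, Prescription
from .rng import substream

__all__ = [
    "TrialPhase",
    "TrialArm",
    "TrialProtocol",
    "run_trial",
    "halve_ics_effect",
    "socs_like_protocol",
    "slic_like_protocol",
]


@dataclass(frozen=True)
class TrialPhase:
    """One follow-up phase: duration, assigned prescriptions, and an
    optional transform of the medication catalog (e.g. dose halving)."""

    duration_days: float
    prescriptions: tuple
    catalog_transform: object = None  # callable(catalog) -> catalog

    def catalog_for(self, catalog: MedicationCatalog) -> MedicationCatalog:
        if self.catalog_transform is None:
            return catalog
        return self.catalog_transform(catalog)


@dataclass(frozen=True)
class TrialArm:
    name: str
    phases: tuple


@dataclass(frozen=True)
class TrialProtocol:
    run_in_days: float
    arms: tuple
    n_participants: int = 300

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError("protocol needs at least one arm")
        durations = {sum(ph.duration_days for ph in a.phases) for a in self.arms}
        if len(durations) != 1:
            raise ValueError("arms must share a common follow-up length")

    @property
    def followup_days(self) -> float:
        return sum(ph.duration_days for ph in self.arms[0].phases)


def halve_ics_effect(catalog: MedicationCatalog) -> MedicationCatalog:
    """Dose-reduction transform: half the corticosteroid effect — the
    recovery-rate boost (gamma_mult - 1) is halved and the sensitivity
    reduction moves halfway back to 1."""
    ics = catalog["ICS"]
    return catalog.replace(
        "ICS",
        gamma_mult=1.0 + 0.5 * (ics.gamma_mult - 1.0),
        sens_mult=ics.sens_mult + 0.5 * (1.0 - ics.sens_mult),
    )


def socs_like_protocol(
    run_in_days: float = 42.0, followup_days: float = 112.0, n: int = 300
) -> TrialProtocol:
    """Three-arm corticosteroid-substitution design (placebo vs inhaled
    long-acting bronchodilator vs inhaled corticosteroid), fully adherent."""
    return TrialProtocol(
        run_in_days=run_in_days,
        n_participants=n,
        arms=(
            TrialArm("placebo", (TrialPhase(followup_days, ()),)),
            TrialArm(
                "salmeterol",
                (TrialPhase(followup_days, (Prescription("LABA", "medium", 1.0),)),),
            ),
            TrialArm(
                "triamcinolone",
                (TrialPhase(followup_days, (Prescription("ICS", "medium", 1.0),)),),
            ),
        ),
    )


def slic_like_protocol(
    run_in_days: float = 42.0,
    reduction_days: float = 56.0,
    elimination_days: float = 112.0,
    n: int = 300,
) -> TrialProtocol:
    """Two-arm design: both arms take a long-acting bronchodilator; the
    'minus' arm has its corticosteroid halved then eliminated, the 'plus'
    arm keeps full corticosteroid throughout."""
    laba = Prescription("LABA", "medium", 1.0)
    ics = Prescription("ICS", "medium", 1.0)
    return TrialProtocol(
        run_in_days=run_in_days,
        n_participants=n,
        arms=(
            TrialArm(
                "salmeterol_minus",
                (
                    TrialPhase(reduction_days, (laba, ics), halve_ics_effect),
                    TrialPhase(elimination_days, (laba,)),
                ),
            ),
            TrialArm(
                "salmeterol_plus",
                (
                    TrialPhase(reduction_days, (laba, ics), halve_ics_effect),
                    TrialPhase(elimination_days, (laba, ics)),
                ),
            ),
        ),
    )


def run_trial(
    population,
    protocol: TrialProtocol,
    catalog: MedicationCatalog,
    seed: int,
    policy: HospitalPolicy | None = None,
    options: EngineOptions | None = None,
) -> pd.DataFrame:
    """Simulate the protocol; returns one row per participant:
    (participant, source_patient, arm, time, event).

    ``time`` is days since randomization; ``event`` is True for treatment
    failure, False for censoring at end of follow-up.  Sampling, arm
    allocation and all patient streams derive from ``seed``.
    """
    policy = policy or HospitalPolicy()
    base_opt = options or EngineOptions()
    alloc_rng = substream(seed, 0, "trial")
    pool = [p for p in population if p.calibrated]
    if not pool:
        raise ValueError("population has no calibrated patients")
    picks = alloc_rng.integers(0, len(pool), size=protocol.n_participants)
    arm_of = np.arange(protocol.n_participants) % len(protocol.arms)
    alloc_rng.shuffle(arm_of)

    rows = []
    for part_id, (pick, ai) in enumerate(zip(picks, arm_of)):
        src = pool[pick]
        arm = protocol.arms[ai]
        streams = make_streams(seed, 1 + part_id)
        # run-in under observed medications
        I = None
        if protocol.run_in_days > 0:
            run_opt = dataclasses.replace(base_opt, collect_log=False)
            log = simulate_patient(
                src, protocol.run_in_days, catalog, streams, policy, run_opt
            )
            I = log.final_I
        failure = None
        t_off = 0.0
        for phase in arm.phases:
            if phase.duration_days <= 0:
                continue
            assigned = dataclasses.replace(
                src, prescriptions=list(phase.prescriptions)
            )
            opt = dataclasses.replace(base_opt, collect_log=False, initial_I=I)
            log = simulate_patient(
                assigned,
                phase.duration_days,
                catalog,
                streams,
                policy,
                opt,
            )
            if log.failure_time is not None:
                failure = t_off + log.failure_time
                break
            t_off += phase.duration_days
            I = log.final_I
        rows.append(
            {
                "participant": part_id,
                "source_patient": src.id,
                "arm": arm.name,
                "time": failure if failure is not None else protocol.followup_days,
                "event": failure is not None,
            }
        )
    return pd.DataFrame(rows)
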