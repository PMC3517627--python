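"""Tabular serialization: populations, event logs, reports.

Populations round-trip through flat CSV (one row per patient, prescriptions
and calibrated parameters flattened into columns) so that users with access
to restricted individual-level survey or trial data can supply their own
tables in the same layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import BehaviorProfile, LungAnchors
from .dynamics import PhysiologyParams
from .engine import VirtualPatient
from .meds import Prescription
from .population import OutcomeTargets

__all__ = [
    "population_to_frame",
    "frame_to_population",
    "save_population",
    "load_population",
    "write_manifest",
]

_REQUIRED = [
    "id",
    "age",
    "sex",
    "smoker",
    "fev1_pct_pred",
    "fev1_best_l",
    "md_visits_past_year",
    "ed_visits_past_year",
    "hosp_past_year",
    "rescue_uses_per_day",
]


def population_to_frame(population) -> pd.DataFrame:
    rows = []
    for p in population:
        row = {
            "id": p.id,
            "age": p.age,
            "sex": p.sex,
            "smoker": p.smoker,
            "fev1_pct_pred": p.fev1_pct_pred,
            "z": p.z,
            "fev1_best_l": p.anchors.fev1_best if p.anchors else np.nan,
            "fev1_floor_l": p.anchors.fev1_floor if p.anchors else np.nan,
        }
        t = p.targets
        row.update(
            md_visits_past_year=t.md_visits_past_year,
            ed_visits_past_year=t.ed_visits_past_year,
            hosp_past_year=t.hosp_past_year,
            rescue_uses_per_day=t.rescue_uses_per_day,
        )
        for cls in ("ICS", "LABA"):
            rx = p.prescription_for(cls)
            row[f"{cls.lower()}_adherence"] = rx.adherence if rx else np.nan
            row[f"{cls.lower()}_dose"] = rx.dose_level if rx else ""
        if p.physiology is not None:
            row.update(
                gamma=p.physiology.gamma,
                lam=p.physiology.lam,
                mean_alpha=p.physiology.mean_alpha,
            )
        if p.behavior is not None:
            row.update(
                q_relief=p.behavior.q_relief,
                q_md=p.behavior.q_md,
                q_ed=p.behavior.q_ed,
                washout=p.behavior.washout,
            )
        row["calibration_distance"] = p.calibration_distance
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_population(df: pd.DataFrame) -> list[VirtualPatient]:
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"population table missing columns: {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            prescriptions = []
            for cls in ("ICS", "LABA"):
                adh = getattr(row, f"{cls.lower()}_adherence", np.nan)
                if adh == adh:  # not NaN
                    dose = getattr(row, f"{cls.lower()}_dose", "medium") or "medium"
                    prescriptions.append(Prescription(cls, dose, float(adh)))
            phys = None
            if hasattr(row, "gamma") and row.gamma == row.gamma:
                phys = PhysiologyParams(
                    gamma=float(row.gamma),
                    lam=float(row.lam),
                    mean_alpha=float(row.mean_alpha),
                )
            beh = None
            if hasattr(row, "q_relief") and row.q_relief == row.q_relief:
                beh = BehaviorProfile(
                    q_relief=float(row.q_relief),
                    q_md=float(row.q_md),
                    q_ed=float(row.q_ed),
                    washout=float(getattr(row, "washout", 2.0)),
                )
            best = float(row.fev1_best_l)
            floor = float(getattr(row, "fev1_floor_l", 0.25 * best))
            out.append(
                VirtualPatient(
                    id=int(row.id),
                    age=float(row.age),
                    sex=str(row.sex),
                    smoker=bool(row.smoker),
                    physiology=phys,
                    anchors=LungAnchors(fev1_best=best, fev1_floor=floor),
                    behavior=beh,
                    prescriptions=prescriptions,
                    targets=OutcomeTargets(
                        md_visits_past_year=int(row.md_visits_past_year),
                        ed_visits_past_year=int(row.ed_visits_past_year),
                        hosp_past_year=int(row.hosp_past_year),
                        rescue_uses_per_day=float(row.rescue_uses_per_day),
                        fev1_pct_pred=float(row.fev1_pct_pred),
                    ),
                    fev1_pct_pred=float(row.fev1_pct_pred),
                    z=float(getattr(row, "z", 0.0)),
                    calibration_distance=float(
                        getattr(row, "calibration_distance", np.nan)
                    ),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"population table row {i}: {exc}") from exc
    return out


def save_population(population, path) -> None:
    population_to_frame(population).to_csv(path, index=False)


def load_population(path) -> list[VirtualPatient]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    # round_trip parsing so calibrated parameters survive bit-exactly
    return frame_to_population(pd.read_csv(p, float_precision="round_trip"))


def write_manifest(path, **fields) -> None:
    """Write a small JSON manifest (inputs, seeds, package version)."""
    from . import __version__

    payload = {"asthmasim_version": __version__}
    payload.update(fields)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
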