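"""Run configuration: schema, defaults, loading, validation.

A run configuration is a YAML mapping with these sections (all optional —
missing fields are filled from the shipped defaults in
``asthmasim/data/default_config.yaml``):

``master_seed``, ``horizon_days``, ``output_dir``, ``scenarios``,
``population`` (marginal targets), ``medications`` (effect catalog),
``hospital`` (admission policy), ``behavior`` (OCS-course policy),
``calibration`` (priors, budget, replicates, tolerance).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import yaml

from .behavior import HospitalPolicy
from .engine import EngineOptions
from .meds import MED_CLASSES, MedicationCatalog, MedicationSpec
from .population import PopulationMarginals, StratumMarginals, default_marginals

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "load_medication_catalog",
    "default_config_dict",
]


class ConfigError(ValueError):
    """Configuration schema violation; message names the offending field path."""


def _default_text() -> str:
    return (
        importlib.resources.files("asthmasim")
        .joinpath("data/default_config.yaml")
        .read_text()
    )


def default_config_dict() -> dict:
    return yaml.safe_load(_default_text())


@dataclass
class CalibrationSettings:
    budget: int = 500
    replicate_years: float = 3.0
    tolerance: float = 0.2
    weights: dict = field(
        default_factory=lambda: {"md": 1.0, "ed": 1.0, "hosp": 1.0, "reliever": 0.5}
    )
    floors: dict = field(
        default_factory=lambda: {"md": 0.5, "ed": 0.5, "hosp": 0.5, "reliever": 0.25}
    )
    priors: dict = field(
        default_factory=lambda: {
            "lam": [5e-4, 8.0],
            "mean_alpha": [0.01, 3.0],
            "gamma": [0.01, 2.5],
            "q_relief": [0.70, 0.93],
            "q_md": [0.45, 0.75],
            "q_ed": [0.25, 0.60],
        }
    )


@dataclass
class RunConfig:
    master_seed: int = 0
    horizon_days: float = 365.0
    output_dir: str = "results"
    scenarios: list = field(default_factory=lambda: ["OO", "OP", "EO", "EP"])
    marginals: PopulationMarginals = field(default_factory=default_marginals)
    catalog: MedicationCatalog = None  # type: ignore[assignment]
    policy: HospitalPolicy = field(default_factory=HospitalPolicy)
    options: EngineOptions = field(default_factory=EngineOptions)
    calibration: CalibrationSettings = field(default_factory=CalibrationSettings)


def _build_catalog(meds: dict) -> MedicationCatalog:
    specs = []
    for cls, entry in meds.items():
        if cls not in MED_CLASSES:
            raise ConfigError(f"medications.{cls}: unknown medication class")
        try:
            specs.append(MedicationSpec(med_class=cls, **entry))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"medications.{cls}: {exc}") from exc
    missing = set(MED_CLASSES) - {s.med_class for s in specs}
    if missing:
        raise ConfigError(f"medications: missing classes {sorted(missing)}")
    return MedicationCatalog(specs)


def load_medication_catalog(path: str | Path | None = None) -> MedicationCatalog:
    """Load the medication-effect catalog (shipped defaults when path=None)."""
    if path is None:
        data = default_config_dict()["medications"]
    else:
        data = yaml.safe_load(Path(path).read_text())
        data = data.get("medications", data)
    return _build_catalog(data)


def _build_stratum(d: dict, path: str) -> StratumMarginals:
    valid = {f.name for f in dc_fields(StratumMarginals)}
    extra = set(d) - valid
    if extra:
        raise ConfigError(f"{path}: unknown fields {sorted(extra)}")
    missing = valid - set(d)
    if missing:
        raise ConfigError(f"{path}: missing fields {sorted(missing)}")
    d = dict(d)
    d["age_range"] = tuple(d["age_range"])
    return StratumMarginals(**d)


def _build_marginals(d: dict) -> PopulationMarginals:
    base = default_marginals()
    kwargs = {}
    for key in ("n", "adult_fraction", "qualify_pct", "fev1_l_mean", "fev1_l_sd", "adherence_concentration"):
        kwargs[key] = d.get(key, getattr(base, key))
    for strat in ("adult", "adolescent"):
        if strat in d:
            kwargs[strat] = _build_stratum(d[strat], f"population.{strat}")
        else:
            kwargs[strat] = getattr(base, strat)
    if kwargs["n"] <= 0:
        raise ConfigError("population.n: must be positive")
    return PopulationMarginals(**kwargs)


def _from_dict(data: dict) -> RunConfig:
    defaults = default_config_dict()
    known = {
        "master_seed",
        "horizon_days",
        "output_dir",
        "scenarios",
        "population",
        "medications",
        "hospital",
        "behavior",
        "calibration",
    }
    extra = set(data) - known
    if extra:
        raise ConfigError(f"unknown top-level fields {sorted(extra)}")

    def section(name):
        merged = dict(defaults.get(name, {}))
        merged.update(data.get(name, {}) or {})
        return merged

    cfg = RunConfig(
        master_seed=int(data.get("master_seed", defaults["master_seed"])),
        horizon_days=float(data.get("horizon_days", defaults["horizon_days"])),
        output_dir=str(data.get("output_dir", defaults["output_dir"])),
        scenarios=list(data.get("scenarios", defaults["scenarios"])),
    )
    if cfg.horizon_days <= 0:
        raise ConfigError("horizon_days: must be > 0")
    for s in cfg.scenarios:
        if s not in ("OO", "OP", "EO", "EP"):
            raise ConfigError(f"scenarios: unknown scenario {s!r}")
    cfg.marginals = _build_marginals(section("population"))
    cfg.catalog = _build_catalog(section("medications"))
    try:
        cfg.policy = HospitalPolicy(**section("hospital"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"hospital: {exc}") from exc
    try:
        cfg.options = EngineOptions(**section("behavior"))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"behavior: {exc}") from exc
    cal = section("calibration")
    valid = {f.name for f in dc_fields(CalibrationSettings)}
    extra = set(cal) - valid
    if extra:
        raise ConfigError(f"calibration: unknown fields {sorted(extra)}")
    cs = CalibrationSettings(**cal)
    if cs.budget < 1:
        raise ConfigError("calibration.budget: must be >= 1")
    pri = cs.priors
    if not (pri["q_ed"][0] < pri["q_md"][1] and pri["q_md"][0] < pri["q_relief"][1]):
        raise ConfigError(
            "calibration.priors: threshold ranges must allow q_ed < q_md < q_relief"
        )
    cfg.calibration = cs
    return cfg


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a run configuration (shipped defaults if None)."""
    if path is None:
        data = default_config_dict()
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        data = yaml.safe_load(p.read_text()) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    return _from_dict(data)
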