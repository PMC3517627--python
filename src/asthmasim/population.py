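"""Synthetic national-survey-like asthma population.

Generates virtual patients whose joint distribution emulates a national
asthma survey sample: age strata (adults, adolescents 12-17), sex, smoking,
FEV1 % predicted, controller prescription status and adherence, daily rescue
inhaler use, and past-year counts of unscheduled doctor visits, ED visits
and hospitalizations.  Individual-level survey records are restricted, so
the joint dependence is induced by a single latent severity factor z ~ N(0,1)
per patient:

* utilization counts are negative binomial, moment-matched per stratum to
  the marginal mean/SD, with a lognormal severity frailty exp(b*z - b^2/2)
  on the mean;
* rescue use is gamma with the same style of frailty;
* FEV1 %% predicted decreases with z.

Categorical marginals (stratum sizes, sex, smoking, prescriptions) are
quota-matched exactly (to +/-1 patient).  Prescription status is assigned
independently of z; with the default frailty slopes this reproduces the
survey's fraction of untreated patients who would qualify for a controller
under guidelines (one or more serious exacerbations in the past year, or
average rescue use of two or more per day).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .behavior import LungAnchors
from .engine import VirtualPatient
from .meds import Prescription
from .rng import population_rng

__all__ = [
    "StratumMarginals",
    "PopulationMarginals",
    "OutcomeTargets",
    "generate_population",
    "qualifies_for_expansion",
    "validate_marginals",
    "default_marginals",
]

# Latent-severity link slopes (frailty exp(b*z - b^2/2)); tuned once so the
# generated joint reproduces the survey's qualifying fraction (~27%).
SEVERITY_SLOPES = {
    "counts": 1.1,
    "rescue": 0.9,
    "fev1_rho": 0.4,
    # Controller prescriptions tilt toward less severe patients (weight
    # exp(-prescribing_gap * z) in the quota draw).  This is the prescribing
    # gap the survey exhibits: a large share of untreated patients report
    # serious exacerbations or heavy rescue use, which is what makes the
    # guideline-qualifying fraction as high as it is.
    "prescribing_gap": 1.0,
}


@dataclass(frozen=True)
class StratumMarginals:
    """Per-stratum marginal targets (percentages in [0, 100])."""

    male_pct: float
    age_mean: float
    age_sd: float
    age_range: tuple[float, float]
    smoker_pct: float  # modeled in adults only; 0 for adolescents
    fev1_pct_pred_mean: float
    fev1_pct_pred_sd: float
    ics_pct: float
    ics_adherence_mean: float  # percent
    ics_laba_pct: float  # overlapping category; generated as subset of ICS
    ics_laba_adherence_mean: float
    rescue_per_day_mean: float
    rescue_per_day_sd: float
    md_visits_mean: float
    md_visits_sd: float
    ed_visits_mean: float
    ed_visits_sd: float
    hosp_mean: float
    hosp_sd: float


@dataclass(frozen=True)
class PopulationMarginals:
    n: int = 4930
    adult_fraction: float = 4090.0 / 4927.0
    qualify_pct: float = 27.1
    fev1_l_mean: float = 2.71
    fev1_l_sd: float = 0.71
    adherence_concentration: float = 10.0
    adult: StratumMarginals = None  # type: ignore[assignment]
    adolescent: StratumMarginals = None  # type: ignore[assignment]


def default_marginals() -> PopulationMarginals:
    """Survey-derived default marginals for the simulated population."""
    adult = StratumMarginals(
        male_pct=63.8,
        age_mean=43.4,
        age_sd=16.2,
        age_range=(18.0, 90.0),
        smoker_pct=20.25,
        fev1_pct_pred_mean=80.4,
        fev1_pct_pred_sd=14.5,
        ics_pct=42.5,
        ics_adherence_mean=81.5,
        ics_laba_pct=22.0,
        ics_laba_adherence_mean=84.2,
        rescue_per_day_mean=1.23,
        rescue_per_day_sd=1.47,
        md_visits_mean=1.56,
        md_visits_sd=2.94,
        ed_visits_mean=0.57,
        ed_visits_sd=1.69,
        hosp_mean=0.17,
        hosp_sd=0.75,
    )
    adolescent = StratumMarginals(
        male_pct=52.1,
        age_mean=14.6,
        age_sd=1.6,
        age_range=(12.0, 17.99),
        smoker_pct=0.0,
        fev1_pct_pred_mean=80.5,
        fev1_pct_pred_sd=14.8,
        ics_pct=46.4,
        ics_adherence_mean=75.7,
        ics_laba_pct=25.1,
        ics_laba_adherence_mean=88.9,
        rescue_per_day_mean=0.57,
        rescue_per_day_sd=0.92,
        md_visits_mean=1.12,
        md_visits_sd=2.89,
        ed_visits_mean=0.51,
        ed_visits_sd=1.63,
        hosp_mean=0.06,
        hosp_sd=0.50,
    )
    return PopulationMarginals(adult=adult, adolescent=adolescent)


@dataclass
class OutcomeTargets:
    """Per-patient past-year utilization (the calibration targets)."""

    md_visits_past_year: int
    ed_visits_past_year: int
    hosp_past_year: int
    rescue_uses_per_day: float
    fev1_pct_pred: float

    def __post_init__(self) -> None:
        for f in ("md_visits_past_year", "ed_visits_past_year", "hosp_past_year"):
            v = getattr(self, f)
            if v < 0 or v != int(v):
                raise ValueError(f"{f} must be a non-negative integer, got {v}")
        if self.rescue_uses_per_day < 0:
            raise ValueError("rescue_uses_per_day must be >= 0")


def _quota_mask(
    n: int,
    pct: float,
    rng: np.random.Generator,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Exact-count random assignment of round(n*pct/100) positives.

    With ``weights``, a weighted draw without replacement
    (Efraimidis-Spirakis keys u^(1/w)) keeps the count exact while tilting
    selection toward high-weight individuals.
    """
    k = int(round(n * pct / 100.0))
    mask = np.zeros(n, dtype=bool)
    if weights is None:
        mask[rng.permutation(n)[:k]] = True
    else:
        keys = rng.random(n) ** (1.0 / weights)
        mask[np.argsort(-keys)[:k]] = True
    return mask


def _nb_counts(
    mean: float, sd: float, z: np.ndarray, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Severity-linked counts, moment-matched to (mean, sd) marginally.

    Conditional on z the count is NB with mean m*exp(b*z - b^2/2) and a
    dispersion chosen so the frailty-mixed marginal variance matches sd^2.
    Falls back to a frailty-mixed Poisson (with a warning) when sd^2 is too
    small for the NB decomposition.
    """
    var = sd**2
    mean_i = mean * np.exp(slope * z - slope**2 / 2.0)
    e_m2 = mean**2 * np.exp(slope**2)
    var_frailty = mean**2 * (np.exp(slope**2) - 1.0)
    denom = var - mean - var_frailty
    if denom <= 0:
        warnings.warn(
            f"marginal SD {sd} too small for negative binomial with mean "
            f"{mean} and severity frailty; falling back to Poisson",
            stacklevel=3,
        )
        return rng.poisson(mean_i)
    r = e_m2 / denom
    p = r / (r + mean_i)
    return rng.negative_binomial(r, p)


def _gamma_rate(
    mean: float, sd: float, z: np.ndarray, slope: float, rng: np.random.Generator
) -> np.ndarray:
    """Severity-linked gamma-distributed positive rate (rescue use/day)."""
    mean_i = mean * np.exp(slope * z - slope**2 / 2.0)
    var_frailty = mean**2 * (np.exp(slope**2) - 1.0)
    denom = sd**2 - var_frailty
    if denom <= 0:
        k = 1.0  # frailty already saturates the variance; exponential noise
    else:
        k = mean**2 * np.exp(slope**2) / denom
    return rng.gamma(shape=k, scale=mean_i / k)


def _beta_adherence(
    mean_pct: float, concentration: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    mu = mean_pct / 100.0
    a, b = mu * concentration, (1.0 - mu) * concentration
    return rng.beta(a, b, size=size)


def _truncnorm(
    mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator
) -> np.ndarray:
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _generate_stratum(
    marg: StratumMarginals,
    n: int,
    id_offset: int,
    pm: PopulationMarginals,
    rng: np.random.Generator,
) -> list[VirtualPatient]:
    z = rng.normal(size=n)
    male = _quota_mask(n, marg.male_pct, rng)
    smoker = _quota_mask(n, marg.smoker_pct, rng)
    age = _truncnorm(marg.age_mean, marg.age_sd, *marg.age_range, n, rng)

    rho = SEVERITY_SLOPES["fev1_rho"]
    noise = rng.normal(size=n)
    fev1_pct = marg.fev1_pct_pred_mean + marg.fev1_pct_pred_sd * (
        -rho * z + np.sqrt(1 - rho**2) * noise
    )
    fev1_pct = np.clip(fev1_pct, 20.0, 150.0)
    fev1_l = np.clip(rng.normal(pm.fev1_l_mean, pm.fev1_l_sd, size=n), 0.8, None)

    b = SEVERITY_SLOPES["counts"]
    md = _nb_counts(marg.md_visits_mean, marg.md_visits_sd, z, b, rng)
    ed = _nb_counts(marg.ed_visits_mean, marg.ed_visits_sd, z, b, rng)
    hosp = _nb_counts(marg.hosp_mean, marg.hosp_sd, z, b, rng)
    rescue = _gamma_rate(
        marg.rescue_per_day_mean,
        marg.rescue_per_day_sd,
        z,
        SEVERITY_SLOPES["rescue"],
        rng,
    )

    rx_weights = np.exp(-SEVERITY_SLOPES["prescribing_gap"] * z)
    ics = _quota_mask(n, marg.ics_pct, rng, weights=rx_weights)
    # combo (ICS+LABA) users are a subset of ICS users
    ics_idx = np.nonzero(ics)[0]
    k_laba = min(int(round(n * marg.ics_laba_pct / 100.0)), len(ics_idx))
    laba_idx = rng.permutation(ics_idx)[:k_laba]
    laba = np.zeros(n, dtype=bool)
    laba[laba_idx] = True

    adh_ics = _beta_adherence(
        marg.ics_adherence_mean, pm.adherence_concentration, n, rng
    )
    adh_laba = _beta_adherence(
        marg.ics_laba_adherence_mean, pm.adherence_concentration, n, rng
    )

    patients = []
    for i in range(n):
        prescriptions = []
        if ics[i]:
            prescriptions.append(
                Prescription("ICS", "medium", float(adh_ics[i]))
            )
        if laba[i]:
            prescriptions.append(
                Prescription("LABA", "medium", float(adh_laba[i]))
            )
        best = float(fev1_l[i])
        patients.append(
            VirtualPatient(
                id=id_offset + i,
                age=float(age[i]),
                sex="male" if male[i] else "female",
                smoker=bool(smoker[i]),
                prescriptions=prescriptions,
                anchors=LungAnchors(fev1_best=best, fev1_floor=0.25 * best),
                targets=OutcomeTargets(
                    md_visits_past_year=int(md[i]),
                    ed_visits_past_year=int(ed[i]),
                    hosp_past_year=int(hosp[i]),
                    rescue_uses_per_day=float(rescue[i]),
                    fev1_pct_pred=float(fev1_pct[i]),
                ),
                fev1_pct_pred=float(fev1_pct[i]),
                z=float(z[i]),
            )
        )
    return patients


def generate_population(
    marginals: PopulationMarginals | None = None, seed: int = 0
) -> list[VirtualPatient]:
    """Generate an uncalibrated population matching the marginal targets."""
    pm = marginals or default_marginals()
    rng = population_rng(seed)
    n_adult = int(round(pm.n * pm.adult_fraction))
    n_adol = pm.n - n_adult
    pats = _generate_stratum(pm.adult, n_adult, 0, pm, rng)
    pats += _generate_stratum(pm.adolescent, n_adol, n_adult, pm, rng)
    return pats


def qualifies_for_expansion(patient: VirtualPatient) -> bool:
    """Guideline-qualifying untreated patient: no ICS prescription and either
    a serious exacerbation (ED visit or hospitalization) in the past year or
    average rescue use of two or more per day."""
    if patient.prescription_for("ICS") is not None:
        return False
    t = patient.targets
    return (t.ed_visits_past_year + t.hosp_past_year >= 1) or (
        t.rescue_uses_per_day >= 2.0
    )


def validate_marginals(population, marginals: PopulationMarginals | None = None, tol: float = 3.0):
    """Compare generated population statistics with their targets.

    ``tol`` is in units of standard errors for continuous means and in
    percentage points for quota-matched percentages.  Returns a DataFrame
    with one row per checked marginal.
    """
    import pandas as pd

    pm = marginals or default_marginals()
    rows = []

    def add(name, got, want, se):
        band = tol * se if se else tol
        rows.append(
            {
                "field": name,
                "generated": got,
                "target": want,
                "tolerance": band,
                "ok": abs(got - want) <= band,
            }
        )

    n = len(population)
    adults = [p for p in population if not p.adolescent]
    w_adult = pm.adult_fraction

    def overall(fa, fo):
        return w_adult * fa + (1 - w_adult) * fo

    add("n", n, pm.n, None)
    add(
        "ics_pct",
        100.0 * np.mean([p.prescription_for("ICS") is not None for p in population]),
        overall(pm.adult.ics_pct, pm.adolescent.ics_pct),
        0.2,
    )
    add(
        "ics_laba_pct",
        100.0 * np.mean([p.prescription_for("LABA") is not None for p in population]),
        overall(pm.adult.ics_laba_pct, pm.adolescent.ics_laba_pct),
        0.2,
    )
    add(
        "male_pct",
        100.0 * np.mean([p.sex == "male" for p in population]),
        overall(pm.adult.male_pct, pm.adolescent.male_pct),
        0.2,
    )
    add(
        "smoker_pct_adults",
        100.0 * np.mean([p.smoker for p in adults]),
        pm.adult.smoker_pct,
        0.2,
    )
    add(
        "qualify_pct",
        100.0 * np.mean([qualifies_for_expansion(p) for p in population]),
        pm.qualify_pct,
        1.0 / tol,  # absolute percentage-point band of 1 at default tol
    )
    fev = np.array([p.fev1_pct_pred for p in population])
    add(
        "fev1_pct_pred_mean",
        float(fev.mean()),
        overall(pm.adult.fev1_pct_pred_mean, pm.adolescent.fev1_pct_pred_mean),
        pm.adult.fev1_pct_pred_sd / np.sqrt(n),
    )
    for fld, ma, mo, sa, so in (
        ("md_visits_mean", pm.adult.md_visits_mean, pm.adolescent.md_visits_mean, pm.adult.md_visits_sd, pm.adolescent.md_visits_sd),
        ("ed_visits_mean", pm.adult.ed_visits_mean, pm.adolescent.ed_visits_mean, pm.adult.ed_visits_sd, pm.adolescent.ed_visits_sd),
        ("hosp_mean", pm.adult.hosp_mean, pm.adolescent.hosp_mean, pm.adult.hosp_sd, pm.adolescent.hosp_sd),
        ("rescue_per_day_mean", pm.adult.rescue_per_day_mean, pm.adolescent.rescue_per_day_mean, pm.adult.rescue_per_day_sd, pm.adolescent.rescue_per_day_sd),
    ):
        field_map = {
            "md_visits_mean": "md_visits_past_year",
            "ed_visits_mean": "ed_visits_past_year",
            "hosp_mean": "hosp_past_year",
            "rescue_per_day_mean": "rescue_uses_per_day",
        }
        got = float(np.mean([getattr(p.targets, field_map[fld]) for p in population]))
        add(fld, got, overall(ma, mo), overall(sa, so) / np.sqrt(n))
    return pd.DataFrame(rows)
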