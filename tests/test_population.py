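"""Synthetic population: quota marginals, severity coherence, qualifying rule."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from asthmasim.engine import VirtualPatient
from asthmasim.meds import Prescription
from asthmasim.population import (
    OutcomeTargets,
    default_marginals,
    generate_population,
    qualifies_for_expansion,
    validate_marginals,
)


@pytest.fixture(scope="module")
def survey_population():
    return generate_population(seed=1)


class TestMarginals:
    def test_counts_and_strata(self, survey_population):
        pm = default_marginals()
        assert len(survey_population) == pm.n
        adults = [p for p in survey_population if not p.adolescent]
        assert len(adults) == round(pm.n * pm.adult_fraction)

    def test_quota_percentages(self, survey_population):
        pm = default_marginals()
        w = pm.adult_fraction
        ics = 100 * np.mean(
            [p.prescription_for("ICS") is not None for p in survey_population]
        )
        want = w * pm.adult.ics_pct + (1 - w) * pm.adolescent.ics_pct  # 43.2
        assert ics == pytest.approx(want, abs=0.1)
        assert ics == pytest.approx(43.2, abs=0.1)
        laba = 100 * np.mean(
            [p.prescription_for("LABA") is not None for p in survey_population]
        )
        assert laba == pytest.approx(22.6, abs=0.2)

    def test_combo_users_subset_of_ics(self, survey_population):
        for p in survey_population:
            if p.prescription_for("LABA") is not None:
                assert p.prescription_for("ICS") is not None

    def test_continuous_means_within_3se(self, survey_population):
        n = len(survey_population)
        md = np.array([p.targets.md_visits_past_year for p in survey_population])
        assert md.mean() == pytest.approx(1.49, abs=3 * 2.94 / np.sqrt(n))
        fev = np.array([p.fev1_pct_pred for p in survey_population])
        assert fev.mean() == pytest.approx(80.4, abs=3 * 14.5 / np.sqrt(n))

    def test_validation_report_self_consistent(self, survey_population):
        report = validate_marginals(survey_population)
        assert report["ok"].all(), report[~report["ok"]]

    def test_validation_flags_perturbation(self, survey_population):
        broken = [dataclasses.replace(p, sex="male") for p in survey_population]
        report = validate_marginals(broken)
        row = report.set_index("field").loc["male_pct"]
        assert not row["ok"]


class TestSeverityStructure:
    def test_utilization_correlates_with_latent_severity(self, survey_population):
        z = np.array([p.z for p in survey_population])
        for field in ("md_visits_past_year", "ed_visits_past_year", "rescue_uses_per_day"):
            x = np.array([getattr(p.targets, field) for p in survey_population])
            rho = stats.spearmanr(z, x).statistic
            assert rho > 0.1, field

    def test_rescue_and_ed_positively_dependent(self, survey_population):
        rescue = np.array([p.targets.rescue_uses_per_day for p in survey_population])
        ed = np.array([p.targets.ed_visits_past_year for p in survey_population])
        assert stats.spearmanr(rescue, ed).statistic > 0

    def test_fev1_decreases_with_severity(self, survey_population):
        z = np.array([p.z for p in survey_population])
        fev = np.array([p.fev1_pct_pred for p in survey_population])
        assert np.corrcoef(z, fev)[0, 1] < -0.2


class TestQualifyingRule:
    def _patient(self, ics, ed, hosp, rescue):
        rx = [Prescription("ICS", "medium", 0.8)] if ics else []
        return VirtualPatient(
            id=0, age=40, sex="f", prescriptions=rx,
            targets=OutcomeTargets(0, ed, hosp, rescue, 80.0),
        )

    def test_current_user_never_qualifies(self):
        assert not qualifies_for_expansion(self._patient(True, 5, 1, 3.0))

    def test_heavy_rescue_use_qualifies(self):
        assert qualifies_for_expansion(self._patient(False, 0, 0, 2.1))

    def test_exacerbation_qualifies(self):
        assert qualifies_for_expansion(self._patient(False, 1, 0, 0.0))
        assert qualifies_for_expansion(self._patient(False, 0, 1, 0.0))

    def test_mild_nonuser_does_not_qualify(self):
        assert not qualifies_for_expansion(self._patient(False, 0, 0, 1.5))

    def test_population_qualifying_fraction(self, survey_population):
        q = 100 * np.mean([qualifies_for_expansion(p) for p in survey_population])
        assert q == pytest.approx(27.1, abs=1.3)  # 2 sigma of the joint draw


class TestDeterminismAndFallback:
    def test_same_seed_identical(self):
        a = generate_population(seed=9)
        b = generate_population(seed=9)
        for pa, pb in zip(a[:200], b[:200]):
            assert pa.targets == pb.targets and pa.age == pb.age

    def test_poisson_fallback_warns(self):
        pm = default_marginals()
        tight = dataclasses.replace(pm.adult, md_visits_sd=1.3)
        pm = dataclasses.replace(pm, n=200, adult=tight)
        with pytest.warns(UserWarning, match="negative binomial"):
            generate_population(pm, seed=0)

    def test_targets_validate(self):
        with pytest.raises(ValueError):
            OutcomeTargets(-1, 0, 0, 0.0, 80.0)
        with pytest.raises(ValueError):
            OutcomeTargets(0, 0, 0, -0.5, 80.0)
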