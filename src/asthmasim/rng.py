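"""Reproducible random-stream policy.

Every source of randomness in a simulation run is a named substream derived
from (master_seed, patient_id, purpose[, scenario]).  Keying the physiological
streams (trigger times, trigger effect sizes) by patient only — never by
scenario — implements common random numbers: the four prescribing/adherence
scenarios expose each virtual patient to the identical sequence of
environmental insults, so paired scenario contrasts are sharpened.
Behavioral streams (adherence coin flips, care dispositions) are additionally
keyed by scenario, because the scenario changes how often those streams are
consumed.
"""

from __future__ import annotations

import numpy as np

# Stable purpose codes; never renumber (would silently change all streams).
PURPOSES = {
    "stimuli": 1,
    "effect_sizes": 2,
    "adherence": 3,
    "care": 4,
    "calibration": 5,
    "population": 6,
    "trial": 7,
    "bootstrap": 8,
}

SCENARIO_CODES = {None: 0, "OO": 1, "OP": 2, "EO": 3, "EP": 4}


def substream(
    master_seed: int,
    patient_id: int,
    purpose: str,
    scenario: str | None = None,
) -> np.random.Generator:
    """Return the named per-patient generator for one purpose.

    Identical arguments always yield a bit-identical stream; distinct
    purposes (or scenarios, where the purpose is scenario-keyed) yield
    independent streams via ``numpy.random.SeedSequence`` spawning.
    """
    code = PURPOSES[purpose]
    scen = SCENARIO_CODES[scenario] if scenario in SCENARIO_CODES else SCENARIO_CODES.get(scenario, 0)
    ss = np.random.SeedSequence((int(master_seed), int(patient_id), code, scen))
    return np.random.default_rng(ss)


def population_rng(master_seed: int) -> np.random.Generator:
    """Generator for population-level sampling (not patient-keyed)."""
    ss = np.random.SeedSequence((int(master_seed), PURPOSES["population"]))
    return np.random.default_rng(ss)
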