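import pytest

from orphanmcda import archetype_profiles, emirates_default

# Printed one-decimal normalized weights of the ten criteria, rank order.
EMIRATES_WEIGHTS_PCT = {
    "cost_effectiveness": 25.1,
    "magnitude_of_health_gain": 20.1,
    "therapeutic_alternative": 14.3,
    "disease_severity": 11.0,
    "budget_impact": 7.9,
    "disease_rarity": 5.6,
    "clinical_evidence": 5.6,
    "household_burden": 4.5,
    "indication_uniqueness": 3.2,
    "patient_age": 2.6,
}


@pytest.fixture(scope="session")
def emirates():
    return emirates_default()


@pytest.fixture(scope="session")
def archetypes():
    return archetype_profiles()
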