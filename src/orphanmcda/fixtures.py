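"""Packaged fixtures: synthetic consensus-vote panels and archetype drug profiles.

The synthetic vote generator emulates an eleven-expert consensus session:
each participant submits a complete ranking (a permutation of the criteria),
a percent weight-increase vote per criterion, and a desired criteria count.
Dispersion parameters control how far individual ballots scatter around the
consensus; at zero dispersion all ballots equal the consensus exactly, so the
full elicitation pipeline reproduces the consensus ranking and weights.

The four archetype profiles are reconstructions of the kinds of test cases
used to validate the tool — a genetic curative therapy for an ultrarare
disease, a highly effective chronic therapy for a rare disease, a
high-quality symptomatic chronic therapy, and a lower-quality symptomatic
chronic therapy. The underlying selections of the original test cases were
never published, so these are representative stand-ins constructed to meet
the qualitative expectations (first two above 50 points, last two below,
in that rank order), not reproductions of the original scores.
"""

from __future__ import annotations

import numpy as np

from .criteria import CriteriaSet, DrugProfile, emirates_default
from .elicitation import CountVotes, IncreaseVotes, RankVotes

DEFAULT_PARTICIPANTS = 11  # size of the consensus session being emulated


def synthetic_votes(
    n_participants: int = DEFAULT_PARTICIPANTS,
    cs: CriteriaSet | None = None,
    seed: int = 0,
    rank_dispersion: float = 0.0,
    increase_sd: float = 0.0,
) -> tuple[RankVotes, IncreaseVotes, CountVotes]:
    """Reproducible random vote panels around a consensus criteria set.

    Parameters
    ----------
    n_participants : number of ballots (>= 1).
    cs : consensus criteria set; the Emirates default when omitted. Its rank
        order (ties broken by declaration order) and increase chain are the
        consensus every ballot scatters around.
    seed : RNG seed; a fixed seed gives identical panels.
    rank_dispersion : standard deviation of Gaussian jitter added to each
        criterion's consensus rank position before re-sorting into the
        participant's permutation. 0 means every ballot is the consensus
        order.
    increase_sd : standard deviation (percentage points) of Gaussian noise on
        each increase vote, clipped at 0.
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    if cs is None:
        cs = emirates_default()
    rng = np.random.default_rng(seed)
    order = cs.ordered_ids()
    n = len(order)

    rank_votes: dict[str, dict[str, float]] = {}
    increase_votes: dict[str, dict[str, float]] = {}
    for i in range(n_participants):
        pid = f"participant_{i + 1:02d}"
        positions = np.arange(1, n + 1, dtype=float)
        if rank_dispersion > 0:
            positions = positions + rng.normal(0.0, rank_dispersion, size=n)
        # argsort turns jittered positions back into a permutation of 1..n
        ballot_order = np.argsort(positions, kind="stable")
        ranks = {order[j]: float(r + 1) for r, j in enumerate(ballot_order)}
        rank_votes[pid] = ranks
        inc = {}
        for cid in order:
            v = cs.increases[cid]
            if increase_sd > 0:
                v = max(0.0, v + rng.normal(0.0, increase_sd))
            inc[cid] = float(v)
        increase_votes[pid] = inc

    if rank_dispersion > 0 or increase_sd > 0:
        jitter = rng.integers(-1, 2, size=n_participants)
        counts = [int(np.clip(n + j, 1, n)) for j in jitter]
    else:
        counts = [n] * n_participants
    return rank_votes, increase_votes, counts


# Selections for the four archetype reconstructions. Chosen to be clinically
# plausible for each archetype (e.g. the curative gene therapy is the least
# cost-effective but scores fully on health gain, unmet need, severity and
# rarity; the low-quality symptomatic therapy scores near the bottom almost
# everywhere).
_ARCHETYPES: dict[str, dict[str, str]] = {
    "genetic curative therapy": {
        "cost_effectiveness": "Between 3-5x GDP per capita",
        "magnitude_of_health_gain": "Curative therapy (no need for further therapy)",
        "therapeutic_alternative": "No effective treatments are available",
        "disease_severity": "Chronic life threatening",
        "budget_impact": "Between 0.01-0.05% of annual drug budget",
        "disease_rarity": "Ultrarare disease",
        "clinical_evidence": "Supportive RCT with <1 year follow-up",
        "household_burden": "Burden on patients or caregivers > direct medical cost",
        "indication_uniqueness": "One unique orphan indication",
        "patient_age": "Pediatrics (0-16 years)",
    },
    "highly effective chronic therapy": {
        "cost_effectiveness": "Between 5-10x GDP per capita",
        "magnitude_of_health_gain": "Long-term remission on therapy (therapy until progression)",
        "therapeutic_alternative": "Less effective treatments are available",
        "disease_severity": "Chronic with severe invalidity",
        "budget_impact": "Between 0.05-0.10% of annual drug budget",
        "disease_rarity": "Rare disease",
        "clinical_evidence": "Supportive RCT and real-world evidence",
        "household_burden": "Significant burden on patients or caregivers",
        "indication_uniqueness": "One unique orphan indication",
        "patient_age": "Young adults (17-30 years)",
    },
    "high-quality symptomatic therapy": {
        "cost_effectiveness": "Between 1-2x GDP per capita",
        "magnitude_of_health_gain": "Symptom relief or short-term benefit",
        "therapeutic_alternative": "Less effective treatments are available",
        "disease_severity": "Other chronic diseases",
        "budget_impact": "Between 0.1-0.3% of annual drug budget",
        "disease_rarity": "Rare disease",
        "clinical_evidence": "Supportive RCT with at least 1 year follow-up",
        "household_burden": "No evidence on household burden",
        "indication_uniqueness": "Two orphan indications",
        "patient_age": "Middle aged adults (31-65 years)",
    },
    "lower-quality symptomatic therapy": {
        "cost_effectiveness": "Between 5-10x GDP per capita",
        "magnitude_of_health_gain": "Symptom relief or short-term benefit",
        "therapeutic_alternative": "Similarly effective treatments are available",
        "disease_severity": "Other chronic diseases",
        "budget_impact": "Above 0.3% of annual drug budget",
        "disease_rarity": "Rare disease",
        "clinical_evidence": "Single arm phase 2 study",
        "household_burden": "No evidence on household burden",
        "indication_uniqueness": "More than two orphan indications",
        "patient_age": "Middle aged adults (31-65 years)",
    },
}


def archetype_profiles() -> tuple[DrugProfile, DrugProfile, DrugProfile, DrugProfile]:
    """Four representative drug profiles over the Emirates set, in expected
    rank order (best first). See the module docstring: these are synthetic
    reconstructions, not the original validation cases."""
    return tuple(DrugProfile(name, dict(sel)) for name, sel in _ARCHETYPES.items())


def archetype_expectation():
    """The predefined expectations for the archetypes: first two above 50
    points, last two below, in declaration order, with the customary
    40-point minimum spread."""
    from .validation import ConcordanceExpectation

    names = list(_ARCHETYPES)
    return ConcordanceExpectation(
        above_50={names[0]: True, names[1]: True, names[2]: False, names[3]: False},
        expected_order=names,
        min_spread=40.0,
    )
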