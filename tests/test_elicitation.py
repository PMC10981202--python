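"""Vote aggregation and the SMART & Swing weight chain.

The independent oracle used here computes each criterion's unnormalized
weight as a direct product of (1 + increase/100) factors over all rank
groups strictly below the top of that criterion's group — no sequential
accumulation — and is checked against the implementation on randomized
small instances.
"""

import math
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orphanmcda import (
    aggregate_ranking,
    average_votes,
    derive_weights,
    normalize,
    select_criteria_count,
    swing_weights,
    truncate_to_count,
)
from orphanmcda.criteria import Ranking

from conftest import EMIRATES_WEIGHTS_PCT

# Chain values for the Emirates ranking/increases, lowest to highest rank,
# frozen from the hand-computed multiplicative chain.
EMIRATES_CHAIN = [1, 1.25, 1.75, 2.1875, 2.1875, 3.0625, 4.2875, 5.57375,
                  7.80325, 9.7540625]


def swing_oracle(groups, increases):
    """Direct-product oracle: independent of the implementation's loop."""
    factors = [1.0 + max(increases[c] for c in g) / 100.0 for g in groups]
    out = {}
    for gi, g in enumerate(groups):
        # climb one factor per group strictly below gi, excluding the lowest
        # group's own entry (it has nothing to swing against)
        w = math.prod(factors[j] for j in range(gi, len(groups) - 1))
        for c in g:
            out[c] = w
    return out


class TestAverageVotes:
    @pytest.mark.parametrize(
        "votes, mean", [([25, 25, 25], 25), ([20, 30], 25), ([0, 0, 75], 25)]
    )
    def test_mean(self, votes, mean):
        assert average_votes(votes) == pytest.approx(mean)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError, match="no votes"):
            average_votes([])


class TestAggregateRanking:
    def test_single_participant_is_identity(self):
        votes = {"p1": {"a": 2, "b": 1, "c": 3}}
        assert aggregate_ranking(votes) == Ranking.from_groups([["b"], ["a"], ["c"]])

    def test_equal_mean_ranks_share_a_group(self):
        votes = {
            "p1": {"A": 1, "B": 2, "C": 3},
            "p2": {"A": 1, "B": 3, "C": 2},
        }
        assert aggregate_ranking(votes) == Ranking.from_groups([["A"], ["B", "C"]])

    def test_duplicate_ranks_error_names_participant(self):
        votes = {"alice": {"a": 1, "b": 1, "c": 3}}
        with pytest.raises(ValueError, match="alice"):
            aggregate_ranking(votes)

    def test_missing_criterion_error_names_participant(self):
        votes = {"p1": {"a": 1, "b": 2}, "p2": {"a": 1}}
        with pytest.raises(ValueError, match="p2"):
            aggregate_ranking(votes)

    def test_rank_numbers_reindex_contiguously(self):
        # raw means 1.0, 2.5, 2.5, 4.0 must become ranks 1, 2, 2, 3
        votes = {"p": {"a": 1, "b": 2, "c": 3, "d": 4},
                 "q": {"a": 1, "b": 3, "c": 2, "d": 4}}
        r = aggregate_ranking(votes)
        assert r.groups == Ranking.from_groups([["a"], ["b", "c"], ["d"]]).groups
        assert r.rank_of("d") == 3


class TestSelectCriteriaCount:
    def test_six_of_eleven_votes_carry(self):
        votes = [10] * 6 + [12, 12, 8, 8, 9]
        assert select_criteria_count(votes) == 10

    def test_plurality(self):
        assert select_criteria_count([8, 8, 10]) == 8

    def test_tie_goes_to_larger_count(self):
        assert select_criteria_count([8, 10]) == 10

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            select_criteria_count([])


class TestTruncateToCount:
    # 12-candidate ranking: the two lowest-ranked criteria drop when 10 are kept
    FULL = Ranking.from_groups(
        [["cost_effectiveness"], ["magnitude_of_health_gain"],
         ["therapeutic_alternative"], ["disease_severity"], ["budget_impact"],
         ["disease_rarity", "clinical_evidence"], ["household_burden"],
         ["indication_uniqueness"], ["patient_age"],
         ["advancement_of_technology"], ["manufacturing_complexity"]]
    )

    def test_lowest_ranked_criteria_are_excluded(self):
        kept = truncate_to_count(self.FULL, 10)
        assert "advancement_of_technology" not in kept.criterion_ids
        assert "manufacturing_complexity" not in kept.criterion_ids
        assert len(kept) == 10

    def test_full_count_is_identity(self):
        assert truncate_to_count(self.FULL, 12) == self.FULL

    def test_cannot_split_a_tied_group(self):
        r = Ranking.from_groups([["A"], ["B", "C"]])
        with pytest.raises(ValueError, match="ambiguous truncation"):
            truncate_to_count(r, 2)


class TestSwingWeights:
    def test_emirates_chain_values(self, emirates):
        w = swing_weights(emirates.ranking, emirates.increases)
        got = sorted(w.values())
        assert got == pytest.approx(EMIRATES_CHAIN, abs=1e-12)

    def test_zero_increases_give_equal_weights(self):
        r = Ranking.from_groups([["a"], ["b"], ["c"]])
        w = swing_weights(r, {"a": 0, "b": 0, "c": 0}, base=3.0)
        assert set(w.values()) == {3.0}

    def test_single_step_of_hundred_percent_doubles(self):
        r = Ranking.from_groups([["top"], ["bottom"]])
        w = swing_weights(r, {"top": 100.0, "bottom": 25.0}, base=2.0)
        assert w == {"bottom": 2.0, "top": 4.0}

    def test_negative_increase_is_an_error(self):
        r = Ranking.from_groups([["a"], ["b"]])
        with pytest.raises(ValueError, match="negative"):
            swing_weights(r, {"a": -1.0, "b": 0.0})

    def test_tied_criteria_share_identical_weight(self, emirates):
        w = swing_weights(emirates.ranking, emirates.increases)
        assert w["disease_rarity"] == w["clinical_evidence"]

    def test_agrees_with_direct_product_oracle_on_random_instances(self):
        rng = random.Random(20240226)
        for _ in range(200):
            n = rng.randint(1, 8)
            ids = [f"c{i}" for i in range(n)]
            rng.shuffle(ids)
            groups, i = [], 0
            while i < n:
                size = min(rng.randint(1, 3), n - i)
                groups.append(ids[i:i + size])
                i += size
            increases = {}
            for g in groups:
                carrier = rng.choice(g)
                for c in g:
                    increases[c] = rng.uniform(0, 80) if c == carrier else 0.0
            ranking = Ranking.from_groups(groups)
            got = swing_weights(ranking, increases)
            want = swing_oracle(groups, increases)
            assert got == pytest.approx(want, rel=1e-12)


class TestNormalize:
    def test_simple_halves(self):
        assert normalize({"A": 2, "B": 2}) == {"A": 0.5, "B": 0.5}

    def test_hand_arithmetic(self):
        assert normalize({"A": 1, "B": 0.5, "C": 0.5}) == pytest.approx(
            {"A": 0.5, "B": 0.25, "C": 0.25}
        )

    def test_degenerate_weights_are_an_error(self):
        with pytest.raises(ValueError, match="degenerate"):
            normalize({"A": 0.0, "B": 0.0})
        with pytest.raises(ValueError, match="degenerate"):
            normalize({})


def test_emirates_weights_match_printed_table(emirates):
    """Chain + normalization reproduces every printed one-decimal weight."""
    weights = derive_weights(emirates.ranking, emirates.increases)
    assert sum(weights.values()) == pytest.approx(1.0, abs=1e-12)
    got = {cid: round(100 * w, 1) for cid, w in weights.items()}
    assert got == EMIRATES_WEIGHTS_PCT


@settings(derandomize=True, max_examples=50)
@given(base=st.floats(min_value=1e-6, max_value=1e6,
                      allow_nan=False, allow_infinity=False))
def test_normalized_weights_are_base_invariant(base):
    r = Ranking.from_groups([["a"], ["b", "c"], ["d"]])
    inc = {"a": 30.0, "b": 0.0, "c": 45.0, "d": 10.0}
    ref = normalize(swing_weights(r, inc, base=1.0))
    scaled = normalize(swing_weights(r, inc, base=base))
    assert scaled == pytest.approx(ref, rel=1e-9)


@settings(derandomize=True, max_examples=50)
@given(bump=st.floats(min_value=0.5, max_value=60.0), group_idx=st.integers(0, 2))
def test_raising_one_increase_never_lowers_criteria_above_it(bump, group_idx):
    r = Ranking.from_groups([["a"], ["b", "c"], ["d"]])
    inc = {"a": 30.0, "b": 0.0, "c": 45.0, "d": 10.0}
    carriers = ["a", "c", "d"]  # one increase carrier per group, top to bottom
    inc2 = dict(inc)
    inc2[carriers[group_idx]] += bump
    w1 = normalize(swing_weights(r, inc))
    w2 = normalize(swing_weights(r, inc2))
    order = ["a", "b", "c", "d"]
    bumped_group = [["a"], ["b", "c"], ["d"]][group_idx]
    at_or_above = set()
    for g in [["a"], ["b", "c"], ["d"]]:
        at_or_above.update(g)
        if set(g) == set(bumped_group):
            break
    for cid in order:
        if cid in at_or_above:
            assert w2[cid] >= w1[cid] - 1e-12
        else:
            assert w2[cid] <= w1[cid] + 1e-12
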