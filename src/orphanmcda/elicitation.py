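"""Consensus-session vote aggregation and SMART & Swing weight derivation.

The elicitation pipeline mirrors a structured consensus-building session:
participants rank the criteria by importance, vote on how many criteria to
keep, and state each criterion's percentage importance increase over the
next-ranked one. Votes are aggregated by plain arithmetic mean. The swing
chain then assigns the lowest-ranked criterion an arbitrary positive base
weight and multiplies upward, rank group by rank group, by (1 + increase/100);
normalization to a unit sum removes the base entirely.

Vote containers are plain mappings:

* RankVotes      — {participant: {criterion_id: rank position}}, 1 = most important
* IncreaseVotes  — {participant: {criterion_id: percent increase}}
* CountVotes     — sequence of desired criteria counts, one per participant
"""

from __future__ import annotations

from collections import Counter
from typing import Mapping, Sequence

from .criteria import Ranking, WeightIncreases, WeightVector

RankVotes = Mapping[str, Mapping[str, float]]
IncreaseVotes = Mapping[str, Mapping[str, float]]
CountVotes = Sequence[int]

#: Mean ranks closer than this are treated as exactly tied. Votes are small
#: integers, so genuine ties are exact; the tolerance only absorbs float noise.
TIE_TOL = 1e-9


def average_votes(votes: Sequence[float]) -> float:
    """Arithmetic mean of a non-empty vote list — the session's blanket
    aggregation rule for every question."""
    if len(votes) == 0:
        raise ValueError("no votes")
    return sum(votes) / len(votes)


def aggregate_ranking(rank_votes: RankVotes) -> Ranking:
    """Mean-rank aggregation of per-participant rankings into one Ranking.

    Criteria are ordered by ascending mean rank; criteria whose means coincide
    (within :data:`TIE_TOL`) share a rank group. Rank numbers are re-indexed
    contiguously from 1, so the output is a valid Ranking regardless of the
    raw mean values.
    """
    if not rank_votes:
        raise ValueError("no votes")
    participants = list(rank_votes)
    criteria = set(rank_votes[participants[0]])
    for p in participants:
        ranks = rank_votes[p]
        if set(ranks) != criteria:
            raise ValueError(
                f"participant {p!r} did not rank exactly the active criteria"
            )
        values = sorted(ranks.values())
        if len(set(values)) != len(values):
            raise ValueError(f"participant {p!r} assigned duplicate ranks")

    means = {
        cid: average_votes([rank_votes[p][cid] for p in participants])
        for cid in criteria
    }
    ordered = sorted(criteria, key=lambda cid: (means[cid], cid))
    groups: list[set[str]] = []
    last_mean: float | None = None
    for cid in ordered:
        if last_mean is not None and abs(means[cid] - last_mean) <= TIE_TOL:
            groups[-1].add(cid)
        else:
            groups.append({cid})
        last_mean = means[cid]
    return Ranking.from_groups(groups)


def select_criteria_count(count_votes: CountVotes) -> int:
    """Plurality choice of how many criteria to keep; ties go to the larger
    count (keeping more criteria is the conservative outcome)."""
    if len(count_votes) == 0:
        raise ValueError("no votes")
    tally = Counter(count_votes)
    best = max(tally.values())
    return max(n for n, c in tally.items() if c == best)


def truncate_to_count(ranking: Ranking, n: int) -> Ranking:
    """Keep the top-n criteria by rank, dropping whole rank groups from the
    bottom. Refuses to split a tied group: exclusion by rank is only
    well-defined group-wise."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total = len(ranking)
    if n > total:
        raise ValueError(f"cannot keep {n} of {total} criteria")
    kept: list[frozenset[str]] = []
    count = 0
    for g in ranking.groups:
        if count == n:
            break
        if count + len(g) > n:
            raise ValueError("ambiguous truncation at tied rank")
        kept.append(g)
        count += len(g)
    return Ranking(tuple(kept))


def _group_increase(group: frozenset[str], increases: WeightIncreases) -> float:
    """A rank group's percent increase over the next-ranked group.

    Within a tied group exactly one member carries the over-next-rank increase
    and the others carry 0 (the within-tie increase), so the group climbs by
    the maximum of its members' entries.
    """
    vals = []
    for cid in group:
        if cid not in increases:
            raise ValueError(f"no weight increase defined for criterion {cid!r}")
        v = increases[cid]
        if v < 0:
            raise ValueError(f"negative weight increase {v} for criterion {cid!r}")
        vals.append(v)
    return max(vals)


def swing_weights(
    ranking: Ranking, increases: WeightIncreases, base: float = 1.0
) -> dict[str, float]:
    """Unnormalized SMART & Swing weights from a ranking and increase chain.

    Every criterion in the lowest rank group gets ``base``; each higher group's
    weight is the group below times (1 + increase/100). Tied criteria receive
    identical weight. The lowest group's own increase entry is ignored — there
    is no lower criterion for it to swing against — and ``base`` is arbitrary
    because normalization cancels it.
    """
    if base <= 0:
        raise ValueError("base must be positive")
    if not ranking.groups:
        raise ValueError("empty ranking")
    weights: dict[str, float] = {}
    w = float(base)
    for i, group in enumerate(reversed(ranking.groups)):
        if i > 0:
            w *= 1.0 + _group_increase(group, increases) / 100.0
        for cid in group:
            weights[cid] = w
    return weights


def normalize(raw: Mapping[str, float]) -> WeightVector:
    """Divide each weight by the total so the vector sums to 1."""
    if not raw:
        raise ValueError("degenerate weights")
    for cid, v in raw.items():
        if v < 0:
            raise ValueError(f"negative weight {v} for criterion {cid!r}")
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("degenerate weights")
    return {cid: v / total for cid, v in raw.items()}


def derive_weights(ranking: Ranking, increases: WeightIncreases) -> WeightVector:
    """Full pipeline: swing chain then normalization."""
    return normalize(swing_weights(ranking, increases))
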