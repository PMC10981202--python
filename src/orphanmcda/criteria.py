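"""Domain model for MCDA criteria sets, rankings, weights, and drug profiles.

An MCDA criteria set bundles everything needed to score a drug: the criteria
themselves (each an ordered ladder of categorical outcome levels mapped to
fractional scores), a consensus ranking of the criteria by importance (ties
allowed), and the per-step weight increases elicited with the SMART & Swing
method. Normalized weights are derived, never stored as primary data.

Fractions are proportions in [0, 1] throughout; percent is presentation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from importlib import resources

import yaml

CATEGORIES = ("disease-related", "economics-related", "treatment-related")

#: Documentation of the rarity convention used by the default criteria set:
#: rare = fewer than 5 per 10,000 population; ultrarare = about 1 per 50,000
#: (NICE convention). Classification is the assessor's categorical selection;
#: the tool never derives it from epidemiological data.
ULTRARARE_PREVALENCE = 1 / 50_000


@dataclass(frozen=True)
class OutcomeLevel:
    """One categorical outcome of a criterion with its fractional score."""

    label: str
    fraction: float


@dataclass(frozen=True)
class Criterion:
    """A named evaluation axis with outcome levels ordered best to worst."""

    id: str
    name: str
    category: str
    levels: tuple[OutcomeLevel, ...]

    def fraction_of(self, label: str) -> float:
        for lv in self.levels:
            if lv.label == label:
                return lv.fraction
        valid = ", ".join(repr(lv.label) for lv in self.levels)
        raise KeyError(
            f"unknown outcome level {label!r} for criterion {self.id!r}; "
            f"valid labels: {valid}"
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lv.label for lv in self.levels)

    @property
    def best_label(self) -> str:
        return self.levels[0].label

    @property
    def worst_label(self) -> str:
        return self.levels[-1].label


@dataclass(frozen=True)
class Ranking:
    """Ordered rank groups of criterion ids; group 0 is rank 1 (most important).

    Criteria inside one group are tied and share the rank. Rank numbers are
    contiguous positive integers starting at 1.
    """

    groups: tuple[frozenset[str], ...]

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "Ranking":
        return cls(tuple(frozenset(g) for g in groups))

    @property
    def criterion_ids(self) -> frozenset[str]:
        out: set[str] = set()
        for g in self.groups:
            out |= g
        return frozenset(out)

    def rank_of(self, criterion_id: str) -> int:
        for i, g in enumerate(self.groups, start=1):
            if criterion_id in g:
                return i
        raise KeyError(f"criterion {criterion_id!r} not in ranking")

    def ordered_ids(self, tie_break: Mapping[str, int] | None = None) -> list[str]:
        """Flatten to a list, most important first; ties broken by `tie_break`
        position (e.g. declaration order in the criteria list) else lexically."""
        out: list[str] = []
        for g in self.groups:
            key = (lambda c: tie_break[c]) if tie_break else (lambda c: c)
            out.extend(sorted(g, key=key))
        return out

    def __len__(self) -> int:
        return sum(len(g) for g in self.groups)


# WeightIncreases: mapping criterion id -> percent increase over the
# next-ranked criterion. WeightVector: mapping criterion id -> weight summing
# to 1. Both are plain dicts; invariants are enforced by validate_criteria_set
# and by the elicitation routines that produce them.
WeightIncreases = dict[str, float]
WeightVector = dict[str, float]


@dataclass(frozen=True)
class DrugProfile:
    """One candidate drug: a selected outcome level label per criterion."""

    drug_name: str
    selections: Mapping[str, str]


@dataclass(frozen=True)
class CriteriaSet:
    """Criteria plus ranking and swing increases; weights are derived and cached."""

    criteria: tuple[Criterion, ...]
    ranking: Ranking
    increases: WeightIncreases
    name: str = "criteria-set"
    _weights: dict = field(default_factory=dict, compare=False, repr=False)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def criterion(self, criterion_id: str) -> Criterion:
        for c in self.criteria:
            if c.id == criterion_id:
                return c
        raise KeyError(f"unknown criterion {criterion_id!r}")

    @property
    def weights(self) -> WeightVector:
        """Normalized SMART & Swing weights (sum 1), computed once and cached."""
        if not self._weights:
            from .elicitation import normalize, swing_weights

            self._weights.update(normalize(swing_weights(self.ranking, self.increases)))
        return dict(self._weights)

    def weight(self, criterion_id: str) -> float:
        return self.weights[criterion_id]

    def ordered_ids(self) -> list[str]:
        """Criterion ids in rank order, ties in declaration order."""
        pos = {cid: i for i, cid in enumerate(self.ids)}
        return self.ranking.ordered_ids(tie_break=pos)


def validate_criteria_set(cs: CriteriaSet) -> list[str]:
    """Check every criteria-set invariant; return human-readable violations.

    Violations are returned, never raised, so a partially-built or hand-edited
    set can be diagnosed in full before use. An empty list means the set is
    valid.
    """
    problems: list[str] = []
    ids = [c.id for c in cs.criteria]
    if len(set(ids)) != len(ids):
        problems.append("duplicate criterion ids in criteria list")

    for c in cs.criteria:
        if c.category not in CATEGORIES:
            problems.append(
                f"criterion {c.id!r}: category {c.category!r} not one of {CATEGORIES}"
            )
        if len(c.levels) < 2:
            problems.append(f"criterion {c.id!r}: fewer than 2 outcome levels")
        labels = [lv.label for lv in c.levels]
        if len(set(labels)) != len(labels):
            problems.append(f"criterion {c.id!r}: duplicate level labels")
        for lv in c.levels:
            if not (0.0 <= lv.fraction <= 1.0):
                problems.append(
                    f"criterion {c.id!r}: level {lv.label!r} fraction "
                    f"{lv.fraction} outside [0, 1]"
                )
        fracs = [lv.fraction for lv in c.levels]
        if any(b >= a for a, b in zip(fracs, fracs[1:])):
            problems.append(
                f"criterion {c.id!r}: level fractions must be strictly "
                f"decreasing, got {fracs}"
            )

    ranked = cs.ranking.criterion_ids
    missing = set(ids) - ranked
    extra = ranked - set(ids)
    if missing:
        problems.append(f"ranking omits criteria: {sorted(missing)}")
    if extra:
        problems.append(f"ranking references unknown criteria: {sorted(extra)}")
    seen: set[str] = set()
    for g in cs.ranking.groups:
        if not g:
            problems.append("ranking contains an empty rank group")
        dup = g & seen
        if dup:
            problems.append(f"criteria appear in multiple rank groups: {sorted(dup)}")
        seen |= g

    inc_missing = set(ids) - set(cs.increases)
    if inc_missing:
        problems.append(f"weight increases missing for: {sorted(inc_missing)}")
    for cid, v in cs.increases.items():
        if v < 0:
            problems.append(f"criterion {cid!r}: negative weight increase {v}")

    return problems


def validate_profile(profile: DrugProfile, cs: CriteriaSet) -> list[str]:
    """Completeness/consistency check of a drug profile against a criteria set."""
    problems: list[str] = []
    for c in cs.criteria:
        if c.id not in profile.selections:
            problems.append(
                f"profile {profile.drug_name!r}: no selection for criterion {c.id!r}"
            )
            continue
        label = profile.selections[c.id]
        if label not in c.labels:
            problems.append(
                f"profile {profile.drug_name!r}: level {label!r} not defined "
                f"for criterion {c.id!r}"
            )
    unknown = set(profile.selections) - set(cs.ids)
    if unknown:
        problems.append(
            f"profile {profile.drug_name!r}: selections for unknown criteria "
            f"{sorted(unknown)}"
        )
    return problems


def _criteria_set_from_mapping(doc: Mapping) -> CriteriaSet:
    criteria = tuple(
        Criterion(
            id=c["id"],
            name=c["name"],
            category=c["category"],
            levels=tuple(
                OutcomeLevel(label=lv["label"], fraction=lv["score_percent"] / 100.0)
                for lv in c["levels"]
            ),
        )
        for c in doc["criteria"]
    )
    ranking = Ranking.from_groups(doc["ranking"])
    increases = {k: float(v) for k, v in doc["increases"].items()}
    return CriteriaSet(
        criteria=criteria,
        ranking=ranking,
        increases=increases,
        name=doc.get("name", "criteria-set"),
    )


def emirates_default() -> CriteriaSet:
    """The ten-criterion Emirates orphan-drug MCDA set.

    Criteria, outcome levels and fractional scores, the importance ranking
    (disease rarity and clinical evidence tied at rank 6), and the SMART &
    Swing weight increases as agreed in the UAE consensus session. Normalized
    weights derive from the swing chain: 25.1% cost-effectiveness down to
    2.6% patient age.
    """
    text = resources.files("orphanmcda").joinpath("data/emirates.yaml").read_text()
    return _criteria_set_from_mapping(yaml.safe_load(text))


def all_best_profile(cs: CriteriaSet, drug_name: str = "all-best") -> DrugProfile:
    return DrugProfile(drug_name, {c.id: c.best_label for c in cs.criteria})


def all_worst_profile(cs: CriteriaSet, drug_name: str = "all-worst") -> DrugProfile:
    return DrugProfile(drug_name, {c.id: c.worst_label for c in cs.criteria})
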