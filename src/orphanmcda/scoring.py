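"""Additive 0-100 scoring of drug profiles and multi-drug comparison.

A drug's score is the weight-fraction dot product scaled to 100 points:

    total = 100 * sum_i  w_i * f_i

where w_i is criterion i's normalized weight and f_i the fraction of the
outcome level selected for the drug on that criterion. A profile of all
best levels therefore scores exactly 100 and all worst levels exactly 0.

Two helper classifiers translate the numeric quantities behind the economic
criteria (budget share of the annual drug budget; incremental
cost-effectiveness ratio as a multiple of GDP per capita) into the
corresponding categorical outcome levels. The scorer itself consumes
categorical selections only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .criteria import CriteriaSet, DrugProfile, validate_profile

#: Scores are reported to one decimal point; full precision is kept internally.
REPORT_DECIMALS = 1


@dataclass(frozen=True)
class BreakdownRow:
    criterion_id: str
    criterion_name: str
    level_label: str
    fraction: float
    weight: float
    contribution: float  # weight * fraction * 100 points


@dataclass(frozen=True)
class ScoreBreakdown:
    """Per-criterion contributions and the 0-100 total for one drug."""

    drug_name: str
    rows: tuple[BreakdownRow, ...]
    total: float

    @property
    def rounded_total(self) -> float:
        return round(self.total, REPORT_DECIMALS)


def level_score(cs: CriteriaSet, criterion_id: str, level_label: str) -> float:
    """Fractional score of one outcome level (raises with the valid labels
    listed if the criterion or label is unknown)."""
    return cs.criterion(criterion_id).fraction_of(level_label)


def score_drug(profile: DrugProfile, cs: CriteriaSet) -> ScoreBreakdown:
    """Score one complete profile; breakdown rows come out in rank order."""
    problems = validate_profile(profile, cs)
    if problems:
        raise ValueError("; ".join(problems))
    weights = cs.weights
    rows = []
    for cid in cs.ordered_ids():
        crit = cs.criterion(cid)
        label = profile.selections[cid]
        frac = crit.fraction_of(label)
        w = weights[cid]
        rows.append(
            BreakdownRow(
                criterion_id=cid,
                criterion_name=crit.name,
                level_label=label,
                fraction=frac,
                weight=w,
                contribution=100.0 * w * frac,
            )
        )
    total = sum(r.contribution for r in rows)
    return ScoreBreakdown(drug_name=profile.drug_name, rows=tuple(rows), total=total)


def compare_drugs(
    profiles: Sequence[DrugProfile], cs: CriteriaSet
) -> list[ScoreBreakdown]:
    """Score several drugs and order them by descending total.

    Totals never depend on input order; the returned list is sorted by total
    (ties broken by drug name for determinism). Any number of drugs is
    accepted. Use :func:`ranks_of` for shared ranks at reported precision.
    """
    if not profiles:
        raise ValueError("no profiles to compare")
    names = [p.drug_name for p in profiles]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate drug names: {dupes}")
    breakdowns = [score_drug(p, cs) for p in profiles]
    return sorted(breakdowns, key=lambda b: (-b.total, b.drug_name))


def ranks_of(breakdowns: Sequence[ScoreBreakdown]) -> dict[str, int]:
    """Competition ranks (1224 style) of scored drugs; drugs whose totals tie
    at reported one-decimal precision share a rank."""
    ordered = sorted(breakdowns, key=lambda b: (-b.total, b.drug_name))
    ranks: dict[str, int] = {}
    last_rounded: float | None = None
    last_rank = 0
    for i, b in enumerate(ordered, start=1):
        r = b.rounded_total
        if last_rounded is not None and r == last_rounded:
            ranks[b.drug_name] = last_rank
        else:
            ranks[b.drug_name] = i
            last_rank = i
        last_rounded = r
    return ranks


# --- numeric helper classifiers -------------------------------------------
# Interval boundaries in the printed scoring functions overlap ("0.01-0.05"
# then "0.05-0.10"); both classifiers adopt half-open intervals with each
# boundary belonging to the range that starts there, giving a total,
# deterministic rule.

_BUDGET_BINS: tuple[tuple[float, str], ...] = (
    (0.01, "Below 0.01% of annual drug budget"),
    (0.05, "Between 0.01-0.05% of annual drug budget"),
    (0.10, "Between 0.05-0.10% of annual drug budget"),
    (0.30, "Between 0.1-0.3% of annual drug budget"),
    (float("inf"), "Above 0.3% of annual drug budget"),
)

_ICER_BINS: tuple[tuple[float, str], ...] = (
    (1.0, "Below 1x GDP per capita"),
    (2.0, "Between 1-2x GDP per capita"),
    (3.0, "Between 2-3x GDP per capita"),
    (5.0, "Between 3-5x GDP per capita"),
    (10.0, "Between 5-10x GDP per capita"),
    (float("inf"), "Above 10x GDP per capita"),
)


def classify_budget_share(share_percent: float) -> str:
    """Map a drug's expected spend, as percent of the annual drug budget, to
    its budget-impact outcome level."""
    if share_percent < 0:
        raise ValueError("budget share must be non-negative")
    for upper, label in _BUDGET_BINS:
        if share_percent < upper:
            return label
    raise AssertionError("unreachable: bins cover [0, inf)")


def classify_icer_multiple(icer: float, gdp_per_capita: float) -> str:
    """Map cost per QALY, relative to GDP per capita, to its
    cost-effectiveness outcome level."""
    if icer <= 0 or gdp_per_capita <= 0:
        raise ValueError("ICER and GDP per capita must be positive")
    ratio = icer / gdp_per_capita
    for upper, label in _ICER_BINS:
        if ratio < upper:
            return label
    raise AssertionError("unreachable: bins cover (0, inf)")
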