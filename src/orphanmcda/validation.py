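"""Concordance validation of scored drugs against predefined expert expectations.

Three deterministic checks, fixed before scoring:

1. **Threshold** — each drug's total falls on the expected side of 50 points
   (strictly above or strictly below; exactly 50.0 satisfies neither and is
   flagged indeterminate).
2. **Rank order** — the observed descending-score order matches the expected
   order. Observed ties are a failure unless the expectation declares the tie
   (by grouping names in one tier).
3. **Spread** — the gap between the highest and lowest total is at least a
   minimum number of points (40 by default).

Totals are rounded to one decimal before every comparison, i.e. checks run at
reported precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .scoring import REPORT_DECIMALS, ScoreBreakdown

DEFAULT_MIN_SPREAD = 40.0


@dataclass(frozen=True)
class ConcordanceExpectation:
    """Predefined expectations for a set of scored drugs.

    ``above_50`` maps each drug name to True (expected strictly above 50
    points) or False (strictly below). ``expected_order`` lists tiers best
    first; each tier is one name or a collection of names expected to tie.
    """

    above_50: Mapping[str, bool]
    expected_order: Sequence[str | Sequence[str]]
    min_spread: float = DEFAULT_MIN_SPREAD

    def order_tiers(self) -> list[frozenset[str]]:
        tiers = []
        for entry in self.expected_order:
            if isinstance(entry, str):
                tiers.append(frozenset([entry]))
            else:
                tiers.append(frozenset(entry))
        return tiers

    def drug_names(self) -> frozenset[str]:
        out: set[str] = set()
        for tier in self.order_tiers():
            out |= tier
        return frozenset(out)


@dataclass(frozen=True)
class ThresholdResult:
    drug_name: str
    total: float  # rounded
    expected_above: bool
    passed: bool
    indeterminate: bool = False


@dataclass(frozen=True)
class ConcordanceReport:
    """Outcome of the three checks; overall passes iff all three pass."""

    threshold_results: tuple[ThresholdResult, ...]
    threshold_pass: bool
    rank_pass: bool
    observed_order: tuple[frozenset[str], ...]
    expected_order: tuple[frozenset[str], ...]
    observed_spread: float
    min_spread: float
    spread_pass: bool
    notes: tuple[str, ...] = field(default=())

    @property
    def overall_pass(self) -> bool:
        return self.threshold_pass and self.rank_pass and self.spread_pass


ScoredLike = ScoreBreakdown | tuple[str, float]


def _name_total(item: ScoredLike) -> tuple[str, float]:
    if isinstance(item, ScoreBreakdown):
        return item.drug_name, item.total
    name, total = item
    return name, float(total)


def check_concordance(
    results: Sequence[ScoredLike], expectation: ConcordanceExpectation
) -> ConcordanceReport:
    """Run the three concordance checks on scored drugs.

    ``results`` may be ScoreBreakdowns or plain (name, total) pairs — the
    latter lets externally reported totals be validated without re-scoring.
    The input order is irrelevant: the observed order is recomputed from the
    totals.
    """
    if not results:
        raise ValueError("no scored drugs to validate")
    totals = dict(_name_total(r) for r in results)
    if len(totals) != len(results):
        raise ValueError("duplicate drug names in results")
    expected_names = expectation.drug_names()
    missing = expected_names - set(totals)
    if missing:
        raise ValueError(f"expected drugs absent from results: {sorted(missing)}")
    extra = set(totals) - expected_names
    if extra:
        raise ValueError(f"scored drugs not covered by expectation: {sorted(extra)}")
    if set(expectation.above_50) != expected_names:
        raise ValueError("threshold expectations must cover exactly the scored drugs")

    rounded = {name: round(t, REPORT_DECIMALS) for name, t in totals.items()}

    # 1. threshold: strict side of 50 at reported precision
    notes: list[str] = []
    threshold_results = []
    for name in sorted(totals, key=lambda n: -rounded[n]):
        r = rounded[name]
        expected_above = expectation.above_50[name]
        indeterminate = r == 50.0
        passed = (r > 50.0) if expected_above else (r < 50.0)
        if indeterminate:
            notes.append(f"{name}: total exactly 50.0 is indeterminate")
        threshold_results.append(
            ThresholdResult(name, r, expected_above, passed, indeterminate)
        )
    threshold_pass = all(t.passed for t in threshold_results)

    # 2. rank order: group observed ties at reported precision into tiers
    by_score = sorted(rounded.items(), key=lambda kv: (-kv[1], kv[0]))
    observed: list[set[str]] = []
    last: float | None = None
    for name, r in by_score:
        if last is not None and r == last:
            observed[-1].add(name)
        else:
            observed.append({name})
        last = r
    observed_tiers = tuple(frozenset(t) for t in observed)
    expected_tiers = tuple(expectation.order_tiers())
    rank_pass = observed_tiers == expected_tiers

    # 3. spread between highest and lowest comparator
    values = list(rounded.values())
    spread = round(max(values) - min(values), REPORT_DECIMALS)
    spread_pass = spread >= expectation.min_spread

    return ConcordanceReport(
        threshold_results=tuple(threshold_results),
        threshold_pass=threshold_pass,
        rank_pass=rank_pass,
        observed_order=observed_tiers,
        expected_order=expected_tiers,
        observed_spread=spread,
        min_spread=expectation.min_spread,
        spread_pass=spread_pass,
        notes=tuple(notes),
    )
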