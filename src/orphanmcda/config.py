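"""Structured-text configuration for criteria sets, profiles, and expectations.

YAML is the canonical dialect; JSON files are accepted as an alternate
encoding of the same schema (every JSON document is valid YAML). Schema
validation is pydantic-based and reports JSON-pointer-style locations
(``/criteria/0/levels/1/score_percent``) so committee-edited configs fail
with an exact position.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Mapping

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .criteria import (
    CATEGORIES,
    CriteriaSet,
    Criterion,
    DrugProfile,
    OutcomeLevel,
    Ranking,
    emirates_default,
)
from .validation import ConcordanceExpectation


class ConfigError(ValueError):
    """A configuration file failed schema validation or resolution."""


def _pointer(loc: tuple) -> str:
    return "/" + "/".join(str(p) for p in loc)


class LevelConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    score_percent: float = Field(ge=0, le=100)


class CriterionConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    name: str
    category: Literal["disease-related", "economics-related", "treatment-related"]
    levels: list[LevelConfig] = Field(min_length=2)


class ProfileConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    drug: str
    selections: dict[str, str]


class ExpectationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    above_50: list[str] = Field(default_factory=list)
    below_50: list[str] = Field(default_factory=list)
    expected_order: list[str | list[str]]
    min_spread: float = Field(default=40.0, ge=0)


class ReportOptions(BaseModel):
    model_config = ConfigDict(extra="forbid")
    precision: int = Field(default=1, ge=0, le=10)
    format: Literal["csv", "json", "markdown"] = "markdown"


class ToolConfig(BaseModel):
    """Top-level config: a criteria-set definition or a reference to the
    embedded Emirates default, plus optional profiles, expectations, and
    report options."""

    model_config = ConfigDict(extra="forbid")

    name: str = "criteria-set"
    use_default: bool = False
    criteria: list[CriterionConfig] = Field(default_factory=list)
    ranking: list[list[str]] = Field(default_factory=list)
    increases: dict[str, float] = Field(default_factory=dict)
    profiles: list[ProfileConfig] = Field(default_factory=list)
    expectations: ExpectationConfig | None = None
    report: ReportOptions = Field(default_factory=ReportOptions)

    @model_validator(mode="after")
    def _check_coverage(self) -> "ToolConfig":
        if self.use_default:
            return self
        if not self.criteria:
            raise ValueError(
                "config must define criteria or set use_default: true"
            )
        ids = {c.id for c in self.criteria}
        ranked = {cid for group in self.ranking for cid in group}
        for cid in sorted(ids - ranked):
            raise ValueError(f"ranking omits criterion {cid!r}")
        for cid in sorted(ranked - ids):
            raise ValueError(f"ranking references unknown criterion {cid!r}")
        for cid in sorted(ids - set(self.increases)):
            raise ValueError(f"increases omit criterion {cid!r}")
        for cid, v in self.increases.items():
            if v < 0:
                raise ValueError(f"negative increase for criterion {cid!r}")
        return self


def load_config(path: str | Path) -> ToolConfig:
    """Parse and schema-validate a YAML/JSON config file."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return ToolConfig.model_validate(doc)
    except ValidationError as exc:
        lines = [
            f"  at {_pointer(err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError(f"{path}: invalid config:\n" + "\n".join(lines)) from exc


def criteria_set_from_config(config: ToolConfig) -> CriteriaSet:
    """Build the domain CriteriaSet a config describes (or the embedded default)."""
    if config.use_default:
        return emirates_default()
    criteria = tuple(
        Criterion(
            id=c.id,
            name=c.name,
            category=c.category,
            levels=tuple(
                OutcomeLevel(lv.label, lv.score_percent / 100.0) for lv in c.levels
            ),
        )
        for c in config.criteria
    )
    return CriteriaSet(
        criteria=criteria,
        ranking=Ranking.from_groups(config.ranking),
        increases=dict(config.increases),
        name=config.name,
    )


def profiles_from_config(config: ToolConfig, cs: CriteriaSet) -> list[DrugProfile]:
    """Resolve profile selections against the criteria set; unknown criteria
    or level labels are resolution errors."""
    profiles = []
    for p in config.profiles:
        for cid, label in p.selections.items():
            try:
                cs.criterion(cid).fraction_of(label)
            except KeyError as exc:
                raise ConfigError(f"profile {p.drug!r}: {exc.args[0]}") from exc
        profiles.append(DrugProfile(p.drug, dict(p.selections)))
    return profiles


def expectation_from_config(config: ExpectationConfig) -> ConcordanceExpectation:
    above = {name: True for name in config.above_50}
    below = {name: False for name in config.below_50}
    overlap = set(above) & set(below)
    if overlap:
        raise ConfigError(f"drugs listed both above and below 50: {sorted(overlap)}")
    return ConcordanceExpectation(
        above_50={**above, **below},
        expected_order=[
            e if isinstance(e, str) else list(e) for e in config.expected_order
        ],
        min_spread=config.min_spread,
    )


def load_expectations(path: str | Path) -> ConcordanceExpectation:
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    try:
        cfg = ExpectationConfig.model_validate(doc)
    except ValidationError as exc:
        lines = [f"  at {_pointer(err['loc'])}: {err['msg']}" for err in exc.errors()]
        raise ConfigError(f"{path}: invalid expectations:\n" + "\n".join(lines)) from exc
    return expectation_from_config(cfg)


# --- serialization ---------------------------------------------------------

def criteria_set_to_mapping(cs: CriteriaSet) -> dict:
    """Plain mapping form of a criteria set, round-trippable through
    :func:`load_config` / :func:`criteria_set_from_config`."""
    pos = {cid: i for i, cid in enumerate(c.id for c in cs.criteria)}
    return {
        "name": cs.name,
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "category": c.category,
                "levels": [
                    # round away float noise so percent -> fraction -> percent
                    # is the identity
                    {"label": lv.label, "score_percent": round(lv.fraction * 100, 10)}
                    for lv in c.levels
                ],
            }
            for c in cs.criteria
        ],
        "ranking": [
            sorted(group, key=lambda cid: pos.get(cid, 0))
            for group in cs.ranking.groups
        ],
        "increases": {c.id: cs.increases[c.id] for c in cs.criteria},
    }


def write_criteria_set(cs: CriteriaSet, path: str | Path) -> None:
    """Export a criteria set to a standalone YAML config file."""
    doc = criteria_set_to_mapping(cs)
    Path(path).write_text(
        yaml.safe_dump(doc, sort_keys=False, allow_unicode=True), encoding="utf-8"
    )


def config_hash(path: str | Path) -> str:
    """SHA-256 of a config file's bytes, for audit logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# --- tabular (CSV) input ---------------------------------------------------

def load_profiles_csv(path: str | Path, cs: CriteriaSet) -> list[DrugProfile]:
    """Read drug profiles from CSV laid out like the original spreadsheet:
    criteria as rows (first column ``criterion`` holding ids), one column per
    drug, cells holding the selected outcome-level label."""
    import pandas as pd

    df = pd.read_csv(path, dtype=str)
    first = df.columns[0]
    if first.lower() != "criterion":
        raise ConfigError(
            f"{path}: first column must be 'criterion', got {first!r}"
        )
    df = df.set_index(first)
    profiles = []
    for drug in df.columns:
        selections = {}
        for cid, label in df[drug].items():
            if not isinstance(label, str) or not label.strip():
                raise ConfigError(f"{path}: empty selection for {drug!r}/{cid!r}")
            try:
                cs.criterion(str(cid)).fraction_of(label.strip())
            except KeyError as exc:
                raise ConfigError(f"{path}: {exc.args[0]}") from exc
            selections[str(cid)] = label.strip()
        profiles.append(DrugProfile(drug, selections))
    return profiles


def _votes_frame(path: str | Path):
    import pandas as pd

    df = pd.read_csv(path)
    first = df.columns[0]
    if first.lower() != "participant":
        raise ConfigError(f"{path}: first column must be 'participant', got {first!r}")
    return df.set_index(first)


def load_rank_votes_csv(path: str | Path) -> dict[str, dict[str, float]]:
    """One row per participant, one column per criterion, cells = rank positions."""
    df = _votes_frame(path)
    return {
        str(p): {str(c): float(v) for c, v in row.items()}
        for p, row in df.iterrows()
    }


def load_increase_votes_csv(path: str | Path) -> dict[str, dict[str, float]]:
    """One row per participant, one column per criterion, cells = percent increases."""
    return load_rank_votes_csv(path)


def load_count_votes_csv(path: str | Path) -> list[int]:
    """One row per participant with a ``count`` column of desired criteria counts."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "count" not in cols:
        raise ConfigError(f"{path}: expected a 'count' column")
    return [int(v) for v in df[cols["count"]]]
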