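"""Deterministic report writers: CSV (RFC 4180), JSON, and markdown.

Identical inputs produce byte-identical files. Numbers are written at the
configured precision (default one decimal, the tool's reporting convention).
"""

from __future__ import annotations

import csv
import io
import json
from pathlib import Path
from typing import Sequence

from .scoring import ScoreBreakdown
from .validation import ConcordanceReport

FORMATS = ("csv", "json", "markdown")


def _fmt(x: float, precision: int) -> str:
    return f"{x:.{precision}f}"


# --- score breakdowns ------------------------------------------------------

def breakdown_rows(
    breakdowns: Sequence[ScoreBreakdown], precision: int = 1
) -> list[dict[str, str]]:
    """Flat one-row-per-criterion-per-drug view shared by all formats."""
    out = []
    for b in breakdowns:
        for r in b.rows:
            out.append(
                {
                    "drug": b.drug_name,
                    "criterion": r.criterion_id,
                    "criterion_name": r.criterion_name,
                    "level": r.level_label,
                    "level_score_percent": _fmt(r.fraction * 100, precision),
                    "weight_percent": _fmt(r.weight * 100, precision),
                    "contribution_points": _fmt(r.contribution, precision),
                    "total_points": _fmt(b.total, precision),
                }
            )
    return out


def breakdowns_to_csv(breakdowns: Sequence[ScoreBreakdown], precision: int = 1) -> str:
    rows = breakdown_rows(breakdowns, precision)
    buf = io.StringIO()
    writer = csv.DictWriter(
        buf, fieldnames=list(rows[0].keys()), lineterminator="\r\n"
    )
    writer.writeheader()
    writer.writerows(rows)
    return buf.getvalue()


def breakdowns_to_json(breakdowns: Sequence[ScoreBreakdown], precision: int = 1) -> str:
    doc = {
        "drugs": [
            {
                "name": b.drug_name,
                "total": round(b.total, precision),
                "criteria": [
                    {
                        "criterion": r.criterion_id,
                        "level": r.level_label,
                        "level_score_percent": round(r.fraction * 100, precision),
                        "weight_percent": round(r.weight * 100, precision),
                        "contribution_points": round(r.contribution, precision),
                    }
                    for r in b.rows
                ],
            }
            for b in breakdowns
        ]
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |"]
    lines.append("| " + " | ".join("---" for _ in header) + " |")
    for row in rows:
        lines.append("| " + " | ".join(row) + " |")
    return "\n".join(lines)


def breakdowns_to_markdown(
    breakdowns: Sequence[ScoreBreakdown], precision: int = 1
) -> str:
    parts = []
    for b in breakdowns:
        parts.append(f"### {b.drug_name} — {_fmt(b.total, precision)} points\n")
        rows = [
            [
                r.criterion_id,
                r.level_label,
                _fmt(r.fraction * 100, precision),
                _fmt(r.weight * 100, precision),
                _fmt(r.contribution, precision),
            ]
            for r in b.rows
        ]
        parts.append(
            _md_table(
                ["criterion", "level", "level score %", "weight %", "points"], rows
            )
        )
        parts.append("")
    return "\n".join(parts) + "\n"


# --- concordance reports ---------------------------------------------------

def _tier_str(tier: frozenset[str]) -> str:
    names = sorted(tier)
    return names[0] if len(names) == 1 else "{" + ", ".join(names) + "}"


def concordance_to_dict(report: ConcordanceReport, precision: int = 1) -> dict:
    return {
        "threshold": {
            "pass": report.threshold_pass,
            "drugs": [
                {
                    "drug": t.drug_name,
                    "total": round(t.total, precision),
                    "expected": "above 50" if t.expected_above else "below 50",
                    "pass": t.passed,
                    "indeterminate": t.indeterminate,
                }
                for t in report.threshold_results
            ],
        },
        "rank_order": {
            "pass": report.rank_pass,
            "observed": [sorted(t) for t in report.observed_order],
            "expected": [sorted(t) for t in report.expected_order],
        },
        "spread": {
            "pass": report.spread_pass,
            "observed": round(report.observed_spread, precision),
            "minimum": report.min_spread,
        },
        "overall_pass": report.overall_pass,
    }


def concordance_to_json(report: ConcordanceReport, precision: int = 1) -> str:
    return json.dumps(concordance_to_dict(report, precision), indent=2, sort_keys=True) + "\n"


def concordance_to_csv(report: ConcordanceReport, precision: int = 1) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(["check", "item", "value", "expected", "pass"])
    for t in report.threshold_results:
        writer.writerow(
            [
                "threshold",
                t.drug_name,
                _fmt(t.total, precision),
                "above 50" if t.expected_above else "below 50",
                str(t.passed),
            ]
        )
    writer.writerow(
        [
            "rank_order",
            "order",
            " > ".join(_tier_str(t) for t in report.observed_order),
            " > ".join(_tier_str(t) for t in report.expected_order),
            str(report.rank_pass),
        ]
    )
    writer.writerow(
        [
            "spread",
            "max-min",
            _fmt(report.observed_spread, precision),
            f">= {report.min_spread}",
            str(report.spread_pass),
        ]
    )
    writer.writerow(["overall", "", "", "", str(report.overall_pass)])
    return buf.getvalue()


def concordance_to_markdown(report: ConcordanceReport, precision: int = 1) -> str:
    def mark(ok: bool) -> str:
        return "PASS" if ok else "FAIL"

    rows = [
        [
            t.drug_name,
            _fmt(t.total, precision),
            "above 50" if t.expected_above else "below 50",
            mark(t.passed),
        ]
        for t in report.threshold_results
    ]
    parts = [
        "## Concordance report\n",
        f"**Threshold check: {mark(report.threshold_pass)}**\n",
        _md_table(["drug", "total", "expected", "result"], rows),
        "",
        f"**Rank-order check: {mark(report.rank_pass)}**\n",
        f"- observed: {' > '.join(_tier_str(t) for t in report.observed_order)}",
        f"- expected: {' > '.join(_tier_str(t) for t in report.expected_order)}",
        "",
        f"**Spread check: {mark(report.spread_pass)}** — observed "
        f"{_fmt(report.observed_spread, precision)} vs minimum {report.min_spread}",
        "",
        f"**Overall: {mark(report.overall_pass)}**",
    ]
    if report.notes:
        parts.append("")
        parts.extend(f"- note: {n}" for n in report.notes)
    return "\n".join(parts) + "\n"


def write_report(
    results: Sequence[ScoreBreakdown] | ConcordanceReport,
    fmt: str,
    path: str | Path,
    precision: int = 1,
) -> None:
    """Write comparison or concordance results to ``path`` in ``fmt``
    (csv / json / markdown). Output is deterministic for identical inputs."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown report format {fmt!r}; choose from {FORMATS}")
    if isinstance(results, ConcordanceReport):
        render = {
            "csv": concordance_to_csv,
            "json": concordance_to_json,
            "markdown": concordance_to_markdown,
        }[fmt]
        text = render(results, precision)
    else:
        render = {
            "csv": breakdowns_to_csv,
            "json": breakdowns_to_json,
            "markdown": breakdowns_to_markdown,
        }[fmt]
        text = render(list(results), precision)
    Path(path).write_text(text, encoding="utf-8", newline="")
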