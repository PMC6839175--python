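"""Hard filtering of called variants with GATK-style filter expressions.

A filter expression is a disjunction of clauses "KEY op THRESHOLD"
joined by "||"; a record FAILS when at least one clause evaluates true
on a *present* annotation. Absent annotations make their clause false
(pass) — the VariantFiltration convention, and load-bearing here because
HaplotypeScore is never computed, so its clause in the standard SNP
expression is always vacuous. Failed records are retained with their
filter status set rather than deleted, so downstream metrics can choose
PASS-only or all records.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

SNP_HARD_FILTER = (
    "QD < 2.0 || FS > 60.0 || MQ < 40.0 || HaplotypeScore > 13.0 "
    "|| MQRankSum < -12.5 || ReadPosRankSum < -8.0"
)
INDEL_HARD_FILTER = "QD < 2.0 || FS > 200.0 || ReadPosRankSum < -20.0"

KNOWN_ANNOTATIONS = frozenset(
    {
        "QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "HaplotypeScore",
        "BaseQRankSum", "SOR", "DP", "QUAL", "AC", "AN",
    }
)

_CLAUSE_RE = re.compile(r"\s*([A-Za-z_][A-Za-z0-9_]*)\s*([<>])\s*(-?\d+(?:\.\d+)?)\s*$")


@dataclass(frozen=True)
class FilterClause:
    key: str
    comparator: str  # '<' or '>'
    threshold: float

    @property
    def name(self) -> str:
        lt = "lt" if self.comparator == "<" else "gt"
        return f"{self.key}_{lt}_{self.threshold:g}"

    def fails(self, value) -> bool:
        """True when the clause fires; absent (None/NaN) values pass."""
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return False
        return value < self.threshold if self.comparator == "<" else value > self.threshold

    def render(self) -> str:
        return f"{self.key} {self.comparator} {self.threshold:g}"


@dataclass(frozen=True)
class FilterSpec:
    name: str
    clauses: tuple[FilterClause, ...]

    def render(self) -> str:
        return " || ".join(c.render() for c in self.clauses)


def parse_filter_expression(text: str, name: str = "hard_filter") -> FilterSpec:
    """Parse 'KEY op NUM || ...' into a FilterSpec.

    Raises ValueError with the character position of a malformed clause
    or an unknown annotation key.
    """
    clauses = []
    offset = 0
    for part in text.split("||"):
        m = _CLAUSE_RE.match(part)
        if m is None:
            raise ValueError(
                f"malformed filter clause at position {offset}: {part.strip()!r}"
            )
        key, op, num = m.group(1), m.group(2), float(m.group(3))
        if key not in KNOWN_ANNOTATIONS:
            raise ValueError(f"unknown annotation key at position {offset}: {key!r}")
        clauses.append(FilterClause(key, op, num))
        offset += len(part) + 2
    if not clauses:
        raise ValueError("empty filter expression")
    return FilterSpec(name, tuple(clauses))


def evaluate_record(annotations: dict, spec: FilterSpec) -> list[str]:
    """Names of the clauses a single annotation mapping fails."""
    return [c.name for c in spec.clauses if c.fails(annotations.get(c.key))]


def apply_hard_filter(
    calls: pd.DataFrame,
    spec: "FilterSpec | str" = SNP_HARD_FILTER,
    indel_spec: "FilterSpec | str | None" = INDEL_HARD_FILTER,
) -> pd.DataFrame:
    """Set the filter column: PASS or semicolon-joined failed clause names.

    SNP records get ``spec``; INS/DEL records get ``indel_spec`` when one
    is supplied (otherwise ``spec`` applies to everything).
    """
    if isinstance(spec, str):
        spec = parse_filter_expression(spec, "snp_filter")
    if isinstance(indel_spec, str):
        indel_spec = parse_filter_expression(indel_spec, "indel_filter")
    out = calls.copy()
    out.attrs.update(calls.attrs)
    status = []
    for _, row in calls.iterrows():
        use = spec
        if indel_spec is not None and row.get("vclass", "SNP") != "SNP":
            use = indel_spec
        failed = evaluate_record(row, use)
        status.append(";".join(failed) if failed else "PASS")
    out["filter"] = status
    return out


def pass_only(calls: pd.DataFrame) -> pd.DataFrame:
    out = calls[calls["filter"] == "PASS"].reset_index(drop=True)
    out.attrs.update(calls.attrs)
    return out
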