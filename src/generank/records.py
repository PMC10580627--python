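"""Pipe-delimited gene scoring records: grammar, parser, formatter, validator.

A scoring response is a single line of 21 ``|``-separated fields:

    gene symbol | gene name | summary |
    (comment | references | score) x 6 criteria (a–f)

Scores are integers on the rubric scale; references are quoted
``"Author, Title, Year, Journal"`` groups or the sentinel
``No specific references found``.  The parser applies a bounded repair pass
(join stray line breaks, strip a leading/trailing delimiter, collapse
doubled delimiters) before requiring exactly 21 fields — chat models
occasionally deviate from the requested format, and bounded repair keeps
the behavior auditable where silent coercion would not be.

Fields may not contain a raw ``|``; the formatter substitutes ``/`` (an
artifact convention, since the record grammar has no escape rule).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError
from .rubric import CRITERION_KEYS, Rubric

__all__ = [
    "ReferenceCitation",
    "CriterionAssessment",
    "ScoreRecord",
    "RecordViolation",
    "NO_REFERENCE_SENTINEL",
    "parse_score_record",
    "format_score_record",
    "parse_references",
    "validate_record",
]

NO_REFERENCE_SENTINEL = "No specific references found"

_FIELD_COUNT = 21
_QUOTED_GROUP = re.compile(r'"([^"]*)"')
_YEAR = re.compile(r"^\s*\d{4}\s*$")


@dataclass(frozen=True)
class ReferenceCitation:
    first_author: str
    title: str
    year: str
    journal: str
    pmid: str | None = None
    note: str | None = None  # set when a malformed group was kept leniently

    def format(self) -> str:
        return f'"{self.first_author}, {self.title}, {self.year}, {self.journal}"'


@dataclass(frozen=True)
class CriterionAssessment:
    comment: str
    references: tuple[ReferenceCitation, ...]
    score: int


@dataclass(frozen=True)
class ScoreRecord:
    gene_symbol: str
    gene_name: str
    summary: str
    assessments: dict[str, CriterionAssessment] = field(default_factory=dict)

    def scores(self) -> tuple[int, ...]:
        return tuple(self.assessments[k].score for k in CRITERION_KEYS)


@dataclass(frozen=True)
class RecordViolation:
    severity: str  # "error" | "warning"
    field: str
    message: str


def parse_references(text: str) -> list[ReferenceCitation]:
    """Split a references field into citations.

    Quoted groups are extracted first; each group is comma-split into
    (author, title..., year, journal), the title absorbing interior commas.
    The no-reference sentinel (or an empty field) yields an empty list.
    A malformed group is kept leniently as a single citation whose title
    preserves the raw text, with a ``note`` explaining the problem.
    """
    stripped = text.strip()
    if not stripped or stripped.lower().startswith("no specific references") \
            or stripped.lower() == "no references found":
        return []
    groups = _QUOTED_GROUP.findall(stripped)
    if not groups:
        groups = [stripped]
    citations: list[ReferenceCitation] = []
    for group in groups:
        parts = [p.strip() for p in group.split(",")]
        if len(parts) >= 4 and _YEAR.match(parts[-2]):
            citations.append(
                ReferenceCitation(
                    first_author=parts[0],
                    title=", ".join(parts[1:-2]),
                    year=parts[-2],
                    journal=parts[-1],
                )
            )
        else:
            citations.append(
                ReferenceCitation(
                    first_author="unknown",
                    title=group.strip(),
                    year="",
                    journal="",
                    note="malformed citation group; raw text kept in title",
                )
            )
    return citations


def _format_references(refs: tuple[ReferenceCitation, ...]) -> str:
    if not refs:
        return NO_REFERENCE_SENTINEL
    return "; ".join(r.format() for r in refs)


def _repair(line: str) -> str:
    # bounded repair: newlines become spaces, stray edge/doubled delimiters go
    joined = " ".join(part.strip() for part in line.splitlines() if part.strip())
    joined = joined.strip()
    joined = re.sub(r"\|\|+", "|", joined)  # literal "||", not empty fields
    joined = joined.strip()
    if joined.startswith("|"):
        joined = joined[1:]
    if joined.endswith("|"):
        joined = joined[:-1]
    return joined.strip()


def parse_score_record(line: str, rubric: Rubric) -> ScoreRecord:
    """Parse one 21-field scoring line into a :class:`ScoreRecord`.

    Raises
    ------
    ParseError
        If the field count differs from 21 after repair, a score field is
        not an integer, or a score falls outside the rubric bounds.
    """
    repaired = _repair(line)
    fields = [f.strip() for f in repaired.split("|")]
    if len(fields) != _FIELD_COUNT:
        raise ParseError(
            f"expected {_FIELD_COUNT} pipe-delimited fields, observed {len(fields)}"
        )
    gene_symbol, gene_name, summary = fields[0], fields[1], fields[2]
    assessments: dict[str, CriterionAssessment] = {}
    for i, key in enumerate(CRITERION_KEYS):
        comment, refs_text, score_text = fields[3 + 3 * i : 6 + 3 * i]
        if not re.fullmatch(r"[+-]?\d+", score_text):
            raise ParseError(
                f"criterion {key!r}: score field {score_text!r} is not an integer"
            )
        score = int(score_text)
        if not (rubric.score_min <= score <= rubric.score_max):
            raise ParseError(
                f"criterion {key!r}: score {score} outside "
                f"[{rubric.score_min}, {rubric.score_max}]"
            )
        assessments[key] = CriterionAssessment(
            comment=comment,
            references=tuple(parse_references(refs_text)),
            score=score,
        )
    return ScoreRecord(
        gene_symbol=gene_symbol,
        gene_name=gene_name,
        summary=summary,
        assessments=assessments,
    )


def _clean_field(text: str) -> str:
    # the grammar has no escape rule for the delimiter; substitute
    return " ".join(text.replace("|", "/").split())


def format_score_record(rec: ScoreRecord) -> str:
    """Serialize a record to its canonical single-line form.

    21 fields joined by `` | `` (20 delimiters, no trailing delimiter);
    empty reference lists emit the no-reference sentinel.
    """
    fields = [
        _clean_field(rec.gene_symbol),
        _clean_field(rec.gene_name),
        _clean_field(rec.summary),
    ]
    for key in CRITERION_KEYS:
        a = rec.assessments[key]
        fields.append(_clean_field(a.comment))
        fields.append(_clean_field(_format_references(a.references)))
        fields.append(str(a.score))
    return " | ".join(fields)


def validate_record(rec: ScoreRecord, rubric: Rubric) -> list[RecordViolation]:
    """Check a parsed record against the rubric's contract.

    Returns violations rather than raising: an out-of-bounds score is an
    error; a score at or above the comment threshold with an empty comment
    or no references, or more than three references, is a warning (the
    format requests "up to three key supporting references").
    """
    violations: list[RecordViolation] = []
    for key in CRITERION_KEYS:
        a = rec.assessments.get(key)
        if a is None:
            violations.append(
                RecordViolation("error", key, f"criterion {key!r} missing")
            )
            continue
        if not (rubric.score_min <= a.score <= rubric.score_max):
            violations.append(
                RecordViolation(
                    "error",
                    key,
                    f"score {a.score} outside [{rubric.score_min}, {rubric.score_max}]",
                )
            )
        if a.score >= rubric.comment_threshold:
            if not a.comment.strip():
                violations.append(
                    RecordViolation(
                        "warning", key,
                        f"score {a.score} >= {rubric.comment_threshold} "
                        "but no evaluative comment",
                    )
                )
            if not a.references:
                violations.append(
                    RecordViolation(
                        "warning", key,
                        f"score {a.score} >= {rubric.comment_threshold} "
                        "but no supporting references",
                    )
                )
        if len(a.references) > 3:
            violations.append(
                RecordViolation(
                    "warning", key,
                    f"{len(a.references)} references exceed the requested maximum of 3",
                )
            )
    return violations
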