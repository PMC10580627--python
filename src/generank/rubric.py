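"""Scoring rubric and prompt templates.

The rubric is the six-statement, three-theme questionnaire each candidate
gene is scored against on an integer 0–10 scale, together with the score
band guide and the "comment required at or above 4" rule.  Step prompts for
the whole workflow (convergence, scoring, summarization, fact-checking,
selection, data-informed selection) live alongside it as fillable templates
with named-brace placeholders and an explicit required-keys manifest, so a
missing context key fails before any backend is called.

Templates are data, not code: the default bundle ships as a YAML resource
and custom bundles can be loaded/dumped through the same round trip,
reflecting how these prompts are refined iteratively in practice.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Any, Mapping

import yaml

from .errors import ValidationError

__all__ = [
    "CriterionStatement",
    "Rubric",
    "PromptTemplate",
    "PromptBundle",
    "CRITERION_KEYS",
    "default_rubric",
    "default_templates",
    "render_prompt",
    "customize_rubric",
    "rubric_context",
    "load_bundle",
    "dump_bundle",
]

CRITERION_KEYS = ("a", "b", "c", "d", "e", "f")


@dataclass(frozen=True)
class CriterionStatement:
    key: str
    text: str
    theme: str

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValidationError(f"criterion {self.key!r}: statement text is empty")


@dataclass(frozen=True)
class Rubric:
    """Six criterion statements plus the scoring scale and band guide."""

    statements: tuple[CriterionStatement, ...]
    score_min: int = 0
    score_max: int = 10
    guide: Mapping[str, str] = field(default_factory=dict)
    comment_threshold: int = 4

    def __post_init__(self) -> None:
        keys = [s.key for s in self.statements]
        if len(set(keys)) != len(keys):
            raise ValidationError(f"duplicate criterion keys: {keys}")
        if self.score_min > self.score_max:
            raise ValidationError("score_min exceeds score_max")

    @property
    def keys(self) -> tuple[str, ...]:
        return tuple(s.key for s in self.statements)

    def statement(self, key: str) -> CriterionStatement:
        for s in self.statements:
            if s.key == key:
                return s
        raise ValidationError(f"unknown criterion key {key!r}")

    def band_for(self, score: int) -> str:
        """Return the guide description covering ``score``.

        Bands are written as ``"0"`` or ``"1–3"`` (en- or plain dash).
        """
        for band, desc in self.guide.items():
            lo, _, hi = band.replace("-", "–").partition("–")
            lo_i = int(lo)
            hi_i = int(hi) if hi else lo_i
            if lo_i <= score <= hi_i:
                return desc
        raise ValidationError(f"score {score} falls in no guide band")


@dataclass(frozen=True)
class PromptTemplate:
    step_id: str
    template: str
    required_keys: tuple[str, ...]

    def placeholders(self) -> set[str]:
        return {
            name
            for _, name, _, _ in string.Formatter().parse(self.template)
            if name
        }

    def render(self, context: Mapping[str, Any]) -> str:
        missing = [k for k in self.required_keys if k not in context]
        if missing:
            raise ValidationError(
                f"prompt {self.step_id}: missing context key(s) {missing}"
            )
        unfilled = self.placeholders() - set(context)
        if unfilled:
            raise ValidationError(
                f"prompt {self.step_id}: no value for placeholder(s) {sorted(unfilled)}"
            )
        prepared = {
            k: " ".join(str(x) for x in v) if isinstance(v, (list, tuple)) else v
            for k, v in context.items()
        }
        return self.template.format_map(prepared)


PromptBundle = dict[str, PromptTemplate]

_DEFAULT_RESOURCE = "prompts.yaml"


def _bundle_from_mapping(payload: Mapping[str, Any]) -> tuple[Rubric, PromptBundle]:
    rub = payload["rubric"]
    rubric = Rubric(
        statements=tuple(
            CriterionStatement(key=s["key"], text=s["text"], theme=s["theme"])
            for s in rub["statements"]
        ),
        score_min=int(rub["score_min"]),
        score_max=int(rub["score_max"]),
        guide=dict(rub["guide"]),
        comment_threshold=int(rub["comment_threshold"]),
    )
    templates: PromptBundle = {}
    for step_id, spec in payload["templates"].items():
        templates[str(step_id)] = PromptTemplate(
            step_id=str(step_id),
            template=spec["template"],
            required_keys=tuple(spec.get("required_keys", ())),
        )
    return rubric, templates


def load_bundle(text: str | None = None) -> tuple[Rubric, PromptBundle]:
    """Load (rubric, templates) from YAML text, or the packaged default."""
    if text is None:
        text = (
            resources.files("generank.data").joinpath(_DEFAULT_RESOURCE).read_text("utf-8")
        )
    return _bundle_from_mapping(yaml.safe_load(text))


def dump_bundle(rubric: Rubric, templates: PromptBundle) -> str:
    """Serialize a bundle back to YAML (inverse of :func:`load_bundle`)."""
    payload = {
        "rubric": {
            "score_min": rubric.score_min,
            "score_max": rubric.score_max,
            "comment_threshold": rubric.comment_threshold,
            "statements": [
                {"key": s.key, "theme": s.theme, "text": s.text}
                for s in rubric.statements
            ],
            "guide": dict(rubric.guide),
        },
        "templates": {
            t.step_id: {
                "required_keys": list(t.required_keys),
                "template": t.template,
            }
            for t in templates.values()
        },
    }
    return yaml.safe_dump(payload, allow_unicode=True, sort_keys=False)


def default_rubric() -> Rubric:
    """The packaged six-statement rubric (0–10 scale, comment rule at 4)."""
    rubric, _ = load_bundle()
    return rubric


def default_templates() -> PromptBundle:
    _, templates = load_bundle()
    return templates


def render_prompt(
    step_id: str,
    context: Mapping[str, Any],
    templates: PromptBundle | None = None,
) -> str:
    """Render the prompt for one workflow step.

    Rendering is pure: the same (step_id, context) always yields identical
    text.  List values are joined by single spaces (gene lists are passed
    space-separated).
    """
    if templates is None:
        templates = default_templates()
    if step_id not in templates:
        raise ValidationError(
            f"unknown prompt step {step_id!r}; known: {sorted(templates)}"
        )
    return templates[step_id].render(context)


def rubric_context(rubric: Rubric) -> dict[str, str]:
    """Context mapping feeding the scoring prompt's statement placeholders."""
    return {f"statement_{s.key}": s.text for s in rubric.statements}


def customize_rubric(base: Rubric, replacements: Mapping[str, str]) -> Rubric:
    """Return a new rubric with some statement texts replaced.

    Statements are tailored per module aggregate (e.g. an erythroid
    statement for the erythroid aggregate, a neutrophil one elsewhere);
    untouched statements, scale, and guide carry over, and ``base`` is not
    modified.
    """
    known = set(base.keys)
    unknown = set(replacements) - known
    if unknown:
        raise ValidationError(f"unknown criterion key(s): {sorted(unknown)}")
    new_statements = tuple(
        replace(s, text=replacements[s.key]) if s.key in replacements else s
        for s in base.statements
    )
    return replace(base, statements=new_statements)
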