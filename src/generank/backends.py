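"""Completion backends: a uniform contract plus deterministic substitutes.

The workflow only ever talks to a backend through :func:`complete`, which
adds context-budget checks, bounded retries on transient failures, optional
transcript recording, and token accounting.  Three backends ship:

* :class:`ScriptedBackend` — a lookup table of canned responses, keyed by
  ``(tag, entity)`` (e.g. ``("3.3", "GPX4")``) or by request cache key.
  Used to replay printed chat transcripts through the pipeline.
* :class:`SimulatedScoringBackend` — a synthetic scorer that answers
  scoring prompts with syntactically valid 21-field records drawn around a
  configured latent relevance profile (clip-round of latent + Gaussian
  noise), with a private, replicate-addressable random stream.  It stands
  in for a live chat model so aggregation and recovery behavior can be
  studied offline with known ground truth.
* :class:`CachingBackend` — a content-addressed cache wrapper (memory or
  directory), keyed by a cryptographic hash of the canonicalized request.

Live vendor adapters are deliberately out of scope here; nothing in this
module touches the network.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Mapping, Protocol

import numpy as np

from .errors import (
    BackendError,
    ContextOverflowError,
    MissingFixtureError,
    TransientBackendError,
)
from .records import NO_REFERENCE_SENTINEL
from .rubric import CRITERION_KEYS

__all__ = [
    "CompletionRequest",
    "CompletionResponse",
    "Transcript",
    "SimulatedScorerConfig",
    "ScriptedBackend",
    "SimulatedScoringBackend",
    "CachingBackend",
    "complete",
    "estimate_tokens",
]


def estimate_tokens(text: str) -> int:
    """Deterministic token estimate: ceiling(character count / 4).

    A stated heuristic rather than a vendor tokenizer, so context budgets
    are reproducible and model-independent.
    """
    return math.ceil(len(text) / 4)


@dataclass(frozen=True)
class CompletionRequest:
    model_id: str
    prompt: str
    params: Mapping[str, Any] = field(default_factory=dict)
    tag: str = ""
    entity: str | None = None  # principal entity (gene, stage, criterion)

    @property
    def cache_key(self) -> str:
        canonical = json.dumps(
            {
                "model_id": self.model_id,
                "prompt": self.prompt,
                "params": dict(sorted(self.params.items())),
            },
            sort_keys=True,
            ensure_ascii=False,
        )
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()


@dataclass(frozen=True)
class CompletionResponse:
    text: str
    model_id: str
    token_estimate_in: int
    token_estimate_out: int
    from_cache: bool = False


@dataclass
class Transcript:
    """Append-only log of request/response pairs with timestamps."""

    entries: list[dict[str, Any]] = field(default_factory=list)
    clock: Callable[[], float] = time.time

    def record(self, request: CompletionRequest, response: CompletionResponse) -> None:
        self.entries.append(
            {
                "timestamp": self.clock(),
                "tag": request.tag,
                "entity": request.entity,
                "model_id": request.model_id,
                "prompt": request.prompt,
                "params": dict(request.params),
                "response": response.text,
                "from_cache": response.from_cache,
                "tokens_in": response.token_estimate_in,
                "tokens_out": response.token_estimate_out,
            }
        )

    def to_jsonl(self) -> str:
        return "".join(
            json.dumps(e, sort_keys=True, ensure_ascii=False) + "\n"
            for e in self.entries
        )

    @classmethod
    def from_jsonl(cls, text: str) -> "Transcript":
        t = cls()
        t.entries = [json.loads(line) for line in text.splitlines() if line.strip()]
        return t


class Backend(Protocol):
    context_budget: int | None

    def respond(self, request: CompletionRequest) -> str: ...


class ScriptedBackend:
    """Deterministic lookup-only backend.

    ``fixtures`` maps ``(tag, entity)`` tuples and/or cache-key strings to
    response texts.  A request with no fixture raises
    :class:`MissingFixtureError`.
    """

    def __init__(
        self,
        fixtures: Mapping[tuple[str, str | None] | str, str],
        context_budget: int | None = None,
    ):
        self.fixtures = dict(fixtures)
        self.context_budget = context_budget

    def respond(self, request: CompletionRequest) -> str:
        key = (request.tag, request.entity)
        if key in self.fixtures:
            return self.fixtures[key]
        if request.cache_key in self.fixtures:
            return self.fixtures[request.cache_key]
        raise MissingFixtureError(
            f"no scripted fixture for tag={request.tag!r} entity={request.entity!r}"
        )


@dataclass(frozen=True)
class SimulatedScorerConfig:
    """Ground truth for the simulated scorer.

    ``latent`` maps ``(gene, criterion_key)`` to a real relevance level in
    [0, 10]; emitted scores are ``clip(round(latent + eps), 0, 10)`` with
    ``eps ~ Normal(0, noise_sd)`` from a stream addressed by
    (seed, gene, criterion, replicate), so any single cell can be replayed
    independently and byte-identically.
    """

    latent: Mapping[tuple[str, str], float]
    noise_sd: float = 0.0
    seed: int = 0
    gene_names: Mapping[str, str] = field(default_factory=dict)
    summaries: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _stable_int(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode("utf-8")).digest()[:4], "big")


class SimulatedScoringBackend:
    """Synthetic scorer emitting parseable 21-field records.

    The gene is read from the scoring prompt's closing phrase
    (``... this gene: SYMBOL``) and the replicate index from request params.
    Comments and references are templated placeholders that respect the
    comment-threshold rule: criteria scored at or above the threshold get a
    comment and one citation, lower scores get the no-reference sentinel.
    """

    def __init__(
        self,
        cfg: SimulatedScorerConfig,
        comment_threshold: int = 4,
        context_budget: int | None = None,
    ):
        self.cfg = cfg
        self.comment_threshold = comment_threshold
        self.context_budget = context_budget

    def draw_score(self, gene: str, criterion: str, replicate: int) -> int:
        latent = self.cfg.latent[(gene, criterion)]
        if self.cfg.noise_sd > 0:
            rng = np.random.default_rng(
                [self.cfg.seed, _stable_int(gene), _stable_int(criterion), replicate]
            )
            latent = latent + rng.normal(0.0, self.cfg.noise_sd)
        return int(np.clip(math.floor(latent + 0.5), 0, 10))

    def score_record_line(self, gene: str, replicate: int) -> str:
        if not any(g == gene for g, _ in self.cfg.latent):
            raise MissingFixtureError(f"no latent profile for gene {gene!r}")
        name = self.cfg.gene_names.get(gene, f"{gene} protein")
        summary = self.cfg.summaries.get(
            gene, f"{gene} is a simulated gene with a configured relevance profile."
        )
        fields = [gene, name, summary]
        for key in CRITERION_KEYS:
            score = self.draw_score(gene, key, replicate)
            if score >= self.comment_threshold:
                comment = (
                    f"Simulated evidence links {gene} to criterion {key} "
                    f"at level {score}."
                )
                refs = (
                    f'"Doe, A synthetic study of {gene} and criterion {key}, '
                    f'2021, Journal of Simulated Biology"'
                )
            else:
                comment = f"Limited simulated evidence for {gene} on criterion {key}."
                refs = NO_REFERENCE_SENTINEL
            fields += [comment, refs, str(score)]
        return " | ".join(fields)

    def respond(self, request: CompletionRequest) -> str:
        gene = request.entity
        if gene is None:
            marker = "this gene:"
            idx = request.prompt.rfind(marker)
            if idx < 0:
                raise MissingFixtureError(
                    "simulated scorer only answers scoring prompts naming a gene"
                )
            gene = request.prompt[idx + len(marker):].strip().split()[0].rstrip(".")
        replicate = int(request.params.get("replicate", 0))
        return self.score_record_line(gene, replicate)


class CachingBackend:
    """Content-addressed cache in front of another backend.

    With ``cache_dir`` set, responses persist as ``<cache_key>.txt`` files;
    otherwise an in-memory dict is used.  An exact request replay is always
    served from cache (`from_cache=True` on the response).
    """

    def __init__(self, inner: Backend, cache_dir: str | Path | None = None):
        self.inner = inner
        self.cache_dir = Path(cache_dir) if cache_dir is not None else None
        if self.cache_dir is not None:
            self.cache_dir.mkdir(parents=True, exist_ok=True)
        self._memory: dict[str, str] = {}
        self.context_budget = getattr(inner, "context_budget", None)

    def lookup(self, key: str) -> str | None:
        if self.cache_dir is not None:
            path = self.cache_dir / f"{key}.txt"
            return path.read_text("utf-8") if path.exists() else None
        return self._memory.get(key)

    def store(self, key: str, text: str) -> None:
        if self.cache_dir is not None:
            (self.cache_dir / f"{key}.txt").write_text(text, "utf-8")
        else:
            self._memory[key] = text

    def respond(self, request: CompletionRequest) -> str:
        # complete() consults lookup() first; respond() is the miss path
        text = self.inner.respond(request)
        self.store(request.cache_key, text)
        return text


def complete(
    backend: Backend,
    request: CompletionRequest,
    transcript: Transcript | None = None,
    max_attempts: int = 3,
) -> CompletionResponse:
    """Run one completion through a backend.

    Enforces the backend's declared context budget, retries transient
    transport failures up to ``max_attempts`` times, serves caching
    backends from their cache on exact replays, and appends to the
    transcript when one is supplied.
    """
    tokens_in = estimate_tokens(request.prompt)
    budget = getattr(backend, "context_budget", None)
    if budget is not None and tokens_in > budget:
        raise ContextOverflowError(
            f"prompt of ~{tokens_in} tokens exceeds the context budget of {budget}"
        )

    from_cache = False
    text: str | None = None
    if isinstance(backend, CachingBackend):
        cached = backend.lookup(request.cache_key)
        if cached is not None:
            text, from_cache = cached, True

    if text is None:
        last_exc: Exception | None = None
        for _ in range(max_attempts):
            try:
                text = backend.respond(request)
                break
            except TransientBackendError as exc:
                last_exc = exc
        else:
            raise BackendError(
                f"backend failed after {max_attempts} attempts: {last_exc}"
            ) from last_exc

    assert text is not None
    response = CompletionResponse(
        text=text,
        model_id=request.model_id,
        token_estimate_in=tokens_in,
        token_estimate_out=estimate_tokens(text),
        from_cache=from_cache,
    )
    if transcript is not None:
        transcript.record(request, response)
    return response


def with_budget(backend: Backend, budget: int | None) -> Backend:
    """Shallow copy of a backend with a different declared context budget."""
    import copy

    clone = copy.copy(backend)
    clone.context_budget = budget
    return clone
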