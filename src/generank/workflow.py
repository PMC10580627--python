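"""End-to-end orchestration of the prioritization workflow.

The seven-step protocol, run per module: identify functional convergences
among the module's genes, score every gene against the six-criterion
rubric (one gene per prompt, in replicate, per model), rank genes by
cumulative score and shortlist the top k, summarize the models' scoring
justifications per criterion, fact-check each summary statement against a
reference resolver (statements with no resolvable backing reference are
eliminated), have each model select a top candidate from the fact-checked
summaries (stepwise) or the raw gene list (direct), and finally re-ask the
selection while feeding in textualized expression data from reference
datasets stage by stage — datasets whose textual corpus cannot fit the
model's context window are skipped with a warning, never truncated.

Everything is deterministic given the config seed and offline backends;
reports regenerate byte-identically.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from . import records as rec_mod
from .aggregation import (
    RankedGene,
    ScoreTensor,
    ThemeAssignment,
    assemble_tensor,
    cumulative_ranking,
    ranking_to_frame,
    top_k,
)
from .backends import (
    Backend,
    CompletionRequest,
    Transcript,
    complete,
    estimate_tokens,
)
from .errors import (
    ConfigError,
    ContextOverflowError,
    ExtractionError,
    GeneRankError,
    ParseError,
    ValidationError,
)
from .records import ReferenceCitation, ScoreRecord, parse_references
from .repertoire import GeneModule, Repertoire, get_module
from .rubric import (
    Rubric,
    default_rubric,
    default_templates,
    render_prompt,
    rubric_context,
)

__all__ = [
    "WorkflowConfig",
    "FactCheckResult",
    "SelectionDecision",
    "PrioritizationReport",
    "OfflineResolver",
    "extract_choice",
    "run_scoring",
    "summarize_justifications",
    "fact_check",
    "select_top_candidate",
    "data_informed_selection",
    "export_convergence_graph",
    "write_report",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = ("summary_only", "plus_rnaseq", "plus_microarray", "plus_cohorts", "final")
_STAGE_PROMPTS = {
    "plus_rnaseq": "7.2",
    "plus_microarray": "7.3",
    "plus_cohorts": "7.4",
}


@dataclass(frozen=True)
class WorkflowConfig:
    module_id: str
    model_ids: tuple[str, ...]
    replicates: int = 3
    rubric: Rubric = field(default_factory=default_rubric)
    k: int = 5
    token_budget: Mapping[str, int] = field(default_factory=dict)
    seed: int = 0
    cache_dir: str | None = None
    resolver: str = "offline"
    min_resolved_references: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        for model, budget in self.token_budget.items():
            if budget <= 0:
                raise ConfigError(f"token budget for {model!r} must be positive")

    def budget_for(self, model_id: str) -> int | None:
        return self.token_budget.get(model_id)

    def snapshot(self) -> dict:
        return {
            "module_id": self.module_id,
            "model_ids": list(self.model_ids),
            "replicates": self.replicates,
            "k": self.k,
            "token_budget": dict(self.token_budget),
            "seed": self.seed,
            "resolver": self.resolver,
            "min_resolved_references": self.min_resolved_references,
            "rubric_statements": {
                s.key: s.text for s in self.rubric.statements
            },
        }


@dataclass(frozen=True)
class FactCheckResult:
    statement: str
    status: str  # "verified" | "unverified" | "eliminated"
    references: tuple[ReferenceCitation, ...]


@dataclass(frozen=True)
class SelectionDecision:
    chosen_gene: str
    mode: str   # "stepwise" | "direct"
    stage: str  # one of STAGES
    rationale: str
    history: tuple["SelectionDecision", ...] = ()

    def stage_choices(self) -> dict[str, str]:
        out = {d.stage: d.chosen_gene for d in self.history}
        out[self.stage] = self.chosen_gene
        return out


@dataclass
class PrioritizationReport:
    module: GeneModule
    ranking: list[RankedGene]
    shortlist: list[RankedGene]
    summaries: dict[str, str]
    fact_checks: list[FactCheckResult]
    decisions: dict[str, SelectionDecision]
    themes: list[ThemeAssignment]
    config_snapshot: dict
    skipped_steps: list[str] = field(default_factory=list)


class OfflineResolver:
    """Citation resolver backed by a packaged lookup table (no network).

    A citation resolves when (first author, year, normalized title) matches
    a table row; the resolved identifier is attached to the citation.  This
    is an interface stub for offline runs — a live literature-database
    resolver can be plugged in through the same callable contract.
    """

    def __init__(self, table: Mapping[tuple[str, str, str], str]):
        self.table = dict(table)

    @staticmethod
    def _norm(text: str) -> str:
        return re.sub(r"[^a-z0-9]+", " ", text.lower()).strip()

    @classmethod
    def from_rows(cls, rows: Iterable[Mapping[str, str]]) -> "OfflineResolver":
        table = {
            (cls._norm(r["first_author"]), r["year"].strip(), cls._norm(r["title"])):
                r["pmid"].strip()
            for r in rows
        }
        return cls(table)

    def __call__(self, citation: ReferenceCitation) -> str | None:
        key = (
            self._norm(citation.first_author),
            citation.year.strip(),
            self._norm(citation.title),
        )
        return self.table.get(key)


def run_scoring(
    cfg: WorkflowConfig,
    backends: Mapping[str, Backend],
    repertoire: Repertoire,
    transcript: Transcript | None = None,
    example_gene: str = "GPX4",
    example_record: str = "",
) -> tuple[list[tuple[str, int, ScoreRecord]], ScoreTensor]:
    """Score every module gene, one gene per prompt, in replicate per model.

    The scoring conversation for a gene is the three scoring prompts
    rendered in order (task description with the rubric statements, worked
    example, per-gene request) and submitted as one prompt.  Malformed
    responses are retried once and then marked missing; a gene with no
    usable replicate on any model is a hard error.
    """
    module = get_module(repertoire, cfg.module_id)
    templates = default_templates()
    ctx = rubric_context(cfg.rubric)
    preamble = render_prompt("3.1", ctx, templates)
    if example_record:
        preamble += "\n" + render_prompt(
            "3.2",
            {"example_gene": example_gene, "example_record": example_record},
            templates,
        )

    records: list[tuple[str, int, ScoreRecord]] = []
    for gene in module.genes:
        usable = 0
        for model_id in cfg.model_ids:
            backend = backends[model_id]
            for rep in range(cfg.replicates):
                prompt = preamble + "\n" + render_prompt("3.3", {"gene": gene}, templates)
                request = CompletionRequest(
                    model_id=model_id,
                    prompt=prompt,
                    params={"replicate": rep, "seed": cfg.seed},
                    tag="3.3",
                    entity=gene,
                )
                parsed: ScoreRecord | None = None
                for attempt in range(2):  # one retry on a malformed response
                    response = complete(backend, request, transcript)
                    try:
                        parsed = rec_mod.parse_score_record(response.text, cfg.rubric)
                        break
                    except ParseError as exc:
                        logger.warning(
                            "malformed record (gene=%s model=%s rep=%d try=%d): %s",
                            gene, model_id, rep, attempt + 1, exc,
                        )
                if parsed is None:
                    continue  # cell stays missing
                records.append((model_id, rep, parsed))
                usable += 1
        if usable == 0:
            raise GeneRankError(
                f"gene {gene}: no parseable scoring response on any model/replicate"
            )
    tensor = assemble_tensor(records, criteria=cfg.rubric.keys)
    return records, tensor


def summarize_justifications(
    top_records: Sequence[tuple[str, ScoreRecord]],
    criterion: str,
    backend: Backend,
    token_budget: int | None = None,
    transcript: Transcript | None = None,
    model_id: str = "summarizer",
) -> str:
    """Summarize per-criterion scoring justifications for the shortlist.

    ``top_records`` pairs each shortlist record with the model that
    produced it; only those genes' comment fields for ``criterion`` enter
    the summarization prompt.
    """
    if not top_records:
        raise ValidationError("no justifications to summarize")
    lines = []
    for source_model, rec in top_records:
        a = rec.assessments[criterion]
        if a.comment.strip():
            lines.append(f"{rec.gene_symbol} ({source_model}): {a.comment}")
    if not lines:
        raise ValidationError(
            f"no non-empty justifications for criterion {criterion!r}"
        )
    prompt = render_prompt("4.1", {"justifications": "\n".join(lines)})
    if token_budget is not None and estimate_tokens(prompt) > token_budget:
        raise ContextOverflowError(
            f"summarization prompt exceeds the token budget of {token_budget}"
        )
    request = CompletionRequest(
        model_id=model_id, prompt=prompt, tag="4.1", entity=criterion
    )
    return complete(backend, request, transcript).text


def fact_check(
    statements: Sequence[str],
    backend: Backend,
    resolver: Callable[[ReferenceCitation], str | None] | None,
    min_resolved: int = 1,
    transcript: Transcript | None = None,
    model_id: str = "factchecker",
) -> list[FactCheckResult]:
    """Fact-check summary statements and resolve their references.

    For each statement the backend is asked for supporting references; the
    quoted citations in its answer are parsed and resolved.  A statement
    with at least ``min_resolved`` resolvable references is ``verified``
    (resolved identifiers attached); one with none is ``eliminated`` and
    must be excluded from downstream summaries.  With no resolver
    available every statement is ``unverified`` — never silently verified.
    """
    results: list[FactCheckResult] = []
    for statement in statements:
        prompt = render_prompt("5.1", {"statement": statement})
        request = CompletionRequest(
            model_id=model_id, prompt=prompt, tag="5.1", entity=statement[:80]
        )
        response = complete(backend, request, transcript)
        citations = parse_references(response.text)
        if resolver is None:
            results.append(FactCheckResult(statement, "unverified", tuple(citations)))
            continue
        resolved = []
        for c in citations:
            pmid = resolver(c)
            if pmid is not None:
                resolved.append(replace(c, pmid=pmid))
        if len(resolved) >= min_resolved:
            results.append(FactCheckResult(statement, "verified", tuple(resolved)))
        else:
            results.append(FactCheckResult(statement, "eliminated", ()))
    return results


_SENTENCE_SPLIT = re.compile(r"(?<=[.!?:])\s+|\n+|•")
_PAREN = re.compile(r"\([^()]*\)")


def extract_choice(text: str, candidates: Sequence[str]) -> str:
    """Find the candidate gene a selection response names.

    Parenthesized spans are stripped first (they carry enumerations of the
    shortlist or protein aliases, never the pick), then the first sentence
    mentioning any candidate is located; exactly one distinct candidate
    must appear there.  Ambiguity fails loudly rather than guessing.
    """
    stripped = text
    for _ in range(3):  # peel nested parentheses
        stripped, n = _PAREN.subn(" ", stripped)
        if n == 0:
            break
    for sentence in _SENTENCE_SPLIT.split(stripped):
        found = {
            c for c in candidates
            if re.search(rf"(?<![A-Z0-9]){re.escape(c)}(?![A-Z0-9])", sentence)
        }
        if len(found) == 1:
            return found.pop()
        if len(found) > 1:
            raise ExtractionError(
                f"multiple candidates named in one sentence: {sorted(found)}"
            )
    raise ExtractionError("response names no shortlisted candidate")


def select_top_candidate(
    payload: str,
    backend: Backend,
    candidates: Sequence[str],
    mode: str,
    transcript: Transcript | None = None,
    model_id: str = "selector",
) -> SelectionDecision:
    """Ask a model to pick a top candidate (stepwise or direct).

    Stepwise mode feeds the fact-checked criterion summaries and selects
    from the shortlist; direct mode feeds the raw gene list and selects
    from the whole module.
    """
    if not payload and mode == "stepwise":
        raise ValidationError("stepwise selection requires a non-empty summary")
    if not candidates:
        raise ValidationError("no candidates to select from")
    if mode == "stepwise":
        prompt = render_prompt("6.1", {"summary": payload})
    elif mode == "direct":
        prompt = render_prompt("6.2", {"genes": " ".join(candidates)})
    else:
        raise ValidationError(f"mode must be 'stepwise' or 'direct', got {mode!r}")
    request = CompletionRequest(
        model_id=model_id, prompt=prompt, tag="6.1" if mode == "stepwise" else "6.2",
        entity=mode,
    )
    response = complete(backend, request, transcript)
    chosen = extract_choice(response.text, candidates)
    return SelectionDecision(
        chosen_gene=chosen, mode=mode, stage="summary_only",
        rationale=response.text, history=(),
    )


def data_informed_selection(
    prior: SelectionDecision,
    corpora: Mapping[str, Sequence[str]],
    backend: Backend,
    candidates: Sequence[str],
    budget: int | None = None,
    run_final: bool = True,
    transcript: Transcript | None = None,
    model_id: str = "selector",
) -> SelectionDecision:
    """Iterate the selection while feeding textualized expression corpora.

    ``corpora`` maps stage names (``plus_rnaseq``, ``plus_microarray``,
    ``plus_cohorts``) to sentence lists; stages are visited in protocol
    order and absent stages are skipped.  A corpus whose token estimate
    exceeds the single-context ``budget`` is skipped with a warning and the
    prior choice carried forward — partial context is never fed silently.
    The optional final stage asks for a conclusions summary and re-extracts
    the choice from it.  The returned decision's ``history`` preserves
    every stage.
    """
    history = list(prior.history) + [replace(prior, history=())]
    current = prior
    for stage in ("plus_rnaseq", "plus_microarray", "plus_cohorts"):
        if stage not in corpora:
            continue
        sentences = list(corpora[stage])
        corpus_text = "\n".join(sentences)
        if budget is not None and estimate_tokens(corpus_text) > budget:
            logger.warning(
                "stage %s skipped: corpus of ~%d tokens exceeds the "
                "single-context budget of %d",
                stage, estimate_tokens(corpus_text), budget,
            )
            current = SelectionDecision(
                chosen_gene=current.chosen_gene, mode=prior.mode, stage=stage,
                rationale="skipped: corpus exceeds single-context budget; "
                          "prior choice carried forward",
                history=(),
            )
            history.append(current)
            continue
        prompt = render_prompt(_STAGE_PROMPTS[stage], {"data": corpus_text})
        request = CompletionRequest(
            model_id=model_id, prompt=prompt, tag=_STAGE_PROMPTS[stage], entity=stage
        )
        response = complete(backend, request, transcript)
        chosen = extract_choice(response.text, candidates)
        current = SelectionDecision(
            chosen_gene=chosen, mode=prior.mode, stage=stage,
            rationale=response.text, history=(),
        )
        history.append(current)
    if run_final:
        prompt = render_prompt("7.5", {})
        request = CompletionRequest(
            model_id=model_id, prompt=prompt, tag="7.5", entity="final"
        )
        response = complete(backend, request, transcript)
        chosen = extract_choice(response.text, candidates)
        current = SelectionDecision(
            chosen_gene=chosen, mode=prior.mode, stage="final",
            rationale=response.text, history=(),
        )
        history.append(current)
    final = history.pop()
    return replace(final, history=tuple(history))


def export_convergence_graph(themes: Iterable[ThemeAssignment]) -> nx.Graph:
    """Bipartite theme–gene graph with one edge per (theme, member) pair.

    Node attribute ``kind`` is ``"theme"`` or ``"gene"``; node insertion
    order is deterministic (input order, members sorted) so serializations
    are reproducible.
    """
    g = nx.Graph()
    for a in themes:
        theme_node = f"{a.source}: {a.theme}" if a.source else a.theme
        g.add_node(theme_node, kind="theme", source=a.source, theme=a.theme)
        for gene in sorted(a.genes):
            if gene not in g:
                g.add_node(gene, kind="gene")
            g.add_edge(theme_node, gene)
    return g


def _decision_payload(d: SelectionDecision) -> dict:
    return {
        "chosen_gene": d.chosen_gene,
        "mode": d.mode,
        "stage": d.stage,
        "rationale": d.rationale,
        "history": [
            {
                "chosen_gene": h.chosen_gene,
                "stage": h.stage,
                "rationale": h.rationale,
            }
            for h in d.history
        ],
    }


def write_report(report: PrioritizationReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the per-module prioritization report.

    Emits a human-readable Markdown document (module function paragraph
    placeholder, ranking table, shortlist, per-criterion summaries with
    fact-check outcomes, selection decisions with revision history) and a
    machine-readable JSON dump.  Output is deterministic: regenerating
    from identical inputs yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    module = report.module

    md: list[str] = [f"# Prioritization report — module {module.module_id}", ""]
    md += [
        f"Aggregate: {module.aggregate_id}; {module.n_genes} candidate genes.",
        "",
        "## Ranking",
        "",
        ranking_to_frame(report.ranking).to_markdown(index=False),
        "",
        "## Shortlist",
        "",
        ", ".join(rg.symbol for rg in report.shortlist) or "(none)",
        "",
        "## Criterion summaries",
        "",
    ]
    if report.summaries:
        for key in sorted(report.summaries):
            md += [f"### Statement {key}", "", report.summaries[key], ""]
    else:
        md += ["_Summarization skipped._", ""]
    md += ["## Fact-check outcomes", ""]
    if report.fact_checks:
        for fc in report.fact_checks:
            refs = "; ".join(
                f"{r.first_author} {r.year}" + (f" [{r.pmid}]" if r.pmid else "")
                for r in fc.references
            )
            md += [f"- **{fc.status}** — {fc.statement[:120]}" + (f" ({refs})" if refs else "")]
        md += [""]
    else:
        md += ["_Fact-checking skipped._", ""]
    md += ["## Selection decisions", ""]
    for model_id in sorted(report.decisions):
        d = report.decisions[model_id]
        md += [f"### {model_id} ({d.mode})", ""]
        for stage, gene in d.stage_choices().items():
            md += [f"- {stage}: {gene}"]
        md += [""]
    if report.skipped_steps:
        md += ["## Skipped steps", ""]
        md += [f"- {s}" for s in report.skipped_steps]
        md += [""]

    md_path = out / f"{module.module_id}_report.md"
    md_path.write_text("\n".join(md), "utf-8")

    payload = {
        "module": {
            "module_id": module.module_id,
            "aggregate_id": module.aggregate_id,
            "genes": list(module.genes),
        },
        "ranking": [
            {
                "rank": rg.rank,
                "gene": rg.symbol,
                "per_criterion_mean": rg.per_criterion_mean,
                "cumulative_score": rg.cumulative_score,
            }
            for rg in report.ranking
        ],
        "shortlist": [rg.symbol for rg in report.shortlist],
        "summaries": report.summaries,
        "fact_checks": [
            {
                "statement": fc.statement,
                "status": fc.status,
                "references": [
                    {
                        "first_author": r.first_author,
                        "title": r.title,
                        "year": r.year,
                        "journal": r.journal,
                        "pmid": r.pmid,
                    }
                    for r in fc.references
                ],
            }
            for fc in report.fact_checks
        ],
        "decisions": {
            m: _decision_payload(d) for m, d in sorted(report.decisions.items())
        },
        "themes": [
            {"source": t.source, "theme": t.theme, "genes": sorted(t.genes)}
            for t in report.themes
        ],
        "skipped_steps": list(report.skipped_steps),
        "config": report.config_snapshot,
    }
    json_path = out / f"{module.module_id}_report.json"
    json_path.write_text(
        json.dumps(payload, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        "utf-8",
    )
    return {"markdown": md_path, "json": json_path}


def run_pipeline(
    cfg: WorkflowConfig,
    backends: Mapping[str, Backend],
    repertoire: Repertoire,
    resolver: Callable[[ReferenceCitation], str | None] | None = None,
    corpora: Mapping[str, Mapping[str, Sequence[str]]] | None = None,
    example_record: str = "",
    transcript: Transcript | None = None,
) -> PrioritizationReport:
    """Run scoring → ranking → summaries → fact-check → selection.

    ``corpora`` optionally maps model id → stage → sentences for the
    data-informed selection stages.  Steps whose prerequisites are missing
    (e.g. no resolver for fact-checking) are recorded as skipped rather
    than failing the whole run.
    """
    module = get_module(repertoire, cfg.module_id)
    skipped: list[str] = []

    records, tensor = run_scoring(
        cfg, backends, repertoire, transcript, example_record=example_record
    )
    ranking = cumulative_ranking(tensor)
    shortlist = top_k(ranking, cfg.k)
    shortlist_genes = [rg.symbol for rg in shortlist]

    by_gene: dict[str, list[tuple[str, ScoreRecord]]] = {}
    for model_id, _rep, rec in records:
        by_gene.setdefault(rec.gene_symbol, []).append((model_id, rec))
    top_records = [
        (m, rec)
        for g in shortlist_genes
        for (m, rec) in by_gene.get(g, [])
    ]

    summarizer = backends[cfg.model_ids[0]]
    summaries: dict[str, str] = {}
    try:
        for key in cfg.rubric.keys:
            summaries[key] = summarize_justifications(
                top_records, key, summarizer,
                token_budget=cfg.budget_for(cfg.model_ids[0]),
                transcript=transcript, model_id=cfg.model_ids[0],
            )
    except GeneRankError as exc:
        logger.warning("summarization skipped: %s", exc)
        summaries = {}
        skipped.append(f"summarize: {exc}")

    fact_checks: list[FactCheckResult] = []
    surviving: list[str] = []
    if summaries and resolver is not None:
        statements = [summaries[k] for k in sorted(summaries)]
        fact_checks = fact_check(
            statements, summarizer, resolver,
            min_resolved=cfg.min_resolved_references,
            transcript=transcript, model_id=cfg.model_ids[0],
        )
        surviving = [fc.statement for fc in fact_checks if fc.status == "verified"]
    else:
        skipped.append("fact_check: no resolver or no summaries")

    decisions: dict[str, SelectionDecision] = {}
    summary_payload = "\n\n".join(surviving) if surviving else "\n\n".join(
        summaries[k] for k in sorted(summaries)
    )
    for model_id in cfg.model_ids:
        backend = backends[model_id]
        try:
            decision = select_top_candidate(
                summary_payload, backend, shortlist_genes, mode="stepwise",
                transcript=transcript, model_id=model_id,
            )
            if corpora and model_id in corpora:
                decision = data_informed_selection(
                    decision, corpora[model_id], backend, shortlist_genes,
                    budget=cfg.budget_for(model_id), run_final=False,
                    transcript=transcript, model_id=model_id,
                )
            decisions[model_id] = decision
        except GeneRankError as exc:
            logger.warning("selection for %s skipped: %s", model_id, exc)
            skipped.append(f"select[{model_id}]: {exc}")

    return PrioritizationReport(
        module=module,
        ranking=ranking,
        shortlist=shortlist,
        summaries=summaries,
        fact_checks=fact_checks,
        decisions=decisions,
        themes=[],
        config_snapshot=cfg.snapshot(),
        skipped_steps=skipped,
    )
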