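"""Packaged worked-example resources and synthetic study generation.

Two kinds of test-and-demo material live here:

* the **paper-faithful bundle** — the A37 module table, the prompt
  templates and rubric, the GPX4 worked-example scoring record, the three
  example expression sentences, the M9.2 theme table, the printed
  stepwise/direct and data-informed selection transcripts, and the
  fact-checked criterion summaries — all plain-text resources verified
  against a checksum manifest before use;

* **synthetic studies** — fully seeded bundles of a repertoire, latent
  gene-relevance profiles with one planted top gene, simulated scoring
  backends, and synthetic expression tables, used for end-to-end runs and
  parameter-recovery experiments with known ground truth.
"""

from __future__ import annotations

import csv
import hashlib
import io
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .aggregation import ThemeAssignment
from .backends import (
    CompletionRequest,
    SimulatedScorerConfig,
    SimulatedScoringBackend,
)
from .errors import ConfigError, CorruptFixtureError, MissingFixtureError
from .repertoire import GeneModule, Repertoire, read_gene_sets
from .rubric import CRITERION_KEYS, PromptBundle, Rubric, load_bundle
from .workflow import OfflineResolver

__all__ = [
    "FixtureBundle",
    "SyntheticStudySettings",
    "SyntheticStudy",
    "load_paper_fixtures",
    "generate_synthetic_study",
    "SimulatedStudyBackend",
]

_DATA = "generank.data"
_MANIFEST = "checksums.sha256"


def _read_bytes(name: str) -> bytes:
    return resources.files(_DATA).joinpath(name).read_bytes()


def verify_checksums() -> dict[str, str]:
    """Check every packaged resource against the manifest.

    Returns the manifest mapping on success; raises
    :class:`CorruptFixtureError` on any mismatch or missing file.
    """
    manifest_text = _read_bytes(_MANIFEST).decode("utf-8")
    manifest: dict[str, str] = {}
    for line in manifest_text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        digest, name = line.split(None, 1)
        manifest[name.strip()] = digest
    for name, expected in manifest.items():
        try:
            actual = hashlib.sha256(_read_bytes(name)).hexdigest()
        except FileNotFoundError as exc:
            raise CorruptFixtureError(f"resource {name!r} missing") from exc
        if actual != expected:
            raise CorruptFixtureError(
                f"resource {name!r} checksum mismatch: {actual} != {expected}"
            )
    return manifest


@dataclass
class FixtureBundle:
    repertoire: Repertoire
    rubric: Rubric
    templates: PromptBundle
    gpx4_record_line: str
    example_sentences: list[str]
    theme_table: list[ThemeAssignment]
    selection_transcripts: dict
    summaries: dict
    resolver: OfflineResolver


def load_paper_fixtures() -> FixtureBundle:
    """Load the packaged worked-example bundle (checksums verified first)."""
    verify_checksums()
    repertoire = read_gene_sets(
        io.StringIO(_read_bytes("a37_modules.gmt").decode("utf-8"))
    )
    rubric, templates = load_bundle()
    gpx4_line = _read_bytes("gpx4_record.txt").decode("utf-8").rstrip("\n")
    sentences = [
        line
        for line in _read_bytes("example_sentences.txt").decode("utf-8").splitlines()
        if line.strip()
    ]
    themes_raw = yaml.safe_load(_read_bytes("theme_table.yaml").decode("utf-8"))
    themes = [
        ThemeAssignment(
            source=a["source"], theme=a["theme"], genes=frozenset(a["genes"])
        )
        for a in themes_raw["assignments"]
    ]
    transcripts = yaml.safe_load(
        _read_bytes("selection_transcripts.yaml").decode("utf-8")
    )
    summaries = yaml.safe_load(_read_bytes("step5_summaries.yaml").decode("utf-8"))
    lookup_text = _read_bytes("pmid_lookup_synthetic.tsv").decode("utf-8")
    rows = [
        r
        for r in csv.DictReader(
            (l for l in lookup_text.splitlines() if not l.startswith("#")),
            delimiter="\t",
        )
    ]
    resolver = OfflineResolver.from_rows(rows)
    return FixtureBundle(
        repertoire=repertoire,
        rubric=rubric,
        templates=templates,
        gpx4_record_line=gpx4_line,
        example_sentences=sentences,
        theme_table=themes,
        selection_transcripts=transcripts,
        summaries=summaries,
        resolver=resolver,
    )


@dataclass(frozen=True)
class SyntheticStudySettings:
    """Conditions for a synthetic prioritization study.

    ``margin`` is the latent cumulative-score gap between the planted top
    gene and the runner-up (further genes sit progressively lower);
    ``noise_sd`` is the per-cell score noise of the simulated scorers.
    """

    n_genes: int = 10
    margin: float = 2.0
    noise_sd: float = 0.5
    replicates: int = 3
    models: tuple[str, ...] = ("model_a", "model_b")
    module_id: str = "MS.1"
    aggregate_id: str = "AS"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ConfigError("margin must be positive")
        if self.n_genes < 2:
            raise ConfigError("need at least 2 genes")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")


@dataclass
class SyntheticStudy:
    settings: SyntheticStudySettings
    seed: int
    repertoire: Repertoire
    module: GeneModule
    planted_gene: str
    scorer_configs: dict[str, SimulatedScorerConfig]
    latent_cumulative: dict[str, float]

    def backends(self, rubric: Rubric | None = None) -> dict[str, "SimulatedStudyBackend"]:
        threshold = rubric.comment_threshold if rubric else 4
        return {
            m: SimulatedStudyBackend(
                SimulatedScoringBackend(cfg, comment_threshold=threshold),
                planted_gene=self.planted_gene,
            )
            for m, cfg in self.scorer_configs.items()
        }


class SimulatedStudyBackend:
    """Backend for whole-pipeline synthetic runs.

    Scoring prompts go to the wrapped simulated scorer; summarization,
    fact-check, and selection prompts get deterministic templated answers —
    the selection answer names the latent-top gene, and the fact-check
    answer cites a reference resolvable by the synthetic offline lookup.
    """

    context_budget: int | None = None

    def __init__(self, scorer: SimulatedScoringBackend, planted_gene: str):
        self.scorer = scorer
        self.planted_gene = planted_gene

    def respond(self, request: CompletionRequest) -> str:
        tag = request.tag
        if tag in ("3.3", "3.1"):
            return self.scorer.respond(request)
        if tag == "4.1":
            return (
                "The shortlisted genes show graded evidence across this "
                "criterion; the strongest support concerns "
                f"{self.planted_gene}."
            )
        if tag == "5.1":
            return (
                'This statement is supported. "Doe, A synthetic study of '
                f'{self.planted_gene} and criterion a, 2021, '
                'Journal of Simulated Biology"'
            )
        if tag in ("6.1", "6.2", "7.2", "7.3", "7.4", "7.5"):
            return (
                f"I would select {self.planted_gene} as the top candidate "
                "based on the evidence provided."
            )
        raise MissingFixtureError(f"simulated study backend: unknown tag {tag!r}")


def generate_synthetic_study(
    settings: SyntheticStudySettings, seed: int
) -> SyntheticStudy:
    """Build a fully seeded synthetic study with one planted top gene.

    Latent per-criterion relevance levels are drawn uniformly in [2, 8] for
    every gene, then the planted gene (the first symbol) is set to a flat
    profile whose cumulative score exceeds the best competitor by exactly
    ``margin``.  Each model gets its own scorer seeded from (seed, model),
    so models are independent scorers of the same latent truth.
    """
    s = settings
    rng = np.random.default_rng([seed, 0x57DD])
    genes = tuple(f"SYN{i+1}" for i in range(s.n_genes))
    planted = genes[0]

    latent: dict[tuple[str, str], float] = {}
    cumulative: dict[str, float] = {}
    for gene in genes[1:]:
        levels = rng.uniform(2.0, 8.0, size=len(CRITERION_KEYS))
        for k, lvl in zip(CRITERION_KEYS, levels):
            latent[(gene, k)] = float(lvl)
        cumulative[gene] = float(levels.sum())
    target = max(cumulative.values()) + s.margin
    per_criterion = min(target / len(CRITERION_KEYS), 10.0)
    for k in CRITERION_KEYS:
        latent[(planted, k)] = per_criterion
    cumulative[planted] = per_criterion * len(CRITERION_KEYS)

    rep = Repertoire()
    module = GeneModule(
        module_id=s.module_id, aggregate_id=s.aggregate_id, genes=genes
    )
    rep.add(module)

    scorer_configs = {
        m: SimulatedScorerConfig(
            latent=latent,
            noise_sd=s.noise_sd,
            seed=int(np.random.default_rng([seed, mi]).integers(0, 2**31 - 1)),
        )
        for mi, m in enumerate(s.models)
    }
    return SyntheticStudy(
        settings=s,
        seed=seed,
        repertoire=rep,
        module=module,
        planted_gene=planted,
        scorer_configs=scorer_configs,
        latent_cumulative=cumulative,
    )
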