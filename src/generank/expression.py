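"""Expression tables: statistics, textualization, and budget-aware chunking.

Generative chat models take text, so expression measurements are serialized
into natural-language sentences that carry both the value and its metadata
(species, measurement platform, sample context).  Three record schemas are
supported, one per reference-dataset shape:

* ``rnaseq_count`` — normalized read counts per sample type,
* ``microarray_intensity`` — signal intensities per isolated cell
  population,
* ``cohort_log2fc`` — whole-blood log2 fold changes of patient cohorts
  versus matched controls.

Each schema has a fixed sentence template and an exact inverse parser, so
textualization is verifiable as a lossless round trip.  Corpora are packed
into whole-sentence chunks under an explicit token budget — a corpus that
cannot fit a single context window is flagged so callers can skip it
rather than silently truncate or split it.

The module also computes the per-patient module-activity statistic: the
percentage of a module's genes differentially expressed beyond fixed
fold-change and raw-difference cutoffs, signed by direction, ranging from
+100 (all genes up) to -100 (all genes down).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import re
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .backends import estimate_tokens
from .errors import ConfigError, ContextOverflowError, ParseError, ValidationError
from .repertoire import GeneModule

__all__ = [
    "SCHEMAS",
    "ExpressionRecord",
    "DifferentialEntry",
    "ModuleActivity",
    "TextChunk",
    "ChunkedCorpus",
    "render_sentence",
    "parse_sentence",
    "estimate_tokens",
    "chunk_corpus",
    "differential_entries",
    "module_activity",
    "SyntheticExpressionConfig",
    "synthetic_expression",
]

logger = logging.getLogger(__name__)

SCHEMAS = ("rnaseq_count", "microarray_intensity", "cohort_log2fc")


def _format_value(value: float) -> str:
    """Counts/intensities print as integers when integral; fold changes keep
    their full precision via the shortest round-trip decimal repr."""
    if float(value) == int(value):
        return str(int(value))
    return repr(float(value))


@dataclass(frozen=True)
class ExpressionRecord:
    dataset_id: str
    schema: str
    gene: str
    context_label: str  # sample type, cell population, or patient cohort
    value: float
    species: str = "Human"

    def __post_init__(self) -> None:
        if self.schema not in SCHEMAS:
            raise ValidationError(f"unknown schema {self.schema!r}; known: {SCHEMAS}")
        if self.schema in ("rnaseq_count", "microarray_intensity") and self.value < 0:
            raise ValidationError(f"{self.schema} value must be >= 0, got {self.value}")


_TEMPLATES = {
    "rnaseq_count": (
        "In {species} {context}, RNA sequencing detected {gene} RNA "
        "at a count of {value}"
    ),
    "microarray_intensity": (
        "In {species} {context}, Microarrays detected {gene} RNA "
        "at a signal intensity unit of {value}"
    ),
    "cohort_log2fc": (
        "In {species} Whole blood, the abundance of {gene} RNA measured by "
        "Microarrays differed in patients with {context} compared to controls "
        "by a Log2 fold change of {value}"
    ),
}

# species is taken as the first whitespace token after "In "; the remainder
# up to the schema's fixed phrase is the context label.
_PARSERS = {
    "rnaseq_count": re.compile(
        r"^In (?P<species>\S+) (?P<context>.+), RNA sequencing detected "
        r"(?P<gene>\S+) RNA at a count of (?P<value>\S+)$"
    ),
    "microarray_intensity": re.compile(
        r"^In (?P<species>\S+) (?P<context>.+), Microarrays detected "
        r"(?P<gene>\S+) RNA at a signal intensity unit of (?P<value>\S+)$"
    ),
    "cohort_log2fc": re.compile(
        r"^In (?P<species>\S+) Whole blood, the abundance of (?P<gene>\S+) RNA "
        r"measured by Microarrays differed in patients with (?P<context>.+) "
        r"compared to controls by a Log2 fold change of (?P<value>\S+)$"
    ),
}


def render_sentence(rec: ExpressionRecord) -> str:
    """Serialize one measurement into its schema's sentence."""
    return _TEMPLATES[rec.schema].format(
        species=rec.species,
        context=rec.context_label,
        gene=rec.gene,
        value=_format_value(rec.value),
    )


def parse_sentence(sentence: str, dataset_id: str = "") -> ExpressionRecord:
    """Recover the record behind a templated sentence.

    The schema is auto-detected from each template's fixed phrases; the
    numeric value is recovered exactly as printed.  The ``cohort_log2fc``
    pattern is tried first because its sentences also mention Microarrays.
    """
    for schema in ("cohort_log2fc", "microarray_intensity", "rnaseq_count"):
        m = _PARSERS[schema].match(sentence.strip())
        if m:
            context = m.group("context") if schema != "cohort_log2fc" else m.group("context")
            return ExpressionRecord(
                dataset_id=dataset_id,
                schema=schema,
                gene=m.group("gene"),
                context_label=context,
                value=float(m.group("value")),
                species=m.group("species"),
            )
    raise ParseError(f"sentence matches no expression template: {sentence!r}")


@dataclass(frozen=True)
class DifferentialEntry:
    patient_id: str
    gene: str
    log2_fold_change: float
    raw_difference: float  # case minus control mean, measurement scale


@dataclass(frozen=True)
class ModuleActivity:
    module_id: str
    patient_id: str
    percent: float  # in [-100, +100]
    n_up: int
    n_down: int
    n_total: int


@dataclass(frozen=True)
class TextChunk:
    sentences: tuple[str, ...]
    token_estimate: int
    budget: int


@dataclass(frozen=True)
class ChunkedCorpus:
    chunks: tuple[TextChunk, ...]
    exceeds_single_context: bool  # corpus needed more than one chunk

    @property
    def sentences(self) -> tuple[str, ...]:
        return tuple(s for c in self.chunks for s in c.sentences)


def chunk_corpus(sentences: Sequence[str], budget: int) -> ChunkedCorpus:
    """Greedily pack sentences into budget-bounded chunks, preserving order.

    Sentences are never split.  A corpus needing more than one chunk is
    flagged ``exceeds_single_context`` so the caller can decide to skip the
    dataset instead of feeding partial context.  A single sentence that
    alone exceeds the budget is an error.
    """
    if budget <= 0:
        raise ValidationError(f"budget must be positive, got {budget}")
    chunks: list[TextChunk] = []
    current: list[str] = []
    current_tokens = 0
    for sentence in sentences:
        t = estimate_tokens(sentence)
        if t > budget:
            raise ContextOverflowError(
                f"sentence of ~{t} tokens exceeds the budget of {budget}: "
                f"{sentence[:80]!r}"
            )
        if current_tokens + t > budget:
            chunks.append(TextChunk(tuple(current), current_tokens, budget))
            current, current_tokens = [], 0
        current.append(sentence)
        current_tokens += t
    if current:
        chunks.append(TextChunk(tuple(current), current_tokens, budget))
    return ChunkedCorpus(tuple(chunks), exceeds_single_context=len(chunks) > 1)


def differential_entries(
    case: pd.DataFrame, control: pd.DataFrame
) -> list[DifferentialEntry]:
    """Per-patient, per-gene log2 fold change and raw difference vs controls.

    ``case``: genes x patients measurement matrix; ``control``: genes x
    control-samples matrix on the same scale.  The control mean per gene is
    the denominator of the ratio and the subtrahend of the difference.

    Raises
    ------
    ValidationError
        For any gene whose control mean is not strictly positive (the
        log-ratio is undefined there).
    """
    control_mean = control.mean(axis=1)
    bad = control_mean[control_mean <= 0]
    if len(bad):
        raise ValidationError(
            f"nonpositive control mean for gene(s): {list(bad.index)}"
        )
    entries: list[DifferentialEntry] = []
    for gene in case.index:
        mean = control_mean.loc[gene]
        for patient in case.columns:
            value = case.loc[gene, patient]
            entries.append(
                DifferentialEntry(
                    patient_id=str(patient),
                    gene=str(gene),
                    log2_fold_change=float(np.log2(value / mean)),
                    raw_difference=float(value - mean),
                )
            )
    return entries


def module_activity(
    entries: Iterable[DifferentialEntry],
    module: GeneModule,
    fc_cutoff: float = 1.5,
    diff_cutoff: float = 10.0,
) -> list[ModuleActivity]:
    """Per-patient signed percentage of differentially expressed module genes.

    A module gene counts as up when log2FC > +fc_cutoff AND raw difference
    > +diff_cutoff, and as down when log2FC < -fc_cutoff AND raw difference
    < -diff_cutoff (the raw-difference gate suppresses large ratios of
    near-zero signals).  percent = 100 x (n_up - n_down) / module size, so
    +100 means every gene up, -100 every gene down.  Module genes absent
    from the entries still count in the denominator; their absence is
    logged.
    """
    module_genes = set(module.genes)
    by_patient: dict[str, list[DifferentialEntry]] = {}
    for e in entries:
        if e.gene in module_genes:
            by_patient.setdefault(e.patient_id, []).append(e)
    if not by_patient:
        raise ValidationError(
            f"no entries cover any gene of module {module.module_id}"
        )
    out: list[ModuleActivity] = []
    for patient in sorted(by_patient):
        patient_entries = by_patient[patient]
        seen = {e.gene for e in patient_entries}
        missing = module_genes - seen
        if missing:
            logger.warning(
                "patient %s: %d module gene(s) absent from entries (%s)",
                patient, len(missing), ", ".join(sorted(missing)[:5]),
            )
        n_up = sum(
            1 for e in patient_entries
            if e.log2_fold_change > fc_cutoff and e.raw_difference > diff_cutoff
        )
        n_down = sum(
            1 for e in patient_entries
            if e.log2_fold_change < -fc_cutoff and e.raw_difference < -diff_cutoff
        )
        n_total = module.n_genes
        out.append(
            ModuleActivity(
                module_id=module.module_id,
                patient_id=patient,
                percent=100.0 * (n_up - n_down) / n_total,
                n_up=n_up,
                n_down=n_down,
                n_total=n_total,
            )
        )
    return out


@dataclass(frozen=True)
class SyntheticExpressionConfig:
    """Settings for the synthetic expression generator.

    The generator emulates the three reference-dataset shapes around an
    erythroid-restricted signature: genes designated ``restricted_genes``
    are expressed ``restriction_ratio`` times higher in the
    ``restricted_populations`` (and in whole blood, which contains the
    restricted cells) than in the other populations; cohorts shift the
    module genes by a configured mean log2 fold change.  Multiplicative
    log-normal noise with ``noise_sd`` (log2 scale) perturbs every
    measurement; ``noise_sd=0`` gives exact ratios.
    """

    genes: tuple[str, ...]
    restricted_genes: tuple[str, ...]
    rnaseq_populations: tuple[str, ...] = (
        "Whole blood", "Neutrophils", "Monocytes", "B cells",
        "CD4 T cells", "CD8 T cells", "NK cells",
    )
    microarray_populations: tuple[str, ...] = (
        "Basophils", "Naive B cells", "Monocytes", "Neutrophils",
        "Erythroid ERY3", "Erythroid ERY4", "Erythroid ERY5",
    )
    restricted_populations: tuple[str, ...] = (
        "Whole blood", "Erythroid ERY3", "Erythroid ERY4", "Erythroid ERY5",
    )
    cohorts: Mapping[str, float] = field(
        default_factory=lambda: {
            "metastatic melanoma": 2.5,
            "pregnancy": 2.0,
            "acute respiratory syncytial virus infection": 1.8,
            "liver transplant recipients": 1.6,
            "acute influenza infection": -1.8,
            "multiple sclerosis": -2.0,
        }
    )
    n_patients: int = 10
    n_controls: int = 10
    baseline: float = 50.0
    restriction_ratio: float = 50.0
    noise_sd: float = 0.25  # log2-scale sd

    def __post_init__(self) -> None:
        if self.restriction_ratio <= 1:
            raise ConfigError("restriction_ratio must exceed 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        unknown = set(self.restricted_genes) - set(self.genes)
        if unknown:
            raise ConfigError(f"restricted_genes not in genes: {sorted(unknown)}")


def synthetic_expression(cfg: SyntheticExpressionConfig, seed: int) -> dict[str, pd.DataFrame]:
    """Generate the three expression tables, deterministically per seed.

    Returns a dict with:

    * ``"rnaseq"`` / ``"microarray"`` — long tables (dataset_id, schema,
      gene, context_label, value, species);
    * ``"cohort_case"`` — MultiIndex-column (cohort, patient) genes x
      patients matrix; ``"cohort_control"`` — genes x controls matrix;
    * ``"cohort_log2fc"`` — long table of cohort-averaged log2 fold
      changes in the cohort_log2fc schema.
    """
    rng = np.random.default_rng([seed, 0x5EED])

    def noisy(level: float) -> float:
        if cfg.noise_sd == 0:
            return float(level)
        return float(level * np.exp2(rng.normal(0.0, cfg.noise_sd)))

    def level_for(gene: str, population: str) -> float:
        restricted = gene in cfg.restricted_genes
        hot = population in cfg.restricted_populations
        if restricted and hot:
            return cfg.baseline * cfg.restriction_ratio
        return cfg.baseline

    long_rows = {"rnaseq": [], "microarray": []}
    for key, schema, populations, dataset in (
        ("rnaseq", "rnaseq_count", cfg.rnaseq_populations, "synthetic-rnaseq"),
        ("microarray", "microarray_intensity", cfg.microarray_populations,
         "synthetic-microarray"),
    ):
        for gene in cfg.genes:
            for pop in populations:
                value = float(noisy(level_for(gene, pop)))
                long_rows[key].append(
                    {
                        "dataset_id": dataset,
                        "schema": schema,
                        "gene": gene,
                        "context_label": pop,
                        "value": round(value, 4),
                        "species": "Human",
                    }
                )

    # cohort matrices: controls at whole-blood baseline, patients shifted on
    # the module genes by the cohort's mean log2 fold change
    control = pd.DataFrame(
        {
            f"control_{i+1}": [
                noisy(level_for(g, "Whole blood")) for g in cfg.genes
            ]
            for i in range(cfg.n_controls)
        },
        index=list(cfg.genes),
    )
    case_blocks: dict[tuple[str, str], list[float]] = {}
    fc_rows = []
    control_mean = control.mean(axis=1)
    for cohort, shift in cfg.cohorts.items():
        for p in range(cfg.n_patients):
            col = []
            for g in cfg.genes:
                base = level_for(g, "Whole blood") * (2.0 ** shift)
                col.append(float(noisy(base)))
            case_blocks[(cohort, f"patient_{p+1}")] = col
    case = pd.DataFrame(case_blocks, index=list(cfg.genes))
    case.columns = pd.MultiIndex.from_tuples(case.columns, names=["cohort", "patient"])
    for cohort in cfg.cohorts:
        cohort_mean = case[cohort].mean(axis=1)
        for g in cfg.genes:
            fc_rows.append(
                {
                    "dataset_id": "synthetic-cohorts",
                    "schema": "cohort_log2fc",
                    "gene": g,
                    "context_label": cohort,
                    "value": round(float(np.log2(cohort_mean[g] / control_mean[g])), 7),
                    "species": "Human",
                }
            )

    return {
        "rnaseq": pd.DataFrame(long_rows["rnaseq"]),
        "microarray": pd.DataFrame(long_rows["microarray"]),
        "cohort_case": case,
        "cohort_control": control,
        "cohort_log2fc": pd.DataFrame(fc_rows),
    }


def records_from_frame(df: pd.DataFrame) -> list[ExpressionRecord]:
    """Rows of a long-format expression table as :class:`ExpressionRecord`s."""
    return [
        ExpressionRecord(
            dataset_id=row.dataset_id,
            schema=row.schema,
            gene=row.gene,
            context_label=row.context_label,
            value=float(row.value),
            species=row.species,
        )
        for row in df.itertuples(index=False)
    ]
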