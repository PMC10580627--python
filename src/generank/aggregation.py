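"""Score aggregation: tensors, cumulative rankings, consistency, consensus.

Scores arrive as one parsed record per (gene, model, replicate).  They are
assembled into a 4-way tensor (gene x criterion x model x replicate, NaN
for missing cells) and reduced in a fixed order: replicates are averaged
within each model first, then models are averaged with equal weight, then
the six per-criterion means are summed into the cumulative score used for
rank ordering.  Equal weighting across criteria/themes is deliberate — the
rubric's themes are weighted equally by design.

Consistency between scorers is quantified as Pearson correlation between
gene-score vectors (scores are interval-scaled 0–10 integers), either per
(model, replicate) pair or between model-wise replicate means.  Theme
consensus counts how many independent sources (models or enrichment tools)
tie a gene to a matching functional theme.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DuplicateCellError, ValidationError
from .records import ScoreRecord
from .rubric import CRITERION_KEYS

__all__ = [
    "ScoreTensor",
    "RankedGene",
    "ConsistencyMatrix",
    "ThemeAssignment",
    "assemble_tensor",
    "cumulative_ranking",
    "top_k",
    "consistency",
    "consensus_members",
]

logger = logging.getLogger(__name__)


@dataclass
class ScoreTensor:
    """Gene x criterion x model x replicate score array (NaN = missing)."""

    genes: tuple[str, ...]
    criteria: tuple[str, ...]
    models: tuple[str, ...]
    replicates: int
    values: np.ndarray  # float array, shape (G, C, M, R)

    def __post_init__(self) -> None:
        expected = (len(self.genes), len(self.criteria), len(self.models), self.replicates)
        if self.values.shape != expected:
            raise ValidationError(
                f"tensor shape {self.values.shape} != expected {expected}"
            )

    def to_long(self) -> pd.DataFrame:
        """Long-format (gene, criterion, model, replicate, score) table."""
        rows = []
        for gi, g in enumerate(self.genes):
            for ci, c in enumerate(self.criteria):
                for mi, m in enumerate(self.models):
                    for r in range(self.replicates):
                        v = self.values[gi, ci, mi, r]
                        if not np.isnan(v):
                            rows.append((g, c, m, r, int(v)))
        return pd.DataFrame(
            rows, columns=["gene", "criterion", "model", "replicate", "score"]
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "ScoreTensor":
        genes = tuple(dict.fromkeys(df["gene"]))
        criteria = tuple(sorted(set(df["criterion"])))
        models = tuple(dict.fromkeys(df["model"]))
        replicates = int(df["replicate"].max()) + 1 if len(df) else 0
        values = np.full((len(genes), len(criteria), len(models), replicates), np.nan)
        gi = {g: i for i, g in enumerate(genes)}
        ci = {c: i for i, c in enumerate(criteria)}
        mi = {m: i for i, m in enumerate(models)}
        for row in df.itertuples(index=False):
            values[gi[row.gene], ci[row.criterion], mi[row.model], row.replicate] = row.score
        return cls(genes, criteria, models, replicates, values)


@dataclass(frozen=True)
class RankedGene:
    symbol: str
    per_criterion_mean: dict[str, float]
    cumulative_score: float
    rank: int


@dataclass
class ConsistencyMatrix:
    labels: tuple[str, ...]
    r: np.ndarray        # symmetric, NaN where undefined
    n_genes: np.ndarray  # genes used per cell


@dataclass(frozen=True)
class ThemeAssignment:
    source: str
    theme: str
    genes: frozenset[str]


def assemble_tensor(
    records: Iterable[tuple[str, int, ScoreRecord]],
    criteria: Sequence[str] = CRITERION_KEYS,
) -> ScoreTensor:
    """Assemble (model, replicate, record) triples into a score tensor.

    Missing cells stay NaN (missing, never zero).  Two records for the same
    (gene, model, replicate) cell must agree exactly; conflicting
    duplicates raise :class:`DuplicateCellError`.  Gene sets must be
    identical across models — asymmetric coverage is an assembly bug, not a
    missing-data condition.
    """
    cells: dict[tuple[str, str, int], ScoreRecord] = {}
    genes: dict[str, None] = {}
    models: dict[str, None] = {}
    max_rep = -1
    genes_by_model: dict[str, set[str]] = {}
    for model, replicate, rec in records:
        key = (rec.gene_symbol, model, replicate)
        if key in cells and cells[key].scores() != rec.scores():
            raise DuplicateCellError(
                f"conflicting records for gene={rec.gene_symbol} "
                f"model={model} replicate={replicate}"
            )
        cells[key] = rec
        genes.setdefault(rec.gene_symbol)
        models.setdefault(model)
        genes_by_model.setdefault(model, set()).add(rec.gene_symbol)
        max_rep = max(max_rep, replicate)

    all_genes = set(genes)
    asymmetric = {
        m: sorted(all_genes - seen) for m, seen in genes_by_model.items()
        if all_genes - seen
    }
    if asymmetric:
        raise ValidationError(f"gene sets differ across models: {asymmetric}")

    gene_order = tuple(genes)
    model_order = tuple(models)
    R = max_rep + 1
    values = np.full((len(gene_order), len(criteria), len(model_order), R), np.nan)
    gi = {g: i for i, g in enumerate(gene_order)}
    mi = {m: i for i, m in enumerate(model_order)}
    for (gene, model, replicate), rec in cells.items():
        for c_idx, ckey in enumerate(criteria):
            values[gi[gene], c_idx, mi[model], replicate] = rec.assessments[ckey].score
    return ScoreTensor(gene_order, tuple(criteria), model_order, R, values)


def cumulative_ranking(t: ScoreTensor) -> list[RankedGene]:
    """Rank genes by cumulative score.

    Per-criterion mean = equal-weight mean over models of each model's
    replicate mean (computed over the replicates that are present);
    cumulative = sum over criteria.  A criterion with every cell missing
    for a gene contributes 0 and logs a warning.  Sort is by descending
    cumulative score with ties broken by ascending symbol; ranks are 1..n.
    """
    ranked: list[tuple[str, dict[str, float], float]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices handled below
        per_model = np.nanmean(t.values, axis=3)      # (G, C, M)
        per_criterion = np.nanmean(per_model, axis=2)  # (G, C)
    for gi, gene in enumerate(t.genes):
        means: dict[str, float] = {}
        for ci, ckey in enumerate(t.criteria):
            v = per_criterion[gi, ci]
            if np.isnan(v):
                logger.warning(
                    "gene %s criterion %s has no scores; contributes 0", gene, ckey
                )
                v = 0.0
            means[ckey] = float(v)
        ranked.append((gene, means, float(sum(means.values()))))
    ranked.sort(key=lambda item: (-item[2], item[0]))
    return [
        RankedGene(symbol=g, per_criterion_mean=m, cumulative_score=c, rank=i + 1)
        for i, (g, m, c) in enumerate(ranked)
    ]


def top_k(ranked: Sequence[RankedGene], k: int) -> list[RankedGene]:
    """First min(k, n) entries of a ranking, in rank order."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return list(ranked[: min(k, len(ranked))])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def consistency(t: ScoreTensor, criterion: str, level: str = "replicate") -> ConsistencyMatrix:
    """Pairwise Pearson correlation of gene-score vectors for one criterion.

    ``level="replicate"`` correlates every (model, replicate) vector pair;
    ``level="model"`` correlates model-wise replicate-mean vectors.  Each
    pair uses the genes non-missing in both vectors; fewer than 3 usable
    genes raises, and a zero-variance vector yields NaN cells (including
    its own diagonal, where r is undefined).
    """
    if criterion not in t.criteria:
        raise ValidationError(f"unknown criterion {criterion!r}")
    ci = t.criteria.index(criterion)
    if level == "replicate":
        labels = tuple(
            f"{m}/rep{r+1}" for m in t.models for r in range(t.replicates)
        )
        vectors = [
            t.values[:, ci, mi, r]
            for mi in range(len(t.models))
            for r in range(t.replicates)
        ]
    elif level == "model":
        labels = tuple(t.models)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            vectors = [
                np.nanmean(t.values[:, ci, mi, :], axis=1)
                for mi in range(len(t.models))
            ]
    else:
        raise ValidationError(f"level must be 'replicate' or 'model', got {level!r}")

    n = len(vectors)
    r = np.full((n, n), np.nan)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i, n):
            mask = ~np.isnan(vectors[i]) & ~np.isnan(vectors[j])
            usable = int(mask.sum())
            counts[i, j] = counts[j, i] = usable
            if usable < 3:
                raise ValidationError(
                    f"fewer than 3 usable genes between {labels[i]} and {labels[j]}"
                )
            rij = _pearson(vectors[i][mask], vectors[j][mask])
            r[i, j] = r[j, i] = rij
    return ConsistencyMatrix(labels=labels, r=r, n_genes=counts)


def consensus_members(
    assignments: Iterable[ThemeAssignment],
    theme_match: Callable[[str], bool],
) -> dict[str, int]:
    """Count, per gene, the distinct sources tying it to a matching theme."""
    supporters: dict[str, set[str]] = {}
    for a in assignments:
        if theme_match(a.theme):
            for gene in a.genes:
                supporters.setdefault(gene, set()).add(a.source)
    return {gene: len(sources) for gene, sources in sorted(supporters.items())}


def ranking_to_frame(ranked: Sequence[RankedGene]) -> pd.DataFrame:
    """Plot-ready ranking table with a stable column order."""
    rows = [
        {
            "rank": rg.rank,
            "gene": rg.symbol,
            **{f"mean_{k}": v for k, v in rg.per_criterion_mean.items()},
            "cumulative_score": rg.cumulative_score,
        }
        for rg in ranked
    ]
    return pd.DataFrame(rows)


def consistency_to_tsv(cm: ConsistencyMatrix) -> str:
    df = pd.DataFrame(cm.r, index=list(cm.labels), columns=list(cm.labels))
    buf = io.StringIO()
    df.to_csv(buf, sep="\t", float_format="%.6f")
    return buf.getvalue()
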