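"""Gene-module repertoires: loading, normalization, and lookup.

A repertoire is a collection of co-expression modules (each a named, ordered
list of gene symbols) grouped into aggregates — the two-tier dimension
reduction used by fixed blood-transcriptome module frameworks such as
BloodGen3, where e.g. aggregate A37 collects the eleven erythroid-associated
modules (M9.2, M11.2, ...).

Files are read and written in a GMT dialect: one tab-separated line per
module, ``module_id <TAB> aggregate_id <TAB> symbol <TAB> symbol ...`` —
standard GMT with the description column carrying the aggregate id.  Member
symbols are normalized lexically (uppercased, trimmed, first-occurrence
deduplicated); no alias or HGNC resolution is attempted, printed symbols are
taken at face value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Iterable

from .errors import GmtFormatError, ModuleLookupError, ValidationError

__all__ = [
    "GeneModule",
    "Repertoire",
    "normalize_symbols",
    "read_gene_sets",
    "write_gene_sets",
    "get_module",
]


def normalize_symbols(raw: Iterable[str]) -> list[str]:
    """Normalize a list of gene symbols.

    Symbols are whitespace-trimmed and uppercased; duplicates are dropped
    keeping the first occurrence, so printed ordering is preserved.

    Raises
    ------
    ValidationError
        If any symbol is empty after trimming; the message names its
        0-based position.
    """
    seen: set[str] = set()
    out: list[str] = []
    for i, sym in enumerate(raw):
        s = sym.strip().upper()
        if not s:
            raise ValidationError(f"empty gene symbol at position {i}")
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


@dataclass(frozen=True)
class GeneModule:
    """One co-expression module: id, aggregate id, ordered unique members."""

    module_id: str
    aggregate_id: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        normalized = tuple(normalize_symbols(self.genes))
        if normalized != self.genes:
            object.__setattr__(self, "genes", normalized)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol.strip().upper() in self.genes


@dataclass
class Repertoire:
    """Modules indexed by id, grouped into ordered aggregates."""

    modules: dict[str, GeneModule] = field(default_factory=dict)
    aggregates: dict[str, list[str]] = field(default_factory=dict)

    def add(self, module: GeneModule) -> None:
        if module.module_id in self.modules:
            raise GmtFormatError(f"duplicate module id {module.module_id!r}")
        for agg, ids in self.aggregates.items():
            if module.module_id in ids and agg != module.aggregate_id:
                raise ValidationError(
                    f"module {module.module_id!r} already listed under {agg!r}"
                )
        self.modules[module.module_id] = module
        self.aggregates.setdefault(module.aggregate_id, []).append(module.module_id)

    def __len__(self) -> int:
        return len(self.modules)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Repertoire):
            return NotImplemented
        return self.modules == other.modules and self.aggregates == other.aggregates


def read_gene_sets(stream: IO[str] | Iterable[str]) -> Repertoire:
    """Parse a GMT-dialect stream into a :class:`Repertoire`.

    Each line must carry at least three tab-separated fields: module id,
    aggregate id, and one or more member symbols.  Members are normalized;
    line order is preserved within aggregates.

    Raises
    ------
    GmtFormatError
        On a line with fewer than three fields (reports the 1-based line
        number) or a duplicate module id.
    """
    rep = Repertoire()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise GmtFormatError(
                f"line {lineno}: expected at least 3 tab-separated fields, "
                f"got {len(fields)}",
                line_number=lineno,
            )
        module_id, aggregate_id = fields[0].strip(), fields[1].strip()
        try:
            genes = tuple(normalize_symbols(fields[2:]))
        except ValidationError as exc:
            raise GmtFormatError(f"line {lineno}: {exc}", line_number=lineno) from exc
        rep.add(GeneModule(module_id=module_id, aggregate_id=aggregate_id, genes=genes))
    return rep


def write_gene_sets(rep: Repertoire, stream: IO[str]) -> None:
    """Serialize a repertoire back to the GMT dialect (newline-terminated).

    Modules are written aggregate by aggregate in insertion order, so a
    read/write/read round trip reproduces an identical repertoire.
    """
    for aggregate_id, module_ids in rep.aggregates.items():
        for module_id in module_ids:
            mod = rep.modules[module_id]
            stream.write("\t".join((mod.module_id, aggregate_id) + mod.genes) + "\n")


def get_module(rep: Repertoire, module_id: str) -> GeneModule:
    """Look up one module by id.

    Raises
    ------
    ModuleLookupError
        If the id is unknown; the message lists the available ids.
    """
    try:
        return rep.modules[module_id]
    except KeyError:
        available = ", ".join(sorted(rep.modules))
        raise ModuleLookupError(
            f"unknown module {module_id!r}; available: {available}"
        ) from None
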