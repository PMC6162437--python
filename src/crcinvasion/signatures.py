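"""Gene-set (signature) reading, validation and registration.

Signatures are carried as GMT (Broad dialect): one tab-separated line per set,
``NAME <TAB> DESCRIPTION <TAB> gene1 <TAB> gene2 ...``.  Gene identifiers are
matched by exact string comparison after uppercasing; no alias resolution is
attempted.  A set needs at least 2 genes present in an expression matrix to be
usable for enrichment scoring — a running sum over a single hit is degenerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

MIN_USABLE_GENES = 2

CATEGORIES = (
    "canonical CRC",
    "cancer pathway",
    "stromal",
    "immune",
    "metabolic",
    "developmental",
)

__all__ = [
    "GeneSet",
    "SignatureCollection",
    "read_gmt",
    "write_gmt",
    "validate_against_matrix",
    "read_direction_table",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if any(not g for g in self.genes):
            raise ValueError(f"gene set {self.name!r} contains an empty gene id")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"gene set {self.name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class SignatureCollection:
    """Named gene sets, optional category tags and a per-subtype direction table.

    ``directions`` (subtypes × set names, entries in {-1, 0, +1}) encodes which
    signatures each molecular subtype is expected to activate or suppress.
    """

    sets: dict[str, GeneSet] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    directions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        for name, gs in self.sets.items():
            if name != gs.name:
                raise ValueError(f"key {name!r} does not match set name {gs.name!r}")
        if self.directions is not None:
            missing = set(self.directions.columns) - set(self.sets)
            if missing:
                raise ValueError(
                    f"direction table references unknown sets: {sorted(missing)}"
                )

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.values())

    def __getitem__(self, name: str) -> GeneSet:
        return self.sets[name]

    def add(self, gene_set: GeneSet, category: str | None = None) -> None:
        if gene_set.name in self.sets:
            raise ValueError(f"duplicate gene set name {gene_set.name!r}")
        self.sets[gene_set.name] = gene_set
        if category is not None:
            self.categories[gene_set.name] = category

    @property
    def total_genes(self) -> int:
        """Total membership count, summed over sets (genes may repeat across sets)."""
        return sum(len(gs) for gs in self.sets.values())


def _dedupe_upper(genes: Iterable[str], set_name: str) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    duplicates = 0
    for g in genes:
        g = g.strip().upper()
        if not g:
            continue
        if g in seen:
            duplicates += 1
        else:
            seen[g] = None
    if duplicates:
        logger.warning(
            "gene set %r: removed %d duplicate gene id(s)", set_name, duplicates
        )
    return tuple(seen)


def read_gmt(path: str | Path) -> SignatureCollection:
    """Parse a GMT file into a :class:`SignatureCollection`.

    Genes are uppercased and deduplicated preserving first occurrence (a
    warning is logged when duplicates are dropped).  Lines with fewer than
    three fields, duplicate set names and empty files are errors.
    """
    path = Path(path)
    collection = SignatureCollection()
    n_lines = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            name, description = fields[0].strip(), fields[1]
            if name in collection.sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = _dedupe_upper(fields[2:], name)
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} has no genes")
            collection.add(GeneSet(name=name, description=description, genes=genes))
    if n_lines == 0:
        raise ValueError(f"{path}: empty GMT file")
    return collection


def write_gmt(collection: SignatureCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for gs in collection:
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


def validate_against_matrix(
    collection: SignatureCollection, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-set coverage of an expression matrix (report-only, never raises).

    Returns a DataFrame indexed by set name with columns ``n_genes``,
    ``n_present``, ``coverage`` and ``usable`` (at least MIN_USABLE_GENES
    member genes found among the matrix rows).
    """
    matrix_genes = {str(g).upper() for g in matrix.index}
    rows = []
    for gs in collection:
        present = sum(1 for g in gs.genes if g in matrix_genes)
        rows.append(
            {
                "n_genes": len(gs),
                "n_present": present,
                "coverage": present / len(gs),
                "usable": present >= MIN_USABLE_GENES,
            }
        )
    report = pd.DataFrame(rows, index=pd.Index([gs.name for gs in collection], name="set"))
    for name in report.index[~report["usable"]]:
        logger.warning("gene set %r is unusable in this matrix (<2 genes present)", name)
    return report


def read_direction_table(path: str | Path) -> pd.DataFrame:
    """Read a signed direction table: rows = set names, one column per subtype.

    The on-disk layout is the transpose of the archetype matrix used by the
    classifier (set name first column, then one signed integer per subtype);
    the returned frame is subtypes × sets to match the classifier convention.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0)
    frame = frame.T
    values = frame.to_numpy()
    if not ((values == -1) | (values == 0) | (values == 1)).all():
        raise ValueError(f"{path}: direction entries must be -1, 0 or +1")
    return frame.astype(int)
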