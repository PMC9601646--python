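"""Circular signed gene orders.

A mitochondrial gene order is modelled as a signed circular permutation:
an ordered ring of named genes, each transcribed from the majority (+) or
minority (-) strand.  Two physical descriptions of one circle differ only
by rotation, or by reading the other strand (which reverses the order and
flips every sign); :func:`canonicalize` collapses both symmetries so that
orders can be compared with plain equality.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .vocab import (
    CR,
    MAJORITY,
    MINORITY,
    STRANDS,
    VOCABULARY,
    category_of,
    normalize_gene_name,
)


class GeneOrderError(ValueError):
    """Invalid gene-order construction or parse."""


@dataclass(frozen=True)
class Gene:
    """One gene on the circle: canonical name plus transcription strand."""

    name: str
    strand: str = MAJORITY

    def __post_init__(self):
        if self.name not in VOCABULARY:
            raise GeneOrderError(
                f"gene name {self.name!r} is not in the canonical vocabulary"
            )
        if self.strand not in STRANDS:
            raise GeneOrderError(
                f"strand must be one of {STRANDS}, got {self.strand!r}"
            )

    @property
    def category(self) -> str:
        return category_of(self.name)

    def flipped(self) -> "Gene":
        """The same gene read from the other strand."""
        return Gene(self.name, MINORITY if self.strand == MAJORITY else MAJORITY)

    def __str__(self) -> str:  # e.g. "cox1" / "-trnQ"
        return self.name if self.strand == MAJORITY else "-" + self.name


#: Complete metazoan gene content: all 37 genes plus the control region.
COMPLETE_GENE_SET = frozenset(VOCABULARY)


class GeneOrder:
    """An ordered ring of :class:`Gene` for one genome.

    Gene names are unique on the circle (duplication intermediates are a
    separate type, see :mod:`mitorearrange.events`).
    """

    def __init__(self, genome_id: str, genes: Iterable[Gene], circular: bool = True):
        self.genome_id = genome_id
        self.genes: tuple[Gene, ...] = tuple(genes)
        self.circular = circular
        names = [g.name for g in self.genes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise GeneOrderError(
                f"duplicate gene(s) in {genome_id!r}: {', '.join(sorted(dupes))}"
            )
        if len(self.genes) > len(VOCABULARY):
            raise GeneOrderError("more genes than the 38-token vocabulary allows")

    # -- basic protocol ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def __repr__(self) -> str:
        return f"GeneOrder({self.genome_id!r}, [{' '.join(map(str, self.genes))}])"

    def __eq__(self, other) -> bool:
        """Circular signed equality (genome ids are ignored)."""
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return equals_circular(self, other)

    def __hash__(self):
        return hash(tuple(canonicalize(self).genes))

    # -- content ----------------------------------------------------------
    @property
    def gene_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(g.name for g in self.genes)

    def is_complete(self) -> bool:
        """True iff the order carries all 37 genes plus the CR."""
        return self.gene_set == COMPLETE_GENE_SET

    def category_counts(self) -> dict[str, int]:
        counts = {"PCG": 0, "tRNA": 0, "rRNA": 0, "CR": 0}
        for g in self.genes:
            counts[g.category] += 1
        return counts

    def index_of(self, name: str) -> int:
        for i, g in enumerate(self.genes):
            if g.name == name:
                return i
        raise KeyError(name)

    # -- symmetry operations ----------------------------------------------
    def rotated(self, k: int) -> "GeneOrder":
        """The same circle read starting from position ``k``."""
        k %= len(self.genes)
        return GeneOrder(self.genome_id, self.genes[k:] + self.genes[:k])

    def reflected(self) -> "GeneOrder":
        """The same circle read from the opposite strand."""
        return GeneOrder(self.genome_id, tuple(g.flipped() for g in reversed(self.genes)))

    def with_id(self, genome_id: str) -> "GeneOrder":
        return GeneOrder(genome_id, self.genes, self.circular)

    # -- serialization ----------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {"genome_id": self.genome_id,
             "genes": [[g.name, g.strand] for g in self.genes]}
        )

    @classmethod
    def from_json(cls, text: str) -> "GeneOrder":
        obj = json.loads(text)
        return cls(obj["genome_id"], (Gene(n, s) for n, s in obj["genes"]))


def _signed_key(genes: Sequence[Gene]) -> tuple:
    return tuple((g.name, g.strand) for g in genes)


def canonicalize(order: GeneOrder) -> GeneOrder:
    """Canonical representative of a circular signed order.

    The circle is rotated to begin with cox1 on the majority strand,
    reflecting (reverse + strand flip) first if cox1 lies on the minority
    strand.  Without cox1, the representative is the lexicographically
    smallest of all rotations of both readings.  Idempotent; identical for
    every rotation/reflection of the same circle.
    """
    if not order.circular:
        return order
    n = len(order.genes)
    if n == 0:
        return order
    candidates: list[tuple[Gene, ...]] = []
    for variant in (order, order.reflected()):
        for k in range(n):
            candidates.append(variant.genes[k:] + variant.genes[:k])
    anchored = [c for c in candidates
                if c[0].name == "cox1" and c[0].strand == MAJORITY]
    if not anchored:
        anchored = [c for c in candidates if c[0].name == "cox1"]
    pool = anchored if anchored else candidates
    best = min(pool, key=_signed_key)
    return GeneOrder(order.genome_id, best, order.circular)


def equals_circular(a: GeneOrder, b: GeneOrder) -> bool:
    """True iff ``a`` and ``b`` describe the same signed circle."""
    if not (a.circular and b.circular):
        return _signed_key(a.genes) == _signed_key(b.genes)
    return _signed_key(canonicalize(a).genes) == _signed_key(canonicalize(b).genes)


# ---------------------------------------------------------------------------
# Gene-order tables (TSV: genome_id, rank, gene, strand)
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["genome_id", "rank", "gene", "strand"]


def parse_gene_order_table(text: str) -> list[GeneOrder]:
    """Parse a gene-order table into one :class:`GeneOrder` per genome.

    The table is TSV with header ``genome_id  rank  gene  strand``, ``#``
    comments, UTF-8.  Ranks must be contiguous from 0 within each genome;
    gene names are normalized through the alias map.
    """
    df = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise GeneOrderError(f"gene-order table missing column(s): {missing}")
    orders = []
    for genome_id, grp in df.groupby("genome_id", sort=False):
        grp = grp.copy()
        grp["rank"] = grp["rank"].astype(int)
        grp = grp.sort_values("rank")
        ranks = grp["rank"].tolist()
        if ranks != list(range(len(ranks))):
            raise GeneOrderError(
                f"ranks for {genome_id!r} are not contiguous from 0: {ranks}"
            )
        genes = []
        for _, row in grp.iterrows():
            name = normalize_gene_name(row["gene"])
            strand = row["strand"].strip()
            if strand not in STRANDS:
                raise GeneOrderError(
                    f"bad strand {strand!r} for {name} in {genome_id!r}"
                )
            genes.append(Gene(name, strand))
        orders.append(GeneOrder(str(genome_id), genes))
    return orders


def serialize_gene_order_table(orders: Iterable[GeneOrder]) -> str:
    """Inverse of :func:`parse_gene_order_table` (parse∘serialize == id)."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for order in orders:
        for rank, gene in enumerate(order.genes):
            lines.append(f"{order.genome_id}\t{rank}\t{gene.name}\t{gene.strand}")
    return "\n".join(lines) + "\n"
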