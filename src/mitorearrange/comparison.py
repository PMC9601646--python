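"""Pairwise comparison of circular signed gene orders.

Two orders are compared through their *oriented adjacencies*.  Each gene is
given a head and a tail end (tail→head in majority orientation); an
adjacency is the unordered pair of gene ends that meet on the circle, so
that reading the other strand yields the same adjacency set.  The
breakpoint distance counts adjacencies of one order absent from the other.

``decompose_blocks`` partitions a query order into maximal blocks whose
internal adjacencies are conserved in a reference, then finds the smallest
set of blocks whose removal makes the remaining circles identical — the
*rearranged units*.  Ties on unit count are broken by the fewest genes
moved (small tRNAs move more readily than long conserved stretches), then
deterministically.  Removed blocks separated in the reference only by other
removed genes are merged into one named unit, which is how a unit like
"nad1-CR" arises when a gene was extracted from the middle of a moved
segment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .order import Gene, GeneOrder, canonicalize, equals_circular
from .vocab import MAJORITY


class ComparisonError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Shared-gene restriction and adjacency sets
# ---------------------------------------------------------------------------

def restrict_to_shared(a: GeneOrder, b: GeneOrder) -> tuple[GeneOrder, GeneOrder]:
    """Project both orders onto the intersection of their gene sets."""
    shared = a.gene_set & b.gene_set
    if not shared:
        raise ComparisonError(
            f"no shared genes between {a.genome_id!r} and {b.genome_id!r}"
        )
    pa = GeneOrder(a.genome_id, (g for g in a.genes if g.name in shared), a.circular)
    pb = GeneOrder(b.genome_id, (g for g in b.genes if g.name in shared), b.circular)
    return pa, pb


def _ends(gene: Gene) -> tuple[tuple, tuple]:
    """(left end, right end) of a gene as oriented on the circle."""
    head, tail = (gene.name, "h"), (gene.name, "t")
    return (tail, head) if gene.strand == MAJORITY else (head, tail)


def adjacency_set(order: GeneOrder) -> frozenset[frozenset]:
    """Oriented adjacencies of a circular signed order.

    Invariant under rotation and under reflection-with-strand-flip.
    """
    genes = order.genes
    n = len(genes)
    adjacencies = set()
    for i in range(n):
        g1, g2 = genes[i], genes[(i + 1) % n]
        adjacencies.add(frozenset((_ends(g1)[1], _ends(g2)[0])))
    return frozenset(adjacencies)


def breakpoint_distance(a: GeneOrder, b: GeneOrder) -> int:
    """Number of oriented adjacencies of ``a`` absent from ``b``.

    Computed on the shared gene set; symmetric; 0 iff the restricted
    orders are identical up to rotation/reflection.
    """
    pa, pb = restrict_to_shared(a, b)
    return len(adjacency_set(pa) - adjacency_set(pb))


# ---------------------------------------------------------------------------
# Block decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Block:
    """A maximal query segment whose internal adjacencies are conserved."""

    genes: tuple[Gene, ...]
    ref_start: int          # position of the block in the reference circle
    ref_end: int            # inclusive, may wrap (mod n)
    orientation: int        # +1 same reading direction as reference, -1 reversed

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.genes)

    @property
    def label(self) -> str:
        if len(self.genes) == 1:
            return self.genes[0].name
        return f"{self.genes[0].name}-{self.genes[-1].name}"


@dataclass
class RearrangedUnit:
    """One moved (and/or inverted) unit: one or more merged blocks."""

    blocks: tuple[Block, ...]
    label: str
    genes: tuple[str, ...]


@dataclass
class BlockDecomposition:
    query_id: str
    reference_id: str
    blocks: list[Block]
    conserved: list[Block]
    units: list[RearrangedUnit] = field(default_factory=list)
    shared_gene_set: frozenset[str] = frozenset()

    @property
    def rearranged_count(self) -> int:
        return len(self.units)

    @property
    def unit_labels(self) -> list[str]:
        return [u.label for u in self.units]

    def summary(self) -> str:
        lines = [
            f"{self.query_id} vs {self.reference_id}: "
            f"{len(self.blocks)} blocks, {self.rearranged_count} rearranged unit(s)"
        ]
        for u in self.units:
            lines.append(f"  rearranged: {u.label} ({', '.join(u.genes)})")
        for b in self.conserved:
            lines.append(f"  conserved:  {b.label}")
        return "\n".join(lines)


def _maximal_blocks(query: GeneOrder, reference: GeneOrder) -> list[Block]:
    """Split the query circle at every adjacency absent from the reference."""
    ref_adj = adjacency_set(reference)
    genes = query.genes
    n = len(genes)
    ref_pos = {g.name: i for i, g in enumerate(reference.genes)}

    breakpoints = sorted(
        i for i in range(n)
        if frozenset((_ends(genes[i])[1], _ends(genes[(i + 1) % n])[0])) not in ref_adj
    )
    segments: list[tuple[Gene, ...]]
    if not breakpoints:
        segments = [genes]
    else:
        # segment j runs from the gene after breakpoint j-1 up to breakpoint j
        segments = []
        m = len(breakpoints)
        for j in range(m):
            s = (breakpoints[j - 1] + 1) % n
            e = breakpoints[j]
            seg = []
            i = s
            while True:
                seg.append(genes[i])
                if i == e:
                    break
                i = (i + 1) % n
            segments.append(tuple(seg))

    blocks = []
    for seg in segments:
        p0 = ref_pos[seg[0].name]
        p1 = ref_pos[seg[-1].name]
        if len(seg) == 1:
            orient = 1 if seg[0].strand == reference.genes[p0].strand else -1
        else:
            orient = 1 if ref_pos[seg[1].name] == (p0 + 1) % len(reference) else -1
        blocks.append(Block(seg, p0, p1, orient))
    return blocks


def _cyclic_equal(a: list, b: list) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    n = len(a)
    doubled = b + b
    return any(doubled[i:i + n] == a for i in range(n))


def _backbone_consistent(kept: tuple[int, ...], blocks: list[Block],
                         ref_order_of_blocks: list[int]) -> bool:
    """Do the kept blocks read identically (as circles) in query and reference?

    Query order of blocks is their list order; reference order is given by
    ``ref_order_of_blocks`` (block indices sorted by reference position).
    A forward backbone needs every kept block in +1 orientation; a reflected
    backbone needs every kept block reversed and the cyclic order reversed.
    """
    q_seq = [i for i in range(len(blocks)) if i in kept]
    r_seq = [i for i in ref_order_of_blocks if i in kept]
    if all(blocks[i].orientation == 1 for i in kept):
        if _cyclic_equal(q_seq, r_seq):
            return True
    if all(blocks[i].orientation == -1 for i in kept):
        if _cyclic_equal(q_seq, list(reversed(r_seq))):
            return True
    # single kept block is a circle segment on its own; orientation moot
    if len(kept) <= 1:
        return True
    return False


def _merge_units(removed: list[Block], blocks: list[Block],
                 reference: GeneOrder, removed_genes: set[str]) -> list[RearrangedUnit]:
    """Merge query-consecutive removed blocks separated in the reference
    only by other removed genes, then name each unit by its endpoints."""
    if not removed:
        return []
    n_ref = len(reference)
    idx_in_all = {id(b): i for i, b in enumerate(blocks)}
    removed_sorted = sorted(removed, key=lambda b: idx_in_all[id(b)])
    order_index = {id(b): idx_in_all[id(b)] for b in removed_sorted}

    def query_adjacent(u: Block, v: Block) -> bool:
        return order_index[id(v)] == order_index[id(u)] + 1

    def ref_gap_removed(u: Block, v: Block) -> bool:
        if u.orientation != v.orientation:
            return False
        if u.orientation == 1:
            i, stop = (u.ref_end + 1) % n_ref, v.ref_start
        else:
            i, stop = (v.ref_end + 1) % n_ref, u.ref_start
        steps = 0
        while i != stop:
            if reference.genes[i].name not in removed_genes:
                return False
            i = (i + 1) % n_ref
            steps += 1
            if steps > n_ref:
                return False
        return True

    units: list[list[Block]] = []
    for b in removed_sorted:
        if units and query_adjacent(units[-1][-1], b) and ref_gap_removed(units[-1][-1], b):
            units[-1].append(b)
        else:
            units.append([b])
    # the block list is circular: the last and first chains may meet across
    # the wrap point
    if len(units) > 1:
        u_last, v_first = units[-1][-1], units[0][0]
        if (order_index[id(u_last)] == len(blocks) - 1
                and order_index[id(v_first)] == 0
                and ref_gap_removed(u_last, v_first)):
            units[-1].extend(units[0])
            units.pop(0)
    out = []
    for chain in units:
        genes = tuple(g.name for b in chain for g in b.genes)
        label = genes[0] if len(genes) == 1 else f"{genes[0]}-{genes[-1]}"
        out.append(RearrangedUnit(tuple(chain), label, genes))
    return out


def decompose_blocks(query: GeneOrder, reference: GeneOrder) -> BlockDecomposition:
    """Decompose ``query`` into conserved blocks and rearranged units
    relative to ``reference`` (restricted to the shared gene set)."""
    q, r = restrict_to_shared(query, reference)
    blocks = _maximal_blocks(q, r)
    b = len(blocks)

    if b == 1 and breakpoint_distance(q, r) == 0:
        return BlockDecomposition(
            query.genome_id, reference.genome_id,
            blocks, conserved=blocks, units=[], shared_gene_set=q.gene_set,
        )

    ref_order_of_blocks = sorted(range(b), key=lambda i: blocks[i].ref_start)
    gene_cost = [len(blk.genes) for blk in blocks]

    solutions: list[tuple[int, ...]] = []
    for k in range(b + 1):
        for removal in itertools.combinations(range(b), k):
            kept = tuple(i for i in range(b) if i not in removal)
            if k == 0 and not equals_circular(q, r):
                continue
            if _backbone_consistent(kept, blocks, ref_order_of_blocks):
                solutions.append(removal)
        if solutions:
            break

    # among minimal-cardinality removals, prefer the fewest moved segments
    # after merging, then the fewest genes moved, then lexicographic order
    def score(removal: tuple[int, ...]):
        rem = [blocks[i] for i in removal]
        rgenes = {g.name for blk in rem for g in blk.genes}
        units = _merge_units(rem, blocks, r, rgenes)
        return (len(units), sum(gene_cost[i] for i in removal), removal, units)

    _, _, removal, units = min(score(s) for s in solutions)
    removed = [blocks[i] for i in removal]
    conserved = [blocks[i] for i in range(b) if i not in removal]
    return BlockDecomposition(
        query.genome_id, reference.genome_id,
        blocks, conserved=conserved, units=units, shared_gene_set=q.gene_set,
    )


# ---------------------------------------------------------------------------
# Transcriptional polarity
# ---------------------------------------------------------------------------

@dataclass
class PolarityReport:
    runs: list[tuple[str, tuple[str, ...]]]       # (strand, gene names)
    singletons: list[str]                          # merge-breaking genes

    @property
    def n_runs(self) -> int:
        return len(self.runs)


def polarity_clusters(order: GeneOrder, include_cr: bool = False) -> PolarityReport:
    """Maximal circular runs of identical transcription strand.

    The control region is not transcribed and is skipped by default, so a
    run may span it.  A *merge-breaking singleton* is a length-1 run whose
    removal would fuse its two (same-strand) neighbours into one run.
    """
    genes = [g for g in order.genes if include_cr or g.name != "CR"]
    n = len(genes)
    if n == 0:
        return PolarityReport([], [])
    strands = [g.strand for g in genes]
    if len(set(strands)) == 1:
        return PolarityReport([(strands[0], tuple(g.name for g in genes))], [])

    # cut the circle at a strand change to linearize cleanly
    start = next(i for i in range(n) if strands[i] != strands[i - 1])
    rotated = genes[start:] + genes[:start]
    runs: list[list[Gene]] = []
    for g in rotated:
        if runs and runs[-1][-1].strand == g.strand:
            runs[-1].append(g)
        else:
            runs.append([g])
    out_runs = [(run[0].strand, tuple(g.name for g in run)) for run in runs]
    singletons = [run[1][0] for run in out_runs if len(run[1]) == 1] \
        if len(out_runs) >= 2 else []
    return PolarityReport(out_runs, singletons)


def linear_diagram(order: GeneOrder) -> str:
    """One-line linearized diagram: genes in order, minority strand marked
    with a leading ``-`` (the text analogue of an underlined label)."""
    c = canonicalize(order)
    return " ".join(str(g) for g in c.genes)


__all__ = [
    "Block", "BlockDecomposition", "ComparisonError", "PolarityReport",
    "RearrangedUnit", "adjacency_set", "breakpoint_distance",
    "decompose_blocks", "equals_circular", "linear_diagram",
    "polarity_clusters", "restrict_to_shared",
]
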