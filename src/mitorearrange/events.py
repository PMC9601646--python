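"""Duplication/loss rearrangement operators and scenarios.

Mitochondrial gene orders evolve mainly through two duplication/loss
mechanisms:

* **TDRL** (tandem duplication — random loss): a contiguous segment is
  duplicated in tandem, then one copy of each duplicated gene is lost.
  The retained copies induce a new order; no gene changes strand.
* **TDNL** (duplication — nonrandom loss): the whole genome duplicates
  into a circular dimer and one copy of each gene is lost *nonrandomly*,
  typically according to its transcriptional orientation, producing
  polarity-sorted gene clusters.

An :class:`Event` is one primitive operation; a :class:`Scenario` is an
ordered event list between two named orders.  ``tdrl`` and
``dimerize_nrl`` compound kinds bundle a duplication with its loss so a
mechanistic step counts as one event.  An ``inversion`` event is included
as well: duplication/loss alone can never change a gene's strand, so
strand differences between taxa require it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .order import Gene, GeneOrder, equals_circular
from .comparison import BlockDecomposition, decompose_blocks


class EventError(ValueError):
    pass


class ScenarioError(ValueError):
    def __init__(self, message: str, step: int | None = None):
        self.step = step
        super().__init__(message if step is None else f"step {step}: {message}")


# ---------------------------------------------------------------------------
# Duplication intermediates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DuplicatedOrder:
    """A circle holding duplicated genes, each entry tagged with its copy.

    Produced by :func:`dimerize` (every gene twice) or
    :func:`tandem_duplicate` (segment genes twice); consumed by the loss
    operators.  Not a valid scenario endpoint.
    """

    genome_id: str
    entries: tuple[tuple[Gene, int], ...]   # (gene, copy 1|2)

    def copies_of(self, name: str) -> list[int]:
        return [c for g, c in self.entries if g.name == name]

    @property
    def duplicated_genes(self) -> frozenset[str]:
        return frozenset(g.name for g, c in self.entries if c == 2)

    def __len__(self) -> int:
        return len(self.entries)


def dimerize(order: GeneOrder) -> DuplicatedOrder:
    """Arrange two tandem copies of the monomer around one circle."""
    entries = tuple((g, 1) for g in order.genes) + tuple((g, 2) for g in order.genes)
    return DuplicatedOrder(order.genome_id, entries)


def nonrandom_loss(dimer: DuplicatedOrder, keep_rule: Mapping[str, int]) -> GeneOrder:
    """Retain one copy of each gene according to ``keep_rule``.

    ``keep_rule`` maps every gene name to the copy (1 or 2) retained.  A
    gene with no retained copy, or with an invalid copy value, is an
    error naming the gene.
    """
    names = {g.name for g, _ in dimer.entries}
    missing = sorted(n for n in names if n not in keep_rule)
    if missing:
        raise EventError("both copies lost: " + ", ".join(missing))
    bad = sorted(n for n in names if keep_rule[n] not in (1, 2))
    if bad:
        raise EventError("keep rule must select copy 1 or 2 for: " + ", ".join(bad))
    for n in names:
        if sorted(dimer.copies_of(n)) != [1, 2]:
            raise EventError(f"dimer does not hold exactly two copies of {n}")
    kept = [g for g, c in dimer.entries if keep_rule[g.name] == c]
    return GeneOrder(dimer.genome_id, kept)


def keep_rule_from_polarity(order: GeneOrder,
                            minority_to_copy2: bool = True,
                            exceptions: Mapping[str, int] | None = None) -> dict[str, int]:
    """Build a nonrandom-loss keep rule from transcriptional orientation.

    Majority-strand genes keep copy 1 and minority-strand genes copy 2 (or
    the reverse), which sorts the monomer into two polarity clusters —
    the classic TDNL outcome.  ``exceptions`` overrides individual genes.
    """
    rule = {}
    for g in order.genes:
        minority = g.strand == "-"
        rule[g.name] = (2 if minority else 1) if minority_to_copy2 else (1 if minority else 2)
    if exceptions:
        rule.update(exceptions)
    return rule


def tandem_duplicate(order: GeneOrder, segment: Sequence[str]) -> DuplicatedOrder:
    """Duplicate the contiguous arc from ``segment[0]`` to ``segment[-1]``
    (inclusive, walking forward) in place."""
    start, end = segment[0], segment[-1]
    n = len(order)
    i = order.index_of(start)
    arc = []
    while True:
        arc.append(order.genes[i])
        if order.genes[i].name == end:
            break
        i = (i + 1) % n
        if len(arc) > n:
            raise EventError(f"segment {start!r}..{end!r} not found")
    # circle order: arc copy 1, arc copy 2, then the untouched remainder
    rest = []
    if len(arc) < n:
        i = (order.index_of(end) + 1) % n
        while order.genes[i].name != start:
            rest.append((order.genes[i], 1))
            i = (i + 1) % n
    entries = [(g, 1) for g in arc] + [(g, 2) for g in arc] + rest
    return DuplicatedOrder(order.genome_id, tuple(entries))


def random_loss(dup: DuplicatedOrder, keep_choices: Mapping[str, int]) -> GeneOrder:
    """Lose one copy of each duplicated gene; ``keep_choices`` maps each
    duplicated gene to the retained copy (1 or 2)."""
    duplicated = dup.duplicated_genes
    missing = sorted(n for n in duplicated if n not in keep_choices)
    if missing:
        raise EventError("keep choice missing for: " + ", ".join(missing))
    kept = []
    for g, c in dup.entries:
        if g.name in duplicated:
            if keep_choices[g.name] == c:
                kept.append(g)
        else:
            kept.append(g)
    return GeneOrder(dup.genome_id, kept)


def invert(order: GeneOrder, segment: Sequence[str]) -> GeneOrder:
    """Reverse the arc from ``segment[0]`` to ``segment[-1]`` and flip its
    strands."""
    start, end = segment[0], segment[-1]
    n = len(order)
    i = order.index_of(start)
    arc_idx = []
    while True:
        arc_idx.append(i)
        if order.genes[i].name == end:
            break
        i = (i + 1) % n
        if len(arc_idx) > n:
            raise EventError(f"segment {start!r}..{end!r} not found")
    flipped = [order.genes[i].flipped() for i in reversed(arc_idx)]
    genes = list(order.genes)
    for k, i in enumerate(arc_idx):
        genes[i] = flipped[k]
    return GeneOrder(order.genome_id, genes)


# ---------------------------------------------------------------------------
# Events and scenarios
# ---------------------------------------------------------------------------

EVENT_KINDS = (
    "dimerize", "nonrandom_loss", "tandem_duplicate", "random_loss",
    "inversion", "tdrl", "dimerize_nrl",
)


@dataclass(frozen=True)
class Event:
    kind: str
    params: tuple = ()   # hashable params, see to_dict

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise EventError(f"unknown event kind {self.kind!r}")

    # params layout per kind:
    #   dimerize:          ()
    #   nonrandom_loss:    (sorted (gene, copy) pairs,)
    #   tandem_duplicate:  (start_gene, end_gene)
    #   random_loss:       (sorted (gene, copy) pairs,)
    #   inversion:         (start_gene, end_gene)
    #   tdrl:              (start_gene, end_gene, sorted (gene, copy) pairs)
    #   dimerize_nrl:      (sorted (gene, copy) pairs,)

    @staticmethod
    def make(kind: str, *, segment: Sequence[str] | None = None,
             keep: Mapping[str, int] | None = None) -> "Event":
        keep_t = tuple(sorted(keep.items())) if keep is not None else None
        if kind == "dimerize":
            return Event(kind)
        if kind in ("nonrandom_loss", "random_loss", "dimerize_nrl"):
            if keep_t is None:
                raise EventError(f"{kind} requires a keep map")
            return Event(kind, (keep_t,))
        if kind == "inversion" or kind == "tandem_duplicate":
            if not segment:
                raise EventError(f"{kind} requires a segment")
            return Event(kind, (segment[0], segment[-1]))
        if kind == "tdrl":
            if not segment or keep_t is None:
                raise EventError("tdrl requires a segment and a keep map")
            return Event(kind, (segment[0], segment[-1], keep_t))
        raise EventError(f"unknown event kind {kind!r}")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind}
        if self.kind in ("tandem_duplicate", "inversion"):
            d["segment"] = list(self.params)
        elif self.kind in ("nonrandom_loss", "random_loss", "dimerize_nrl"):
            d["keep"] = dict(self.params[0])
        elif self.kind == "tdrl":
            d["segment"] = [self.params[0], self.params[1]]
            d["keep"] = dict(self.params[2])
        return d

    @staticmethod
    def from_dict(d: Mapping) -> "Event":
        return Event.make(d["kind"], segment=d.get("segment"), keep=d.get("keep"))


@dataclass
class Scenario:
    start_id: str
    target_id: str
    events: list[Event] = field(default_factory=list)
    description: str = ""

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(
            {"start_id": self.start_id, "target_id": self.target_id,
             "description": self.description,
             "events": [e.to_dict() for e in self.events]},
            indent=indent,
        )

    @staticmethod
    def from_json(text: str) -> "Scenario":
        obj = json.loads(text)
        return Scenario(
            obj["start_id"], obj["target_id"],
            [Event.from_dict(d) for d in obj["events"]],
            obj.get("description", ""),
        )


def apply_event(state: GeneOrder | DuplicatedOrder, event: Event):
    """Apply one event, enforcing the state type it requires."""
    k = event.kind
    if k == "dimerize":
        _need_order(state, k)
        return dimerize(state)
    if k == "nonrandom_loss":
        if not isinstance(state, DuplicatedOrder):
            raise EventError("nonrandom_loss requires a dimerized order")
        return nonrandom_loss(state, dict(event.params[0]))
    if k == "tandem_duplicate":
        _need_order(state, k)
        return tandem_duplicate(state, event.params)
    if k == "random_loss":
        if not isinstance(state, DuplicatedOrder):
            raise EventError("random_loss requires a duplicated order")
        return random_loss(state, dict(event.params[0]))
    if k == "inversion":
        _need_order(state, k)
        return invert(state, event.params)
    if k == "tdrl":
        _need_order(state, k)
        dup = tandem_duplicate(state, (event.params[0], event.params[1]))
        return random_loss(dup, dict(event.params[2]))
    if k == "dimerize_nrl":
        _need_order(state, k)
        return nonrandom_loss(dimerize(state), dict(event.params[0]))
    raise EventError(f"unknown event kind {k!r}")


def _need_order(state, kind):
    if not isinstance(state, GeneOrder):
        raise EventError(f"{kind} requires a plain gene order, not a duplication intermediate")


def apply_scenario(start: GeneOrder, scenario: Scenario,
                   trace: list | None = None) -> GeneOrder:
    """Apply events left to right; errors carry the failing step index."""
    state: GeneOrder | DuplicatedOrder = start
    for i, event in enumerate(scenario.events):
        try:
            state = apply_event(state, event)
        except EventError as exc:
            raise ScenarioError(str(exc), step=i) from exc
        if trace is not None:
            trace.append(state)
    if isinstance(state, DuplicatedOrder):
        raise ScenarioError("scenario ends on a duplication intermediate",
                            step=len(scenario.events) - 1)
    return state


@dataclass
class VerificationReport:
    ok: bool
    result: GeneOrder | None
    failed_step: int | None = None
    error: str | None = None
    diff: BlockDecomposition | None = None

    def __bool__(self) -> bool:
        return self.ok


def verify_scenario(start: GeneOrder, scenario: Scenario,
                    target: GeneOrder) -> VerificationReport:
    """Replay ``scenario`` from ``start`` and compare the endpoint with
    ``target``; on mismatch the report carries a block-level diff."""
    try:
        result = apply_scenario(start, scenario)
    except ScenarioError as exc:
        return VerificationReport(False, None, failed_step=exc.step, error=str(exc))
    if equals_circular(result, target):
        return VerificationReport(True, result)
    return VerificationReport(False, result,
                              diff=decompose_blocks(result, target))
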