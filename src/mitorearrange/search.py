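"""Bounded exhaustive search for minimal duplication/loss scenarios.

A breadth-first enumeration over gene orders modulo rotation/reflection
(circular genomes have no origin, so states are compared by canonical
form).  Each search step is one mechanistic event: a ``tdrl`` (tandem
duplication + random loss of a segment), a ``dimerize_nrl`` (whole-genome
duplication + one-copy-per-gene loss), or an ``inversion``.  The search
space is exponential in gene count, so hard guard rails keep it at toy
scale; full-size scenarios are checked by replay, not search.
"""

from __future__ import annotations

import itertools
from typing import Iterable, Iterator, Sequence

from .events import Event, Scenario, apply_event
from .order import Gene, GeneOrder, canonicalize, equals_circular
from .vocab import MAJORITY, MINORITY, VOCABULARY


class SearchError(ValueError):
    pass


DEFAULT_OPERATORS = ("tdrl",)
_GUARD_GENES = 10
_GUARD_EVENTS = 3


def toy_order(signed: Sequence[int], genome_id: str = "toy") -> GeneOrder:
    """Build a small order from signed integers: ``i`` maps to the i-th
    vocabulary gene, negative for the minority strand.  ``toy_order([1, -3, 2])``
    is a 3-gene circle."""
    genes = []
    for s in signed:
        if s == 0:
            raise SearchError("signed indices are 1-based; 0 is invalid")
        genes.append(Gene(VOCABULARY[abs(s) - 1],
                          MINORITY if s < 0 else MAJORITY))
    return GeneOrder(genome_id, genes)


def _canonical_key(order: GeneOrder) -> tuple:
    return tuple((g.name, g.strand) for g in canonicalize(order).genes)


def _segments(order: GeneOrder, min_len: int, max_len: int) -> Iterator[tuple[str, str]]:
    n = len(order)
    names = order.gene_names
    starts = sorted(range(n), key=lambda i: names[i])  # deterministic ordering
    for i in starts:
        for m in range(min_len, max_len + 1):
            yield names[i], names[(i + m - 1) % n]


def successor_events(order: GeneOrder,
                     operators: Iterable[str] = DEFAULT_OPERATORS) -> Iterator[Event]:
    """Enumerate candidate events in a deterministic order."""
    n = len(order)
    names = order.gene_names
    for op in operators:
        if op == "tdrl":
            pos = {g: i for i, g in enumerate(names)}
            for start, end in _segments(order, 2, n):
                m = (pos[end] - pos[start]) % n + 1
                seg = [names[(pos[start] + j) % n] for j in range(m)]
                for mask in range(1, 2 ** m - 1):   # all-copy-1/2 are identities
                    keep = {g: 1 + ((mask >> j) & 1) for j, g in enumerate(seg)}
                    yield Event.make("tdrl", segment=[start, end], keep=keep)
        elif op == "inversion":
            for start, end in _segments(order, 1, n - 1):
                yield Event.make("inversion", segment=[start, end])
        elif op == "dimerize_nrl":
            ordered = sorted(names)
            for mask in range(1, 2 ** n - 1):   # all-copy-1/2 are identities
                keep = {g: 1 + ((mask >> j) & 1) for j, g in enumerate(ordered)}
                yield Event.make("dimerize_nrl", keep=keep)
        else:
            raise SearchError(f"unknown operator {op!r}; expected "
                              "tdrl, inversion, dimerize_nrl")


def _check_guards(n: int, max_events: int, force: bool):
    if not force and (n > _GUARD_GENES or max_events > _GUARD_EVENTS):
        raise SearchError(
            f"search limited to {_GUARD_GENES} genes and {_GUARD_EVENTS} events "
            f"(got n={n}, max_events={max_events}); restrict the problem or "
            "pass force=True"
        )


def search(start: GeneOrder, target: GeneOrder,
           operators: Iterable[str] = DEFAULT_OPERATORS,
           max_events: int = 2, all_minimal: bool = True,
           force: bool = False) -> list[Scenario]:
    """All (or the first) minimal scenarios from ``start`` to ``target``.

    Breadth-first over canonical forms; returns scenarios of the minimal
    length ``<= max_events`` reaching ``target``, deduplicated by their
    intermediate-order traces, or an empty list if the target is
    unreachable within the bound.  Every returned scenario replays from
    ``start`` to an order equal to ``target``.
    """
    if start.gene_set != target.gene_set:
        raise SearchError("start and target must share one gene set; "
                          "restrict to shared genes first")
    operators = tuple(operators)
    _check_guards(len(start), max_events, force)

    target_key = _canonical_key(target)
    start_key = _canonical_key(start)
    concrete = {start_key: start}
    depth = {start_key: 0}
    parents: dict[tuple, list[tuple[tuple, Event]]] = {start_key: []}
    frontier = [start_key]
    found_depth = None
    if start_key == target_key:
        return [Scenario(start.genome_id, target.genome_id, [],
                         "start equals target")]

    for d in range(1, max_events + 1):
        next_frontier: list[tuple] = []
        for key in frontier:
            state = concrete[key]
            for event in successor_events(state, operators):
                child = apply_event(state, event)
                ck = _canonical_key(child)
                if ck not in depth:
                    depth[ck] = d
                    concrete[ck] = child
                    parents[ck] = [(key, event)]
                    next_frontier.append(ck)
                elif depth[ck] == d:
                    # another minimal-depth route; keep one event per parent
                    if all(p != key for p, _ in parents[ck]):
                        parents[ck].append((key, event))
                if ck == target_key and found_depth is None:
                    found_depth = d
                    if not all_minimal:
                        break
            if found_depth is not None and not all_minimal:
                break
        if found_depth is not None:
            break
        frontier = next_frontier

    if found_depth is None:
        return []

    # reconstruct all minimal event paths
    paths: list[list[Event]] = []

    def backtrack(key: tuple, suffix: list[Event]):
        if depth[key] == 0:
            paths.append(list(suffix))
            return
        for pkey, event in parents[key]:
            if depth[pkey] == depth[key] - 1:
                backtrack(pkey, [event] + suffix)

    backtrack(target_key, [])
    scenarios = []
    seen_traces = set()
    for events in paths:
        scen = Scenario(start.genome_id, target.genome_id, events,
                        f"minimal scenario ({len(events)} event(s))")
        trace: list = []
        try:
            from .events import apply_scenario
            result = apply_scenario(start, scen, trace=trace)
        except Exception:
            continue
        if not equals_circular(result, target):
            continue
        sig = tuple(_canonical_key(t) for t in trace if isinstance(t, GeneOrder))
        if sig in seen_traces:
            continue
        seen_traces.add(sig)
        scenarios.append(scen)
        if not all_minimal:
            break
    return scenarios


def reachability_census(n_genes: int,
                        operators: Iterable[str] = DEFAULT_OPERATORS,
                        depth: int = 1) -> list[int]:
    """Distinct orders (modulo rotation/reflection) reachable from the
    identity order within each depth; index d gives the count at depth
    ``<= d``.  Exact, deterministic, and monotone by construction."""
    if n_genes > 6 or depth > 2:
        raise SearchError("census limited to n_genes <= 6 and depth <= 2")
    start = toy_order(list(range(1, n_genes + 1)), "census")
    seen = {_canonical_key(start)}
    counts = [1]
    frontier = [start]
    for _ in range(depth):
        nxt = []
        for state in frontier:
            for event in successor_events(state, tuple(operators)):
                child = apply_event(state, event)
                ck = _canonical_key(child)
                if ck not in seen:
                    seen.add(ck)
                    nxt.append(child)
        counts.append(len(seen))
        frontier = nxt
    return counts
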