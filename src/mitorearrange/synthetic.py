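"""Synthetic gene orders, sequences, and annotated records.

Everything here is a pure function of its inputs and a seed, so every
other module can be tested without downloads:

* :func:`evolve` applies a known number of sampled duplication/loss
  events to a starting order and returns both the result and the true
  scenario, grounding search-recovery tests.
* :func:`random_sequence` draws i.i.d. bases with controlled A+T
  fraction and AT/GC skews; the defaults mirror a typical chilopod
  mitogenome (A+T 69.5%, AT skew 0.12, GC skew -0.33, 15,279 bp).
* :func:`synthetic_record` builds a miniature fully annotated circular
  mitogenome whose per-gene properties (codon structure, tRNA lengths,
  engineered overlaps) are known by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import Event, Scenario, apply_event, apply_scenario
from .order import GeneOrder
from .records import FeatureSpan, MitogenomeRecord, reverse_complement
from .references import ancestral_order
from .vocab import MINORITY, category_of


class SyntheticError(ValueError):
    pass


DEFAULT_OPERATOR_WEIGHTS = {"tdrl": 0.5, "dimerize_nrl": 0.25, "inversion": 0.25}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions."""

    seed: int
    n_events: int = 2
    operator_weights: dict = field(
        default_factory=lambda: dict(DEFAULT_OPERATOR_WEIGHTS))
    at_fraction: float = 0.695
    at_skew: float = 0.12
    gc_skew: float = -0.33
    length: int = 15_279

    def __post_init__(self):
        if self.seed is None:
            raise SyntheticError("seed is mandatory")
        if any(w < 0 for w in self.operator_weights.values()) \
                or not any(self.operator_weights.values()):
            raise SyntheticError("operator weights must be nonnegative, not all zero")
        if not (0 < self.at_fraction < 1):
            raise SyntheticError("at_fraction must lie in (0, 1)")
        for name in ("at_skew", "gc_skew"):
            if not (-1 < getattr(self, name) < 1):
                raise SyntheticError(f"{name} must lie in (-1, 1)")


def base_probabilities(config: SyntheticConfig) -> dict[str, float]:
    """P(A), P(C), P(G), P(T) implied by (at_fraction, at_skew, gc_skew)."""
    p, q, r = config.at_fraction, config.at_skew, config.gc_skew
    probs = {
        "A": p * (1 + q) / 2,
        "T": p * (1 - q) / 2,
        "G": (1 - p) * (1 + r) / 2,
        "C": (1 - p) * (1 - r) / 2,
    }
    if any(not (0 <= v <= 1) for v in probs.values()):
        raise SyntheticError(f"composition targets imply invalid probabilities: {probs}")
    return probs


def random_sequence(config: SyntheticConfig, length: int | None = None) -> str:
    """An i.i.d. nucleotide sequence with the configured composition."""
    L = config.length if length is None else length
    if L <= 0:
        raise SyntheticError("sequence length must be positive")
    probs = base_probabilities(config)
    rng = np.random.default_rng(config.seed)
    bases = rng.choice(np.array(list("ACGT")), size=L,
                       p=[probs["A"], probs["C"], probs["G"], probs["T"]])
    return "".join(bases)


# ---------------------------------------------------------------------------
# Order evolution
# ---------------------------------------------------------------------------

def _sample_event(order: GeneOrder, rng: np.random.Generator,
                  weights: dict[str, float]) -> Event:
    kinds = sorted(weights)
    w = np.array([weights[k] for k in kinds], dtype=float)
    kind = kinds[rng.choice(len(kinds), p=w / w.sum())]
    names = order.gene_names
    n = len(names)
    if kind == "tdrl":
        i = int(rng.integers(n))
        m = int(rng.integers(2, n + 1))
        seg = [names[(i + j) % n] for j in range(m)]
        keep = {g: int(rng.integers(1, 3)) for g in seg}
        return Event.make("tdrl", segment=[seg[0], seg[-1]], keep=keep)
    if kind == "dimerize_nrl":
        keep = {g: int(rng.integers(1, 3)) for g in names}
        return Event.make("dimerize_nrl", keep=keep)
    if kind == "inversion":
        i = int(rng.integers(n))
        m = int(rng.integers(1, n))
        seg = [names[i], names[(i + m - 1) % n]]
        return Event.make("inversion", segment=seg)
    raise SyntheticError(f"unknown operator {kind!r}")


def evolve(start: GeneOrder, config: SyntheticConfig,
           max_retries: int = 10) -> tuple[GeneOrder, Scenario]:
    """Apply ``config.n_events`` sampled events to ``start``.

    Returns the final order and the true scenario; replaying the scenario
    from ``start`` reproduces the returned order exactly.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    state = start
    events: list[Event] = []
    for _ in range(config.n_events):
        for attempt in range(max_retries):
            event = _sample_event(state, rng, config.operator_weights)
            try:
                state = apply_event(state, event)
            except Exception:
                continue
            events.append(event)
            break
        else:
            raise SyntheticError("no valid event parameters found after retries")
    scenario = Scenario(start.genome_id, f"{start.genome_id}_evolved",
                        events, f"synthetic evolution, {config.n_events} event(s)")
    return state.with_id(scenario.target_id), scenario


# ---------------------------------------------------------------------------
# Annotated synthetic records
# ---------------------------------------------------------------------------

#: gene-length plan for the miniature record (bp); PCG lengths of
#: remainder 1 or 2 mod 3 model truncated stop codons
_PCG_LEN = 150
_TRUNCATED = {"nad2": 151, "cox3": 152}      # stop "T" and "TA"
_TRNA_LEN = {"trnS1": 52, "trnW": 79}        # engineered extremes; rest 62
_RRNA_LEN = {"rrnS": 120, "rrnL": 180}
_CR_LEN = 100
#: engineered negative gaps (overlaps) after these genes
_OVERLAP_AFTER = {"trnA": -2, "trnD": -1, "trnH": -3}

_STOPLESS_CODONS = [a + b + c
                    for a in "TCAG" for b in "TCAG" for c in "TCAG"
                    if a + b + c not in ("TAA", "TAG", "TGA")]


def _gene_length(name: str) -> int:
    cat = category_of(name)
    if cat == "PCG":
        return _TRUNCATED.get(name, _PCG_LEN)
    if cat == "tRNA":
        return _TRNA_LEN.get(name, 62)
    if cat == "rRNA":
        return _RRNA_LEN[name]
    return _CR_LEN


def _coding_sequence(name: str, length: int, rng: np.random.Generator) -> str:
    """ATG start, internal stop-free codons, TAA or truncated stop."""
    rem = length % 3
    n_codons = length // 3
    body = "".join(rng.choice(_STOPLESS_CODONS) for _ in range(n_codons - 2))
    if rem == 0:
        return "ATG" + body + "TAA"
    middle = str(rng.choice(_STOPLESS_CODONS))
    return "ATG" + body + middle + ("T" if rem == 1 else "TA")


def synthetic_record(seed: int = 0, genome_id: str = "synthetic_mito",
                     order: GeneOrder | None = None,
                     overlaps: dict[str, int] | None = None) -> MitogenomeRecord:
    """A miniature, fully annotated circular mitogenome.

    All 37 genes + CR laid around the circle in ``order`` (ancestral by
    default) with known lengths, two PCGs carrying truncated stop codons,
    engineered tRNA length extremes (52 bp trnS1, 79 bp trnW), and three
    intergenic overlaps.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    order = order or ancestral_order().with_id(genome_id)
    overlaps = _OVERLAP_AFTER if overlaps is None else overlaps

    spans: list[FeatureSpan] = []
    cur = 0
    for gene in order.genes:
        length = _gene_length(gene.name)
        spans.append(FeatureSpan(gene.name, cur, cur + length, gene.strand))
        cur = cur + length + overlaps.get(gene.name, 0)
    L = cur
    seq = np.array(list("ACGT"))[rng.integers(0, 4, size=L)]
    genome = list("".join(seq))
    # write PCG coding content last so overlaps never corrupt codon structure
    for span in sorted(spans, key=lambda s: category_of(s.gene) == "PCG"):
        if category_of(span.gene) == "PCG":
            coding = _coding_sequence(span.gene, span.length, rng)
            forward = (reverse_complement(coding)
                       if span.strand == MINORITY else coding)
            genome[span.start:span.end] = list(forward)
    return MitogenomeRecord(genome_id, "".join(genome), spans)


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

def make_fixtures(output_dir, seed: int = 0) -> list[str]:
    """Write the full fixture set to ``output_dir``; returns the file names.

    Includes the packaged reference gene orders and scenario, a synthetic
    GenBank record with its FASTA, and three orders evolved from the
    ancestral arrangement with their truth scenarios.  Byte-identical for
    a given seed.
    """
    from pathlib import Path

    from .order import serialize_gene_order_table
    from .records import write_genbank_record
    from .references import load_reference_orders, marmoratus_scenario

    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise SyntheticError(f"cannot write to {output_dir}: {exc}") from exc

    written = []

    def emit(name: str, text: str):
        (out / name).write_text(text)
        written.append(name)

    refs = load_reference_orders()
    emit("gene_orders.tsv", serialize_gene_order_table(refs.values()))
    emit("scenario_m_marmoratus.json", marmoratus_scenario().to_json() + "\n")

    record = synthetic_record(seed=seed)
    emit("synthetic_mito.gb", write_genbank_record(record))
    emit("synthetic_mito.fasta",
         f">{record.genome_id}\n" + "\n".join(
             record.sequence[i:i + 70] for i in range(0, len(record.sequence), 70)
         ) + "\n")

    start = refs["L_polyphemus"]
    evolved = []
    truths = []
    for i in range(3):
        config = SyntheticConfig(seed=seed + i + 1, n_events=i + 1)
        final, scenario = evolve(start, config)
        final = final.with_id(f"evolved_{i + 1}")
        scenario.target_id = final.genome_id
        evolved.append(final)
        truths.append(scenario)
    emit("evolved_orders.tsv", serialize_gene_order_table(evolved))
    emit("evolved_scenarios.json",
         "[\n" + ",\n".join(s.to_json() for s in truths) + "\n]\n")
    return written
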