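"""Annotated mitogenome records: sequence + per-gene coordinate spans.

Coordinates are 0-based half-open on the forward (majority) strand.  A
feature crossing the circle's origin is stored with ``end > len(sequence)``
so that span arithmetic stays ordinary; ``wraps`` flags it.  GenBank input
(1-based inclusive, possibly a join across the origin) is converted on
parse and converted back on write, so the round-trip is exact.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .order import Gene, GeneOrder
from .vocab import MAJORITY, MINORITY, UnknownGeneError, category_of, normalize_gene_name

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class RecordError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureSpan:
    """One gene's location: 0-based half-open forward-strand span."""

    gene: str
    start: int
    end: int          # exclusive; > genome length when the span wraps
    strand: str = MAJORITY

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise RecordError(f"bad span for {self.gene}: [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def wraps(self, genome_length: int) -> bool:
        return self.end > genome_length


@dataclass
class ParseReport:
    skipped: list[tuple[str, str]] = field(default_factory=list)   # (descriptor, reason)

    @property
    def clean(self) -> bool:
        return not self.skipped


class MitogenomeRecord:
    """A gene order plus its nucleotide sequence and per-gene spans."""

    def __init__(self, genome_id: str, sequence: str,
                 features: list[FeatureSpan], circular: bool = True,
                 report: ParseReport | None = None):
        sequence = sequence.upper()
        bad = set(sequence) - set("ACGTN")
        if bad:
            raise RecordError(
                f"sequence of {genome_id!r} contains unsupported symbol(s): "
                + ", ".join(sorted(bad))
            )
        if not sequence:
            raise RecordError(f"record {genome_id!r} has no sequence")
        L = len(sequence)
        names = [f.gene for f in features]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise RecordError(f"duplicate feature(s): {', '.join(sorted(dupes))}")
        for f in features:
            if f.start >= L or f.end > 2 * L:
                raise RecordError(f"span of {f.gene} outside sequence: "
                                  f"[{f.start}, {f.end}) with length {L}")
        self.genome_id = genome_id
        self.sequence = sequence
        self.features = sorted(features, key=lambda f: f.start)
        self.circular = circular
        self.report = report or ParseReport()
        self.order = GeneOrder(
            genome_id, (Gene(f.gene, f.strand) for f in self.features), circular
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def feature(self, gene: str) -> FeatureSpan:
        for f in self.features:
            if f.gene == gene:
                return f
        raise KeyError(gene)

    def span_sequence(self, span: FeatureSpan) -> str:
        """Forward-strand sequence under a span, following the wrap."""
        L = len(self.sequence)
        if span.end <= L:
            return self.sequence[span.start:span.end]
        return self.sequence[span.start:] + self.sequence[:span.end - L]

    def gene_sequence(self, gene: str) -> str:
        """The gene's sequence in its own coding orientation (minority-strand
        genes are reverse-complemented)."""
        span = self.feature(gene)
        seq = self.span_sequence(span)
        return reverse_complement(seq) if span.strand == MINORITY else seq

    def features_by_category(self, category: str) -> list[FeatureSpan]:
        return [f for f in self.features if category_of(f.gene) == category]


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_FEATURE_TYPES = {"CDS", "tRNA", "rRNA", "D-loop", "misc_feature"}


def _feature_name(feat) -> str | None:
    for key in ("gene", "product", "note"):
        for value in feat.qualifiers.get(key, []):
            try:
                return normalize_gene_name(value)
            except UnknownGeneError:
                continue
    if feat.type == "D-loop":
        return "CR"
    return None


def _location_to_span(name: str, loc, L: int) -> FeatureSpan:
    strand = MINORITY if loc.strand == -1 else MAJORITY
    if isinstance(loc, CompoundLocation):
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        # origin-crossing join: [a, L) + [0, b)
        if (len(parts) == 2 and int(parts[1].end) == L and int(parts[0].start) == 0):
            return FeatureSpan(name, int(parts[1].start), L + int(parts[0].end), strand)
        raise RecordError(f"unsupported compound location for {name}: {loc}")
    return FeatureSpan(name, int(loc.start), int(loc.end), strand)


def parse_genbank_record(text: str) -> MitogenomeRecord:
    """Parse a GenBank flat file into a :class:`MitogenomeRecord`.

    Features with names that cannot be mapped onto the vocabulary are
    skipped and listed in ``record.report``.  The gene order is inferred
    from feature start positions around the circle.
    """
    try:
        rec = SeqIO.read(io.StringIO(text), "genbank")
    except Exception as exc:
        raise RecordError(f"not a parseable GenBank record: {exc}") from exc
    sequence = str(rec.seq)
    if not sequence or set(sequence) == {"N"}:
        raise RecordError(f"record {rec.id!r} has no ORIGIN sequence")
    report = ParseReport()
    spans: list[FeatureSpan] = []
    seen: set[str] = set()
    for feat in rec.features:
        if feat.type not in _FEATURE_TYPES:
            continue
        name = _feature_name(feat)
        descriptor = f"{feat.type}@{feat.location}"
        if name is None:
            report.skipped.append((descriptor, "unmappable gene/product name"))
            continue
        if name in seen:
            report.skipped.append((descriptor, f"duplicate annotation for {name}"))
            continue
        seen.add(name)
        spans.append(_location_to_span(name, feat.location, len(sequence)))
    return MitogenomeRecord(rec.id or rec.name, sequence, spans, report=report)


def _span_to_location(span: FeatureSpan, L: int) -> SimpleLocation | CompoundLocation:
    strand = -1 if span.strand == MINORITY else 1
    if span.end <= L:
        return SimpleLocation(span.start, span.end, strand)
    return CompoundLocation(
        [SimpleLocation(span.start, L, strand), SimpleLocation(0, span.end - L, strand)]
    )


def write_genbank_record(record: MitogenomeRecord) -> str:
    """Serialize a record to GenBank flat-file text (inverse of parse)."""
    rec = SeqRecord(Seq(record.sequence), id=record.genome_id,
                    name=record.genome_id[:16], description="mitochondrion")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    rec.annotations["date"] = "01-JAN-2022"   # fixed: output is reproducible
    type_of = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "CR": "D-loop"}
    L = len(record.sequence)
    for span in record.features:
        feat = SeqFeature(_span_to_location(span, L),
                          type=type_of[category_of(span.gene)])
        feat.qualifiers["gene"] = [span.gene]
        rec.features.append(feat)
    out = io.StringIO()
    SeqIO.write(rec, out, "genbank")
    return out.getvalue()


def read_fasta(text: str) -> dict[str, str]:
    """Read FASTA text into ``{id: sequence}`` (uppercased)."""
    out = {}
    try:
        for rec in SeqIO.parse(io.StringIO(text), "fasta"):
            out[rec.id] = str(rec.seq).upper()
    except ValueError as exc:
        raise RecordError(f"not parseable FASTA: {exc}") from exc
    if not out:
        raise RecordError("no FASTA records found")
    return out
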