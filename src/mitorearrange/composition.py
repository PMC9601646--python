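"""Nucleotide composition, skew, and codon-usage statistics.

The strand-asymmetry statistics are the standard ones:

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed on the sequence as deposited (the majority strand), which is the
convention under which animal mitogenomes typically show positive AT skew
and negative GC skew.  ``N`` bases are excluded from every denominator.
Protein-coding statistics concatenate the 13 PCGs each read in its own
coding orientation (minority-strand genes reverse-complemented first).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .records import MitogenomeRecord, reverse_complement
from .vocab import PCGS, TRNAS


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class CompositionStats:
    """Base counts and derived statistics for one sequence (a Table-row).

    A skew whose denominator is zero (e.g. GC skew of a pure-AT sequence)
    is undefined; accessing it raises :class:`CompositionError` naming the
    degenerate quantity.
    """

    counts: dict   # A, C, G, T, other
    at_fraction: float
    at_skew_: float | None
    gc_skew_: float | None

    @property
    def at_skew(self) -> float:
        if self.at_skew_ is None:
            raise CompositionError("A+T count is zero; AT skew undefined")
        return self.at_skew_

    @property
    def gc_skew(self) -> float:
        if self.gc_skew_ is None:
            raise CompositionError("G+C count is zero; GC skew undefined")
        return self.gc_skew_

    @property
    def length(self) -> int:
        return sum(self.counts.values())

    def table_row(self) -> dict:
        """Presentation values: A+T as %, one decimal; skews, two decimals."""
        return {
            "A+T (%)": round(100 * self.at_fraction, 1),
            "AT skew": round(self.at_skew, 2),
            "GC skew": round(self.gc_skew, 2),
        }


def composition(sequence: str) -> CompositionStats:
    """Composition statistics of a nucleotide sequence over {A,C,G,T,N}."""
    if not sequence:
        raise CompositionError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise CompositionError(
            "unsupported symbol(s) in sequence: " + ", ".join(sorted(bad))
        )
    c = Counter(seq)
    a, t, g, cc = c["A"], c["T"], c["G"], c["C"]
    if a + cc + g + t == 0:
        raise CompositionError("sequence holds no unambiguous bases")
    counts = {"A": a, "C": cc, "G": g, "T": t, "other": c["N"]}
    return CompositionStats(
        counts=counts,
        at_fraction=(a + t) / (a + cc + g + t),
        at_skew_=(a - t) / (a + t) if a + t else None,
        gc_skew_=(g - cc) / (g + cc) if g + cc else None,
    )


def pcg_composition(record: MitogenomeRecord) -> CompositionStats:
    """Composition of the concatenated protein-coding genes, each in its
    coding orientation."""
    present = [f.gene for f in record.features_by_category("PCG")]
    if not present:
        missing = ", ".join(PCGS)
        raise CompositionError(f"record has no PCG features; expected some of: {missing}")
    concat = "".join(record.gene_sequence(g) for g in present)
    return composition(concat)


# ---------------------------------------------------------------------------
# Codon usage and start/stop codons
# ---------------------------------------------------------------------------

@dataclass
class CodonUsageTable:
    counts: pd.Series        # index: 64 codons; values: counts
    frequencies: pd.Series   # counts / total

    @property
    def total(self) -> int:
        return int(self.counts.sum())


_BASES = "TCAG"
ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]


def codon_usage(record: MitogenomeRecord) -> tuple[CodonUsageTable, pd.DataFrame]:
    """Codon usage over all PCGs plus a per-gene start/stop codon report.

    A coding length with remainder 1 or 2 modulo 3 is read as a truncated
    stop codon ("T" or "TA"), completed to TAA by polyadenylation of the
    transcript; such trailing bases are excluded from the usage counts.
    """
    pcgs = record.features_by_category("PCG")
    if not pcgs:
        raise CompositionError("record has no PCG features")
    counts = Counter()
    rows = []
    for f in pcgs:
        seq = record.gene_sequence(f.gene)
        if len(seq) < 6:
            raise CompositionError(f"PCG {f.gene} shorter than 6 nt")
        rem = len(seq) % 3
        body = seq[:len(seq) - rem] if rem else seq
        codons = [body[i:i + 3] for i in range(0, len(body), 3)]
        counts.update(codons)
        stop = seq[-rem:] if rem else codons[-1]
        rows.append({"gene": f.gene, "start_codon": codons[0], "stop_codon": stop,
                     "incomplete_stop": rem != 0, "length_nt": len(seq)})
    series = pd.Series({c: counts.get(c, 0) for c in ALL_CODONS}, name="count")
    table = CodonUsageTable(series, series / series.sum())
    return table, pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# tRNA lengths and intergenic overlaps
# ---------------------------------------------------------------------------

def trna_length_table(record: MitogenomeRecord) -> pd.DataFrame:
    """Lengths of annotated tRNAs, with absent tRNAs flagged.

    The returned frame has one row per canonical tRNA name; ``length_bp``
    is NA for missing ones.  ``df.attrs`` carries min/max over present rows.
    """
    lengths = {f.gene: f.length for f in record.features_by_category("tRNA")}
    rows = [{"trna": name,
             "length_bp": lengths.get(name),
             "present": name in lengths}
            for name in TRNAS]
    df = pd.DataFrame(rows).set_index("trna")
    present = df[df["present"]]
    if len(present):
        shortest = present["length_bp"].astype(int).idxmin()
        longest = present["length_bp"].astype(int).idxmax()
        df.attrs["min"] = (shortest, int(present.loc[shortest, "length_bp"]))
        df.attrs["max"] = (longest, int(present.loc[longest, "length_bp"]))
    return df


def overlap_report(record: MitogenomeRecord) -> pd.DataFrame:
    """Gap length between each pair of adjacent features around the circle.

    Negative gaps are overlaps; abutting half-open spans (end == next
    start) have gap 0 and do not count.  The wrap boundary is an ordinary
    adjacency.  ``df.attrs['overlap_count']`` and ``['overlap_fraction']``
    summarize the circle.
    """
    feats = record.features
    if len(feats) < 2:
        raise CompositionError("need at least two features for an overlap report")
    L = len(record.sequence)
    rows = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        nxt_start = nxt.start + (L if (i + 1) == len(feats) else 0)
        gap = nxt_start - f.end
        rows.append({"gene": f.gene, "next_gene": nxt.gene, "gap_bp": gap,
                     "overlap": gap < 0})
    df = pd.DataFrame(rows)
    df.attrs["overlap_count"] = int(df["overlap"].sum())
    df.attrs["overlap_fraction"] = float(df["overlap"].mean())
    return df
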