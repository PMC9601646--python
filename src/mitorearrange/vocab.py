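"""Canonical gene vocabulary for animal mitochondrial genomes.

Animal mitogenomes carry 37 genes — 13 protein-coding genes (PCGs), 22
tRNAs, 2 rRNAs — plus a long noncoding control region (CR).  Deposited
records name these genes inconsistently (``COI``, ``COX1``, ``cox1`` ...),
so a fixed 38-token vocabulary plus an alias map gives deterministic
normalization.

Leucine and serine each have two tRNA isoacceptors, disambiguated the
standard way: trnL1 (CUN), trnL2 (UUR), trnS1 (AGN), trnS2 (UCN).
"""

from __future__ import annotations

MAJORITY = "+"
MINORITY = "-"
STRANDS = (MAJORITY, MINORITY)

PCGS = (
    "cox1", "cox2", "cox3", "cob",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
    "atp6", "atp8",
)

TRNAS = (
    "trnA", "trnR", "trnN", "trnD", "trnC", "trnQ", "trnE", "trnG",
    "trnH", "trnI", "trnL1", "trnL2", "trnK", "trnM", "trnF", "trnP",
    "trnS1", "trnS2", "trnT", "trnW", "trnY", "trnV",
)

RRNAS = ("rrnS", "rrnL")

CR = "CR"

#: The full 38-token vocabulary: 13 PCGs + 22 tRNAs + 2 rRNAs + CR.
VOCABULARY = PCGS + TRNAS + RRNAS + (CR,)

CATEGORY = {name: "PCG" for name in PCGS}
CATEGORY.update({name: "tRNA" for name in TRNAS})
CATEGORY.update({name: "rRNA" for name in RRNAS})
CATEGORY[CR] = "CR"

# Aliases found in deposited records and the older literature.  Keys are
# matched case-insensitively after stripping separators.  rrnS is the small
# (12S) subunit and rrnL the large (16S) subunit, the standard convention.
ALIASES = {
    "coi": "cox1", "co1": "cox1", "coxi": "cox1",
    "coii": "cox2", "co2": "cox2", "coxii": "cox2",
    "coiii": "cox3", "co3": "cox3", "coxiii": "cox3",
    "cytb": "cob", "cob": "cob", "cyb": "cob",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nad4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "atpase6": "atp6", "atpase8": "atp8",
    "12s": "rrnS", "srrna": "rrnS", "12srrna": "rrnS", "rrns": "rrnS",
    "16s": "rrnL", "lrrna": "rrnL", "16srrna": "rrnL", "rrnl": "rrnL",
    "dloop": "CR", "d-loop": "CR", "controlregion": "CR", "cr": "CR",
    "at-richregion": "CR", "atrichregion": "CR",
    # one-letter amino-acid tRNA forms, e.g. trnL(UUR) handled in normalize
    "trnl(uur)": "trnL2", "trnl(cun)": "trnL1",
    "trns(agn)": "trnS1", "trns(ucn)": "trnS2",
    "trnleu(uur)": "trnL2", "trnleu(cun)": "trnL1",
    "trnser(agn)": "trnS1", "trnser(ucn)": "trnS2",
}

_CANONICAL_LOWER = {name.lower(): name for name in VOCABULARY}

_TRNA_THREE_LETTER = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "lys": "K", "met": "M", "phe": "F", "pro": "P", "thr": "T",
    "trp": "W", "tyr": "Y", "val": "V",
}


class UnknownGeneError(ValueError):
    """Raised when a gene name cannot be mapped to the vocabulary."""

    def __init__(self, name: str):
        self.name = name
        super().__init__(
            f"unknown gene name {name!r}; valid names are: "
            + ", ".join(VOCABULARY)
        )


def normalize_gene_name(raw: str) -> str:
    """Map ``raw`` onto the canonical 38-token vocabulary.

    Case-insensitive; tolerates common aliases (``COI`` -> ``cox1``,
    ``12S`` -> ``rrnS``, ``D-loop`` -> ``CR``) and three-letter tRNA
    forms (``trnAla`` -> ``trnA``).  Raises :class:`UnknownGeneError`
    otherwise.
    """
    key = raw.strip()
    low = key.lower()
    if low in _CANONICAL_LOWER:
        return _CANONICAL_LOWER[low]
    squashed = low.replace(" ", "").replace("_", "")
    for variant in (squashed, squashed.replace("-", "")):
        if variant in ALIASES:
            return ALIASES[variant]
    if squashed.startswith("trna-"):   # e.g. tRNA-Ser(AGN), tRNA-Trp
        squashed = "trn" + squashed[5:]
        if squashed in ALIASES:
            return ALIASES[squashed]
    if squashed.startswith("trn"):
        body = squashed[3:]
        if body in _TRNA_THREE_LETTER:
            return "trn" + _TRNA_THREE_LETTER[body]
        cand = "trn" + body.upper()
        if cand in VOCABULARY:
            return cand
        if body.lower() in ("l", "s"):  # ambiguous isoacceptor
            raise UnknownGeneError(raw)
    raise UnknownGeneError(raw)


def category_of(name: str) -> str:
    """Return ``PCG``, ``tRNA``, ``rRNA`` or ``CR`` for a canonical name."""
    return CATEGORY[name]
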