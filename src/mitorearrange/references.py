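"""Packaged reference gene orders and the M. marmoratus scenario.

The package ships a gene-order table for the horseshoe crab *Limulus
polyphemus* — whose arrangement is ancestral for arthropods — and eleven
chilopod taxa, plus the inferred duplication/loss scenario deriving the
*Mecistocephalus marmoratus* arrangement from the ancestral one.

Orders constrained by the source comparisons: *S. subspinipes* is
identical to *L. polyphemus*; *S. dehaani* is the same minus trnE and
trnL2; *S. mutilans* differs from *S. subspinipes* by five rearranged
units; *M. marmoratus* is extensively rearranged with its genes clustered
by transcriptional polarity except trnS2.  Two taxa (*S. maritima*,
*S. coleoptrata*) are synthetic stand-in variants, marked as such in the
table comments.
"""

from __future__ import annotations

from importlib import resources

from .events import Scenario
from .order import GeneOrder, parse_gene_order_table

ANCESTRAL_ID = "L_polyphemus"


def _data_text(name: str) -> str:
    return resources.files("mitorearrange.data").joinpath(name).read_text("utf-8")


def load_reference_orders() -> dict[str, GeneOrder]:
    """All packaged gene orders, keyed by genome id."""
    orders = parse_gene_order_table(_data_text("gene_orders.tsv"))
    return {o.genome_id: o for o in orders}


def ancestral_order() -> GeneOrder:
    """The ancestral arthropod gene order (*L. polyphemus*)."""
    return load_reference_orders()[ANCESTRAL_ID]


def marmoratus_scenario() -> Scenario:
    """The packaged duplication/loss scenario from the ancestral order to
    *M. marmoratus*: dimerize, polarity-guided nonrandom loss (trnS2 and CR
    following the minority cluster), then TDRL translocations."""
    return Scenario.from_json(_data_text("scenario_m_marmoratus.json"))
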