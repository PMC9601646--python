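# Methods

## The gene-order model

A mitochondrial genome is modelled as a signed circular permutation over
a fixed 38-token vocabulary: 13 protein-coding genes (cox1–3, cob,
nad1–6, nad4L, atp6, atp8), 22 tRNAs (with the leucine and serine
isoacceptors disambiguated as trnL1/CUN, trnL2/UUR, trnS1/AGN,
trnS2/UCN), 2 rRNAs, and the control region (CR). Each gene carries a
strand flag: majority (`+`) or minority (`-`). Two descriptions of one
circle differ only by rotation or by reading the other strand (reverse
the list and flip every strand), so orders are compared through a
canonical form: rotate to put cox1 first on the majority strand,
reflecting first if cox1 is on the minority strand; without cox1, take
the lexicographically smallest rotation over both readings. The
canonicalization is idempotent and collapses all 2n symmetric
representations to one; circular equality is equality of canonical
forms.

Naming follows the standard convention that rrnS is the small (12S) and
rrnL the large (16S) subunit; deposited records that label them
otherwise are normalized through the alias map (COI→cox1, 12S→rrnS,
D-loop→CR, tRNA-Ser(AGN)→trnS1, ...). An order need not be complete —
completeness (all 37 genes + CR) is a checkable predicate, since real
genomes such as *S. dehaani* lack individual tRNAs.

Coordinates on annotated records are 0-based half-open on the forward
strand; a feature crossing the circle's origin is stored with
`end > genome length` so span arithmetic stays ordinary. GenBank input
(1-based inclusive, `join` across the origin) is converted on parse and
back on write; the round-trip is exact.

## Comparison

**Breakpoint distance.** Each gene contributes a head and a tail end
(tail→head in majority orientation); an adjacency is the unordered pair
of ends meeting on the circle, which makes the adjacency set invariant
under rotation and reflection. After restricting both orders to their
shared gene set, the distance is the number of adjacencies of one order
absent from the other; it is symmetric, zero iff the restricted orders
are circularly equal, and is checked in the test suite against an
independent brute-force oracle on all signed circular orders of four
genes and sampled orders of six.

**Rearranged units.** The query circle is cut at every adjacency absent
from the reference, giving maximal blocks whose internal adjacencies are
conserved (a block may be traversed in reverse orientation). The
rearranged units are then defined by minimum removal: the smallest set
of blocks whose deletion leaves the remaining blocks reading identically
(as circles, orientation included) in query and reference. Among
minimal-cardinality removals the decomposition prefers (1) the fewest
moved segments after merging, then (2) the fewest moved genes, then a
deterministic lexicographic order. Query-adjacent removed blocks are
merged into a single unit when only removed genes separate their
reference spans — this is how a unit like `nad1-CR` arises when a gene
(trnV) was extracted from the middle of a moved segment. The preference
for few segments and few genes encodes the parsimony intuition that
small tRNAs translocate readily while long conserved stretches do not.
This counting convention is the package's own; it is exercised against
the two published-scale inventories (five units for *S. mutilans* vs
*S. subspinipes*; eight for *M. marmoratus* vs the ancestral order) in
the acceptance tests. Enumeration is exponential in the number of
blocks, which is bounded by the breakpoint count (≤ 38 genes here;
the *M. marmoratus* case, 20 blocks, decomposes in about two seconds).

**Polarity clustering.** Maximal circular runs of identical strand,
skipping the control region by default (it is not transcribed, so a run
may span it). A merge-breaking singleton is a length-1 run whose removal
would fuse its neighbours; with two strand values the neighbours of any
singleton necessarily agree, so these are exactly the length-1 runs
(when more than one run exists).

## Rearrangement events

Events operate on orders or on explicit duplication intermediates
(circles of (gene, copy) entries):

* `dimerize` — two tandem copies of the monomer on one circle (76
  entries for a complete genome).
* `nonrandom_loss` — keep one copy of each gene per an explicit keep
  map; a convenience constructor derives the map from transcriptional
  orientation (majority keeps copy 1, minority copy 2), the classic
  duplication–nonrandom-loss outcome that sorts the circle into two
  polarity clusters. Losing both or neither copy of a gene is an error
  naming the gene.
* `tandem_duplicate` + `random_loss` — standard TDRL semantics: the
  retained copies induce the new order; gene content is conserved and
  no strand ever changes. The compound kinds `tdrl` and `dimerize_nrl`
  bundle duplication with loss so one mechanistic step counts as one
  event in generated and searched scenarios.
* `inversion` — reverse a segment and flip its strands. Included
  because duplication/loss alone is closed under orientation (proved
  exhaustively on four-gene orders in the tests), so strand differences
  between taxa require it.

Scenarios (ordered event lists with named endpoints) serialize to JSON
losslessly; `verify_scenario` replays and compares endpoints, reporting
the failing step index or a block-level diff on mismatch.

**The packaged *M. marmoratus* scenario** encodes the derivation of its
arrangement from the ancestral arthropod order in two phases: (1)
whole-genome duplication into a circular dimer followed by nonrandom
loss guided by transcriptional orientation, with trnS2 and the control
region following the minority cluster — which is precisely why trnS2
ends up as the lone polarity singleton; (2) seven TDRL translocations
that place individual genes and blocks (trnN, nad6–cob, nad3, trnT,
trnI, trnY, trnL1). Only the endpoints and the event semantics are
constrained by the available evidence; where several loss patterns would
yield the same endpoint the packaged file fixes one consistent reading.
Verification is endpoint equality, not intermediate-layout identity.

## Scenario search

Bounded breadth-first enumeration over canonical forms (circular
genomes have no origin, so states are deduplicated modulo
rotation/reflection). Parameter enumeration is lexicographic so output
order is deterministic; returned scenarios are deduplicated by their
full intermediate-order traces and each is re-verified by replay from
the concrete start order before being returned. Guard rails (≤ 10
genes, ≤ 3 events, overridable with `force=True`) keep the exponential
space at toy scale; the full 38-gene scenario is checked by replay, not
search. The census utility counts exactly the distinct orders reachable
per depth (≤ 6 genes, depth ≤ 2) and is tested against a second, naive
enumeration.

## Synthetic data

The generator is the package's test bed and defines its study
conditions:

* `evolve` applies a stated number of events sampled by operator weight
  (defaults: tdrl 0.5, dimerize_nrl 0.25, inversion 0.25 — the two
  duplication/loss mechanisms dominating, inversion as the documented
  extension) with uniformly sampled valid parameters, returning the
  true scenario; replay of the scenario is asserted to reproduce the
  returned order over 100 seeds.
* `random_sequence` draws i.i.d. bases with P(A)=p(1+q)/2,
  P(T)=p(1−q)/2, P(G)=(1−p)(1+r)/2, P(C)=(1−p)(1−r)/2. Defaults
  p=0.695, q=0.12, r=−0.33, L=15,279 — a typical chilopod whole-genome
  composition row. The i.i.d. model carries no codon structure, repeat
  structure, or within-genome heterogeneity, so it grounds skew/content
  estimation only; codon-usage tests use constructed coding sequences
  instead.
* `synthetic_record` builds a miniature annotated circular genome
  (~3.7 kb) with known per-gene properties: ATG starts, stop-free
  codon bodies, two engineered incomplete stops (length ≡ 1 mod 3 → `T`,
  ≡ 2 → `TA`), tRNA lengths 52–79 bp with known extremes, and three
  engineered intergenic overlaps. Passing tests on these records shows
  the statistics are computed correctly, not that any real genome has
  these values; statistics on real material should go through
  `parse_genbank_record` on a locally provided flat file.

Every output is a pure function of (inputs, seed); fixture sets are
byte-identical for a given seed.

## Numerical and presentation conventions

Skews are computed on the deposited (majority) strand as given — the
standard mitogenomics practice under which GC skew is typically
negative; the PCG row concatenates each coding sequence in its own
coding orientation (minority-strand genes reverse-complemented), the
common convention where the alternative (majority-strand projection) is
isolated behind `pcg_composition` so it could be flipped in one place.
`N` bases are excluded from all denominators; other ambiguity codes are
rejected outright. A skew whose denominator is zero (e.g. GC skew of a
pure-AT sequence) is undefined and raises on access rather than
returning a sentinel. Percentages are rounded to one decimal and skews
to two only at presentation (`table_row`); internal values keep full
precision. Intergenic gaps use half-open spans, so abutting features
have gap 0 and only strictly negative gaps count as overlaps; the
origin-wrap boundary is an ordinary adjacency.

## Reference data

The packaged table encodes the ancestral arthropod order (*L.
polyphemus*) and eleven chilopod taxa. *S. subspinipes* (identical to
the ancestor), *S. dehaani* (identical minus trnE/trnL2), *S. mutilans*
(five moved units), and *M. marmoratus* (eight moved units, polarity
sorted except trnS2) are constrained by the published comparisons;
*C. longicornis* and the Lithobiomorpha taxa are encoded as ancestral as
reported. For *S. maritima* and *S. coleoptrata* no usable arrangement
was available to encode, so the table ships clearly marked synthetic
stand-in variants (single-gene translocations of the ancestral order);
they exercise parsing and comparison only and no scientific claim
attaches to them.

## Known limitations

* The rearranged-unit convention is one defensible counting rule among
  several; unit inventories from tools with different conventions (e.g.
  common-interval methods) need not coincide block-for-block.
* Breakpoint distance is the only distance implemented; no
  inversion/DCJ distance or rearrangement-based tree inference.
* The minimum-removal decomposition enumerates block subsets and is
  exponential in the worst case; it is intended for single-genome-scale
  comparisons, not batch all-vs-all sweeps over heavily shuffled pairs.
* Scenario search is exhaustive and limited to toy sizes by design.
* The sequence generator is i.i.d.; no substitution/indel evolution and
  no tree-structured order evolution.
* Annotations are taken as given; there is no de-novo gene finding or
  tRNA secondary-structure prediction.
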