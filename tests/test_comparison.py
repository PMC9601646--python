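"""Order comparison: breakpoints, block decomposition, polarity."""

import itertools

import pytest

from mitorearrange.comparison import (
    ComparisonError,
    breakpoint_distance,
    decompose_blocks,
    polarity_clusters,
    restrict_to_shared,
)
from mitorearrange.order import Gene, GeneOrder, equals_circular
from mitorearrange.search import toy_order
from mitorearrange.synthetic import SyntheticConfig, evolve


# -- independent oracle ------------------------------------------------------

def oracle_breakpoints(a: GeneOrder, b: GeneOrder) -> int:
    """Brute-force oracle: enumerate signed adjacencies as ordered pairs,
    closing each under reverse-complement; count a-pairs absent from b."""

    def pairs(order):
        out = set()
        gs = list(order.genes)
        for i in range(len(gs)):
            x, y = gs[i], gs[(i + 1) % len(gs)]
            out.add(((x.name, x.strand), (y.name, y.strand)))
            out.add(((y.name, y.strand.translate(str.maketrans("+-", "-+"))),
                     (x.name, x.strand.translate(str.maketrans("+-", "-+")))))
        return out

    pa, pb = pairs(a), pairs(b)
    return len({p for p in pa if p not in pb}) // 2


class TestRestriction:
    def test_dehaani_equals_subspinipes_on_shared_genes(self, dehaani, subspinipes):
        pa, pb = restrict_to_shared(dehaani, subspinipes)
        assert pa.gene_set == pb.gene_set
        assert equals_circular(pa, pb)

    def test_identical_gene_sets_returned_unchanged(self, limulus, marmoratus):
        pa, pb = restrict_to_shared(marmoratus, limulus)
        assert tuple(pa.genes) == tuple(marmoratus.genes)
        assert tuple(pb.genes) == tuple(limulus.genes)

    def test_disjoint_gene_sets_error(self):
        a = GeneOrder("a", [Gene("cox1"), Gene("trnK")])
        b = GeneOrder("b", [Gene("cox2"), Gene("trnW")])
        with pytest.raises(ComparisonError, match="shared"):
            restrict_to_shared(a, b)


class TestBreakpointDistance:
    def test_self_distance_zero(self, marmoratus):
        assert breakpoint_distance(marmoratus, marmoratus) == 0

    def test_subspinipes_vs_ancestral_zero(self, subspinipes, limulus):
        assert breakpoint_distance(subspinipes, limulus) == 0

    def test_toy_transposition_matches_oracle(self):
        a, b = toy_order([1, 2, 3]), toy_order([1, 3, 2])
        assert breakpoint_distance(a, b) == oracle_breakpoints(a, b) == 3

    def test_symmetry_and_reflection_invariance(self, mutilans, subspinipes):
        d = breakpoint_distance(mutilans, subspinipes)
        assert d == breakpoint_distance(subspinipes, mutilans)
        assert d == breakpoint_distance(mutilans.reflected(), subspinipes)
        assert d == breakpoint_distance(mutilans.rotated(7), subspinipes.rotated(3))

    def test_oracle_equivalence_exhaustive_four_genes(self):
        # all signed circular orders of 4 genes (first gene pinned +) vs a
        # fixed reference: implementation must match the brute-force oracle
        ref = toy_order([1, 2, 3, 4])
        for perm in itertools.permutations([2, 3, 4]):
            for signs in itertools.product([1, -1], repeat=3):
                other = toy_order([1] + [p * s for p, s in zip(perm, signs)])
                assert breakpoint_distance(other, ref) == \
                    oracle_breakpoints(other, ref)

    def test_oracle_equivalence_sampled_six_genes(self):
        import random
        rnd = random.Random(0)
        ref = toy_order([1, 2, 3, 4, 5, 6])
        for _ in range(200):
            perm = [1, 2, 3, 4, 5, 6]
            rnd.shuffle(perm)
            signed = [p * rnd.choice([1, -1]) for p in perm]
            other = toy_order(signed)
            assert breakpoint_distance(other, ref) == oracle_breakpoints(other, ref)


class TestBlockDecomposition:
    def test_identical_orders_one_conserved_block(self, subspinipes, limulus):
        d = decompose_blocks(subspinipes, limulus)
        assert len(d.blocks) == 1
        assert d.rearranged_count == 0

    def test_mutilans_printed_units(self, mutilans, subspinipes):
        d = decompose_blocks(mutilans, subspinipes)
        assert d.rearranged_count == 5
        unit_genes = {u.genes for u in d.units}
        assert unit_genes == {
            ("trnF", "nad5", "trnH", "nad4", "nad4L"),
            ("trnP", "nad6", "cob", "trnS2"),
            ("nad1", "trnL1", "rrnL", "rrnS", "CR"),
            ("trnV",),
            ("trnQ",),
        }

    def test_marmoratus_units_include_the_eight_named(self, marmoratus, limulus):
        d = decompose_blocks(marmoratus, limulus)
        assert d.rearranged_count >= 8
        unit_genes = {u.genes for u in d.units}
        for expected in [("nad3",), ("nad6", "cob"), ("trnM", "nad2", "trnW"),
                         ("trnT",), ("trnN",), ("trnY",), ("trnL1",), ("trnI",)]:
            assert expected in unit_genes

    def test_rearranged_zero_iff_breakpoints_zero(self, refs):
        anc = refs["L_polyphemus"]
        for seed in range(8):
            final, _ = evolve(anc, SyntheticConfig(seed=seed, n_events=1))
            d = decompose_blocks(final, anc)
            assert (d.rearranged_count == 0) == \
                (breakpoint_distance(final, anc) == 0)

    def test_blocks_partition_shared_genes(self, mutilans, subspinipes):
        d = decompose_blocks(mutilans, subspinipes)
        covered = [g.name for blk in d.blocks for g in blk.genes]
        assert sorted(covered) == sorted(d.shared_gene_set)


class TestPolarity:
    def test_all_majority_is_one_run(self):
        order = toy_order([1, 2, 3, 4, 5])
        report = polarity_clusters(order)
        assert report.n_runs == 1 and not report.singletons

    def test_alternating_strands_all_runs_singletons(self):
        order = toy_order([1, -2, 3, -4])
        report = polarity_clusters(order)
        assert report.n_runs == 4
        assert len(report.singletons) == 4

    def test_marmoratus_single_merge_breaker_is_trnS2(self, marmoratus):
        report = polarity_clusters(marmoratus)
        assert report.singletons == ["trnS2"]

    def test_control_region_does_not_break_a_run(self, marmoratus):
        with_cr = polarity_clusters(marmoratus, include_cr=True)
        without = polarity_clusters(marmoratus)
        assert without.n_runs <= with_cr.n_runs
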