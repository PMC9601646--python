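"""Duplication/loss operators, scenarios, and replay verification."""

import itertools

import pytest

from mitorearrange.events import (
    Event,
    EventError,
    Scenario,
    ScenarioError,
    apply_scenario,
    dimerize,
    invert,
    keep_rule_from_polarity,
    nonrandom_loss,
    random_loss,
    tandem_duplicate,
    verify_scenario,
)
from mitorearrange.order import Gene, GeneOrder, equals_circular
from mitorearrange.search import toy_order


class TestDimerize:
    def test_doubles_length_with_block_copy_tags(self):
        order = toy_order([1, 2, 3])
        dimer = dimerize(order)
        assert len(dimer) == 6
        assert [c for _, c in dimer.entries] == [1, 1, 1, 2, 2, 2]

    def test_keep_copy_one_rule_is_identity(self, limulus):
        rule = {g.name: 1 for g in limulus.genes}
        assert equals_circular(nonrandom_loss(dimerize(limulus), rule), limulus)

    def test_dimer_of_ancestral_order_has_76_entries(self, limulus):
        assert len(dimerize(limulus)) == 76


class TestNonrandomLoss:
    def test_rule_missing_a_gene_names_it(self):
        dimer = dimerize(toy_order([1, 2, 3]))
        with pytest.raises(EventError, match="both copies lost: cox3"):
            nonrandom_loss(dimer, {"cox1": 1, "cox2": 1})

    def test_invalid_copy_value_rejected(self):
        dimer = dimerize(toy_order([1, 2]))
        with pytest.raises(EventError, match="copy 1 or 2"):
            nonrandom_loss(dimer, {"cox1": 3, "cox2": 1})

    def test_polarity_rule_sorts_strands_into_two_clusters(self):
        order = toy_order([1, -2, 3, -4, 5])
        rule = keep_rule_from_polarity(order)
        result = nonrandom_loss(dimerize(order), rule)
        strands = [g.strand for g in result.genes]
        # one strand switch at most going around the circle
        switches = sum(strands[i] != strands[i - 1] for i in range(len(strands)))
        assert switches == 2


class TestTdrl:
    def test_duplicate_all_keep_copy_one_is_identity(self):
        order = toy_order([1, 2, 3, 4])
        dup = tandem_duplicate(order, ["cox1", "cob"])
        kept = random_loss(dup, {g: 1 for g in order.gene_names})
        assert equals_circular(kept, order)

    def test_two_gene_swap_example(self):
        # duplicate (2..3) of (+1,+2,+3,+4); keep copy 1 of 3, copy 2 of 2
        order = toy_order([1, 2, 3, 4])
        dup = tandem_duplicate(order, ["cox2", "cox3"])
        result = random_loss(dup, {"cox2": 2, "cox3": 1})
        assert equals_circular(result, toy_order([1, 3, 2, 4]))

    def test_reachable_set_of_two_gene_duplication_matches_brute_force(self):
        # every keep choice of the (2..3) duplication, versus direct
        # enumeration of subsequence merges of the duplicated segment
        order = toy_order([1, 2, 3, 4])
        dup = tandem_duplicate(order, ["cox2", "cox3"])
        reached = set()
        for c2, c3 in itertools.product([1, 2], repeat=2):
            out = random_loss(dup, {"cox2": c2, "cox3": c3})
            reached.add(tuple((g.name, g.strand) for g in
                              out.rotated(out.index_of("cox1")).genes))
        brute = set()
        seg = ["cox2", "cox3"]
        for kept1 in itertools.chain.from_iterable(
                itertools.combinations(seg, r) for r in range(3)):
            kept2 = [g for g in seg if g not in kept1]
            middle = list(kept1) + kept2
            brute.add(tuple((g, "+") for g in ["cox1"] + middle + ["cob"]))
        assert reached == brute

    def test_incomplete_keep_choices_rejected(self):
        dup = tandem_duplicate(toy_order([1, 2, 3]), ["cox1", "cox2"])
        with pytest.raises(EventError, match="cox2"):
            random_loss(dup, {"cox1": 1})

    def test_strands_never_change(self):
        order = toy_order([1, -2, 3, -4, 5])
        dup = tandem_duplicate(order, ["cox2", "cob"])
        out = random_loss(dup, {"cox2": 2, "cox3": 2, "cob": 1})
        strands = {g.name: g.strand for g in out.genes}
        assert strands == {g.name: g.strand for g in order.genes}


class TestInversion:
    def test_segment_reversed_and_flipped(self):
        order = toy_order([1, 2, 3, 4])
        out = invert(order, ["cox2", "cox3"])
        assert equals_circular(out, toy_order([1, -3, -2, 4]))


class TestScenario:
    def test_empty_scenario_with_equal_endpoints_verifies(self, limulus):
        scen = Scenario("a", "a", [])
        assert verify_scenario(limulus, scen, limulus).ok

    def test_json_roundtrip_replays_to_same_order(self, limulus, marmoratus):
        from mitorearrange.references import marmoratus_scenario
        scen = marmoratus_scenario()
        again = Scenario.from_json(scen.to_json())
        assert apply_scenario(limulus, again) == apply_scenario(limulus, scen)
        assert verify_scenario(limulus, again, marmoratus).ok

    def test_wrong_target_fails_with_block_diff(self, limulus, subspinipes):
        from mitorearrange.references import marmoratus_scenario
        report = verify_scenario(limulus, marmoratus_scenario(), subspinipes)
        assert not report.ok
        assert report.diff is not None
        assert report.diff.rearranged_count > 0

    def test_invalid_event_mid_scenario_reports_step_index(self, limulus):
        events = [Event.make("dimerize"),
                  Event.make("inversion", segment=["cox1", "cox2"])]
        with pytest.raises(ScenarioError, match="step 1"):
            apply_scenario(limulus, Scenario("a", "b", events))

    def test_dangling_duplication_is_an_error(self, limulus):
        with pytest.raises(ScenarioError, match="intermediate"):
            apply_scenario(limulus, Scenario("a", "b", [Event.make("dimerize")]))

    def test_gene_content_conserved_at_boundaries(self, limulus):
        from mitorearrange.references import marmoratus_scenario
        trace: list = []
        final = apply_scenario(limulus, marmoratus_scenario(), trace=trace)
        assert final.gene_set == limulus.gene_set
        for state in trace:
            if isinstance(state, GeneOrder):
                assert state.gene_set == limulus.gene_set
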