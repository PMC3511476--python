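"""Outgroup detection, scoring, disruption classification, aggregation."""

import pytest

from argscan.arg import PopulationMap, local_tree, parse_kwarg_dot
from argscan.scan import (R_A, R_O, OTHER, RecombEvent, aggregate_gene,
                          classify_disrupting, genome_tally, is_outgroup,
                          outgroup_intervals, recombination_score)
from conftest import three_leaf_arg


@pytest.fixture(scope="module")
def yeast13_popmap():
    pairs = [(f"WE_{i}", "WE") for i in (1, 2, 3)]
    pairs += [(f"S_{i}", "S") for i in (1, 2, 3)]
    pairs += [(f"M_{i}", "M") for i in (1, 2, 3)]
    pairs += [("NA_1", "NA"), ("NA_2", "NA"), ("WA_1", "WA"), ("WA_2", "WA")]
    return PopulationMap.from_pairs(pairs)


class TestIsOutgroup:
    def test_clade_adjacent_to_root(self, synthetic_dot_text, yeast_popmap):
        arg = parse_kwarg_dot(synthetic_dot_text)
        tree = local_tree(arg, 95500)
        assert is_outgroup(tree, "WE", yeast_popmap)
        assert not is_outgroup(tree, "NA", yeast_popmap)

    def test_two_leaf_tree_both_outgroups(self):
        pm = PopulationMap.from_pairs([("a", "A"), ("b", "B")])
        arg = parse_kwarg_dot("digraph { a -> r; b -> r; }")
        tree = local_tree(arg, 0)
        assert is_outgroup(tree, "A", pm) and is_outgroup(tree, "B", pm)

    def test_mixed_root_children_false_for_all(self, no_recomb_arg):
        pm = PopulationMap.from_pairs([("a", "P"), ("b", "Q"),
                                       ("c", "P"), ("d", "Q")])
        tree = local_tree(no_recomb_arg, 0)
        assert not is_outgroup(tree, "P", pm)
        assert not is_outgroup(tree, "Q", pm)

    def test_unknown_population_rejected(self, no_recomb_arg):
        pm = PopulationMap.from_pairs([(s, "X") for s in "abcd"])
        with pytest.raises(KeyError):
            is_outgroup(local_tree(no_recomb_arg, 0), "Z", pm)


class TestScore:
    def test_full_single_population(self, yeast13_popmap):
        ev = RecombEvent(10, "r1", frozenset({"M_1", "M_2", "M_3"}))
        scores = recombination_score(ev, yeast13_popmap)
        assert scores["M"] == 1.0
        assert sum(scores.values()) == pytest.approx(1.0)

    def test_three_full_populations_split_equally(self, yeast13_popmap):
        desc = frozenset({"NA_1", "NA_2", "S_1", "S_2", "S_3",
                          "WA_1", "WA_2"})
        scores = recombination_score(RecombEvent(10, "r1", desc), yeast13_popmap)
        assert scores["NA"] == pytest.approx(1 / 3)
        assert scores["S"] == pytest.approx(1 / 3)
        assert scores["WA"] == pytest.approx(1 / 3)
        assert scores["WE"] == 0.0

    def test_partial_subtension_normalized(self, yeast13_popmap):
        scores = recombination_score(RecombEvent(10, "r1",
                                                 frozenset({"S_1"})),
                                     yeast13_popmap)
        assert scores["S"] == pytest.approx(1.0)

    def test_empty_descendants_rejected(self):
        with pytest.raises(ValueError):
            RecombEvent(10, "r1", frozenset())


class TestClassify:
    def test_ancestral_to_clade(self, yeast13_popmap):
        ev = RecombEvent(10, "r1", frozenset({"M_1", "M_2", "M_3"}))
        assert classify_disrupting(ev, "M", yeast13_popmap) == R_A

    def test_ancestral_to_others_only(self, yeast13_popmap):
        ev = RecombEvent(10, "r1", frozenset({"NA_1", "S_1"}))
        assert classify_disrupting(ev, "M", yeast13_popmap) == R_O

    def test_mixed_descent(self, yeast13_popmap):
        ev = RecombEvent(10, "r1", frozenset({"M_1", "NA_1"}))
        assert classify_disrupting(ev, "M", yeast13_popmap) == OTHER


class TestOutgroupIntervals:
    def test_synthetic_graph_boundaries(self, synthetic_dot_text, yeast_popmap):
        arg = parse_kwarg_dot(synthetic_dot_text)
        ivs = outgroup_intervals(arg, yeast_popmap)
        we = [iv for iv in ivs if iv.population == "WE"]
        assert len(we) == 1
        iv = we[0]
        # outgroup downstream of 1-based position 94864, to the window edge
        assert iv.interval == (94864, 96000)
        assert iv.left_event is not None and iv.right_event is None
        assert iv.left_event.classification == R_A
        assert iv.left_event.descendants == frozenset({"we1", "we2", "we3"})
        # the middle interval has the West African singleton as outgroup,
        # bounded by one R_A and one R_O event
        wa = [iv for iv in ivs if iv.population == "WA"]
        assert len(wa) == 1
        assert wa[0].left_event.classification == R_A
        assert wa[0].right_event.classification == R_O

    def test_recombination_free_outgroup_has_no_events(self, no_recomb_arg):
        pm = PopulationMap.from_pairs([("a", "P"), ("b", "P"),
                                       ("c", "Q"), ("d", "Q")])
        ivs = outgroup_intervals(no_recomb_arg, pm)
        assert {iv.population for iv in ivs} == {"P", "Q"}
        for iv in ivs:
            assert iv.interval == no_recomb_arg.sequence_span
            assert iv.boundary_events == []

    def test_toggle_off_then_on(self):
        # three-leaf ARG: prefix ((a,c),b) -> b outgroup; suffix ((a,b),c)
        # -> c outgroup: two intervals with one identifiable event each
        pm = PopulationMap.from_pairs([("a", "A"), ("b", "B"), ("c", "C")])
        arg = three_leaf_arg(breakpoint=49)
        ivs = outgroup_intervals(arg, pm)
        by_pop = {iv.population: iv for iv in ivs}
        assert by_pop["B"].interval == (0, 50)
        assert by_pop["B"].right_event is not None
        assert by_pop["B"].left_event is None
        assert by_pop["C"].interval == (50, 100)
        assert by_pop["C"].left_event is not None
        assert by_pop["C"].left_event.classification == R_A  # desc == {c}


class TestAggregate:
    def test_identical_replicates_equal_single(self, synthetic_dot_text,
                                               yeast_popmap):
        arg = parse_kwarg_dot(synthetic_dot_text)
        one = aggregate_gene("g", [arg], yeast_popmap)
        many = aggregate_gene("g", [arg] * 100, yeast_popmap)
        assert not many.excluded
        assert [(iv.population, iv.interval) for iv in many.consensus_intervals] \
            == [(iv.population, iv.interval) for iv in one.consensus_intervals]

    def test_disagreeing_recombination_counts_excluded(self, synthetic_dot_text,
                                                       yeast_popmap, toy_arg):
        arg = parse_kwarg_dot(synthetic_dot_text)
        pm = PopulationMap.from_pairs([(s, s[:2].upper()) for s in arg.samples])
        other = parse_kwarg_dot(synthetic_dot_text.replace(
            'R2 [shape=ellipse, label="91000"];\n', '')
            .replace('wa1 -> R2;\n', '')
            .replace('R2 -> c5 [label="P"];\n', 'wa1 -> c5;\n')
            .replace('R2 -> c7 [label="S"];\n', ''))
        assert len(other.breakpoints) == 1
        summary = aggregate_gene("g", [arg, arg, other], pm)
        assert summary.excluded
        assert summary.consensus_intervals == []

    def test_majority_vote(self, yeast_popmap, synthetic_dot_text):
        arg = parse_kwarg_dot(synthetic_dot_text)
        # variant with the same breakpoint count but WE attached lower on
        # the suffix side (no WE outgroup): 60/40 vote keeps the interval
        variant = parse_kwarg_dot(synthetic_dot_text
                                  .replace("R1 -> r [label=\"S 95102\"];",
                                           "R1 -> c7 [label=\"S 95102\"];")
                                  .replace("c6 -> c7;", "c6 -> r;")
                                  .replace("c7 -> r;", "c7 -> c6x; c6x -> r;")
                                  )
        reps = [arg] * 3 + [variant] * 2
        summary = aggregate_gene("g", reps, yeast_popmap)
        assert not summary.excluded
        we = [iv for iv in summary.consensus_intervals if iv.population == "WE"]
        assert len(we) == 1

    def test_empty_replicates_rejected(self, yeast_popmap):
        with pytest.raises(ValueError):
            aggregate_gene("g", [], yeast_popmap)


def test_genome_tally_counts(synthetic_dot_text, yeast_popmap):
    arg = parse_kwarg_dot(synthetic_dot_text)
    summary = aggregate_gene("g1", [arg], yeast_popmap)
    tally = genome_tally([summary], yeast_popmap)
    rec = tally.set_index("population")
    assert rec.loc["WE", "n_RA"] == 1
    assert rec.loc["WA", "n_RA"] == 1 and rec.loc["WA", "n_RO"] == 1
    assert rec.loc["WE", "frac_outgroup"] == 1.0  # outgroup in its one gene
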