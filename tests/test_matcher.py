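import math

import pytest

import motifmatch as mm
from motifmatch import (
    DisconnectedMotifError,
    LinkTypeRegistry,
    MatcherError,
    TypedGraph,
    determine_set,
    find_motifs_isma,
    find_motifs_isma_recursive,
    find_motifs_rsma,
    parse_motif,
    residual_deduplicate,
    select_first_motif_node,
)
from motifmatch.matcher import poll_next

from conftest import complete_directed, complete_undirected, out_star


class TestDetermineSet:
    def test_empty_instance_intersection(self, worked):
        assert determine_set({}, 2, worked.graph, worked.motif) == ["5", "6"]

    def test_two_mapped_singleton(self, worked):
        got = determine_set({2: "5", 3: "4"}, 1, worked.graph, worked.motif)
        assert got == ["1"]

    def test_second_branch_singleton(self, worked):
        got = determine_set({2: "6", 1: "5"}, 3, worked.graph, worked.motif)
        assert got == ["3"]

    def test_candidate_soundness(self, worked):
        g, m = worked.graph, worked.motif
        inst = {2: "5"}
        got = set(determine_set(inst, 1, g, m))
        assert got <= set(g.neighbors_of_type("5", "a"))

    def test_injectivity_exclusion(self, reg_x):
        _, g = complete_undirected(4)
        m = parse_motif("XXX", reg_x)
        got = determine_set({1: "0", 2: "1"}, 3, g, m)
        assert "0" not in got and "1" not in got

    def test_disconnected_ordering_error(self, reg_abc):
        g = TypedGraph(reg_abc)
        g.add_link("1", "2", "A")
        m = parse_motif("AB0", reg_abc)  # node 3 linked to 1 only
        with pytest.raises(DisconnectedMotifError):
            determine_set({2: "2"}, 3, g, m)


class TestSelectFirst:
    def test_worked_example_tie_break(self, worked):
        g, m = worked.graph, worked.motif
        counts = {c: len(g.start_nodes_of_type(c)) for c in "ABCab"}
        assert counts == {"A": 3, "B": 4, "C": 5, "a": 3, "b": 3}
        mn, cands = select_first_motif_node(g, m)
        assert mn == 2
        assert cands == ["5", "6"]

    def test_single_edge_triangle_short_circuits(self):
        reg = LinkTypeRegistry([("S", True)])
        g = TypedGraph(reg)
        g.add_link("u", "v", "S")
        m = parse_motif("SSS", reg)
        _, cands = select_first_motif_node(g, m)
        assert cands == []
        assert find_motifs_isma(m, g)[0] == []

    def test_star_with_no_c_edges_terminates(self, reg_abc):
        _, g = out_star(5)
        reg = g.registry
        m = parse_motif("AAC", reg)
        mn, cands = select_first_motif_node(g, m)
        assert cands == []
        instances, _ = find_motifs_isma(m, g)
        assert instances == []

    def test_all_zero_motif_rejected(self, reg_abc):
        g = TypedGraph(reg_abc)
        g.add_link("1", "2", "A")
        m = parse_motif("000", reg_abc)
        with pytest.raises(MatcherError):
            select_first_motif_node(g, m)


class TestPollNext:
    def test_global_minimum_wins(self):
        # data-structure example: two mapped nodes contribute objects to the
        # two uninvestigated motif nodes; node '5' has the fewest neighbors
        pqm = {1: [(3, 2, "9"), (2, 4, "5")], 3: [(4, 2, "9"), (1, 4, "5")]}
        assert poll_next(pqm, {1, 3}) == 3

    def test_tie_goes_to_smallest_motif_index(self):
        pqm = {2: [(1, 1, "a")], 4: [(1, 1, "b")]}
        assert poll_next(pqm, {2, 4}) == 2

    def test_empty_queues_error(self):
        with pytest.raises(MatcherError):
            poll_next({1: []}, {1})

    def test_nondestructive(self):
        pqm = {1: [(1, 2, "x")]}
        poll_next(pqm, {1})
        assert pqm[1] == [(1, 2, "x")]


class TestWorkedExample:
    def test_isma_instances_and_tree(self, worked):
        instances, stats = find_motifs_isma(worked.motif, worked.graph)
        assert instances == [("1", "5", "4"), ("5", "6", "3")]
        assert stats.tree_nodes == 6

    def test_rsma_instances_and_tree(self, worked):
        instances, stats = find_motifs_rsma(worked.motif, worked.graph)
        assert sorted(instances) == [("1", "5", "4"), ("5", "6", "3")]
        assert stats.tree_nodes == 12

    def test_recursive_isma_matches(self, worked):
        instances, stats = find_motifs_isma_recursive(worked.motif, worked.graph)
        assert sorted(instances) == [("1", "5", "4"), ("5", "6", "3")]
        assert stats.tree_nodes == 6

    def test_trace_reproduces_narrated_candidate_sets(self, worked):
        trace = []
        find_motifs_isma(worked.motif, worked.graph, trace=trace)
        checks = [(e[1], e[2]) for e in trace if e[0] == "check"]
        assert checks == [
            (2, ["5", "6"]),
            (3, ["4"]),
            (1, ["1"]),
            (1, ["5"]),
            (3, ["3"]),
        ]

    def test_backtrack_returns_to_first_motif_node(self, worked):
        # after exporting (1,5,4) the engine must unwind to the first
        # checked motif node and map network node 6 on it
        trace = []
        find_motifs_isma(worked.motif, worked.graph, trace=trace)
        maps = [(e[1], e[2]) for e in trace if e[0] == "map"]
        assert maps == [
            (2, "5"), (3, "4"), (1, "1"),
            (2, "6"), (1, "5"), (3, "3"),
        ]

    def test_alternative_reconstruction_same_results(self, worked_alt):
        instances, isma_stats = find_motifs_isma(worked_alt.motif, worked_alt.graph)
        _, rsma_stats = find_motifs_rsma(worked_alt.motif, worked_alt.graph)
        assert instances == [("1", "5", "4"), ("5", "6", "3")]
        assert (rsma_stats.tree_nodes, isma_stats.tree_nodes) == (12, 6)


class TestEmptyAndTrivial:
    def test_empty_graph(self, reg_abc):
        g = TypedGraph(reg_abc)
        m = parse_motif("ABC", reg_abc)
        instances, stats = find_motifs_rsma(m, g)
        assert instances == [] and stats.tree_nodes == 0
        assert find_motifs_isma(m, g)[0] == []

    def test_triangles_on_k5(self, reg_x):
        _, g = complete_undirected(5)
        m = parse_motif("XXX", reg_x)
        for engine in (find_motifs_rsma, find_motifs_isma, find_motifs_isma_recursive):
            instances, _ = engine(m, g)
            assert len(instances) == 10

    def test_disconnected_motif_rejected_by_isma(self, reg_abc):
        g = TypedGraph(reg_abc)
        g.add_link("1", "2", "A")
        m = parse_motif("A00000", reg_abc)  # nodes 3 and 4 isolated
        with pytest.raises(DisconnectedMotifError):
            find_motifs_isma(m, g)
        with pytest.raises(DisconnectedMotifError):
            find_motifs_isma_recursive(m, g)


class TestSymmetryPruning:
    @pytest.mark.parametrize("s", [4, 5, 7])
    def test_reflection_pair_explores_combinations(self, s):
        _, g = out_star(s)
        m = parse_motif("AA0", g.registry)
        instances, stats = find_motifs_isma(m, g)
        assert len(instances) == math.comb(s, 2)
        assert stats.duplicates_discarded == 0

    @pytest.mark.parametrize("s", [4, 6])
    def test_reflection_triple_explores_combinations(self, s):
        _, g = out_star(s)
        m = parse_motif("AA0A00", g.registry)
        instances, stats = find_motifs_isma(m, g)
        assert len(instances) == math.comb(s, 3)
        assert stats.duplicates_discarded == 0

    @pytest.mark.parametrize("s", [4, 5, 6])
    def test_rotation_explores_cyclic_selections(self, s):
        _, g = complete_directed(s)
        m = parse_motif("AaA", g.registry)
        instances, stats = find_motifs_isma(m, g)
        assert len(instances) == s * (s - 1) * (s - 2) // 3
        assert stats.duplicates_discarded == 0

    def test_symmetry_off_same_instances_more_duplicates(self, reg_x):
        _, g = complete_undirected(5)
        m = parse_motif("XXX", reg_x)
        with_sym, st_on = find_motifs_isma(m, g, use_symmetry=True)
        without, st_off = find_motifs_isma(m, g, use_symmetry=False)
        assert set(with_sym) == set(without)
        assert st_on.duplicates_discarded == 0
        assert st_off.duplicates_discarded == 50  # 60 ordered embeddings, 10 kept


class TestResidualDeduplicate:
    def test_asymmetric_motif_keeps_everything(self):
        seen = set()
        auts = [(1, 2, 3)]
        assert residual_deduplicate(("a", "b", "c"), auts, seen)
        assert residual_deduplicate(("a", "c", "b"), auts, seen)

    def test_four_cycle_reversal_discarded(self, reg_x):
        m = parse_motif("X0XX0X", reg_x)
        auts = mm.automorphisms(m)
        seen = set()
        assert residual_deduplicate(("a", "b", "c", "d"), auts, seen)
        assert not residual_deduplicate(("b", "a", "d", "c"), auts, seen)

    def test_triangle_all_orders_collapse(self, reg_x):
        m = parse_motif("XXX", reg_x)
        auts = mm.automorphisms(m)
        seen = set()
        from itertools import permutations

        kept = sum(residual_deduplicate(t, auts, seen) for t in permutations("xyz"))
        assert kept == 1


class TestInducedMode:
    def test_chord_excluded_in_induced_mode(self, reg_x):
        # 4-cycle with one chord: non-induced finds the cycle, induced rejects
        g = TypedGraph(reg_x)
        for u, v in [("1", "2"), ("2", "3"), ("3", "4"), ("4", "1"), ("1", "3")]:
            g.add_link(u, v, "X")
        m = parse_motif("X0XX0X", reg_x)
        non_induced, _ = find_motifs_isma(m, g)
        induced, _ = find_motifs_isma(m, g, induced=True)
        assert len(non_induced) == 1
        assert induced == []

    def test_induced_agrees_with_oracle(self, reg_x):
        _, g = complete_undirected(6)
        m = parse_motif("X0XX0X", reg_x)
        _, unique = mm.oracle_enumerate(m, g, "induced")
        for engine in (find_motifs_rsma, find_motifs_isma, find_motifs_isma_recursive):
            instances, _ = engine(m, g, induced=True)
            assert set(instances) == set(unique) == set()
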