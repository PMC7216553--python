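"""Character coding, step distances, the tie-retaining MSN and ancestor ranking."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import satclone as sc
from conftest import exhaustive_msn_edges
from satclone.network import CharacterMatrix, pairwise_distances

# published coding matrix: tract lengths per clone in column order
# (Du215 mat/pat, Du281 mat/pat, Du323 mat/pat, Du47G mat/pat)
TABLE_TRACTS = {
    "C1": (4, 9, 10, 9, 7, 2, 5, 3),
    "C2": (4, 10, 9, 9, 7, 2, 5, 3),
    "C3": (4, 9, 10, 10, 7, 2, 5, 3),
    "C4": (4, 9, 12, 9, 7, 2, 5, 3),
    "C5": (4, 10, 10, 9, 7, 2, 5, 3),
    "C6": (4, 9, 10, 9, 7, 2, 5, 4),
    "C7": (4, 9, 9, 10, 7, 2, 5, 3),
    "C8": (4, 10, 9, 9, 7, 2, 5, 4),
    "C9": (4, 9, 9, 9, 7, 2, 5, 3),
    "C10": (4, 9, 10, 10, 7, 2, 5, 4),
    "C11": (4, 9, 11, 9, 7, 2, 5, 3),
    "C12": (4, 9, 12, 9, 7, 2, 5, 4),
}
# published polymorphic flanking-site states, sites 1–6 ("-" = gap/absent)
TABLE_SITES = {
    "C1": "-A----", "C2": "A-----", "C3": "-A--A-", "C4": "-AAA--",
    "C5": "AA----", "C6": "-A---A", "C7": "----A-", "C8": "A----A",
    "C9": "------", "C10": "-A--AA", "C11": "-AA---", "C12": "-AAA-A",
}


class TestEncodeMatrix:
    def test_full_matrix_reproduces_published_tract_rows(self, clone_table):
        matrix = sc.encode_matrix(clone_table, drop_constant=False)
        assert len(matrix.tract_columns) == 8
        for name, expected in TABLE_TRACTS.items():
            tracts, _ = matrix.row(name)
            assert tuple(tracts) == expected

    def test_six_polymorphic_site_columns_recovered(self, character_matrix):
        assert len(character_matrix.site_columns) == 6
        for name, expected in TABLE_SITES.items():
            _, sites = character_matrix.row(name)
            pattern = "".join("A" if s == "A" else "-" for s in sites)
            assert pattern == expected

    def test_constant_columns_dropped(self, character_matrix):
        assert ("Du323", "maternal", "t1") not in character_matrix.tract_columns
        assert ("Du215", "maternal", "t1") not in character_matrix.tract_columns
        assert len(character_matrix.tract_columns) == 4

    def test_identical_clones_identical_rows(self, character_matrix):
        rows = [character_matrix.row(n) for n in character_matrix.clone_names]
        # all 12 published clones are distinct once sites are included
        combined = {(tuple(t), tuple(s)) for t, s in rows}
        assert len(combined) == 12


class TestStepDistance:
    def test_self_distance_zero(self, character_matrix):
        for mode in ("unit", "event"):
            assert sc.step_distance(character_matrix, "C1", "C1", mode) == 0

    def test_c2_c8_single_event(self, character_matrix):
        # only the Du47G paternal tract changes (3 → 4)
        assert sc.step_distance(character_matrix, "C2", "C8", "event") == 1
        assert sc.step_distance(character_matrix, "C2", "C8", "unit") == 1

    def test_c1_c4_one_event_two_units(self, character_matrix):
        # Du281 maternal tract 10 → 12: one contiguous change, two repeat units
        assert sc.step_distance(character_matrix, "C1", "C4", "event") == 1
        assert sc.step_distance(character_matrix, "C1", "C4", "unit") == 2

    def test_unknown_mode_rejected(self, character_matrix):
        with pytest.raises(sc.SatcloneError):
            sc.step_distance(character_matrix, "C1", "C2", "parsimony")

    def test_site_differences_optional(self, character_matrix):
        bare = sc.step_distance(character_matrix, "C1", "C2", "event")
        with_sites = sc.step_distance(character_matrix, "C1", "C2", "event",
                                      include_sites=True)
        assert with_sites == bare + 2  # site1 and site2 both flip

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.data())
    def test_unit_mode_is_a_metric(self, data):
        rows = data.draw(
            st.lists(
                st.tuples(
                    st.lists(st.integers(0, 6), min_size=3, max_size=3),
                    st.lists(st.sampled_from("AC-"), min_size=2, max_size=2),
                ),
                min_size=3, max_size=3,
            )
        )
        names = ["a", "b", "c"]
        matrix = CharacterMatrix(
            names,
            [("L1", "maternal", f"t{i}") for i in range(3)],
            [list(t) for t, _ in rows],
            [("L1", "maternal", f"s{i}") for i in range(2)],
            [list(s) for _, s in rows],
        )

        def d(x, y):
            return sc.step_distance(matrix, x, y, "unit", include_sites=True)

        for x, y, z in itertools.permutations(names, 3):
            assert d(x, y) == d(y, x)
            assert d(x, y) <= d(x, z) + d(z, y)
        for x, y in itertools.combinations(names, 2):
            identical = rows[names.index(x)] == rows[names.index(y)]
            assert (d(x, y) == 0) == identical


def _random_matrix(rng, n):
    """Random clone-like character matrix with n rows (tract columns only)."""
    values = rng.integers(0, 4, size=(n, 3))
    names = [f"n{i}" for i in range(n)]
    return CharacterMatrix(
        names,
        [("L", "maternal", f"t{j}") for j in range(3)],
        [list(map(int, row)) for row in values],
        [],
        [[] for _ in range(n)],
    )


def _fake_table(matrix):
    """CloneTable shell so build_network can attach node metadata."""
    from fractions import Fraction

    from satclone.clones import CloneRecord, CloneTable

    clones = [
        CloneRecord(name, {}, [name], {"pop": 1}, 1, Fraction(1, len(matrix.clone_names)))
        for name in matrix.clone_names
    ]
    return CloneTable(clones, [], ["pop"], {})


class TestBuildNetwork:
    def test_single_clone_single_node(self, clone_table, character_matrix):
        from satclone.clones import CloneTable

        sub = CloneTable(clone_table.clones[:1], clone_table.locus_order,
                         clone_table.populations, clone_table.population_summaries)
        matrix = sc.encode_matrix(sub, drop_constant=False)
        net = sc.build_network(matrix, sub)
        assert net.graph.number_of_nodes() == 1
        assert net.graph.number_of_edges() == 0
        assert net.is_connected

    def test_reference_network_connected_with_all_clones(self, clone_table, character_matrix):
        net = sc.build_network(character_matrix, clone_table, mode="event")
        assert net.is_connected
        assert set(net.graph.nodes) == {c.name for c in clone_table.clones}

    def test_c8_unique_nearest_neighbour_is_c2(self, character_matrix):
        dists = {
            other: sc.step_distance(character_matrix, "C8", other, "event")
            for other in character_matrix.clone_names if other != "C8"
        }
        assert dists["C2"] == 1
        assert all(d >= 2 for name, d in dists.items() if name != "C2")

    def test_all_but_c8_within_two_steps_of_c1(self, character_matrix):
        dists = {
            other: sc.step_distance(character_matrix, "C1", other, "event")
            for other in character_matrix.clone_names if other != "C1"
        }
        near = [name for name, d in dists.items() if d <= 2]
        assert len(near) == 10
        assert dists["C8"] == 3

    def test_chain_of_single_step_clones_yields_path(self):
        n = 5
        matrix = CharacterMatrix(
            [f"n{i}" for i in range(n)],
            [("L", "maternal", "t1")],
            [[10 + i] for i in range(n)],
            [], [[] for _ in range(n)],
        )
        net = sc.build_network(matrix, _fake_table(matrix), mode="unit")
        degrees = sorted(d for _, d in net.graph.degree())
        assert degrees == [1, 1, 2, 2, 2]

    @pytest.mark.parametrize("mode", ["unit", "event"])
    def test_matches_exhaustive_spanning_tree_oracle(self, mode):
        rng = np.random.default_rng(99)
        for _ in range(40):
            n = int(rng.integers(4, 8))
            matrix = _random_matrix(rng, n)
            net = sc.build_network(matrix, _fake_table(matrix), mode=mode)
            dist = {
                frozenset(pair): d
                for pair, d in pairwise_distances(matrix, mode).items()
            }
            oracle = exhaustive_msn_edges(matrix.clone_names, dist)
            ours = {(a, b) for a, b, _ in net.edges()}
            assert ours == oracle

    def test_connection_limit_splits_network(self, clone_table, character_matrix):
        net = sc.build_network(character_matrix, clone_table, mode="event",
                               connection_limit=0)
        assert net.graph.number_of_edges() == 0
        assert net.n_subnetworks == 12
        full = sc.build_network(character_matrix, clone_table, mode="event",
                                connection_limit=10)
        assert full.is_connected


class TestAncestralCandidate:
    def test_reference_top_candidate_is_c1(self, clone_table, character_matrix):
        net = sc.build_network(character_matrix, clone_table, mode="event")
        report = sc.ancestral_candidate(net, clone_table)
        assert report.top == "C1"
        assert report.ranking[0] == ("C1", 7, 37, net.graph.degree("C1"))
        assert report.rootable is False

    def test_tied_clones_reported_without_arbitrary_winner(self):
        matrix = CharacterMatrix(
            ["x", "y"], [("L", "maternal", "t1")], [[4], [5]], [], [[], []],
        )
        table = _fake_table(matrix)
        net = sc.build_network(matrix, table, mode="unit")
        report = sc.ancestral_candidate(net, table)
        assert report.top is None
        assert sorted(report.top_candidates) == ["x", "y"]


class TestExports:
    def test_edgelist_dot_graphml_written(self, clone_table, character_matrix, tmp_path):
        net = sc.build_network(character_matrix, clone_table, mode="event")
        net.write_edgelist(tmp_path / "edges.tsv")
        net.write_dot(tmp_path / "net.dot")
        net.write_graphml(tmp_path / "net.graphml")
        lines = (tmp_path / "edges.tsv").read_text().splitlines()
        assert lines[0] == "clone_a\tclone_b\tsteps"
        assert len(lines) - 1 == net.graph.number_of_edges()
        assert "C1" in (tmp_path / "net.dot").read_text()
        import networkx as nx

        back = nx.read_graphml(tmp_path / "net.graphml")
        assert back.number_of_nodes() == 12
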