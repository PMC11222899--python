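"""Cyclic topology generation, cyclization of linear templates, and the
graph-enumeration completeness checks (networkx as independent oracle)."""

import itertools

import networkx as nx
import pytest

from peptube import topology as T
from peptube.errors import TopologyError
from peptube.sequences import parse_sequence

BB_ONLY = {c: [{"name": "BB", "type": "P5", "charge": 0.0, "atoms": ["N", "CA", "C", "O"]}]
           for c in "ACDEFGHIKLMNPQRSTVWY"}
ONE_SIDE = {c: [{"name": "BB", "type": "P5", "charge": 0.0, "atoms": ["N", "CA", "C", "O"]},
                {"name": "SC1", "type": "C3", "charge": 0.0, "atoms": ["CB"]}]
            for c in "ACDEFHIKLMNQRSTVWY"}


def nx_paths(graph, length):
    """All simple paths of a given edge count, canonicalised, via networkx."""
    found = set()
    for a, b in itertools.combinations(graph.nodes, 2):
        for path in nx.all_simple_paths(graph, a, b, cutoff=length):
            if len(path) == length + 1:
                t = tuple(path)
                found.add(min(t, t[::-1]))
    return found


def graph_of(spec):
    g = nx.Graph()
    g.add_nodes_from(range(len(spec.particles)))
    g.add_edges_from(spec.bond_pairs())
    return g


class TestGenerateCG:
    def test_bb_only_counts_are_cyclic(self, cg_params):
        top = T.generate_cg_topology(parse_sequence("RRKWLWLW"), BB_ONLY, cg_params)
        assert len(top.bonds) == 8
        assert len(top.angles) == 8
        assert len(top.dihedrals) == 8

    def test_four_residue_angle_triples_wrap_around(self, cg_params):
        top = T.generate_cg_topology(parse_sequence("QAEA"), BB_ONLY, cg_params)
        got = {tuple(sorted(a.indices)) for a in top.angles}
        expect = {tuple(sorted(((i, (i + 1) % 4, (i + 2) % 4)))) for i in range(4)}
        assert got == expect
        assert got == {tuple(sorted(t)) for t in nx_paths(graph_of(top), 2)}

    def test_one_side_bead_adds_bb_sc_bonds_only(self, cg_params):
        top = T.generate_cg_topology(parse_sequence("ACDEFA"), ONE_SIDE, cg_params)
        names = [(top.particles[i].name, top.particles[j].name) for i, j in
                 (b.indices for b in top.bonds)]
        bb_sc = [p for p in names if "SC1" in p and "BB" in p]
        sc_sc = [p for p in names if p == ("SC1", "SC1")]
        assert len(bb_sc) == 6 and len(sc_sc) == 0

    @pytest.mark.parametrize("text", ["QAEA", "RRKWLW", "RRKWLWLW", "ACDEFGHIKL", "ACDEFGHIKLMN"])
    def test_angle_and_dihedral_sets_equal_brute_force(self, text, cg_mapping, cg_params):
        top = T.generate_cg_topology(parse_sequence(text), cg_mapping, cg_params)
        g = graph_of(top)
        assert {min(a.indices, a.indices[::-1]) for a in top.angles} == nx_paths(g, 2)
        assert {min(d.indices, d.indices[::-1]) for d in top.dihedrals
                if not d.improper} == nx_paths(g, 3)
        assert T.verify_cycle(top, expected_size=top.backbone_indices().__len__()).ok

    def test_charge_conservation(self, cg_mapping, cg_params):
        formal = {"R": 1, "K": 1, "D": -1, "E": -1}
        for text in ("RRKWLWLW", "QAEA", "DEKR"):
            top = T.generate_cg_topology(parse_sequence(text), cg_mapping, cg_params)
            assert top.total_charge == pytest.approx(sum(formal.get(c, 0) for c in text))

    def test_missing_param_raises(self, cg_mapping):
        with pytest.raises(TopologyError) as err:
            T.generate_cg_topology(parse_sequence("QAEA"), cg_mapping, {"bonds": {}})
        assert err.value.code == "MISSING_PARAM"


def toy_chain():
    parts = [T.Particle(n, "X", i + 1, "GLY", 0.0) for i, n in enumerate("abcd")]
    return T.TopologySpec(
        "toy", parts,
        bonds=[T.BondedTerm((0, 1)), T.BondedTerm((1, 2)), T.BondedTerm((2, 3))],
        angles=[T.BondedTerm((0, 1, 2)), T.BondedTerm((1, 2, 3))],
        dihedrals=[T.BondedTerm((0, 1, 2, 3))],
        nrexcl=2,
    )


class TestCyclize:
    def test_toy_chain_gains_exact_junction_terms(self):
        cyc = T.cyclize_linear_topology(toy_chain())
        assert {tuple(sorted(b.indices)) for b in cyc.bonds} == {(0, 1), (1, 2), (2, 3), (0, 3)}
        gained_angles = {min(a.indices, a.indices[::-1]) for a in cyc.angles} - {(0, 1, 2), (1, 2, 3)}
        assert gained_angles == {min(t, t[::-1]) for t in [(2, 3, 0), (3, 0, 1)]}
        gained_dih = {min(d.indices, d.indices[::-1]) for d in cyc.dihedrals} - {(0, 1, 2, 3)}
        assert gained_dih == {min(t, t[::-1]) for t in [(1, 2, 3, 0), (2, 3, 0, 1), (3, 0, 1, 2)]}

    def test_already_cyclic_is_rejected(self):
        cyc = T.cyclize_linear_topology(toy_chain())
        with pytest.raises(TopologyError) as err:
            T.cyclize_linear_topology(cyc)
        assert err.value.code == "NOT_LINEAR"

    def test_branched_backbone_is_ambiguous(self):
        parts = [T.Particle(n, "X", 1, "GLY", 0.0) for n in "abcd"]
        star = T.TopologySpec("star", parts,
                              bonds=[T.BondedTerm((0, 1)), T.BondedTerm((0, 2)), T.BondedTerm((0, 3))])
        with pytest.raises(TopologyError) as err:
            T.cyclize_linear_topology(star)
        assert err.value.code == "JUNCTION_AMBIGUOUS"

    def test_gly4_bond_count_arithmetic(self, gly4_linear):
        profile, linear = gly4_linear
        cyc = T.cyclize_linear_topology(linear, profile.internal_charges)
        removed = [p.name for p in linear.particles if p.name in T.TERMINAL_ONLY_NAMES]
        # each removed terminal particle carried exactly one bond
        assert len(cyc.bonds) == len(linear.bonds) - len(removed) + 1
        assert len(removed) == 3

    def test_gly4_junction_terms_complete_and_charges_internal(self, gly4_linear):
        profile, linear = gly4_linear
        cyc = T.cyclize_linear_topology(linear, profile.internal_charges)
        g = graph_of(cyc)
        assert {min(a.indices, a.indices[::-1]) for a in cyc.angles} == nx_paths(g, 2)
        assert {min(d.indices, d.indices[::-1]) for d in cyc.dihedrals
                if not d.improper} == nx_paths(g, 3)
        # all-glycine ring with internal charges everywhere is neutral
        assert cyc.total_charge == pytest.approx(0.0, abs=1e-9)
        assert not any(p.name in T.TERMINAL_ONLY_NAMES for p in cyc.particles)

    def test_gly4_exclusions_match_bfs_oracle(self, gly4_linear):
        profile, linear = gly4_linear
        cyc = T.cyclize_linear_topology(linear, profile.internal_charges)
        g = graph_of(cyc)
        expect = set()
        for node, dists in nx.all_pairs_shortest_path_length(g, cutoff=linear.nrexcl):
            for other, d in dists.items():
                if 0 < d and other > node:
                    expect.add((node, other))
        assert set(cyc.exclusions) == expect

    def test_junction_impropers_replicated(self, gly4_linear):
        profile, linear = gly4_linear
        n_lin = sum(1 for d in linear.dihedrals if d.improper)
        cyc = T.cyclize_linear_topology(linear, profile.internal_charges)
        n_cyc = sum(1 for d in cyc.dihedrals if d.improper)
        assert n_cyc == n_lin + 2  # one C-centred + one N-centred across the junction


class TestVerifyCycle:
    @pytest.mark.parametrize("n", [4, 6, 8, 10, 12])
    def test_generated_topologies_verify(self, n, cg_mapping, cg_params):
        text = ("RKWLDESTQAGN" * 2)[:n]
        top = T.generate_cg_topology(parse_sequence(text), cg_mapping, cg_params)
        assert T.verify_cycle(top, expected_size=n).ok

    def test_broken_cycle_is_refuted(self, cg_params):
        top = T.generate_cg_topology(parse_sequence("QAEA"), BB_ONLY, cg_params)
        top.bonds = top.bonds[1:]
        assert not T.verify_cycle(top, expected_size=4).backbone_is_cycle

    def test_random_graphs_agree_with_networkx_cycle_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(3, 9))
            nodes = list(range(n))
            edges = set()
            for i in nodes:
                for j in range(i + 1, n):
                    if rng.random() < 0.35:
                        edges.add((i, j))
            got = T.is_single_cycle(nodes, edges)
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from(edges)
            want = (
                len(g.edges) == n
                and nx.is_connected(g)
                and all(d == 2 for _, d in g.degree)
            )
            assert got == want
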