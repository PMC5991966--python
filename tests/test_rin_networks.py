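import itertools

import networkx as nx
import numpy as np
import pytest

from allostruct import rin_networks as rin
from allostruct import synthetic_data as synth
from allostruct.structures_io import Atom, LigandGroup, Residue, Structure


def ca_structure(points, sid="TEST_A"):
    residues = [
        Residue(i + 1, "ALA", [Atom("CA", "C", *p)]) for i, p in enumerate(points)
    ]
    return Structure(sid, residues, [])


def brute_betweenness(g):
    """Exhaustive path enumeration: all simple paths, keep the shortest by
    total weight, count pair fractions through each interior node."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    score = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(g, s, t))
        if not paths:
            continue
        lengths = [
            sum(g.edges[a, b]["weight"] for a, b in zip(p, p[1:])) for p in paths
        ]
        best = min(lengths)
        shortest = [p for p, l in zip(paths, lengths) if abs(l - best) < 1e-12]
        for node in nodes:
            through = sum(1 for p in shortest if node in p[1:-1])
            score[node] += through / len(shortest)
    norm = (n - 1) * (n - 2) / 2
    return {v: score[v] / norm for v in nodes}


def random_weighted_graph(rng, n_nodes, p_edge=0.5):
    g = nx.Graph()
    g.add_nodes_from(range(1, n_nodes + 1))
    for i, j in itertools.combinations(range(1, n_nodes + 1), 2):
        if rng.random() < p_edge:
            g.add_edge(i, j, weight=float(np.round(rng.uniform(1, 10), 3)))
    return g


class TestBuildRin:
    def test_edge_just_inside_cutoff(self):
        net = rin.build_rin(ca_structure([(0, 0, 0), (6.9, 0, 0)]))
        assert net.graph.has_edge(1, 2)
        assert net.edge_weight(1, 2) == pytest.approx(6.9)

    def test_no_edge_just_outside_cutoff(self):
        net = rin.build_rin(ca_structure([(0, 0, 0), (7.1, 0, 0)]))
        assert not net.graph.has_edge(1, 2)

    def test_edge_set_matches_all_pairs_scan(self):
        st = synth.make_chain(50, seed=21)
        net = rin.build_rin(st, cutoff=7.0)
        pts = {r.number: np.array(r.ca.xyz) for r in st.residues}
        expected = {
            (i, j)
            for i, j in itertools.combinations(sorted(pts), 2)
            if np.linalg.norm(pts[i] - pts[j]) <= 7.0
        }
        got = {tuple(sorted(e)) for e in net.graph.edges}
        assert got == expected
        for i, j in expected:
            assert net.edge_weight(i, j) == pytest.approx(
                np.linalg.norm(pts[i] - pts[j]), abs=5e-4
            )

    def test_raising_cutoff_only_adds_edges(self):
        st = synth.make_chain(40, seed=22)
        e7 = set(rin.build_rin(st, cutoff=7.0).graph.edges)
        e9 = set(rin.build_rin(st, cutoff=9.0).graph.edges)
        assert e7 <= e9

    def test_rigid_transform_leaves_network_unchanged(self, rng):
        st = synth.make_chain(30, seed=23)
        net1 = rin.build_rin(st)
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        t = rng.normal(size=3) * 20
        moved = ca_structure(
            [(np.array(r.ca.xyz) @ R.T + t) for r in st.residues]
        )
        net2 = rin.build_rin(moved)
        assert set(net1.graph.edges) == set(net2.graph.edges)
        for i, j in net1.graph.edges:
            assert net1.edge_weight(i, j) == pytest.approx(net2.edge_weight(i, j), abs=2e-3)


class TestBetweenness:
    def test_path_network_center(self):
        net = rin.build_rin(ca_structure([(0, 0, 0), (5, 0, 0), (10, 0, 0)]))
        bc = rin.betweenness(net)
        assert bc[2] == pytest.approx(1.0)
        assert bc[1] == bc[3] == 0.0

    def test_complete_unit_network_all_zero(self):
        g = nx.complete_graph([1, 2, 3, 4])
        nx.set_edge_attributes(g, 1.0, "weight")
        net = rin.ResidueInteractionNetwork(g, cutoff=7.0)
        assert all(v == 0.0 for v in rin.betweenness(net).values())

    def test_matches_enumeration_oracle_on_random_networks(self, rng):
        for _ in range(25):
            g = random_weighted_graph(rng, int(rng.integers(4, 9)))
            net = rin.ResidueInteractionNetwork(g, cutoff=0)
            got = rin.betweenness(net)
            want = brute_betweenness(g)
            for v in g.nodes:
                assert got[v] == pytest.approx(want[v], abs=1e-9)


class TestShortestPaths:
    def test_direct_edge_beats_detour(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=3.0)
        g.add_edge(1, 3, weight=1.0)
        g.add_edge(3, 2, weight=5.0)
        net = rin.ResidueInteractionNetwork(g, cutoff=0)
        (rep,) = rin.shortest_paths(net, {1}, {2})
        assert rep.nodes == [1, 2]
        assert rep.length == pytest.approx(3.0)

    def test_unreachable_flagged(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        g.add_node(9)
        net = rin.ResidueInteractionNetwork(g, cutoff=0)
        (rep,) = rin.shortest_paths(net, {1}, {9})
        assert not rep.reachable

    def test_tie_broken_by_fewer_nodes_then_lexicographic(self):
        g = nx.Graph()
        # two length-4 routes: direct 1-4 (4.0) and 1-2-4 (2+2)
        g.add_edge(1, 4, weight=4.0)
        g.add_edge(1, 2, weight=2.0)
        g.add_edge(2, 4, weight=2.0)
        # and 1-3-4, also 4.0, lexicographically after 1-2-4
        g.add_edge(1, 3, weight=2.0)
        g.add_edge(3, 4, weight=2.0)
        net = rin.ResidueInteractionNetwork(g, cutoff=0)
        (rep,) = rin.shortest_paths(net, {1}, {4})
        assert rep.nodes == [1, 4]

    def test_lengths_match_floyd_warshall(self, rng):
        for _ in range(20):
            g = random_weighted_graph(rng, int(rng.integers(4, 11)), p_edge=0.4)
            net = rin.ResidueInteractionNetwork(g, cutoff=0)
            fw = dict(nx.floyd_warshall(g, weight="weight"))
            nodes = sorted(g.nodes)
            src, tgt = set(nodes[:2]), set(nodes[-2:])
            for rep in rin.shortest_paths(net, src, tgt):
                expected = fw[rep.source][rep.target]
                if np.isinf(expected):
                    assert not rep.reachable
                else:
                    assert rep.length == pytest.approx(expected, abs=1e-9)
                    # path consistency: consecutive nodes are edges
                    for a, b in zip(rep.nodes, rep.nodes[1:]):
                        assert g.has_edge(a, b)

    def test_unknown_residue_rejected(self):
        g = nx.Graph()
        g.add_edge(1, 2, weight=1.0)
        net = rin.ResidueInteractionNetwork(g, cutoff=0)
        with pytest.raises(ValueError, match="not in network"):
            rin.shortest_paths(net, {1}, {77})


class TestNucleotideContacts:
    def test_planted_single_contact(self):
        residues = [
            Residue(1, "ALA", [Atom("CA", "C", 0, 0, 0), Atom("CB", "C", 0, 3.0, 0)]),
            Residue(2, "GLY", [Atom("CA", "C", 30, 0, 0)]),
        ]
        gdp = LigandGroup("GDP", 900, [Atom("PB", "P", 0, 6.0, 0)])
        st = Structure("X_A", residues, [gdp])
        assert rin.nucleotide_contacts(st, cutoff=4.0) == {1}

    def test_matches_brute_force_scan(self, rng):
        st = synth.make_chain(25, seed=31)
        anchor = np.array(st.residues[10].ca.xyz)
        lig = LigandGroup("GNP", 900, [
            Atom(f"C{i}", "C", *(anchor + rng.normal(0, 3.0, size=3))) for i in range(8)
        ])
        st = Structure(st.id, st.residues, [lig])
        got = rin.nucleotide_contacts(st, cutoff=4.0)
        expected = set()
        for res in st.residues:
            for a in res.atoms:
                for la in lig.atoms:
                    if np.linalg.norm(np.subtract(a.xyz, la.xyz)) <= 4.0:
                        expected.add(res.number)
        assert got == expected

    def test_missing_nucleotide_rejected(self):
        st = synth.make_chain(5, seed=32)
        with pytest.raises(ValueError, match="no ligand"):
            rin.nucleotide_contacts(st)


class TestCenterOfMass:
    def test_single_atom_protein(self):
        st = Structure("X_A", [Residue(1, "GLY", [Atom("CA", "C", 1, 2, 3)])], [])
        assert rin.center_of_mass_distances(st, {1})[1] == pytest.approx(0.0)

    def test_symmetric_dimer_mirror_residues_equidistant(self):
        half = [
            Residue(1, "ALA", [Atom("CA", "C", 1, 1, 0), Atom("CB", "C", 2, 1, 0)]),
            Residue(2, "GLY", [Atom("CA", "C", 4, 2, 0)]),
        ]
        mirror = [
            Residue(11, "ALA", [Atom("CA", "C", -1, 1, 0), Atom("CB", "C", -2, 1, 0)]),
            Residue(12, "GLY", [Atom("CA", "C", -4, 2, 0)]),
        ]
        st = Structure("DIM_A", half + mirror, [])
        d = rin.center_of_mass_distances(st)
        assert d[1] == pytest.approx(d[11])
        assert d[2] == pytest.approx(d[12])

    def test_ligands_excluded_from_com(self):
        st = Structure(
            "X_A",
            [Residue(1, "GLY", [Atom("CA", "C", 0, 0, 0)]),
             Residue(2, "GLY", [Atom("CA", "C", 2, 0, 0)])],
            [LigandGroup("GDP", 900, [Atom("PB", "P", 100, 0, 0)])],
        )
        d = rin.center_of_mass_distances(st)
        assert d[1] == pytest.approx(1.0)

    def test_unknown_residue_rejected(self):
        st = synth.make_chain(5, seed=33)
        with pytest.raises(KeyError):
            rin.center_of_mass_distances(st, {99})

    def test_rigid_transform_invariance(self, rng):
        st = synth.make_chain(15, seed=34)
        d1 = rin.center_of_mass_distances(st)
        R = np.linalg.qr(rng.normal(size=(3, 3)))[0]
        if np.linalg.det(R) < 0:
            R[:, 0] *= -1
        t = rng.normal(size=3) * 10
        moved_res = [
            Residue(r.number, r.name, [
                Atom(a.name, a.element, *(np.array(a.xyz) @ R.T + t)) for a in r.atoms
            ])
            for r in st.residues
        ]
        d2 = rin.center_of_mass_distances(Structure(st.id, moved_res, []))
        for k in d1:
            assert d2[k] == pytest.approx(d1[k], abs=1e-9)
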