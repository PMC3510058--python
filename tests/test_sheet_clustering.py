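import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aggkin.cg_model import Frame
from aggkin.sheet_clustering import (ANTIPARALLEL, DISORDERED, PARALLEL,
                                     THREE_PLUS_SHEET, TWO_SHEET,
                                     ClusterPartition, analyze_frame,
                                     classify_polymorph, cluster_timeseries,
                                     clusters, count_sheets, pair_orientation,
                                     parallel_fraction, strand_graph)
from aggkin.synthetic_data import build_ideal_sheet, merge_structures


def _uf_components(n, edges):
    """Brute-force union-find oracle for connected components."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return sorted((frozenset(c) for c in comps.values()), key=min)


class TestStrandGraph:
    def test_ideal_sheet_path(self, parallel_sheet5):
        frame, top = parallel_sheet5
        g = strand_graph(frame, top)
        assert set(g.nodes) == set(range(5))
        # adjacent strands attached; brute-force verified by the fixture
        for a in range(4):
            assert g.has_edge(a, a + 1)
            assert g.edges[a, a + 1]["n_hbonds"] >= 2
        assert nx.is_connected(g)

    def test_coil_empty(self, coil20):
        frame, top = coil20
        g = strand_graph(frame, top)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 0  # no peptide passes the beta test

    def test_perturbed_strand_excluded(self, parallel_sheet5):
        frame, top = parallel_sheet5
        coords = frame.coords.copy()
        # scramble strand 2's backbone out of the beta region
        idx = top.chain_atom_indices(2)
        rng = np.random.default_rng(5)
        center = coords[idx].mean(axis=0)
        coords[idx] = center + rng.normal(scale=3.0, size=(len(idx), 3))
        g = strand_graph(Frame(coords=coords, box_edge=frame.box_edge), top)
        assert 2 not in g.nodes
        assert all(2 not in e for e in g.edges)


class TestClusters:
    def test_two_edges_one_cluster(self):
        g = nx.Graph([(0, 1), (1, 2)])
        g.add_nodes_from(range(3))
        part = clusters(g, 20)
        assert part.clusters == [frozenset({0, 1, 2})]
        assert len(part.monomers) == 17

    def test_empty_graph_all_monomers(self):
        part = clusters(nx.Graph(), 20)
        assert part.clusters == []
        assert len(part.monomers) == 20

    def test_random_graphs_match_union_find_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 9))
            edges = [(a, b) for a in range(n) for b in range(a + 1, n)
                     if rng.random() < 0.3]
            g = nx.Graph(edges)
            g.add_nodes_from(range(n))
            part = clusters(g, n)
            oracle = [c for c in _uf_components(n, edges) if len(c) >= 2]
            assert sorted(part.clusters, key=min) == oracle
            assert part.monomers == frozenset(range(n)) - set().union(
                frozenset(), *oracle)

    def test_mass_conservation_invariant(self):
        g = nx.Graph([(0, 1), (2, 3), (3, 4)])
        g.add_nodes_from(range(8))
        part = clusters(g, 8)
        assert sum(part.size_histogram() * np.arange(9)) == 8

    @given(st.integers(0, 10 ** 6))
    @settings(max_examples=30, deadline=None)
    def test_relabeling_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        edges = [(a, b) for a in range(n) for b in range(a + 1, n)
                 if rng.random() < 0.3]
        perm = rng.permutation(n)
        g1 = nx.Graph(edges)
        g1.add_nodes_from(range(n))
        g2 = nx.Graph([(int(perm[a]), int(perm[b])) for a, b in edges])
        g2.add_nodes_from(range(n))
        p1 = {frozenset(int(perm[x]) for x in c) for c in clusters(g1, n).clusters}
        p2 = set(clusters(g2, n).clusters)
        assert p1 == p2

    def test_edge_monotonicity(self, rng):
        # removing an edge never merges; adding never splits
        for _ in range(50):
            n = int(rng.integers(3, 9))
            edges = [(a, b) for a in range(n) for b in range(a + 1, n)
                     if rng.random() < 0.4]
            if not edges:
                continue
            g = nx.Graph(edges)
            g.add_nodes_from(range(n))
            n_before = nx.number_connected_components(g)
            g2 = g.copy()
            g2.remove_edge(*edges[0])
            assert nx.number_connected_components(g2) >= n_before
            g3 = g.copy()
            g3.add_edge(int(rng.integers(n)), int(rng.integers(n)))
            if nx.number_of_selfloops(g3):
                continue
            assert nx.number_connected_components(g3) <= n_before


class TestOrientation:
    def test_parallel_sheet(self, parallel_sheet5):
        frame, top = parallel_sheet5
        assert pair_orientation(frame, top, 0, 1) == PARALLEL
        part = clusters(strand_graph(frame, top), 5)
        assert parallel_fraction(part) == 1.0

    def test_antiparallel_sheet(self, antiparallel_sheet2):
        frame, top = antiparallel_sheet2
        assert pair_orientation(frame, top, 0, 1) == ANTIPARALLEL
        part = clusters(strand_graph(frame, top), 2)
        assert parallel_fraction(part) == 0.0

    def test_reversing_chain_flips_verdict(self, parallel_sheet5):
        frame, top = parallel_sheet5
        coords = frame.coords.copy()
        # swap residue blocks of chain 1 end-for-end
        idx = top.chain_atom_indices(1).reshape(7, 6)
        coords[idx] = coords[idx[::-1]]
        flipped = Frame(coords=coords, box_edge=frame.box_edge)
        assert pair_orientation(flipped, top, 0, 1) == ANTIPARALLEL

    def test_antiparallel_complement(self, parallel_sheet5):
        frame, top = parallel_sheet5
        part = clusters(strand_graph(frame, top), 5)
        pf = parallel_fraction(part)
        assert pf is not None
        assert pf + (1 - pf) == pytest.approx(1.0)

    def test_no_pairs_undefined(self):
        part = clusters(nx.Graph(), 4)
        assert parallel_fraction(part) is None


class TestTimeseries:
    def test_growth_script_largest_sizes(self, growth8):
        traj, partitions, _events = growth8
        records = list(cluster_timeseries(traj))
        truth = [max(len(g) for g in groups) for groups in partitions]
        got = [r.largest_cluster_size for r in records]
        assert got == truth

    def test_static_trajectory_identical_partitions(self, parallel_sheet5):
        from aggkin.cg_model import Trajectory
        frame, top = parallel_sheet5
        frames = [Frame(coords=frame.coords, box_edge=frame.box_edge, time=t)
                  for t in (0.0, 7.5, 15.0)]
        traj = Trajectory(topology=top, frames=frames)
        recs = list(cluster_timeseries(traj))
        parts = [tuple(sorted(r.partition.clusters, key=min)) for r in recs]
        assert parts[0] == parts[1] == parts[2]

    def test_mass_conservation_every_frame(self, growth8):
        traj, _, _ = growth8
        for r in cluster_timeseries(traj):
            hist = r.partition.size_histogram()
            assert int((hist * np.arange(len(hist))).sum()) == 8


class TestPolymorph:
    def test_two_stacked_sheets(self):
        f1, t1 = build_ideal_sheet(10, PARALLEL)
        frame, top = merge_structures(
            [(f1, t1, (0, 0, 0)), (f1, t1, (0, 0, 12.0))], box_edge=200.0)
        rec = analyze_frame(frame, top)
        assert len(rec.partition.clusters) == 2
        assert classify_polymorph(rec.partition) == TWO_SHEET

    def test_three_sheets(self):
        f7, t7 = build_ideal_sheet(7, PARALLEL)
        f6, t6 = build_ideal_sheet(6, PARALLEL)
        frame, top = merge_structures(
            [(f7, t7, (0, 0, 0)), (f7, t7, (0, 0, 14.0)), (f6, t6, (0, 0, 28.0))],
            box_edge=200.0)
        rec = analyze_frame(frame, top)
        assert classify_polymorph(rec.partition) == THREE_PLUS_SHEET

    def test_all_monomers_disordered(self, coil20):
        frame, top = coil20
        rec = analyze_frame(frame, top)
        assert classify_polymorph(rec.partition) == DISORDERED

    def test_count_sheets_splits_at_branch(self):
        # star graph: center has 3 neighbours -> branches split
        g = nx.Graph()
        for chain in ([0, 1, 2, 3], [3, 4, 5, 6], [3, 7, 8, 9]):
            for a, b in zip(chain, chain[1:]):
                g.add_edge(a, b, n_hbonds=4)
        assert count_sheets(g, min_sheet_len=3) >= 2
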