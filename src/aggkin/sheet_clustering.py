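"""Strand-attachment graphs, beta-sheet cluster partitions and orientation.

A peptide joins a cluster when it is attached to another strand of that
cluster by at least ``min_hbonds`` inter-strand hydrogen bonds, and both
peptides pass the beta-state test; clusters are connected components of the
resulting graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cg_model import Frame, Topology, Trajectory, minimum_image
from .structure_metrics import (DEFAULT_BETA_WINDOWS, DEFAULT_CONTACT_CUTOFF,
                                HBOND_ENERGY_CUTOFF, BetaWindows, beta_report,
                                interstrand_hbonds, sidechain_contacts)

PARALLEL = "parallel"
ANTIPARALLEL = "antiparallel"


@dataclass(frozen=True)
class Criteria:
    """All clustering criteria in one configurable block."""

    hb_energy_cutoff: float = HBOND_ENERGY_CUTOFF
    min_hbonds: int = 2               # per single partner strand, not summed
    windows: BetaWindows = DEFAULT_BETA_WINDOWS
    min_beta_residues: int = 3
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF


DEFAULT_CRITERIA = Criteria()


def pair_orientation(frame: Frame, topology: Topology, peptide_a: int,
                     peptide_b: int) -> str | None:
    """Parallel/antiparallel verdict from end-to-end CA vector dot product.

    Positive dot product -> parallel.  An exactly perpendicular pair (dot 0)
    is counted antiparallel with a warning.  Zero-length vectors -> ``None``.
    """
    box = frame.box_edge

    def end_to_end(p):
        ca = topology.ca_indices(p)
        v = minimum_image(frame.coords[ca[-1]] - frame.coords[ca[0]], box)
        return v

    va, vb = end_to_end(peptide_a), end_to_end(peptide_b)
    if np.linalg.norm(va) < 1e-9 or np.linalg.norm(vb) < 1e-9:
        warnings.warn(f"zero-length end-to-end vector for pair ({peptide_a},{peptide_b})")
        return None
    dot = float(np.dot(va, vb))
    if dot == 0.0:
        warnings.warn(f"perpendicular strand pair ({peptide_a},{peptide_b}); "
                      "counted antiparallel")
    return PARALLEL if dot > 0 else ANTIPARALLEL


def strand_graph(frame: Frame, topology: Topology,
                 criteria: Criteria = DEFAULT_CRITERIA,
                 beta: "BetaStateReport | None" = None) -> nx.Graph:
    """Per-frame strand-attachment graph.

    Nodes are peptides passing the beta-strand test; an edge connects two
    peptides sharing >= ``criteria.min_hbonds`` accepted hydrogen bonds.
    Edge attributes: ``n_hbonds``, ``orientation``.
    """
    if beta is None:
        beta = beta_report(frame, topology, criteria.windows, criteria.min_beta_residues)
    g = nx.Graph()
    strand_peptides = [i for i, ok in enumerate(beta.peptide_flags) if ok]
    g.add_nodes_from(strand_peptides)
    g.graph["n_hbonds_total"] = 0

    # cheap prefilter: pairs whose closest CA atoms are far apart cannot
    # reach the DSSP energy cutoff (|E| ~ Q/r^2 < 0.5 beyond ~8 A)
    box = frame.box_edge
    ca = {p: frame.coords[topology.ca_indices(p)] for p in range(topology.n_chains)}
    total_hb = 0
    for idx, a in enumerate(range(topology.n_chains)):
        for b in range(a + 1, topology.n_chains):
            delta = minimum_image(ca[a][:, None, :] - ca[b][None, :, :], box)
            if np.min((delta ** 2).sum(-1)) > 14.0 ** 2:
                continue
            bonds = interstrand_hbonds(frame, topology, a, b,
                                       energy_cutoff=criteria.hb_energy_cutoff)
            total_hb += len(bonds)
            if a in g and b in g and len(bonds) >= criteria.min_hbonds:
                g.add_edge(a, b, n_hbonds=len(bonds),
                           orientation=pair_orientation(frame, topology, a, b))
    g.graph["n_hbonds_total"] = total_hb
    return g


@dataclass
class ClusterPartition:
    """Partition of all peptides into beta-sheet clusters and free monomers."""

    time: float
    n_peptides: int
    clusters: list                 # list of frozenset of peptide indices, size >= 2
    monomers: frozenset            # free peptides
    parallel_fractions: list       # per cluster, None if no oriented pair
    graph: nx.Graph | None = None

    def __post_init__(self):
        covered = set(self.monomers)
        for c in self.clusters:
            if len(c) < 2:
                raise ValueError("clusters must have size >= 2")
            if covered & set(c):
                raise ValueError("partition overlaps")
            covered |= set(c)
        if covered != set(range(self.n_peptides)):
            raise ValueError("partition does not cover all peptides")

    @property
    def sizes(self) -> list:
        """All aggregate sizes including monomers (as 1s)."""
        return sorted([len(c) for c in self.clusters] + [1] * len(self.monomers),
                      reverse=True)

    @property
    def largest(self) -> int:
        return max((len(c) for c in self.clusters), default=1 if self.monomers else 0)

    def size_histogram(self, max_size: int | None = None) -> np.ndarray:
        """N_n: count of aggregates of each size n (index 1..max)."""
        m = max_size or self.n_peptides
        h = np.zeros(m + 1, dtype=int)
        h[1] = len(self.monomers)
        for c in self.clusters:
            h[len(c)] += 1
        return h

    def groups(self) -> list:
        """Clusters plus singleton monomer groups, as frozensets."""
        return list(self.clusters) + [frozenset([m]) for m in self.monomers]


def _edge_parallel_fraction(graph: nx.Graph, nodes) -> float | None:
    n_par = n_tot = 0
    for a, b, data in graph.subgraph(nodes).edges(data=True):
        ori = data.get("orientation")
        if ori is None:
            continue
        n_tot += 1
        n_par += ori == PARALLEL
    return (n_par / n_tot) if n_tot else None


def clusters(graph: nx.Graph, n_peptides: int, time: float = 0.0,
             frame: Frame | None = None) -> ClusterPartition:
    """Connected components of size >= 2 are clusters; the rest are monomers."""
    comps = [frozenset(c) for c in nx.connected_components(graph)]
    clus = sorted((c for c in comps if len(c) >= 2), key=lambda c: (-len(c), min(c)))
    in_cluster = set().union(*clus) if clus else set()
    monomers = frozenset(set(range(n_peptides)) - in_cluster)
    pf = [_edge_parallel_fraction(graph, c) for c in clus]
    return ClusterPartition(time=time, n_peptides=n_peptides, clusters=clus,
                            monomers=monomers, parallel_fractions=pf, graph=graph)


def parallel_fraction(partition_or_graph) -> float | None:
    """Fraction of H-bonded strand pairs with parallel orientation.

    The antiparallel fraction is 1 minus this value by construction.
    Returns ``None`` (undefined) when there is no oriented pair.
    """
    g = getattr(partition_or_graph, "graph", partition_or_graph)
    if g is None:
        return None
    return _edge_parallel_fraction(g, list(g.nodes))


@dataclass
class FrameRecord:
    time: float
    partition: ClusterPartition
    n_hbonds: int
    n_contacts: int
    beta_fraction: float
    total_beta_residues: int
    largest_cluster_size: int
    parallel_fraction: float | None


def analyze_frame(frame: Frame, topology: Topology,
                  criteria: Criteria = DEFAULT_CRITERIA) -> FrameRecord:
    beta = beta_report(frame, topology, criteria.windows, criteria.min_beta_residues)
    g = strand_graph(frame, topology, criteria, beta=beta)
    part = clusters(g, topology.n_chains, time=frame.time, frame=frame)
    n_contacts, _ = sidechain_contacts(frame, topology, criteria.contact_cutoff)
    return FrameRecord(time=frame.time, partition=part,
                       n_hbonds=g.graph.get("n_hbonds_total", 0),
                       n_contacts=n_contacts,
                       beta_fraction=beta.beta_fraction,
                       total_beta_residues=beta.total_beta_residues,
                       largest_cluster_size=part.largest,
                       parallel_fraction=parallel_fraction(part))


def cluster_timeseries(trajectory: Trajectory,
                       criteria: Criteria = DEFAULT_CRITERIA):
    """Yield one :class:`FrameRecord` per frame (streaming)."""
    for frame in trajectory:
        yield analyze_frame(frame, trajectory.topology, criteria)


# ---------------------------------------------------------------------------
# polymorph classification
# ---------------------------------------------------------------------------

TWO_SHEET = "two_sheet"
THREE_PLUS_SHEET = "three_plus_sheet"
DISORDERED = "disordered"


def _ladder_subgraph(graph: nx.Graph) -> nx.Graph:
    """Keep each node's two strongest edges; an edge survives iff kept by both.

    This prunes the strand graph to ladder topology: every strand retains at
    most two sheet-neighbours, branch nodes split sheets deterministically
    (ties broken by neighbour index).
    """
    def top2(node):
        ranked = sorted(graph.edges(node, data=True),
                        key=lambda e: (-e[2].get("n_hbonds", 0), min(e[0], e[1]),
                                       max(e[0], e[1])))
        return {frozenset((a, b)) for a, b, _ in ranked[:2]}

    kept_per_node = {node: top2(node) for node in graph.nodes}
    g2 = nx.Graph()
    g2.add_nodes_from(graph.nodes)
    for a, b in graph.edges:
        e = frozenset((a, b))
        if e in kept_per_node[a] and e in kept_per_node[b]:
            g2.add_edge(a, b)
    return g2


def count_sheets(graph: nx.Graph, min_sheet_len: int = 3) -> int:
    """Number of maximal ladders (sheets) with >= ``min_sheet_len`` strands."""
    ladders = _ladder_subgraph(graph)
    return sum(1 for c in nx.connected_components(ladders) if len(c) >= min_sheet_len)


def classify_polymorph(partition: ClusterPartition, min_sheet_len: int = 3,
                       min_cluster_size: int = 4) -> str:
    """Classify a final-frame partition into the two polymorph families.

    Sheets are counted as maximal ladder components of the strand graph
    (every strand <= 2 sheet-neighbours; branch nodes split sheets).  Two
    sheets -> ``two_sheet``; three or more -> ``three_plus_sheet``; no
    cluster of at least ``min_cluster_size`` peptides -> ``disordered``.
    """
    if partition.graph is None:
        raise ValueError("partition lacks its strand graph")
    if partition.largest < min_cluster_size:
        return DISORDERED
    n = count_sheets(partition.graph, min_sheet_len)
    if n >= 3:
        return THREE_PLUS_SHEET
    if n == 2:
        return TWO_SHEET
    return DISORDERED if n == 0 else TWO_SHEET  # single long sheet: fibril-like
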