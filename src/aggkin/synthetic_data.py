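"""Synthetic inputs with known ground truth.

Idealized coarse-grained structures (beta sheets, random coils), scripted
trajectories whose partitions and kinetic events are known exactly, and an
exact stochastic (Gillespie) aggregation simulator with optional
detailed-balance mode targeting a prescribed free-energy profile.

Every structural fixture is self-verified through the analysis stack
(structure_metrics / sheet_clustering) before it is returned.
"""

from __future__ import annotations

import functools
import math
import random
from dataclasses import dataclass, field

import numpy as np

from .cg_model import DEFAULT_SEQUENCE, ROLES, Frame, Topology, Trajectory
from .kinetics import (FRAGMENTATION, FUSION, MONOMER_ADDITION, MONOMER_LOSS,
                       MONOMERS_TO_OLIGOMER, OLIGOMER_TO_MONOMERS)
from .sheet_clustering import (ANTIPARALLEL, DEFAULT_CRITERIA, PARALLEL,
                               Criteria, clusters, strand_graph)
from .structure_metrics import beta_report

# backbone internal coordinates (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O, B_N_H, B_CA_SC = 1.458, 1.525, 1.329, 1.231, 1.000, 2.400
A_N_CA_C, A_CA_C_N, A_C_N_CA = 111.0, 116.2, 121.7
A_CA_C_O, A_C_N_H, A_N_CA_SC = 120.8, 119.5, 110.0

# sheet torsions; chosen to sit inside the default beta windows and to give
# robust DSSP-criterion hydrogen bonds after registry optimization
SHEET_TORSIONS = {PARALLEL: (-119.0, 113.0), ANTIPARALLEL: (-139.0, 135.0)}
SHEET_SPACING = 4.8  # Angstrom between adjacent strands


class FixtureError(RuntimeError):
    """A generated fixture failed its self-verification."""


# ---------------------------------------------------------------------------
# internal-coordinate chain building (NeRF)
# ---------------------------------------------------------------------------

def _place(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d with |cd|=bond, angle(bcd)=angle, torsion(abcd)=torsion."""
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d_local = np.array([-bond * math.cos(ang),
                        bond * math.sin(ang) * math.cos(tor),
                        bond * math.sin(ang) * math.sin(tor)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_strand(sequence: str = DEFAULT_SEQUENCE, phi=-119.0, psi=113.0,
                 omega: float = 180.0) -> np.ndarray:
    """Backbone + SC coordinates for one peptide with the given torsions.

    ``phi``/``psi`` may be scalars or per-residue sequences.  Returns an
    (n_res * 6, 3) array in the canonical role order per residue.
    """
    n_res = len(sequence)
    phis = np.full(n_res, phi, dtype=float) if np.isscalar(phi) else np.asarray(phi, float)
    psis = np.full(n_res, psi, dtype=float) if np.isscalar(psi) else np.asarray(psi, float)

    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([B_N_CA, 0.0, 0.0])]
    c0 = _place(np.array([0.0, 1.0, 0.0]), N[0], CA[0], B_CA_C, A_N_CA_C, 0.0)
    C = [c0]
    for i in range(1, n_res):
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1], B_C_N, A_CA_C_N, psis[i - 1]))
        CA.append(_place(CA[i - 1], C[i - 1], N[i], B_N_CA, A_C_N_CA, omega))
        C.append(_place(C[i - 1], N[i], CA[i], B_CA_C, A_N_CA_C, phis[i]))

    coords = np.zeros((n_res * 6, 3))
    for i in range(n_res):
        psi_eff = psis[i] if i < n_res - 1 else psis[-1]
        O = _place(N[i], CA[i], C[i], B_C_O, A_CA_C_O, psi_eff + 180.0)
        if i > 0:
            H = _place(CA[i - 1], C[i - 1], N[i], B_N_H, A_C_N_H, 0.0)
        else:
            H = _place(C[0], CA[0], N[0], B_N_H, A_C_N_H, 180.0)
        SC = _place(C[i], N[i], CA[i], B_CA_SC, A_N_CA_SC, -120.0)
        if sequence[i] == "G":
            SC = CA[i].copy()
        base = i * 6
        for j, xyz in enumerate((N[i], H, CA[i], C[i], O, SC)):
            coords[base + j] = xyz
    return coords


def _single_chain_frame(coords, box_edge=200.0, sequence=DEFAULT_SEQUENCE):
    top = Topology.from_sequences([sequence])
    centered = coords - coords.mean(axis=0) + box_edge / 2.0
    return Frame(coords=centered, box_edge=box_edge), top


def _rotate_about(coords, axis, center, angle_rad):
    axis = axis / np.linalg.norm(axis)
    k = axis
    v = coords - center
    cos, sin = math.cos(angle_rad), math.sin(angle_rad)
    rot = (v * cos + np.cross(k, v) * sin
           + np.outer(v @ k, k) * (1.0 - cos))
    return rot + center


@functools.lru_cache(maxsize=8)
def _sheet_geometry(orientation: str, sequence: str, spacing: float):
    """Optimal inter-strand offset for a two-strand sheet of given orientation.

    Scans the registry shift along the strand axis (and a small spacing
    range) for the placement maximizing the number of DSSP-criterion
    hydrogen bonds between the pair.  Returns (base_coords, partner_coords,
    stack_offset) with the partner already in register; additional strands
    are generated by repeating the transformation.
    """
    from .structure_metrics import interstrand_hbonds

    phi, psi = SHEET_TORSIONS[orientation]
    base = build_strand(sequence, phi, psi)
    n_res = len(sequence)
    ca = base[[i * 6 + 2 for i in range(n_res)]]
    axis = ca[-1] - ca[0]
    axis = axis / np.linalg.norm(axis)
    # inter-strand direction: H-bond donor direction of a mid-strand residue,
    # orthogonalized against the strand axis
    mid = n_res // 2
    hvec = base[mid * 6 + 1] - base[mid * 6 + 0]
    u = hvec - (hvec @ axis) * axis
    u = u / np.linalg.norm(u)

    centroid = base.mean(axis=0)
    top2 = Topology.from_sequences([sequence, sequence])

    def partner(d, s):
        if orientation == PARALLEL:
            p = base + d * u + s * axis
        else:
            p = _rotate_about(base, u, centroid, math.pi) + d * u + s * axis
        return p

    best = None
    for d in np.arange(spacing - 0.6, spacing + 0.61, 0.15):
        for s in np.arange(-3.5, 3.51, 0.25):
            p = partner(d, s)
            stacked = np.vstack([base, p])
            frame = Frame(coords=stacked - stacked.mean(0) + 100.0, box_edge=200.0)
            nhb = len(interstrand_hbonds(frame, top2, 0, 1))
            if best is None or nhb > best[0]:
                best = (nhb, d, s)
    nhb, d, s = best
    if nhb < 2:
        raise FixtureError(
            f"could not realize a {orientation} sheet with >= 2 hydrogen bonds")
    return base, partner(d, s), d * u + s * axis, u


def build_ideal_sheet(n_strands: int, orientation: str = PARALLEL,
                      spacing: float = SHEET_SPACING, box_edge: float = 200.0,
                      sequence: str = DEFAULT_SEQUENCE, time: float = 0.0,
                      criteria: Criteria = DEFAULT_CRITERIA,
                      verify: bool = True):
    """An idealized beta sheet of ``n_strands`` peptides.

    Returns ``(frame, topology)``.  The construction is verified through the
    analysis stack: every strand passes the beta-residue rule, every adjacent
    pair shares >= 2 DSSP-criterion hydrogen bonds with the requested
    orientation; otherwise a :class:`FixtureError` is raised.
    """
    if not 2 <= n_strands <= 20:
        raise ValueError("n_strands must be between 2 and 20")
    if orientation not in (PARALLEL, ANTIPARALLEL):
        raise ValueError(f"unknown orientation {orientation!r}")
    base, partner, offset, _u = _sheet_geometry(orientation, sequence, spacing)
    strands = []
    for k in range(n_strands):
        if orientation == PARALLEL:
            strands.append(base + k * offset)
        else:
            ref = base if k % 2 == 0 else partner - offset
            strands.append(ref + k * offset)
    coords = np.vstack(strands)
    coords = coords - coords.mean(axis=0) + box_edge / 2.0
    topology = Topology.from_sequences([sequence] * n_strands)
    frame = Frame(coords=coords, box_edge=box_edge, time=time)
    if verify:
        _verify_sheet(frame, topology, orientation, criteria)
    return frame, topology


def _verify_sheet(frame, topology, orientation, criteria):
    beta = beta_report(frame, topology, criteria.windows, criteria.min_beta_residues)
    if not all(beta.peptide_flags):
        raise FixtureError("sheet fixture: some strands fail the beta-residue rule")
    g = strand_graph(frame, topology, criteria, beta=beta)
    n = topology.n_chains
    for a in range(n - 1):
        if not g.has_edge(a, a + 1):
            raise FixtureError(f"sheet fixture: strands {a},{a + 1} not attached")
        if g.edges[a, a + 1]["n_hbonds"] < criteria.min_hbonds:
            raise FixtureError("sheet fixture: too few hydrogen bonds")
        if g.edges[a, a + 1]["orientation"] != orientation:
            raise FixtureError("sheet fixture: wrong strand orientation")


def build_random_coil(n_peptides: int, box_edge: float = 200.0,
                      min_separation: float = 10.0, seed: int | None = None,
                      sequence: str = DEFAULT_SEQUENCE,
                      criteria: Criteria = DEFAULT_CRITERIA, verify: bool = True):
    """Self-avoiding random-coil monomers with a guaranteed empty strand graph.

    Per-residue torsions are drawn outside the beta windows, so no peptide
    can pass the beta-state test regardless of packing.  Returns
    ``(frame, topology)``.
    """
    if min_separation > box_edge / 2.0:
        raise ValueError(
            "infeasible: min_separation exceeds half the box edge (minimum image)")
    rng = np.random.default_rng(seed)
    placed_centroids: list = []
    coords_all = []
    n_res = len(sequence)
    for _ in range(n_peptides):
        phis = rng.uniform(30.0, 120.0, size=n_res)    # outside phi beta windows
        psis = rng.uniform(-120.0, -30.0, size=n_res)  # outside psi beta windows
        pep = build_strand(sequence, phis, psis)
        pep = pep - pep.mean(axis=0)
        # random rigid rotation
        axis = rng.normal(size=3)
        pep = _rotate_about(pep, axis, np.zeros(3), rng.uniform(0, 2 * math.pi))
        radius = float(np.linalg.norm(pep, axis=1).max())
        ok = False
        for _attempt in range(5000):
            c = rng.uniform(0.0, box_edge, size=3)
            feasible = True
            for other, r_other in placed_centroids:
                delta = c - other
                delta -= box_edge * np.round(delta / box_edge)
                if np.linalg.norm(delta) < min_separation + radius + r_other:
                    feasible = False
                    break
            if feasible:
                ok = True
                break
        if not ok:
            raise ValueError("infeasible placement density for random coil")
        placed_centroids.append((c, radius))
        coords_all.append(pep + c)
    topology = Topology.from_sequences([sequence] * n_peptides)
    frame = Frame(coords=np.vstack(coords_all), box_edge=box_edge)
    if verify:
        beta = beta_report(frame, topology, criteria.windows, criteria.min_beta_residues)
        g = strand_graph(frame, topology, criteria, beta=beta)
        if g.number_of_edges() != 0 or any(beta.peptide_flags):
            raise FixtureError("random-coil fixture is not strand-free")
    return frame, topology


def merge_structures(pieces, box_edge: float = 200.0, time: float = 0.0):
    """Combine (frame, topology, offset) pieces into one frame/topology."""
    sequences, coords = [], []
    for frame, topology, offset in pieces:
        sequences.extend(chain.sequence for chain in topology.chains)
        coords.append(frame.coords + np.asarray(offset, dtype=float))
    topology = Topology.from_sequences(sequences)
    return Frame(coords=np.vstack(coords), box_edge=box_edge, time=time), topology


# ---------------------------------------------------------------------------
# scripted scenarios
# ---------------------------------------------------------------------------

@dataclass
class ScenarioScript:
    """Scripted aggregation/disassembly with exact ground truth.

    Directives are ``(frame_index, op, *args)`` applied between frames
    ``frame_index - 1`` and ``frame_index``:

    - ``("form", peptides)``          k >= 2 monomers -> new cluster
    - ``("add", cluster, peptide)``   monomer addition
    - ``("remove", cluster, peptide)``monomer loss (cluster stays >= 2)
    - ``("fuse", cluster, cluster)``  oligomer fusion
    - ``("split", cluster, subset)``  fragmentation (both parts >= 2)
    - ``("dissolve", cluster)``       oligomer -> monomers
    """

    n_peptides: int = 20
    n_frames: int = 10
    frame_dt: float = 7.5
    box_edge: float = 200.0
    noise: float = 0.0
    seed: int = 0
    orientation: str = PARALLEL
    sequence: str = DEFAULT_SEQUENCE
    directives: list = field(default_factory=list)

    def simulate(self):
        """Ground-truth partitions per frame and typed events per interval.

        Returns ``(partitions, events)`` where ``partitions[i]`` is a list of
        groups (frozensets, clusters and singleton monomers) and ``events``
        is a list of ``(frame_index, type, sizes_before, sizes_after)``.
        """
        free = set(range(self.n_peptides))
        clusters_state: dict = {}
        next_id = 0
        by_frame: dict = {}
        for fi, op, *args in self.directives:
            if not 1 <= fi < self.n_frames:
                raise ValueError(f"directive frame {fi} out of range")
            by_frame.setdefault(fi, []).append((op, args))

        def snapshot():
            groups = [frozenset(v) for v in clusters_state.values()]
            groups += [frozenset([p]) for p in sorted(free)]
            return groups

        partitions = [snapshot()]
        events = []
        for fi in range(1, self.n_frames):
            for op, args in by_frame.get(fi, []):
                if op == "form":
                    (peptides,) = args
                    peptides = set(peptides)
                    if len(peptides) < 2 or not peptides <= free:
                        raise ValueError(f"form: invalid peptides {peptides}")
                    free -= peptides
                    clusters_state[next_id] = set(peptides)
                    etype = MONOMER_ADDITION if len(peptides) == 2 else MONOMERS_TO_OLIGOMER
                    events.append((fi, etype,
                                   tuple([1] * len(peptides)), (len(peptides),)))
                    next_id += 1
                elif op == "add":
                    cid, pep = args
                    if pep not in free:
                        raise ValueError(f"add: peptide {pep} not free")
                    n = len(clusters_state[cid])
                    free.discard(pep)
                    clusters_state[cid].add(pep)
                    events.append((fi, MONOMER_ADDITION, (n, 1), (n + 1,)))
                elif op == "remove":
                    cid, pep = args
                    c = clusters_state[cid]
                    if pep not in c or len(c) < 3:
                        raise ValueError("remove: needs member of a cluster >= 3")
                    c.discard(pep)
                    free.add(pep)
                    events.append((fi, MONOMER_LOSS, (len(c) + 1,), (len(c), 1)))
                elif op == "fuse":
                    c1, c2 = args
                    a, b = len(clusters_state[c1]), len(clusters_state[c2])
                    clusters_state[c1] |= clusters_state.pop(c2)
                    events.append((fi, FUSION, tuple(sorted((a, b), reverse=True)),
                                   (a + b,)))
                elif op == "split":
                    cid, subset = args
                    subset = set(subset)
                    c = clusters_state[cid]
                    if not subset < c or len(subset) < 2 or len(c - subset) < 2:
                        raise ValueError("split: both fragments must have >= 2 peptides")
                    clusters_state[cid] = c - subset
                    clusters_state[next_id] = subset
                    next_id += 1
                    events.append((fi, FRAGMENTATION, (len(c),),
                                   tuple(sorted((len(c) - len(subset), len(subset)),
                                                reverse=True))))
                elif op == "dissolve":
                    cid = args[0]
                    c = clusters_state.pop(cid)
                    free |= c
                    etype = MONOMER_LOSS if len(c) == 2 else OLIGOMER_TO_MONOMERS
                    events.append((fi, etype, (len(c),), tuple([1] * len(c))))
                else:
                    raise ValueError(f"unknown directive {op!r}")
            partitions.append(snapshot())
        return partitions, events

    @staticmethod
    def growth(n_peptides: int = 20, **kwargs) -> "ScenarioScript":
        """Coil -> dimer -> ... -> full aggregate by single additions."""
        directives = [(1, "form", [0, 1])]
        for i in range(2, n_peptides):
            directives.append((i, "add", 0, i))
        return ScenarioScript(n_peptides=n_peptides, n_frames=n_peptides + 1,
                              directives=directives, **kwargs)


def script_trajectory(script: ScenarioScript,
                      criteria: Criteria = DEFAULT_CRITERIA):
    """Geometric realization of a scenario script.

    Returns ``(trajectory, partitions, events)``; the partitions/events are
    the script's ground truth, which the clustering + kinetics stack must
    reproduce from the generated coordinates.
    """
    partitions, events = script.simulate()
    topology = Topology.from_sequences([script.sequence] * script.n_peptides)
    rng = np.random.default_rng(script.seed)

    n_res = len(script.sequence)
    # per-peptide frozen coil conformations for monomer frames
    coil_confs = []
    for _ in range(script.n_peptides):
        phis = rng.uniform(30.0, 120.0, size=n_res)
        psis = rng.uniform(-120.0, -30.0, size=n_res)
        pep = build_strand(script.sequence, phis, psis)
        coil_confs.append(pep - pep.mean(axis=0))

    base, partner, offset, _u = _sheet_geometry(script.orientation,
                                                script.sequence, SHEET_SPACING)

    def cluster_coords(members):
        members = sorted(members)
        strands = []
        for k in range(len(members)):
            if script.orientation == PARALLEL:
                strands.append(base + k * offset)
            else:
                ref = base if k % 2 == 0 else partner - offset
                strands.append(ref + k * offset)
        return members, [s - np.vstack(strands).mean(axis=0) for s in strands]

    frames = []
    margin = 18.0
    for fi, groups in enumerate(partitions):
        # shelf-pack entity bounding boxes into the box with clearance
        entities = []
        for g in sorted(groups, key=lambda g: (-len(g), min(g))):
            if len(g) == 1:
                (p,) = g
                entities.append(([p], [coil_confs[p]]))
            else:
                entities.append(cluster_coords(g))
        coords = np.zeros((topology.n_atoms, 3))
        x = y = z = margin
        row_depth = layer_depth = 0.0
        for members, parts in entities:
            stacked = np.vstack(parts)
            lo, hi = stacked.min(axis=0), stacked.max(axis=0)
            ext = hi - lo
            if x + ext[0] > script.box_edge - margin:
                x = margin
                y += row_depth + margin
                row_depth = 0.0
            if y + ext[1] > script.box_edge - margin:
                y = margin
                z += layer_depth + margin
                layer_depth = 0.0
            origin = np.array([x, y, z]) - lo
            for pep, part in zip(members, parts):
                idx = topology.chain_atom_indices(pep)
                coords[idx] = part + origin
            x += ext[0] + margin
            row_depth = max(row_depth, ext[1])
            layer_depth = max(layer_depth, ext[2])
        if script.noise > 0:
            coords = coords + rng.normal(0.0, script.noise, size=coords.shape)
        frames.append(Frame(coords=coords, box_edge=script.box_edge,
                            time=fi * script.frame_dt))
    traj = Trajectory(topology=topology, frames=frames,
                      save_interval=script.frame_dt)
    return traj, partitions, events


# ---------------------------------------------------------------------------
# Gillespie aggregation simulator
# ---------------------------------------------------------------------------

def _as_rate_fn(rate):
    return rate if callable(rate) else (lambda *args, _r=float(rate): _r)


@dataclass
class KMCConfig:
    """Rate kernels and run parameters for the stochastic simulator."""

    n_peptides: int = 20
    attach_rate: object = 1.0       # k+(n): per (cluster, monomer); k+(1) dimerization
    detach_rate: object = 0.2       # k-(n): per cluster
    fusion_rate: object = 0.0       # f(a, b): per cluster pair
    fragmentation_rate: object = 0.0  # g(a, b): per split channel
    t_max: float = float("inf")
    max_events: int = 10_000
    seed: int = 0
    snapshot_stride: int = 1
    snapshot_interval: float | None = None  # time-grid sampling (detailed balance)
    detailed_balance: bool = False
    target_profile: np.ndarray | None = None  # F(n) in kT, index 1..n_peptides

    def __post_init__(self):
        if self.detailed_balance and self.target_profile is None:
            raise ValueError("detailed-balance mode needs a target profile")


@dataclass
class KMCTrace:
    """Event log + state snapshots of one stochastic aggregation run."""

    config: KMCConfig
    event_log: list                 # (time, type, sizes_before, sizes_after)
    snapshot_times: np.ndarray
    snapshots: list | None = None   # labeled mode: list of group lists
    tracked_sizes: np.ndarray | None = None  # detailed-balance mode
    occupancy_time: np.ndarray | None = None  # exact per-size residence time

    @property
    def n_events(self) -> int:
        return len(self.event_log)

    def partitions(self):
        if self.snapshots is None:
            raise ValueError("labeled snapshots unavailable in detailed-balance mode")
        return self.snapshots

    def frame_sizes(self):
        """Per-snapshot aggregate-size lists (monomers as 1s)."""
        n = self.config.n_peptides
        if self.tracked_sizes is not None:
            out = []
            for s in self.tracked_sizes:
                out.append([int(s)] + [1] * (n - int(s)) if s >= 2 else [1] * n)
            return out
        return [sorted((len(g) for g in snap), reverse=True) for snap in self.snapshots]

    def largest_sizes(self):
        if self.tracked_sizes is not None:
            return np.maximum(self.tracked_sizes, 1)
        return np.array([max((len(g) for g in snap), default=1) for snap in self.snapshots])


def _gillespie_detailed_balance(config: KMCConfig) -> KMCTrace:
    """Birth-death chain over the tracked-aggregate size with equilibrium
    distribution exp(-F(n)) prescribed by the target profile."""
    n_max = config.n_peptides
    f = np.asarray(config.target_profile, dtype=float)
    if f.shape[0] != n_max + 1:
        raise ValueError("target profile must have length n_peptides + 1 (index 0 unused)")
    attach = _as_rate_fn(config.attach_rate)
    a = np.zeros(n_max + 1)
    b = np.zeros(n_max + 1)
    for n in range(1, n_max):
        a[n] = attach(n)
    for n in range(2, n_max + 1):
        b[n] = a[n - 1] * math.exp(f[n] - f[n - 1])

    rng = random.Random(config.seed)
    t = 0.0
    n = 1
    sizes = []
    times = []
    log = []
    keep_log = config.max_events <= 200_000
    interval = config.snapshot_interval
    stride = config.snapshot_stride
    occupancy = np.zeros(n_max + 1)
    next_out = 0.0
    for step in range(config.max_events):
        total = a[n] + b[n]
        if total <= 0.0:
            break
        t_new = t + rng.expovariate(total)
        occupancy[n] += min(t_new, config.t_max) - t
        if interval is not None:
            # sample the CTMC path on a fixed time grid: the state during
            # (t, t_new] is still n, so grid points in that span record n
            while next_out < t_new and next_out <= config.t_max:
                sizes.append(n)
                times.append(next_out)
                next_out += interval
        t = t_new
        if t > config.t_max:
            break
        if rng.random() * total < a[n]:
            before = (n, 1) if n >= 2 else (1, 1)
            n += 1
            etype = MONOMER_ADDITION
            after = (n,)
        else:
            before = (n,)
            n -= 1
            etype = MONOMER_LOSS
            after = (n, 1) if n >= 2 else (1, 1)
        if keep_log:
            log.append((t, etype, before, after))
        if interval is None and step % stride == 0:
            sizes.append(n)
            times.append(t)
    return KMCTrace(config=config, event_log=log,
                    snapshot_times=np.array(times),
                    tracked_sizes=np.array(sizes, dtype=int),
                    occupancy_time=occupancy)


def _gillespie_labeled(config: KMCConfig) -> KMCTrace:
    """Exact next-event simulation over labeled peptide clusters."""
    rng = random.Random(config.seed)
    n = config.n_peptides
    attach = _as_rate_fn(config.attach_rate)
    detach = _as_rate_fn(config.detach_rate)
    fuse = _as_rate_fn(config.fusion_rate)
    frag = _as_rate_fn(config.fragmentation_rate)

    free = set(range(n))
    clus: dict = {}
    next_id = 0
    t = 0.0
    log = []
    snaps = []
    snap_times = []

    def snapshot():
        groups = [frozenset(v) for v in clus.values()]
        groups += [frozenset([p]) for p in free]
        snaps.append(groups)
        snap_times.append(t)

    snapshot()
    for step in range(config.max_events):
        reactions = []  # (propensity, kind, payload)
        nf = len(free)
        if nf >= 2:
            reactions.append((attach(1) * nf * (nf - 1) / 2.0, "dimer", None))
        ids = list(clus.keys())
        for cid in ids:
            m = len(clus[cid])
            if nf >= 1:
                reactions.append((attach(m) * nf, "attach", cid))
            reactions.append((detach(m), "detach", cid))
            for a_size in range(2, m // 2 + 1):
                if m - a_size >= 2:
                    reactions.append((frag(a_size, m - a_size), "frag", (cid, a_size)))
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                a_sz, b_sz = len(clus[ids[i]]), len(clus[ids[j]])
                reactions.append((fuse(a_sz, b_sz), "fuse", (ids[i], ids[j])))
        total = sum(r[0] for r in reactions)
        if total <= 0.0:
            break
        t += rng.expovariate(total)
        if t > config.t_max:
            break
        pick = rng.random() * total
        acc = 0.0
        for prop, kind, payload in reactions:
            acc += prop
            if pick < acc:
                break
        if kind == "dimer":
            pair = rng.sample(sorted(free), 2)
            free -= set(pair)
            clus[next_id] = set(pair)
            next_id += 1
            log.append((t, MONOMER_ADDITION, (1, 1), (2,)))
        elif kind == "attach":
            cid = payload
            pep = rng.choice(sorted(free))
            m = len(clus[cid])
            free.discard(pep)
            clus[cid].add(pep)
            log.append((t, MONOMER_ADDITION, (m, 1), (m + 1,)))
        elif kind == "detach":
            cid = payload
            m = len(clus[cid])
            if m == 2:
                members = clus.pop(cid)
                free |= members
                log.append((t, MONOMER_LOSS, (2,), (1, 1)))
            else:
                pep = rng.choice(sorted(clus[cid]))
                clus[cid].discard(pep)
                free.add(pep)
                log.append((t, MONOMER_LOSS, (m,), (m - 1, 1)))
        elif kind == "frag":
            cid, a_size = payload
            members = sorted(clus[cid])
            m = len(members)
            part = set(rng.sample(members, a_size))
            clus[cid] = set(members) - part
            clus[next_id] = part
            next_id += 1
            log.append((t, FRAGMENTATION, (m,),
                        tuple(sorted((m - a_size, a_size), reverse=True))))
        else:  # fuse
            c1, c2 = payload
            a_sz, b_sz = len(clus[c1]), len(clus[c2])
            clus[c1] |= clus.pop(c2)
            log.append((t, FUSION, tuple(sorted((a_sz, b_sz), reverse=True)),
                        (a_sz + b_sz,)))
        # mass conservation invariant
        assert sum(len(c) for c in clus.values()) + len(free) == n
        if (step + 1) % config.snapshot_stride == 0:
            snapshot()
    return KMCTrace(config=config, event_log=log,
                    snapshot_times=np.array(snap_times), snapshots=snaps)


def gillespie_aggregation(config: KMCConfig) -> KMCTrace:
    """Run the exact stochastic aggregation simulation for ``config``."""
    if config.detailed_balance:
        return _gillespie_detailed_balance(config)
    return _gillespie_labeled(config)


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def paper_like_profile(n_peptides: int = 20) -> np.ndarray:
    """Default target free-energy profile: barrier at size 5, downhill beyond,
    finite-size rise at the boundary.  kT units, index = aggregate size."""
    f = np.array([np.nan, 0.0, 1.3, 2.1, 2.6, 3.0, 2.6, 2.0, 1.4, 0.9, 0.5,
                  0.2, 0.0, 0.1, 0.3, 0.6, 1.0, 1.4, 1.9, 2.4, 3.0])
    if n_peptides != 20:
        raise ValueError("the paper-like preset is defined for 20 peptides")
    return f


def paper_like_config(seed: int = 0, max_events: int = 1_000_000,
                      snapshot_interval: float = 50.0, **overrides) -> KMCConfig:
    """Detailed-balance preset with the barrier-at-5 profile.

    The default snapshot interval (~100 event holding times) decorrelates
    successive samples so the occupancy estimator is near-multinomial.
    """
    kwargs = dict(n_peptides=20, attach_rate=1.0, detailed_balance=True,
                  target_profile=paper_like_profile(), seed=seed,
                  max_events=max_events, snapshot_interval=snapshot_interval)
    kwargs.update(overrides)
    return KMCConfig(**kwargs)


def kinetic_preset_config(seed: int = 0, max_events: int = 10_000,
                          **overrides) -> KMCConfig:
    """Labeled-cluster preset exercising every event type."""
    kwargs = dict(n_peptides=20, attach_rate=1.0, detach_rate=0.6,
                  fusion_rate=0.3, fragmentation_rate=0.08, seed=seed,
                  max_events=max_events)
    kwargs.update(overrides)
    return KMCConfig(**kwargs)
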