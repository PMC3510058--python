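"""Domain types, trajectory/topology I/O, unit conversions and geometry primitives.

Coarse-grained peptide model: five backbone atoms per residue (N, H, CA, C, O)
plus a single side-chain bead (SC).  Coordinates are stored in Angstrom, times
in picoseconds; conversions happen only at I/O edges.  All inter-atomic
distances use the minimum-image convention on the cubic periodic box.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23

#: canonical atom roles, in the order they are written per residue
ROLES = ("N", "H", "CA", "C", "O", "SC")

#: alternate PDB atom names accepted for each role
_ROLE_ALIASES = {
    "N": "N",
    "H": "H",
    "HN": "H",
    "H1": "H",
    "CA": "CA",
    "C": "C",
    "O": "O",
    "OXT": None,  # ignored terminal oxygen
    "SC": "SC",
    "CB": "SC",
}

DEFAULT_SEQUENCE = "GNNQQNY"

_AA3 = {
    "G": "GLY", "A": "ALA", "N": "ASN", "Q": "GLN", "Y": "TYR",
    "S": "SER", "T": "THR", "V": "VAL", "L": "LEU", "I": "ILE",
    "F": "PHE", "W": "TRP", "M": "MET", "C": "CYS", "P": "PRO",
    "K": "LYS", "R": "ARG", "H": "HIS", "D": "ASP", "E": "GLU",
}
_AA1 = {v: k for k, v in _AA3.items()}


class TopologyError(ValueError):
    pass


class TrajectoryError(ValueError):
    pass


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def concentration(n_molecules: int, box_edge: float) -> float:
    """Molar concentration, in mM, of ``n_molecules`` in a cubic box.

    Parameters
    ----------
    n_molecules : number of solute molecules in the box (>= 0).
    box_edge : cubic box edge length in Angstrom (> 0).
    """
    if box_edge <= 0:
        raise ValueError(f"box edge must be positive, got {box_edge}")
    if n_molecules < 0:
        raise ValueError(f"molecule count must be >= 0, got {n_molecules}")
    volume_litres = (box_edge * 1e-9) ** 3  # 1 A = 1e-9 dm; dm^3 = L
    molar = n_molecules / (AVOGADRO * volume_litres)
    return molar * 1e3  # M -> mM


def box_volume_litres(box_edge: float) -> float:
    """Volume of a cubic box (edge in Angstrom) in litres."""
    if box_edge <= 0:
        raise ValueError(f"box edge must be positive, got {box_edge}")
    return (box_edge * 1e-9) ** 3


@dataclass(frozen=True)
class Duration:
    """A simulated duration stored in femtoseconds with unit helpers."""

    fs: float

    @property
    def ps(self) -> float:
        return self.fs * 1e-3

    @property
    def ns(self) -> float:
        return self.fs * 1e-6

    def render(self) -> tuple[float, str]:
        """Value in the largest unit (fs/ps/ns) in which it is >= 1."""
        if self.fs == 0:
            return 0.0, "fs"
        for value, unit in ((self.ns, "ns"), (self.ps, "ps")):
            if value >= 1:
                return value, unit
        return self.fs, "fs"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        value, unit = self.render()
        return f"{value:g} {unit}"


def steps_to_time(n_steps: int, dt_fs: float) -> Duration:
    """Duration of ``n_steps`` integration steps of ``dt_fs`` femtoseconds."""
    if n_steps < 0:
        raise ValueError("step count must be >= 0")
    if dt_fs <= 0:
        raise ValueError("time step must be positive")
    return Duration(fs=n_steps * dt_fs)


# ---------------------------------------------------------------------------
# periodic-boundary geometry
# ---------------------------------------------------------------------------

def minimum_image(delta: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box_edge is None:
        return delta
    return delta - box_edge * np.round(delta / box_edge)


def pair_distances(a: np.ndarray, b: np.ndarray, box_edge: float | None) -> np.ndarray:
    """Minimum-image distance matrix between two coordinate sets (n,3)/(m,3)."""
    delta = a[:, None, :] - b[None, :, :]
    delta = minimum_image(delta, box_edge)
    return np.sqrt((delta ** 2).sum(axis=-1))


# ---------------------------------------------------------------------------
# topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Residue:
    name: str
    index: int                       # 0-based position within the chain
    atoms: dict                      # role -> global atom index

    def atom(self, role: str) -> int:
        return self.atoms[role]


@dataclass(frozen=True)
class Chain:
    index: int
    residues: tuple

    @property
    def sequence(self) -> str:
        return "".join(_AA1.get(r.name, "X") for r in self.residues)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Topology:
    chains: tuple
    n_atoms: int
    warnings: tuple = ()

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)

    def residue(self, chain: int, res: int) -> Residue:
        return self.chains[chain].residues[res]

    def chain_atom_indices(self, chain: int) -> np.ndarray:
        idx = []
        for res in self.chains[chain].residues:
            idx.extend(sorted(res.atoms.values()))
        return np.array(sorted(set(idx)), dtype=int)

    def role_indices(self, role: str) -> np.ndarray:
        """Global atom indices of ``role`` for every residue, chain-major order."""
        out = []
        for chain in self.chains:
            for res in chain.residues:
                out.append(res.atoms[role])
        return np.array(out, dtype=int)

    def ca_indices(self, chain: int) -> np.ndarray:
        return np.array([r.atoms["CA"] for r in self.chains[chain].residues], dtype=int)

    @staticmethod
    def from_sequences(sequences) -> "Topology":
        """Build a coarse-grained topology from one-letter sequences.

        Atoms are laid out chain-major, residue-major, role order ``ROLES``.
        """
        chains = []
        warnings = []
        atom = 0
        for ci, seq in enumerate(sequences):
            residues = []
            for ri, aa in enumerate(seq):
                roles = {}
                for role in ROLES:
                    roles[role] = atom
                    atom += 1
                if aa == "G":
                    warnings.append(f"chain {ci} residue {ri}: glycine SC bead coincides with CA")
                residues.append(Residue(name=_AA3.get(aa, "UNK"), index=ri, atoms=roles))
            chains.append(Chain(index=ci, residues=tuple(residues)))
        return Topology(chains=tuple(chains), n_atoms=atom, warnings=tuple(warnings))


def load_topology(path: str) -> Topology:
    """Parse a coarse-grained PDB file into a :class:`Topology`.

    Chain identity is positional (order of appearance / TER records), not the
    PDB chain letter, so files with more than 26 chains are handled.  Every
    residue must expose the six roles; glycine may alias SC to CA.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    # (chain_key, resseq) -> {role: atom_index}; insertion ordered
    residues: dict = {}
    res_names: dict = {}
    unassignable = []
    chain_counter = 0
    prev_chain_id = None
    prev_resseq = None
    atom_index = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "ENDMDL":
                break  # topology comes from the first model
            if rec == "TER   " or line.strip() == "TER":
                chain_counter += 1
                prev_resseq = None
                continue
            if rec not in ("ATOM  ", "HETATM"):
                continue
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain_id = line[21]
            resseq = int(line[22:26])
            if prev_chain_id is not None and chain_id != prev_chain_id:
                chain_counter += 1
                prev_resseq = None
            elif prev_resseq is not None and resseq < prev_resseq:
                chain_counter += 1
            prev_chain_id = chain_id
            prev_resseq = resseq
            role = _ROLE_ALIASES.get(name, "?")
            key = (chain_counter, resseq)
            if key not in residues:
                residues[key] = {}
                res_names[key] = resname
            if role == "?":
                unassignable.append(f"atom {atom_index} name {name!r} ({resname} {resseq})")
            elif role is not None:
                if role in residues[key]:
                    raise TopologyError(
                        f"duplicate role {role} in chain {chain_counter} residue {resseq}")
                residues[key][role] = atom_index
            atom_index += 1

    if not residues:
        raise TopologyError(f"no ATOM records found in {path}")

    chains: dict = {}
    warnings = list(unassignable)
    for (ci, resseq), roles in residues.items():
        resname = res_names[(ci, resseq)]
        if "SC" not in roles and resname == "GLY" and "CA" in roles:
            roles["SC"] = roles["CA"]
        missing = [r for r in ROLES if r not in roles]
        if resname == "PRO" and missing == ["H"]:
            missing = []
        if missing:
            raise TopologyError(
                f"chain {ci} residue {resname} {resseq} missing role(s) {missing}")
        if resname == "GLY" and roles["SC"] == roles.get("CA"):
            warnings.append(f"chain {ci} residue {resseq}: glycine SC bead coincides with CA")
        chains.setdefault(ci, []).append((resseq, resname, roles))

    chain_objs = []
    for ci in sorted(chains):
        entries = sorted(chains[ci])
        resseqs = [e[0] for e in entries]
        if resseqs != list(range(resseqs[0], resseqs[0] + len(resseqs))):
            raise TopologyError(f"chain {ci}: residue numbers not contiguous: {resseqs}")
        residues_t = tuple(
            Residue(name=resname, index=i, atoms=dict(roles))
            for i, (_, resname, roles) in enumerate(entries)
        )
        chain_objs.append(Chain(index=len(chain_objs), residues=residues_t))
    return Topology(chains=tuple(chain_objs), n_atoms=atom_index, warnings=tuple(warnings))


# ---------------------------------------------------------------------------
# frames & trajectories
# ---------------------------------------------------------------------------

@dataclass
class Frame:
    coords: np.ndarray          # (n_atoms, 3) Angstrom
    box_edge: float             # Angstrom
    time: float = 0.0           # ps

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise TrajectoryError(f"coordinates must be (n,3), got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise TrajectoryError("frame contains non-finite coordinates")
        if self.box_edge <= 0:
            raise TrajectoryError(f"box edge must be positive, got {self.box_edge}")
        if self.time < 0:
            raise TrajectoryError(f"time must be non-negative, got {self.time}")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    topology: Topology
    frames: list
    save_interval: float = 7.5   # ps
    temperature: float = 280.0   # K label only

    def __post_init__(self):
        if len(self.frames) < 1:
            raise TrajectoryError("a trajectory needs at least one frame")
        for i, fr in enumerate(self.frames):
            if fr.n_atoms != self.topology.n_atoms:
                raise TrajectoryError(
                    f"frame {i}: {fr.n_atoms} atoms but topology has {self.topology.n_atoms}")
        times = self.times
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise TrajectoryError("frame times must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise TrajectoryError("non-uniform save interval")

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time for fr in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def select(self, start: int = 0, stop: int | None = None, step: int = 1) -> "Trajectory":
        """Frame-range selector (thermalization windows etc.)."""
        return Trajectory(self.topology, self.frames[start:stop:step],
                          save_interval=self.save_interval * step,
                          temperature=self.temperature)


# -- PDB writing ------------------------------------------------------------

def _pdb_atom_line(serial, name, resname, chain_id, resseq, xyz):
    pad_name = f" {name:<3s}" if len(name) < 4 else name
    return (f"ATOM  {serial:>5d} {pad_name}{'':1s}{resname:>3s} {chain_id}{resseq:>4d}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}\n")


def _chain_letter(i: int) -> str:
    return "ABCDEFGHIJKLMNOPQRSTUVWXYZ"[i % 26]


def write_pdb(path: str, topology: Topology, frames) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        box = frames[0].box_edge
        fh.write(f"CRYST1{box:9.3f}{box:9.3f}{box:9.3f}  90.00  90.00  90.00 P 1           1\n")
        multi = len(frames) > 1
        for mi, frame in enumerate(frames, start=1):
            if multi:
                fh.write(f"MODEL     {mi:>4d}\n")
            serial = 1
            for chain in topology.chains:
                cid = _chain_letter(chain.index)
                for res in chain.residues:
                    written = set()
                    for role in ROLES:
                        ai = res.atoms[role]
                        if ai in written:  # glycine SC aliased to CA
                            continue
                        written.add(ai)
                        name = role
                        fh.write(_pdb_atom_line(serial, name, res.name, cid,
                                                res.index + 1, frame.coords[ai]))
                        serial += 1
                fh.write("TER\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def write_dcd(path: str, topology: Topology, frames, save_interval: float = 7.5) -> None:
    """Write frames to a DCD binary trajectory (via MDAnalysis)."""
    import MDAnalysis as mda

    if isinstance(frames, Frame):
        frames = [frames]
    u = mda.Universe.empty(topology.n_atoms, trajectory=True)
    with mda.Writer(path, n_atoms=topology.n_atoms) as w:
        for frame in frames:
            u.atoms.positions = frame.coords
            u.dimensions = [frame.box_edge] * 3 + [90.0] * 3
            w.write(u.atoms)


def _read_pdb_models(path: str, n_atoms: int):
    """Yield (coords, box_edge) per model of a multi-model PDB."""
    box = None
    coords: list = []
    any_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "CRYST1":
                box = float(line[6:15])
            elif rec in ("ATOM  ", "HETATM"):
                coords.append((float(line[30:38]), float(line[38:46]), float(line[46:54])))
            elif rec == "ENDMDL":
                any_model = True
                yield np.array(coords), box
                coords = []
    if coords and not any_model:
        yield np.array(coords), box
    elif coords:
        yield np.array(coords), box


def load_trajectory(path: str, topology: Topology, dt: float | None = None,
                    times=None, box_edge: float | None = None,
                    temperature: float = 280.0) -> Trajectory:
    """Load a trajectory from a multi-model PDB or a DCD binary file.

    Time stamps come from ``times`` if given, otherwise ``frame_index * dt``
    (``dt`` defaults to 7.5 ps).  PDB files carry the box in CRYST1;
    for DCD (or boxless PDB) pass ``box_edge``.
    """
    if dt is None:
        dt = 7.5
    ext = os.path.splitext(path)[1].lower()
    frames = []
    if ext in (".pdb", ".ent"):
        for i, (coords, box) in enumerate(_read_pdb_models(path, topology.n_atoms)):
            edge = box if box is not None else box_edge
            if edge is None:
                raise TrajectoryError("no CRYST1 record and no box_edge given")
            t = times[i] if times is not None else i * dt
            if coords.shape[0] != topology.n_atoms:
                raise TrajectoryError(
                    f"frame {i}: {coords.shape[0]} atoms, topology has {topology.n_atoms}")
            if not np.all(np.isfinite(coords)):
                raise TrajectoryError(f"frame {i} contains non-finite coordinates")
            frames.append(Frame(coords=coords, box_edge=edge, time=t))
    elif ext == ".dcd":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDReader

        reader = DCDReader(path)
        for i, ts in enumerate(reader):
            coords = np.array(ts.positions, dtype=float)
            if coords.shape[0] != topology.n_atoms:
                raise TrajectoryError(
                    f"frame {i}: {coords.shape[0]} atoms, topology has {topology.n_atoms}")
            edge = box_edge
            if edge is None and ts.dimensions is not None and ts.dimensions[0] > 0:
                edge = float(ts.dimensions[0])
            if edge is None:
                raise TrajectoryError("DCD lacks box dimensions; pass box_edge")
            t = times[i] if times is not None else i * dt
            frames.append(Frame(coords=coords, box_edge=edge, time=t))
        reader.close()
    else:
        raise TrajectoryError(f"unsupported trajectory format: {ext}")
    if not frames:
        raise TrajectoryError(f"no frames found in {path}")
    return Trajectory(topology=topology, frames=frames, save_interval=dt,
                      temperature=temperature)
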