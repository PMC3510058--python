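"""Per-frame geometric descriptors.

Backbone dihedrals, Ramachandran beta-state classification, DSSP-style
(Kabsch-Sander) hydrogen bonds between strands, and side-chain contact
counts.  All distance computations honour the minimum-image convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .cg_model import Frame, Topology, minimum_image, pair_distances

# Kabsch-Sander electrostatic model: E = Q * (1/rON + 1/rCH - 1/rOH - 1/rCN)
KS_Q = 0.42 * 0.20 * 332.0        # kcal/mol * Angstrom
HBOND_ENERGY_CUTOFF = -0.5        # kcal/mol; bond accepted iff E < cutoff
CLASH_DISTANCE = 0.5              # Angstrom; below this the pair is a clash

#: default side-chain bead contact cutoff (Angstrom).  The source analysis
#: does not publish its value; structure-map axes depend on it directly.
DEFAULT_CONTACT_CUTOFF = 6.5


def _norm_angle(deg: float) -> float:
    """Map an angle to (-180, 180]."""
    a = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def dihedral(p1, p2, p3, p4, box_edge: float | None = None) -> float | None:
    """Signed torsion angle (IUPAC convention) in degrees, in (-180, 180].

    Returns ``None`` for degenerate (collinear) geometry instead of a number.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = minimum_image(p2 - p1, box_edge)
    b2 = minimum_image(p3 - p2, box_edge)
    b3 = minimum_image(p4 - p3, box_edge)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1)
    n2n = np.linalg.norm(n2)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-9 or n1n < 1e-9 or n2n < 1e-9:
        return None
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / b2n))
    return _norm_angle(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# beta-state classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BetaWindows:
    """Closed phi/psi interval unions defining the beta region.

    The published window notation is ambiguous in symbol order; the default
    assignment is the one under which the canonical beta-sheet point
    (phi=-120, psi=+130) lies inside the region.  Fully configurable.
    """

    phi: tuple = ((-180.0, 0.0), (150.0, 180.0))
    psi: tuple = ((-180.0, -150.0), (0.0, 180.0))

    @staticmethod
    def _inside(angle: float, intervals) -> bool:
        return any(lo <= angle <= hi for lo, hi in intervals)

    def phi_inside(self, phi: float) -> bool:
        return self._inside(phi, self.phi)

    def psi_inside(self, psi: float) -> bool:
        return self._inside(psi, self.psi)


DEFAULT_BETA_WINDOWS = BetaWindows()


def residue_beta_state(phi: float | None, psi: float | None,
                       windows: BetaWindows = DEFAULT_BETA_WINDOWS) -> tuple[bool, str]:
    """Whether a (phi, psi) pair falls in the configured beta region.

    Returns ``(flag, reason)``; an undefined dihedral (terminus or degenerate
    geometry) yields ``(False, "undefined")``, never a silent zero.
    """
    if phi is None or psi is None:
        return False, "undefined"
    inside = windows.phi_inside(phi) and windows.psi_inside(psi)
    return inside, "ok"


def peptide_beta_state(flags, min_count: int = 3) -> bool:
    """A peptide is a beta strand iff >= ``min_count`` residues are beta."""
    flags = list(flags)
    if not flags:
        raise ValueError("need at least one residue flag")
    return sum(bool(f) for f in flags) >= min_count


@dataclass
class ResidueDihedrals:
    phi: float | None
    psi: float | None

    @property
    def phi_defined(self) -> bool:
        return self.phi is not None

    @property
    def psi_defined(self) -> bool:
        return self.psi is not None


def backbone_dihedrals(frame: Frame, topology: Topology, chain: int,
                       use_pbc: bool = True) -> list[ResidueDihedrals]:
    """phi/psi per residue of one chain; termini carry undefined flags."""
    box = frame.box_edge if use_pbc else None
    residues = topology.chains[chain].residues
    xyz = frame.coords
    out = []
    for i, res in enumerate(residues):
        phi = psi = None
        if i > 0:
            prev = residues[i - 1]
            phi = dihedral(xyz[prev.atoms["C"]], xyz[res.atoms["N"]],
                           xyz[res.atoms["CA"]], xyz[res.atoms["C"]], box)
        if i < len(residues) - 1:
            nxt = residues[i + 1]
            psi = dihedral(xyz[res.atoms["N"]], xyz[res.atoms["CA"]],
                           xyz[res.atoms["C"]], xyz[nxt.atoms["N"]], box)
        out.append(ResidueDihedrals(phi=phi, psi=psi))
    return out


@dataclass
class BetaStateReport:
    """Frame-wide beta-state summary."""

    residue_flags: list           # per chain: list of bool
    residue_reasons: list         # per chain: list of str
    peptide_counts: list          # beta-residue count per chain
    peptide_flags: list           # strand flag per chain
    min_beta_residues: int

    @property
    def beta_fraction(self) -> float:
        flags = [f for chain in self.residue_flags for f in chain]
        return float(np.mean([bool(f) for f in flags])) if flags else 0.0

    @property
    def total_beta_residues(self) -> int:
        return int(sum(self.peptide_counts))


def beta_report(frame: Frame, topology: Topology,
                windows: BetaWindows = DEFAULT_BETA_WINDOWS,
                min_beta_residues: int = 3) -> BetaStateReport:
    res_flags, res_reasons, counts, pep_flags = [], [], [], []
    for ci in range(topology.n_chains):
        dihs = backbone_dihedrals(frame, topology, ci)
        flags, reasons = [], []
        for d in dihs:
            flag, reason = residue_beta_state(d.phi, d.psi, windows)
            flags.append(flag)
            reasons.append(reason)
        res_flags.append(flags)
        res_reasons.append(reasons)
        counts.append(sum(flags))
        pep_flags.append(peptide_beta_state(flags, min_beta_residues))
    return BetaStateReport(residue_flags=res_flags, residue_reasons=res_reasons,
                           peptide_counts=counts, peptide_flags=pep_flags,
                           min_beta_residues=min_beta_residues)


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBond:
    donor: tuple          # (chain, residue) providing N-H
    acceptor: tuple       # (chain, residue) providing C=O
    energy: float         # kcal/mol

    def __post_init__(self):
        if self.donor == self.acceptor:
            raise ValueError("hydrogen bond donor and acceptor must differ")


def hbond_energy(n, h, c, o, box_edge: float | None = None) -> float:
    """Kabsch-Sander electrostatic hydrogen-bond energy (kcal/mol).

    ``n``/``h`` are the donor backbone N and amide H, ``c``/``o`` the acceptor
    carbonyl C and O.
    """
    n, h, c, o = (np.asarray(p, dtype=float) for p in (n, h, c, o))

    def dist(a, b):
        return float(np.linalg.norm(minimum_image(a - b, box_edge)))

    r_on = dist(o, n)
    r_ch = dist(c, h)
    r_oh = dist(o, h)
    r_cn = dist(c, n)
    for r in (r_on, r_ch, r_oh, r_cn):
        if r < 1e-9:
            raise ValueError("coincident atoms in hydrogen-bond geometry")
    return KS_Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _clash(n, h, c, o, box_edge) -> bool:
    pts = [np.asarray(p, float) for p in (n, h, c, o)]
    # donor-acceptor cross distances only; N-H and C=O are bonded pairs
    for a in pts[:2]:
        for b in pts[2:]:
            if np.linalg.norm(minimum_image(a - b, box_edge)) < CLASH_DISTANCE:
                return True
    return False


def interstrand_hbonds(frame: Frame, topology: Topology, peptide_a: int,
                       peptide_b: int, energy_cutoff: float = HBOND_ENERGY_CUTOFF,
                       use_pbc: bool = True) -> list[HBond]:
    """All accepted inter-peptide hydrogen bonds between two peptides.

    Scans donor->acceptor pairs in both directions; intra-peptide bonds are
    excluded by construction.  Pairs with donor/acceptor atoms closer than
    the clash distance are rejected with a warning.
    """
    if peptide_a == peptide_b:
        raise ValueError("interstrand_hbonds requires two distinct peptides")
    box = frame.box_edge if use_pbc else None
    xyz = frame.coords
    bonds = []
    for don, acc in ((peptide_a, peptide_b), (peptide_b, peptide_a)):
        for dres in topology.chains[don].residues:
            if "H" not in dres.atoms:
                continue
            n = xyz[dres.atoms["N"]]
            h = xyz[dres.atoms["H"]]
            for ares in topology.chains[acc].residues:
                c = xyz[ares.atoms["C"]]
                o = xyz[ares.atoms["O"]]
                if _clash(n, h, c, o, box):
                    warnings.warn(
                        f"steric clash between peptide {don} res {dres.index} and "
                        f"peptide {acc} res {ares.index}; pair rejected")
                    continue
                e = hbond_energy(n, h, c, o, box)
                if e < energy_cutoff:
                    bonds.append(HBond(donor=(don, dres.index),
                                       acceptor=(acc, ares.index), energy=e))
    return bonds


# ---------------------------------------------------------------------------
# side-chain contacts
# ---------------------------------------------------------------------------

def sidechain_contacts(frame: Frame, topology: Topology,
                       cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       use_pbc: bool = True) -> tuple[int, np.ndarray]:
    """Count inter-peptide SC-bead pairs within ``cutoff`` (minimum image).

    Returns ``(total, matrix)`` where ``matrix[i, j]`` is the number of
    contacting bead pairs between peptides i and j (symmetric, zero diagonal).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    box = frame.box_edge if use_pbc else None
    n_pep = topology.n_chains
    sc_idx, owner = [], []
    for ci, chain in enumerate(topology.chains):
        for res in chain.residues:
            sc_idx.append(res.atoms["SC"])
            owner.append(ci)
    pts = frame.coords[np.array(sc_idx)]
    owner = np.array(owner)
    d = pair_distances(pts, pts, box)
    close = (d <= cutoff) & (owner[:, None] != owner[None, :])
    matrix = np.zeros((n_pep, n_pep), dtype=int)
    ii, jj = np.nonzero(np.triu(close))
    for a, b in zip(owner[ii], owner[jj]):
        matrix[a, b] += 1
        matrix[b, a] += 1
    return int(close.sum() // 2), matrix
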