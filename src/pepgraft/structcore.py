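"""Structure data model, PDB I/O and core geometry.

The hierarchy is deliberately small: :class:`Structure` → chains (ordered
dicts of :class:`Residue`) → :class:`Atom`.  Coordinates are Å throughout;
residue numbering follows the author numbering of the source PDB file,
while fragment indices elsewhere in the package are 0-based half-open.

Parsing is delegated to :mod:`gemmi`; only heavy atoms of standard ATOM
records are retained (waters, HETATM and hydrogens are dropped, because
every downstream rule — clash filtering, SASA, superposition — is defined
over heavy atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Structure",
    "RigidTransform",
    "vdw_radius",
    "element_from_name",
    "parse_pdb",
    "write_pdb",
    "dihedral",
    "backbone_dihedrals",
    "kabsch_superpose",
    "place_atom",
    "VDW_RADII",
    "BACKBONE_NAMES",
]

#: Bondi (1964) van der Waals radii, Å.  Config-overridable by passing an
#: explicit table to the functions that consume radii.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}

BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

_AA3 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1 = {v: k for k, v in _AA3.items()}


def three_to_one(name: str) -> str:
    return _AA3.get(name.upper(), "X")


def one_to_three(letter: str) -> str:
    try:
        return _AA1[letter.upper()]
    except KeyError:
        raise ValueError(f"unknown one-letter residue code {letter!r}") from None


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    """Van der Waals radius (Å) of an element, Bondi convention."""
    tab = VDW_RADII if table is None else table
    try:
        return tab[element.capitalize()]
    except KeyError:
        raise KeyError(f"no van der Waals radius for element {element!r}") from None


def element_from_name(name: str) -> str:
    """Infer the chemical element from a PDB atom name (heavy atoms)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    if stripped[:2].upper() in ("SE", "FE", "ZN", "MG", "MN", "CL", "BR"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray  # (3,), Å
    is_backbone: bool = False
    vdw: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name}: coords must be a finite 3-vector")
        if not self.element:
            self.element = element_from_name(self.name)
        if self.vdw <= 0.0:
            self.vdw = VDW_RADII.get(self.element.capitalize(), 1.70)
        self.is_backbone = self.name in BACKBONE_NAMES

    def copy(self) -> "Atom":
        return Atom(self.name, self.element, self.coords.copy())


@dataclass
class Residue:
    name: str
    seq_id: int
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)
    icode: str = ""

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def __contains__(self, name: str) -> bool:
        return self.atom(name) is not None

    @property
    def one_letter(self) -> str:
        return three_to_one(self.name)

    def has_backbone(self) -> bool:
        return all(n in self for n in ("N", "CA", "C"))

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.element != "H"]

    def sidechain_atoms(self) -> list[Atom]:
        """Heavy atoms beyond the backbone (CB included)."""
        return [a for a in self.heavy_atoms() if a.name not in BACKBONE_NAMES]

    def copy(self) -> "Residue":
        return Residue(self.name, self.seq_id, self.chain_id,
                       [a.copy() for a in self.atoms], self.icode)


@dataclass
class Structure:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    source: str = "synthetic"

    def residues(self) -> list[Residue]:
        return [r for ch in self.chains.values() for r in ch]

    def atoms(self) -> list[Atom]:
        return [a for r in self.residues() for a in r.atoms]

    def coords(self) -> np.ndarray:
        ats = self.atoms()
        if not ats:
            return np.zeros((0, 3))
        return np.array([a.coords for a in ats])

    def n_residues(self) -> int:
        return sum(len(ch) for ch in self.chains.values())

    def get_residue(self, chain_id: str, seq_id: int, icode: str = "") -> Residue:
        for r in self.chains.get(chain_id, []):
            if r.seq_id == seq_id and r.icode == icode:
                return r
        raise KeyError(f"no residue {chain_id}/{seq_id}{icode} in structure {self.id!r}")

    def copy(self) -> "Structure":
        return Structure(self.id,
                         {c: [r.copy() for r in ch] for c, ch in self.chains.items()},
                         self.source)

    def _validate(self) -> None:
        for cid, ch in self.chains.items():
            keys = [(r.seq_id, r.icode) for r in ch]
            if len(set(keys)) != len(keys):
                raise ValueError(f"duplicate (seq_id, icode) in chain {cid}")
            if keys != sorted(keys):
                raise ValueError(f"chain {cid} not ordered by (seq_id, icode)")


@dataclass
class RigidTransform:
    """Proper rigid-body transform x ↦ R·x + t with the RMSD that produced it."""
    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)
    rmsd: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        err = np.abs(self.rotation.T @ self.rotation - np.eye(3)).max()
        if err > 1e-6:
            raise ValueError(f"rotation not orthonormal (‖RᵀR−I‖∞ = {err:.2e})")
        if self.rmsd < 0:
            raise ValueError("rmsd must be ≥ 0")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def apply_structure(self, s: Structure) -> Structure:
        out = s.copy()
        for a in out.atoms():
            a.coords = self.rotation @ a.coords + self.translation
        return out

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)


# ---------------------------------------------------------------------------
# PDB I/O


def parse_pdb(path, model_policy: str = "first") -> Structure:
    """Read a PDB file into a :class:`Structure`.

    Altloc policy: highest occupancy wins, ties resolved toward altloc 'A'.
    Hydrogens, waters and HETATM records are dropped.

    Parameters
    ----------
    model_policy:
        ``"first"`` takes model 1 of a multi-model file; ``"error"`` raises.
    """
    if model_policy not in ("first", "error"):
        raise ValueError(f"model_policy must be 'first' or 'error', got {model_policy!r}")
    try:
        st = gemmi.read_pdb(str(path))
    except (OSError, RuntimeError, ValueError) as exc:
        raise IOError(f"cannot read PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"{path}: no ATOM records")
    if len(st) > 1 and model_policy == "error":
        raise ValueError(f"{path}: {len(st)} models present with model_policy='error'")
    model = st[0]

    out = Structure(id=st.name or str(path), source=str(path))
    for chain in model:
        residues: list[Residue] = []
        for res in chain:
            if res.is_water() or res.het_flag == "H":
                continue
            # altloc resolution: best occupancy per atom name, ties → 'A'
            best: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.is_hydrogen:
                    continue
                prev = best.get(at.name)
                if prev is None or at.occ > prev.occ or (
                        at.occ == prev.occ and (at.altloc or "A") < (prev.altloc or "A")):
                    best[at.name] = at
            if not best:
                continue
            atoms = [Atom(name=a.name,
                          element=a.element.name if a.element.name != "X" else "",
                          coords=np.array([a.pos.x, a.pos.y, a.pos.z]))
                     for a in best.values()]
            residues.append(Residue(name=res.name, seq_id=res.seqid.num,
                                    chain_id=chain.name, atoms=atoms,
                                    icode=(res.seqid.icode or "").strip()))
        if residues:
            out.chains[chain.name] = residues
    if not out.chains:
        raise ValueError(f"{path}: no polymer ATOM records after filtering")
    out._validate()
    return out


def write_pdb(s: Structure, path) -> None:
    """Serialize a structure as fixed-width PDB ATOM records (8.3 coordinates)."""
    if not s.chains or not s.atoms():
        raise ValueError("refusing to write an empty structure")
    lines: list[str] = []
    serial = 0
    for cid, residues in s.chains.items():
        for res in residues:
            for at in res.atoms:
                serial += 1
                name = at.name
                # names of length < 4 start in column 14 unless element is 2 chars
                fname = f" {name:<3s}" if len(name) < 4 and len(at.element) < 2 else f"{name:<4s}"
                x, y, z = at.coords
                lines.append(
                    f"ATOM  {serial:5d} {fname} {res.name:>3s} {cid[:1]}"
                    f"{res.seq_id:4d}{res.icode or ' ':1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {at.element:>2s}"
                )
        serial += 1
        last = residues[-1]
        lines.append(f"TER   {serial:5d}      {last.name:>3s} {cid[:1]}{last.seq_id:4d}")
    lines.append("END")
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise IOError(f"cannot write PDB file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Geometry


def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle in degrees, in (−180, 180], IUPAC sign convention."""
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    ang = math.degrees(math.atan2(y, x))
    return 180.0 if ang <= -180.0 else ang


def bond_angle(p0, p1, p2) -> float:
    """Angle at p1 in degrees."""
    v1 = np.asarray(p0, float) - np.asarray(p1, float)
    v2 = np.asarray(p2, float) - np.asarray(p1, float)
    c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def backbone_dihedrals(s: Structure, chain: str) -> list[tuple[float | None, float | None, float | None]]:
    """Per-residue (phi, psi, omega) in degrees for one chain.

    Angles that cannot be computed (termini, missing backbone atoms, broken
    peptide bonds) are ``None`` — never a sentinel number.  omega_i is the
    torsion CA_i–C_i–N_{i+1}–CA_{i+1}.
    """
    residues = s.chains.get(chain)
    if residues is None:
        raise KeyError(f"no chain {chain!r} in structure {s.id!r}")

    def bb(i: int, name: str) -> np.ndarray | None:
        if i < 0 or i >= len(residues):
            return None
        a = residues[i].atom(name)
        return None if a is None else a.coords

    out = []
    for i in range(len(residues)):
        n, ca, c = bb(i, "N"), bb(i, "CA"), bb(i, "C")
        prev_c = bb(i - 1, "C")
        next_n, next_ca = bb(i + 1, "N"), bb(i + 1, "CA")
        phi = psi = omega = None
        if all(p is not None for p in (prev_c, n, ca, c)):
            phi = dihedral(prev_c, n, ca, c)
        if all(p is not None for p in (n, ca, c, next_n)):
            psi = dihedral(n, ca, c, next_n)
        if all(p is not None for p in (ca, c, next_n, next_ca)):
            omega = dihedral(ca, c, next_n, next_ca)
        out.append((phi, psi, omega))
    return out


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of point correspondences (Kabsch).

    Returns the proper rotation + translation minimizing the RMSD of
    ``mobile`` onto ``target``; reflections are never returned.  Rank-deficient
    (near-collinear) configurations are solved but flagged ``degenerate``.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be matching N×3 arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 point pairs, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    if np.allclose(P0, 0.0) or np.allclose(Q0, 0.0):
        raise ValueError("degenerate input: all points coincident")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    degenerate = bool(np.linalg.matrix_rank(P0, tol=1e-6) < 2)
    return RigidTransform(R, t, rmsd, degenerate=degenerate)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """NeRF placement: position d with |c−d| = bond, ∠(b,c,d) = angle and
    dihedral(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    tor = math.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([-bond * math.cos(ang),
                   bond * math.sin(ang) * math.cos(tor),
                   bond * math.sin(ang) * math.sin(tor)])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n
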