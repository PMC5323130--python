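"""Deterministic synthetic-structure generators.

Everything the test suite and the toy end-to-end run need is built here from
ideal internal coordinates (NeRF chain building with standard bond lengths
and angles), so no external structure files are required.  All generators
are bit-deterministic under a fixed seed.

The toy receptor–donor complex emulates the real use-case geometry — a
receptor surface, a donor presenting two anchor groups (three contiguous
strand anchors and two spaced helix anchors) — at a scale where ground
truth is known by construction: the donor's own fragments regenerate the
docked anchor constellation exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sidechains import mutate_residue
from .structcore import Atom, Residue, Structure, place_atom

__all__ = [
    "BOND", "ANGLE",
    "build_chain",
    "make_ideal_helix",
    "make_ideal_strand",
    "make_beta_hairpin",
    "make_helix_loop_strand",
    "make_toy_complex",
    "make_decoy_library_structures",
    "make_loop_cut_fixture",
    "ToyComplex",
]

#: Standard backbone bond lengths (Å) and angles (degrees), shared with the
#: linker's idealization step.
BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "CA-CB": 1.521}
ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}

#: Ideal (phi, psi) for the canonical secondary structures.
HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-120.0, 130.0)

# Two-residue turn connecting antiparallel strands (type-I'-like); values
# chosen so that torsion-built hairpins pair at 4.5–5.5 Å Cα–Cα.
_TURN_TORSIONS = ((60.0, 30.0), (90.0, 0.0))


def _cb_position(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    # ideal tetrahedral Cβ from the backbone triad
    b = ca - n
    cvec = c - ca
    a = np.cross(b, cvec)
    return -0.58273431 * a + 0.56802827 * b - 0.54067466 * cvec + ca


def build_chain(torsions: list[tuple[float, float, float]], chain_id: str = "A",
                names: list[str] | None = None, start_seq: int = 1,
                with_cb: bool = True) -> list[Residue]:
    """Build a backbone chain from per-residue (phi, psi, omega) torsions.

    phi of the first residue and psi/omega of the last are ignored (they are
    undefined for a free chain).  Residues are poly-Ala (N, CA, C, O, CB)
    unless ``names`` overrides them or ``with_cb`` is false (then GLY).
    """
    n_res = len(torsions)
    if n_res < 1:
        raise ValueError("need at least one residue")
    if names is not None and len(names) != n_res:
        raise ValueError("names must match torsion list length")

    N = [None] * n_res
    CA = [None] * n_res
    C = [None] * n_res
    O = [None] * n_res

    N[0] = np.zeros(3)
    CA[0] = np.array([BOND["N-CA"], 0.0, 0.0])
    ang = math.radians(ANGLE["N-CA-C"])
    C[0] = CA[0] + BOND["CA-C"] * np.array([-math.cos(ang), math.sin(ang), 0.0])

    for i in range(n_res - 1):
        _phi, psi, omega = torsions[i]
        N[i + 1] = place_atom(N[i], CA[i], C[i], BOND["C-N"], ANGLE["CA-C-N"], psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], BOND["N-CA"], ANGLE["C-N-CA"], omega)
        phi_next = torsions[i + 1][0]
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], BOND["CA-C"], ANGLE["N-CA-C"], phi_next)
        # carbonyl O in the peptide plane, anti to the next N
        O[i] = place_atom(N[i + 1], CA[i], C[i], BOND["C-O"], ANGLE["CA-C-O"], 180.0)
    # C-terminal O: anti to a virtual continuation at psi = 120°
    O[-1] = place_atom(N[-1], CA[-1], C[-1], BOND["C-O"], ANGLE["CA-C-O"],
                       (torsions[-1][1] if torsions[-1][1] is not None else 120.0) + 180.0)

    residues = []
    for i in range(n_res):
        name = names[i] if names is not None else ("ALA" if with_cb else "GLY")
        atoms = [Atom("N", "N", N[i]), Atom("CA", "C", CA[i]),
                 Atom("C", "C", C[i]), Atom("O", "O", O[i])]
        if name != "GLY" and with_cb:
            atoms.append(Atom("CB", "C", _cb_position(N[i], CA[i], C[i])))
        residues.append(Residue(name=name, seq_id=start_seq + i, chain_id=chain_id,
                                atoms=atoms))
    return residues


def _uniform_chain(n: int, phi_psi: tuple[float, float], chain_id: str,
                   start_seq: int = 1) -> list[Residue]:
    tors = [(phi_psi[0], phi_psi[1], 180.0)] * n
    return build_chain(tors, chain_id=chain_id, start_seq=start_seq)


def make_ideal_helix(n: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """Ideal poly-Ala α-helix (phi −57°, psi −47°), Cβ at tetrahedral positions."""
    if n < 4:
        raise ValueError(f"helix needs n ≥ 4 residues, got {n}")
    s = Structure(id=f"helix{n}_s{seed}")
    s.chains[chain_id] = _uniform_chain(n, HELIX_PHI_PSI, chain_id)
    return s


def make_ideal_strand(n: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """Ideal poly-Ala β-strand (phi −120°, psi 130°)."""
    if n < 3:
        raise ValueError(f"strand needs n ≥ 3 residues, got {n}")
    s = Structure(id=f"strand{n}_s{seed}")
    s.chains[chain_id] = _uniform_chain(n, STRAND_PHI_PSI, chain_id)
    return s


def make_beta_hairpin(n_per_strand: int, seed: int = 0, chain_id: str = "A") -> Structure:
    """Two antiparallel ideal strands bridged by a 2-residue turn, one chain."""
    if n_per_strand < 3:
        raise ValueError(f"hairpin needs ≥ 3 residues per strand, got {n_per_strand}")
    tors = ([(STRAND_PHI_PSI[0], STRAND_PHI_PSI[1], 180.0)] * n_per_strand
            + [(t[0], t[1], 180.0) for t in _TURN_TORSIONS]
            + [(STRAND_PHI_PSI[0], STRAND_PHI_PSI[1], 180.0)] * n_per_strand)
    s = Structure(id=f"hairpin{n_per_strand}_s{seed}")
    s.chains[chain_id] = build_chain(tors, chain_id=chain_id)
    return s


def make_helix_loop_strand(n_helix: int = 10, n_loop: int = 4, n_strand: int = 6,
                           seed: int = 0, chain_id: str = "A") -> Structure:
    """Continuous helix–loop–strand chain, the substrate for loop-cut fixtures."""
    rng = np.random.default_rng(seed)
    loop = [(float(rng.uniform(-150, -60)), float(rng.uniform(60, 160)), 180.0)
            for _ in range(n_loop)]
    tors = ([(HELIX_PHI_PSI[0], HELIX_PHI_PSI[1], 180.0)] * n_helix
            + loop
            + [(STRAND_PHI_PSI[0], STRAND_PHI_PSI[1], 180.0)] * n_strand)
    s = Structure(id=f"hls_s{seed}")
    s.chains[chain_id] = build_chain(tors, chain_id=chain_id)
    return s


# ---------------------------------------------------------------------------
# Toy receptor–donor complex


@dataclass
class ToyComplex:
    receptor: Structure
    donor: Structure
    anchor_spec: dict  # same schema as the anchor YAML file

    def anchors(self) -> list[dict]:
        return [a for g in self.anchor_spec["groups"].values() for a in g["anchors"]]


def _rigid_place(residues: list[Residue], rotation: np.ndarray,
                 translation: np.ndarray) -> None:
    for r in residues:
        for a in r.atoms:
            a.coords = rotation @ a.coords + translation


def _rot(axis: str, deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], float)
    if axis == "y":
        return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], float)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]], float)


def _axis_align(residues: list[Residue]) -> None:
    """Rotate/translate so the Cα principal axis lies along +x, centroid at 0."""
    ca = np.array([r.atom("CA").coords for r in residues])
    centroid = ca.mean(axis=0)
    _u, _s, vt = np.linalg.svd(ca - centroid, full_matrices=False)
    v = vt[0] / np.linalg.norm(vt[0])  # dominant Cα axis
    if v @ (ca[-1] - ca[0]) < 0:
        v = -v
    x = np.array([1.0, 0.0, 0.0])
    w = np.cross(v, x)
    if np.linalg.norm(w) < 1e-9:
        R = np.eye(3)
    else:
        w /= np.linalg.norm(w)
        angle = math.acos(max(-1.0, min(1.0, v @ x)))
        K = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
        R = np.eye(3) + math.sin(angle) * K + (1 - math.cos(angle)) * K @ K
    for r in residues:
        for a in r.atoms:
            a.coords = R @ (a.coords - centroid)


def _donor_helix_torsions(n: int) -> list[tuple[float, float, float]]:
    """Deterministically irregular helical torsions (still inside the H
    assignment window).  Real anchor-bearing segments are never ideal; the
    wobble gives the planted constellation a distinctive geometry that only
    the donor's own fragments reproduce exactly."""
    return [(-62.0 + 5.0 * math.sin(1.7 * k), -41.0 + 5.0 * math.cos(2.3 * k), 180.0)
            for k in range(n)]


def _donor_strand_torsions(n: int, off: int = 0) -> list[tuple[float, float, float]]:
    return [(-125.0 + 6.0 * math.sin(2.1 * (k + off) + 0.5),
             136.0 + 6.0 * math.cos(1.3 * (k + off)), 180.0) for k in range(n)]


def make_toy_complex(seed: int = 0) -> ToyComplex:
    """Flat receptor slab plus a docked donor (helix + sheet-paired strand).

    The donor presents five anchors mirroring the real grouping: three
    contiguous anchors (ALA/ASP/TYR, the ALA tagged keep-original) on the
    first hairpin strand and two spaced anchors (TYR/ARG) on the helix.
    Donor fragments carry deterministic torsion wobble — their geometry is
    distinctive, as in a real complex — and sit at a packing optimum over
    the slab.  The complex is clash-free at vdW scale 0.75 by construction
    (asserted), with the anchor side chains in contact with the surface.
    """
    # receptor: two close-packed helix patches, one under each anchor site,
    # with empty space between them (under the linker path) and beyond their
    # edges — the binding epitope is local, as on a real receptor
    rec = Structure(id=f"toyrec_s{seed}", source="synthetic")
    rec_res: list[Residue] = []
    seq0 = 1
    for cx, cz, n_res in ((-12.0, 1.2, 13), (14.0, 1.2, 7)):
        for dy, dz in [(-5.5, -1.2), (0.0, 0.0), (5.5, -1.2), (11.0, 0.0), (16.5, -1.2)]:
            helix = _uniform_chain(n_res, HELIX_PHI_PSI, "R", start_seq=seq0)
            _axis_align(helix)
            _rigid_place(helix, np.eye(3), np.array([cx, dy, dz + cz]))
            rec_res.extend(helix)
            seq0 += 15
    rec.chains["R"] = rec_res

    # donor helix, chain H: 12 residues, TYR at index 2 and ARG at index 8
    helix_names = ["ALA"] * 12
    helix_names[2], helix_names[8] = "TYR", "ARG"
    dh = build_chain(_donor_helix_torsions(12), chain_id="H")
    _axis_align(dh)
    dh = [mutate_residue(r, helix_names[i]) for i, r in enumerate(dh)]
    # sit above the receptor slab, side chains toward it
    _rigid_place(dh, _rot("x", 180.0), np.array([-10.0, 4.0, 9.0]))

    # donor hairpin, chain S: anchors ALA/ASP/TYR at strand-1 indices 1..3
    hp_tors = (_donor_strand_torsions(5)
               + [(t[0], t[1], 180.0) for t in _TURN_TORSIONS]
               + _donor_strand_torsions(5, off=7))
    hp = build_chain(hp_tors, chain_id="S")
    strand_names = ["ALA"] * len(hp)
    strand_names[1], strand_names[2], strand_names[3] = "ALA", "ASP", "TYR"
    _axis_align(hp)
    hp = [mutate_residue(r, strand_names[i]) for i, r in enumerate(hp)]
    _rigid_place(hp, _rot("x", 180.0) @ _rot("z", 180.0), np.array([13.0, 4.0, 10.3]))

    donor = Structure(id=f"toydonor_s{seed}", source="synthetic")
    donor.chains["H"] = dh
    donor.chains["S"] = hp

    anchor_spec = {
        "receptor": {"id": rec.id, "chain": "R"},
        "donor": {"id": donor.id},
        "groups": {
            "helix_group": {
                "ss_type": "H",
                "contiguity": "spaced",
                "anchors": [
                    {"chain": "H", "seq_id": 3, "name": "TYR", "keep_original": False},
                    {"chain": "H", "seq_id": 9, "name": "ARG", "keep_original": False},
                ],
            },
            "strand_group": {
                "ss_type": "E",
                "contiguity": "contiguous",
                "anchors": [
                    {"chain": "S", "seq_id": 2, "name": "ALA", "keep_original": True},
                    {"chain": "S", "seq_id": 3, "name": "ASP", "keep_original": False},
                    {"chain": "S", "seq_id": 4, "name": "TYR", "keep_original": False},
                ],
            },
        },
    }

    toy = ToyComplex(receptor=rec, donor=donor, anchor_spec=anchor_spec)
    _assert_toy_invariants(toy)
    return toy


def _assert_toy_invariants(toy: ToyComplex) -> None:
    from .grafting import clash_check

    rec_atoms = [a for r in toy.receptor.residues() for a in r.heavy_atoms()]
    don_atoms = [a for r in toy.donor.residues() for a in r.heavy_atoms()]
    n = clash_check(rec_atoms, don_atoms, scale=0.75)
    if n != 0:
        raise AssertionError(f"toy complex generator produced {n} donor–receptor clashes")
    hx = [a for r in toy.donor.chains["H"] for a in r.heavy_atoms()]
    st = [a for r in toy.donor.chains["S"] for a in r.heavy_atoms()]
    n = clash_check(hx, st, scale=0.75)
    if n != 0:
        raise AssertionError(f"toy donor helix–strand internal clashes: {n}")
    for a in toy.anchors():
        res = toy.donor.get_residue(a["chain"], a["seq_id"])
        if res.name != a["name"]:
            raise AssertionError(f"anchor {a} name mismatch: donor has {res.name}")
        if res.atom("CA") is None or (res.name != "GLY" and res.atom("CB") is None):
            raise AssertionError(f"anchor {a} missing CA/CB")


def make_decoy_library_structures(n_decoys: int = 20, seed: int = 1) -> list[Structure]:
    """Decoy scaffolds: regular fragments with non-native geometry.

    Helix decoys are regular rods with one (phi, psi) pair per fragment,
    drawn from the helical assignment window but kept ≥ 10° away from the
    ideal α-helix torsions the donor uses (so they span 3₁₀-like to π-like
    pitches without duplicating the planted scaffold); hairpin decoys
    likewise use per-fragment-constant strand torsions displaced from the
    ideal, keeping the two strands sheet-paired."""
    rng = np.random.default_rng(seed)

    def draw(lo_phi, hi_phi, lo_psi, hi_psi, ideal, min_dist=10.0):
        while True:
            phi = float(rng.uniform(lo_phi, hi_phi))
            psi = float(rng.uniform(lo_psi, hi_psi))
            if max(abs(phi - ideal[0]), abs(psi - ideal[1])) >= min_dist:
                return phi, psi

    out = []
    for i in range(n_decoys):
        if i % 2 == 0:
            n = int(rng.integers(8, 14))
            phi, psi = draw(-100, -35, -75, -10, (-62.0, -41.0))
            tors = [(phi, psi, 180.0)] * n
            s = Structure(id=f"decoy_helix_{i}_s{seed}")
        else:
            n = int(rng.integers(4, 7))
            phi1, psi1 = draw(-145, -95, 105, 155, (-125.0, 136.0))
            phi2, psi2 = draw(-145, -95, 105, 155, (-125.0, 136.0))
            tors = ([(phi1, psi1, 180.0)] * n
                    + [(t[0] + rng.uniform(-8, 8), t[1] + rng.uniform(-8, 8), 180.0)
                       for t in _TURN_TORSIONS]
                    + [(phi2, psi2, 180.0)] * n)
            s = Structure(id=f"decoy_hairpin_{i}_s{seed}")
        chain = build_chain([(float(p), float(q), o) for p, q, o in tors], chain_id="A")
        # scatter in space so decoys carry no docking information
        R = _rot("z", float(rng.uniform(0, 360))) @ _rot("y", float(rng.uniform(0, 360)))
        t = rng.uniform(-40, 40, size=3)
        _rigid_place(chain, R, t)
        s.chains["A"] = chain
        out.append(s)
    return out


def make_loop_cut_fixture(structure: Structure, cut_len: int, seed: int = 0):
    """Excise ``cut_len`` interior residues from the longest chain; return the
    flanking pieces (as Fragments in the original frame) plus the excised
    residues as ground truth for cut-and-rebuild closure tests."""
    from .scaffoldlib import Fragment

    chain_id = max(structure.chains, key=lambda c: len(structure.chains[c]))
    residues = structure.chains[chain_id]
    if len(residues) < cut_len + 6:
        raise ValueError(f"chain {chain_id} too short for a {cut_len}-residue cut")
    rng = np.random.default_rng(seed)
    lo, hi = 3, len(residues) - cut_len - 3  # keep ≥3 residues per flank
    start = int(rng.integers(lo, hi + 1))
    frag_a = Fragment(source_id=structure.id, chain_id=chain_id, ss_type="H",
                      start=0, end=start,
                      residues=[r.copy() for r in residues[:start]])
    frag_b = Fragment(source_id=structure.id, chain_id=chain_id, ss_type="H",
                      start=start + cut_len, end=len(residues),
                      residues=[r.copy() for r in residues[start + cut_len:]])
    truth = [r.copy() for r in residues[start:start + cut_len]]
    return frag_a, frag_b, truth
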