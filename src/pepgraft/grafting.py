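"""Anchor grafting: screen scaffolds against anchor constellations and pair them.

An *anchor set* is a handful of hotspot residues on a donor ligand whose
interaction geometry is to be transplanted onto designed peptides.  Each
scaffold fragment is superposed onto an anchor group over the corresponding
Cα/Cβ atoms; fragments matching with RMSD below the cutoff (default 2.0 Å)
receive the anchor side chains (rigid transplant of donor coordinates) and
surviving fragments from the two groups are paired subject to a steric
clash filter: two heavy atoms clash when their distance is smaller than the
sum of their van der Waals radii scaled by 0.75.

One anchor may be tagged ``keep_original`` (the alanine-like case): its
scaffold position keeps the original scaffold residue, because a methyl
side chain contributes nothing beyond backbone contacts and the scaffold's
own residue may add interactions there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .scaffoldlib import Fragment
from .sidechains import sidechain_template
from .structcore import Atom, RigidTransform, Structure, kabsch_superpose, parse_pdb

__all__ = [
    "Anchor",
    "AnchorGroup",
    "AnchorSet",
    "GraftMatch",
    "ScaffoldPair",
    "GraftError",
    "load_anchor_spec",
    "enumerate_position_maps",
    "screen_fragment",
    "graft_sidechains",
    "clash_check",
    "pair_scaffolds",
]

DEFAULT_RMSD_CUTOFF = 2.0  # Å, strict: kept only if rmsd < cutoff
DEFAULT_CLASH_SCALE = 0.75
SPACED_CA_TOLERANCE = 2.0  # Å window on donor Cα–Cα distance for spaced groups


class GraftError(RuntimeError):
    pass


@dataclass(frozen=True)
class Anchor:
    chain: str
    seq_id: int
    name: str
    keep_original: bool = False

    def label(self) -> str:
        return f"{self.chain}/{self.seq_id}:{self.name}"


@dataclass
class AnchorGroup:
    label: str
    ss_type: str  # 'H' or 'E'
    contiguity: str  # 'contiguous' | 'spaced'
    anchors: list[Anchor]

    def __post_init__(self) -> None:
        if self.ss_type not in ("H", "E"):
            raise ValueError(f"group {self.label}: ss_type must be H or E")
        if self.contiguity not in ("contiguous", "spaced"):
            raise ValueError(f"group {self.label}: bad contiguity {self.contiguity!r}")

    def __len__(self) -> int:
        return len(self.anchors)


@dataclass
class AnchorSet:
    receptor: Structure
    donor: Structure
    groups: dict[str, AnchorGroup]

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for g in self.groups.values():
            for a in g.anchors:
                key = (a.chain, a.seq_id)
                if key in seen:
                    raise ValueError(f"anchor {a.label()} appears in two groups")
                seen.add(key)
                res = self.donor.get_residue(a.chain, a.seq_id)
                if res.name != a.name:
                    raise ValueError(
                        f"anchor {a.label()}: donor residue is {res.name}")
                if res.atom("CA") is None:
                    raise ValueError(f"anchor {a.label()}: no Cα in donor")
                if res.name != "GLY" and res.atom("CB") is None:
                    raise ValueError(f"anchor {a.label()}: no Cβ in donor")

    def donor_residue(self, a: Anchor):
        return self.donor.get_residue(a.chain, a.seq_id)


def load_anchor_spec(path, receptor: Structure | None = None,
                     donor: Structure | None = None) -> AnchorSet:
    """Build an :class:`AnchorSet` from a YAML/JSON spec file.

    The file names the receptor and donor PDB files (resolved relative to
    the spec file) and lists per-group anchors; pre-parsed structures may be
    passed instead to skip file loading."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if receptor is None:
        rec_cfg = raw["receptor"]
        receptor = parse_pdb(path.parent / rec_cfg["pdb"])
        if "chain" in rec_cfg:
            keep = str(rec_cfg["chain"])
            receptor.chains = {keep: receptor.chains[keep]}
    if donor is None:
        donor = parse_pdb(path.parent / raw["donor"]["pdb"])
    groups = {}
    for label, g in raw["groups"].items():
        anchors = [Anchor(chain=str(a["chain"]), seq_id=int(a["seq_id"]),
                          name=str(a["name"]).upper(),
                          keep_original=bool(a.get("keep_original", False)))
                   for a in g["anchors"]]
        groups[label] = AnchorGroup(label=label, ss_type=g["ss_type"],
                                    contiguity=g["contiguity"], anchors=anchors)
    return AnchorSet(receptor=receptor, donor=donor, groups=groups)


@dataclass
class GraftMatch:
    fragment: Fragment
    group_label: str
    position_map: tuple[int, ...]  # fragment residue index per anchor, anchor order
    transform: RigidTransform
    rmsd: float
    grafted: Fragment | None = None

    def id(self) -> str:
        src, ch, s, e = self.fragment.key()
        pos = ",".join(map(str, self.position_map))
        return f"{src}:{ch}:{s}-{e}@{pos}"


@dataclass
class ScaffoldPair:
    match_a: GraftMatch
    match_b: GraftMatch
    n_clashes: int = 0

    @property
    def clash_free(self) -> bool:
        return self.n_clashes == 0

    def id(self) -> str:
        return f"{self.match_a.id()}|{self.match_b.id()}"


# ---------------------------------------------------------------------------
# Enumeration and screening


def enumerate_position_maps(frag: Fragment, group: AnchorGroup,
                            anchor_set: AnchorSet,
                            spaced_tol: float = SPACED_CA_TOLERANCE
                            ) -> list[tuple[int, ...]]:
    """Candidate assignments of group anchors to fragment residue indices.

    Contiguous groups slide a window (donor sequence order preserved);
    spaced pairs enumerate index pairs whose fragment Cα–Cα distance is
    within ``spaced_tol`` of the donor anchors' Cα–Cα distance, in both
    chain directions.  A fragment shorter than the group yields no maps.
    """
    k = len(group)
    n = len(frag)
    if frag.ss_type != group.ss_type:
        raise ValueError(
            f"fragment type {frag.ss_type} does not match group {group.label} "
            f"({group.ss_type})")
    if n < k:
        return []
    if group.contiguity == "contiguous":
        return [tuple(range(i, i + k)) for i in range(n - k + 1)]
    if k != 2:
        raise ValueError("spaced enumeration implemented for anchor pairs")
    ca = frag.ca_coords()
    a1, a2 = (anchor_set.donor_residue(a).atom("CA").coords for a in group.anchors)
    d_donor = float(np.linalg.norm(a1 - a2))
    maps: list[tuple[int, ...]] = []
    for i, j in combinations(range(n), 2):
        d = float(np.linalg.norm(ca[i] - ca[j]))
        if abs(d - d_donor) <= spaced_tol:
            maps.append((i, j))
            maps.append((j, i))
    return maps


def _correspondence(frag: Fragment, group: AnchorGroup, anchor_set: AnchorSet,
                    pos_map: tuple[int, ...]) -> tuple[np.ndarray, np.ndarray]:
    """Matched (fragment, anchor) Cα+Cβ coordinate arrays for one map.

    A GLY on either side of a pairing contributes Cα only; the partner's Cβ
    is dropped to keep the correspondence consistent."""
    frag_pts, anchor_pts = [], []
    for anchor, idx in zip(group.anchors, pos_map):
        fres = frag.residues[idx]
        ares = anchor_set.donor_residue(anchor)
        frag_pts.append(fres.atom("CA").coords)
        anchor_pts.append(ares.atom("CA").coords)
        fcb, acb = fres.atom("CB"), ares.atom("CB")
        if fcb is not None and acb is not None:
            frag_pts.append(fcb.coords)
            anchor_pts.append(acb.coords)
    return np.array(frag_pts), np.array(anchor_pts)


def screen_fragment(frag: Fragment, group: AnchorGroup, anchor_set: AnchorSet,
                    rmsd_cutoff: float = DEFAULT_RMSD_CUTOFF,
                    spaced_tol: float = SPACED_CA_TOLERANCE) -> list[GraftMatch]:
    """Superpose the fragment onto the anchor group at every candidate map;
    keep matches with RMSD strictly below the cutoff, side chains grafted."""
    matches: list[GraftMatch] = []
    for pos_map in enumerate_position_maps(frag, group, anchor_set, spaced_tol):
        P, Q = _correspondence(frag, group, anchor_set, pos_map)
        if len(P) < 3:
            continue
        tf = kabsch_superpose(P, Q)
        if tf.rmsd < rmsd_cutoff:
            m = GraftMatch(fragment=frag, group_label=group.label,
                           position_map=pos_map, transform=tf, rmsd=tf.rmsd)
            m.grafted = graft_sidechains(m, group, anchor_set)
            matches.append(m)
    matches.sort(key=lambda m: (m.rmsd, m.position_map))
    return matches


def graft_sidechains(match: GraftMatch, group: AnchorGroup,
                     anchor_set: AnchorSet) -> Fragment:
    """Grafted fragment in the receptor frame.

    The scaffold backbone is carried rigidly through the match transform; at
    each mapped position the scaffold side chain is replaced by the donor
    anchor's side-chain heavy atoms at their donor coordinates (Cβ included,
    so the transplanted side chain keeps the donor's exact geometry), except
    at keep-original positions, which are left untouched."""
    grafted = match.fragment.copy()
    for r in grafted.residues:
        for a in r.atoms:
            a.coords = match.transform.rotation @ a.coords + match.transform.translation
    for anchor, idx in zip(group.anchors, match.position_map):
        if anchor.keep_original:
            continue
        donor_res = anchor_set.donor_residue(anchor)
        if donor_res.name != "GLY":
            expected = {name for name, _el, _xyz in sidechain_template(donor_res.name)[1]}
            have = {a.name for a in donor_res.sidechain_atoms()}
            missing = expected - have
            if missing:
                raise GraftError(
                    f"anchor {anchor.label()}: donor side chain missing atoms "
                    f"{sorted(missing)}")
        res = grafted.residues[idx]
        res.name = donor_res.name
        res.atoms = [a for a in res.atoms if a.is_backbone]
        for sc in donor_res.sidechain_atoms():
            res.atoms.append(Atom(name=sc.name, element=sc.element,
                                  coords=sc.coords.copy()))
    return grafted


# ---------------------------------------------------------------------------
# Clash filter


def _atom_arrays(atoms: list[Atom]) -> tuple[np.ndarray, np.ndarray]:
    if not atoms:
        return np.zeros((0, 3)), np.zeros((0,))
    return (np.array([a.coords for a in atoms]),
            np.array([a.vdw for a in atoms]))


def clash_check(atoms_a: list[Atom], atoms_b: list[Atom],
                scale: float = DEFAULT_CLASH_SCALE) -> int:
    """Number of cross-set heavy-atom pairs with d < scale·(rᵢ + rⱼ).

    Grid-accelerated via a k-d tree; exact (strict inequality), symmetric in
    its arguments, and equal to the quadratic double loop by construction
    (the tree only prunes pairs beyond the largest possible threshold)."""
    A, ra = _atom_arrays(atoms_a)
    B, rb = _atom_arrays(atoms_b)
    if len(A) == 0 or len(B) == 0 or scale <= 0:
        return 0
    rmax = scale * (ra.max() + rb.max())
    tree_b = cKDTree(B)
    neighbors = cKDTree(A).query_ball_tree(tree_b, r=rmax)
    n = 0
    for i, js in enumerate(neighbors):
        if not js:
            continue
        js = np.asarray(js)
        d = np.linalg.norm(B[js] - A[i], axis=1)
        n += int((d < scale * (ra[i] + rb[js])).sum())
    return n


def clash_check_structures(a: Structure | Fragment, b: Structure | Fragment,
                           scale: float = DEFAULT_CLASH_SCALE) -> int:
    def heavies(x):
        res = x.residues() if isinstance(x, Structure) else x.residues
        return [at for r in res for at in r.heavy_atoms()]
    return clash_check(heavies(a), heavies(b), scale=scale)


# ---------------------------------------------------------------------------
# Pairing


def pair_scaffolds(matches_1: list[GraftMatch], matches_2: list[GraftMatch],
                   receptor: Structure,
                   scale: float = DEFAULT_CLASH_SCALE) -> list[ScaffoldPair]:
    """Clash-filtered Cartesian product of the two match lists.

    A match whose grafted fragment clashes with the receptor is disqualified
    before pairing; surviving combinations are kept only when the two
    grafted fragments are mutually clash-free."""
    rec_atoms = [a for r in receptor.residues() for a in r.heavy_atoms()]

    def receptor_ok(m: GraftMatch) -> bool:
        atoms = [a for r in m.grafted.residues for a in r.heavy_atoms()]
        return clash_check(atoms, rec_atoms, scale=scale) == 0

    ok_1 = [m for m in matches_1 if receptor_ok(m)]
    ok_2 = [m for m in matches_2 if receptor_ok(m)]
    pairs: list[ScaffoldPair] = []
    for m1 in ok_1:
        atoms_1 = [a for r in m1.grafted.residues for a in r.heavy_atoms()]
        for m2 in ok_2:
            atoms_2 = [a for r in m2.grafted.residues for a in r.heavy_atoms()]
            n = clash_check(atoms_1, atoms_2, scale=scale)
            if n == 0:
                pairs.append(ScaffoldPair(match_a=m1, match_b=m2, n_clashes=n))
    return pairs
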