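"""Interface scoring, post-hoc design filters, and ranking.

The interface score is a transparent geometric surrogate for a full
energy-function interface analysis.  Its components:

* ``contact_score`` — Σ over cross-interface heavy-atom pairs of w(d),
  with w = 1 for d ≤ 4 Å falling linearly to 0 at 6 Å;
* ``hbond_count`` — N/O donor–acceptor pairs across the interface within
  3.5 Å whose angle at the donor-side base atom exceeds 120°;
* ``clash_penalty`` — heavy-atom clash count at vdW scale 0.75 (zero for
  any design that survived grafting);
* ``buried_proxy`` — SASA lost on complexation, Å².

``total = contact_score + 2·hbond_count − 10·clash_penalty +
0.05·buried_proxy``.  The weights are plumbing, config-exposed, and carry
no claim of energy-function parity: they exist to produce deterministic,
physically sensible orderings over candidate designs.

Two post-hoc filters codify the visual-inspection step of a design round:
designs whose peptide has too little regular secondary structure, or whose
anchor side chains drifted from the donor-defined positions, are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .grafting import clash_check
from .linker import DesignedPeptide, sasa
from .scaffoldlib import SSWindows, assign_secondary_structure
from .structcore import Structure

__all__ = [
    "ScoreWeights",
    "InterfaceScore",
    "score_interface",
    "filter_designs",
    "rank_and_select",
]

NO_INTERFACE_DISTANCE = 12.0  # Å; beyond this min cross distance → no interface


@dataclass(frozen=True)
class ScoreWeights:
    hbond: float = 2.0
    clash: float = 10.0
    buried: float = 0.05


@dataclass
class InterfaceScore:
    contact_score: float
    hbond_count: int
    clash_penalty: int
    buried_proxy: float
    no_interface: bool = False

    def total(self, w: ScoreWeights = ScoreWeights()) -> float:
        return (self.contact_score + w.hbond * self.hbond_count
                - w.clash * self.clash_penalty + w.buried * self.buried_proxy)


def _heavy(structure: Structure):
    return [a for r in structure.residues() for a in r.heavy_atoms()]


def _bonded_base(atom, residue):
    """Nearest heavy atom in the same residue (≤ 1.8 Å): the covalent base
    used for the angle test on heavy-atom-only structures."""
    best, best_d = None, 1.8
    for other in residue.heavy_atoms():
        if other is atom:
            continue
        d = float(np.linalg.norm(other.coords - atom.coords))
        if d < best_d:
            best, best_d = other, d
    return best


def _hbond_count(pep: Structure, rec: Structure) -> int:
    """Geometric H-bond count over heavy atoms: cross-interface N/O pairs
    within 3.5 Å with a base–donor···acceptor angle > 120° on at least one
    side (donor hydrogens are not present, so either atom may be the donor)."""
    def polar(structure):
        out = []
        for r in structure.residues():
            for a in r.heavy_atoms():
                if a.element in ("N", "O"):
                    out.append((a, r))
        return out

    pp, rp = polar(pep), polar(rec)
    if not pp or not rp:
        return 0
    rec_xyz = np.array([a.coords for a, _r in rp])
    tree = cKDTree(rec_xyz)
    n = 0
    for a, res_a in pp:
        for j in tree.query_ball_point(a.coords, 3.5):
            b, res_b = rp[j]
            if float(np.linalg.norm(a.coords - b.coords)) > 3.5:
                continue
            ok = False
            for donor, acceptor, res in ((a, b, res_a), (b, a, res_b)):
                base = _bonded_base(donor, res)
                if base is None:
                    ok = True  # isolated polar atom: no geometry to violate
                    break
                v1 = base.coords - donor.coords
                v2 = acceptor.coords - donor.coords
                cosang = float(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                if cosang < -0.5:  # angle > 120°
                    ok = True
                    break
            n += ok
    return n


def score_interface(pep: DesignedPeptide | Structure, receptor: Structure,
                    clash_scale: float = 0.75) -> InterfaceScore:
    """Score the peptide–receptor interface (heavy atoms only)."""
    pep_struct = pep.structure if isinstance(pep, DesignedPeptide) else pep
    pa, ra = _heavy(pep_struct), _heavy(receptor)
    pxyz = np.array([a.coords for a in pa])
    rxyz = np.array([a.coords for a in ra])
    tree = cKDTree(rxyz)
    dmin, _ = tree.query(pxyz)
    if dmin.min() > NO_INTERFACE_DISTANCE:
        return InterfaceScore(0.0, 0, 0, 0.0, no_interface=True)

    contact = 0.0
    for i, a in enumerate(pa):
        for j in tree.query_ball_point(a.coords, 6.0):
            d = float(np.linalg.norm(a.coords - rxyz[j]))
            if d <= 4.0:
                contact += 1.0
            elif d < 6.0:
                contact += (6.0 - d) / 2.0

    hb = _hbond_count(pep_struct, receptor)
    clashes = clash_check(pa, ra, scale=clash_scale)

    complex_st = Structure(id="cx")
    complex_st.chains["P"] = [r.copy() for r in pep_struct.residues()]
    for cid, ch in receptor.chains.items():
        complex_st.chains[f"_{cid}"] = [r.copy() for r in ch]
    buried = float(sasa(pep_struct).sum() + sasa(receptor).sum()
                   - sasa(complex_st).sum())
    return InterfaceScore(contact_score=contact, hbond_count=hb,
                          clash_penalty=clashes, buried_proxy=buried)


def anchor_deviation(design: DesignedPeptide,
                     anchor_ref: dict[str, tuple[np.ndarray, np.ndarray]]) -> float:
    """Worst-anchor side-chain orientation deviation (Å) of a design.

    Side-chain coordinates are transplanted rigidly from the donor, so the
    copied atoms themselves cannot drift; what can disagree is the backbone
    frame that presents them.  The deviation therefore re-attaches the donor
    side chain to the design's own backbone: the donor residue's N/CA/C
    triad is superposed onto the design residue's triad, the donor
    side-chain centroid is carried through that transform, and the
    displacement from the donor-defined centroid is reported.  A design
    whose anchor-bearing backbone matches the donor scores ~0 regardless of
    residue identity, which also makes the measure meaningful at
    keep-original positions.
    """
    from .structcore import kabsch_superpose

    dev = 0.0
    for label, pos in design.anchor_positions.items():
        ref = anchor_ref.get(label)
        if ref is None:
            continue
        donor_triad, donor_centroid = ref
        res = design.residues[pos - 1]
        triad = np.array([res.atom(x).coords for x in ("N", "CA", "C")])
        tf = kabsch_superpose(donor_triad, triad)
        cur = tf.rotation @ donor_centroid + tf.translation
        dev = max(dev, float(np.linalg.norm(cur - donor_centroid)))
    return dev


def filter_designs(designs: list[DesignedPeptide],
                   anchor_ref: dict[str, tuple[np.ndarray, np.ndarray]],
                   ss_min_frac: float = 0.6, anchor_dev_max: float = 2.5,
                   windows: SSWindows = SSWindows()
                   ) -> tuple[list[DesignedPeptide], dict[str, list[str]]]:
    """Keep designs with enough regular secondary structure and with anchor
    side chains still oriented as the donor defined them.

    ``anchor_ref`` maps anchor labels to (donor backbone triad, donor
    side-chain centroid); see :func:`anchor_deviation`.  Returns the kept
    designs and per-design rejection reasons ("ss", "anchor_orientation").
    """
    kept: list[DesignedPeptide] = []
    reasons: dict[str, list[str]] = {}
    for d in designs:
        why: list[str] = []
        labels = assign_secondary_structure(d.structure, windows)["P"]
        non_linker = [i for i in range(1, len(labels) + 1) if not d.is_linker(i)]
        if non_linker:
            frac = sum(labels[i - 1] in "HE" for i in non_linker) / len(non_linker)
            if frac < ss_min_frac:
                why.append("ss")
        if anchor_deviation(d, anchor_ref) > anchor_dev_max:
            why.append("anchor_orientation")
        name = d.provenance.get("id", d.sequence)
        reasons[name] = why
        if not why:
            kept.append(d)
    return kept, reasons


def rank_and_select(designs: list[DesignedPeptide], k: int,
                    weights: ScoreWeights = ScoreWeights()
                    ) -> list[DesignedPeptide]:
    """Top-k designs by total interface score (descending); deterministic
    tie-break on (hbond_count desc, sequence).  Requires scores attached."""
    if k <= 0:
        raise ValueError("k must be positive")
    def sort_key(d: DesignedPeptide):
        s: InterfaceScore = d.scores["interface"]
        return (-s.total(weights), -s.hbond_count, d.sequence)
    return sorted(designs, key=sort_key)[:k]
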