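"""Scaffold fragment library: secondary structure, extraction, persistence.

Scaffold fragments are maximal runs of helix (H) or strand (E) residues
harvested from structures; strand fragments are kept only when they pair
into a sheet with another strand.  Secondary structure is assigned from
backbone torsions with configurable (phi, psi) windows rather than from
hydrogen-bond patterns: the fragments this library exists for are regular,
near-ideal segments, for which torsion windows are an adequate and
dependency-free criterion.

The on-disk format is JSON lines: one header record (format version, build
parameters, counts) followed by one record per fragment.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .structcore import Atom, Residue, Structure, parse_pdb

__all__ = [
    "SSWindows",
    "Fragment",
    "ScaffoldLibrary",
    "assign_secondary_structure",
    "extract_fragments",
    "strand_in_sheet",
    "build_library",
    "build_library_from_structures",
    "save_library",
    "load_library",
]

LIBRARY_FORMAT_VERSION = 1


@dataclass(frozen=True)
class SSWindows:
    """Torsion windows (degrees) for secondary-structure assignment."""
    helix_phi: tuple[float, float] = (-100.0, -30.0)
    helix_psi: tuple[float, float] = (-80.0, -5.0)
    strand_phi: tuple[float, float] = (-180.0, -40.0)
    strand_psi: tuple[float, float] = (90.0, 180.0)
    strand_psi_wrap: tuple[float, float] = (-180.0, -170.0)


def assign_secondary_structure(s: Structure, windows: SSWindows = SSWindows()
                               ) -> dict[str, list[str]]:
    """Per-residue H/E/C labels for every chain.

    H iff (phi, psi) falls in the helical window, E iff in the extended
    window (psi wraps across ±180°), else C.  Residues with undefined
    torsions (termini, missing atoms) are C.
    """
    from .structcore import backbone_dihedrals

    out: dict[str, list[str]] = {}
    for chain_id in s.chains:
        labels = []
        for phi, psi, _omega in backbone_dihedrals(s, chain_id):
            if phi is None or psi is None:
                labels.append("C")
            elif windows.helix_phi[0] <= phi <= windows.helix_phi[1] and \
                    windows.helix_psi[0] <= psi <= windows.helix_psi[1]:
                labels.append("H")
            elif windows.strand_phi[0] <= phi <= windows.strand_phi[1] and (
                    windows.strand_psi[0] <= psi <= windows.strand_psi[1]
                    or windows.strand_psi_wrap[0] <= psi <= windows.strand_psi_wrap[1]):
                labels.append("E")
            else:
                labels.append("C")
        out[chain_id] = labels
    return out


@dataclass
class Fragment:
    source_id: str
    chain_id: str
    ss_type: str  # 'H' or 'E'
    start: int  # 0-based half-open over the source chain
    end: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ss_type not in ("H", "E"):
            raise ValueError(f"ss_type must be 'H' or 'E', got {self.ss_type!r}")
        if self.end - self.start != len(self.residues) or not self.residues:
            raise ValueError("fragment length inconsistent with residue list")
        for r in self.residues:
            if not r.has_backbone():
                raise ValueError(
                    f"fragment {self.key()}: residue {r.seq_id} missing backbone")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues)

    def key(self) -> tuple:
        return (self.source_id, self.chain_id, self.start, self.end)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.atom("CA").coords for r in self.residues])

    def heavy_atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.heavy_atoms()]

    def copy(self) -> "Fragment":
        return Fragment(self.source_id, self.chain_id, self.ss_type,
                        self.start, self.end, [r.copy() for r in self.residues])

    def as_structure(self, chain_id: str = "P") -> Structure:
        st = Structure(id=f"{self.source_id}:{self.chain_id}:{self.start}-{self.end}")
        st.chains[chain_id] = [r.copy() for r in self.residues]
        return st


def extract_fragments(s: Structure, min_helix: int = 6, min_strand: int = 3,
                      windows: SSWindows = SSWindows()) -> list[Fragment]:
    """Maximal H/E runs meeting the per-type minimum length, full-atom copies."""
    labels = assign_secondary_structure(s, windows)
    min_len = {"H": min_helix, "E": min_strand}
    frags: list[Fragment] = []
    for chain_id, lab in labels.items():
        residues = s.chains[chain_id]
        i = 0
        while i < len(lab):
            if lab[i] in ("H", "E"):
                j = i
                while j < len(lab) and lab[j] == lab[i]:
                    j += 1
                run = residues[i:j]
                if j - i >= min_len[lab[i]] and all(r.has_backbone() for r in run):
                    frags.append(Fragment(source_id=s.id, chain_id=chain_id,
                                          ss_type=lab[i], start=i, end=j,
                                          residues=[r.copy() for r in run]))
                i = j
            else:
                i += 1
    return frags


def strand_in_sheet(frag: Fragment, s: Structure, max_ca_dist: float = 5.5,
                    min_frac: float = 0.5, min_strand: int = 3,
                    windows: SSWindows = SSWindows()) -> bool:
    """True iff ≥ ``min_frac`` of the strand's residues have a Cα within
    ``max_ca_dist`` Å of a Cα belonging to a *different* strand fragment of
    the parent structure (a cheap surrogate for inter-strand H-bonding)."""
    if frag.ss_type != "E":
        raise ValueError("strand_in_sheet is defined for strand fragments only")
    others = [f for f in extract_fragments(s, min_strand=min_strand, windows=windows)
              if f.ss_type == "E" and f.key() != frag.key()]
    if not others:
        return False
    other_ca = np.vstack([f.ca_coords() for f in others])
    own_ca = frag.ca_coords()
    d = np.linalg.norm(own_ca[:, None, :] - other_ca[None, :, :], axis=2)
    n_paired = int((d.min(axis=1) <= max_ca_dist).sum())
    return n_paired >= min_frac * len(frag)


@dataclass
class ScaffoldLibrary:
    fragments: list[Fragment] = field(default_factory=list)
    build_params: dict = field(default_factory=dict)

    @property
    def counts(self) -> dict[str, int]:
        return {"H": sum(1 for f in self.fragments if f.ss_type == "H"),
                "E": sum(1 for f in self.fragments if f.ss_type == "E")}

    def __len__(self) -> int:
        return len(self.fragments)

    def helices(self) -> list[Fragment]:
        return [f for f in self.fragments if f.ss_type == "H"]

    def strands(self) -> list[Fragment]:
        return [f for f in self.fragments if f.ss_type == "E"]


def build_library_from_structures(structures: list[Structure], min_helix: int = 6,
                                  min_strand: int = 3,
                                  windows: SSWindows = SSWindows(),
                                  sheet_max_ca_dist: float = 5.5,
                                  sheet_min_frac: float = 0.5) -> ScaffoldLibrary:
    """Extract, sheet-filter and de-duplicate fragments from parsed structures."""
    if not structures:
        raise ValueError("no structures to build a library from")
    seen: set[tuple] = set()
    fragments: list[Fragment] = []
    for s in structures:
        for frag in extract_fragments(s, min_helix=min_helix, min_strand=min_strand,
                                      windows=windows):
            if frag.key() in seen:
                continue
            if frag.ss_type == "E" and not strand_in_sheet(
                    frag, s, max_ca_dist=sheet_max_ca_dist, min_frac=sheet_min_frac,
                    min_strand=min_strand, windows=windows):
                continue
            seen.add(frag.key())
            fragments.append(frag)
    fragments.sort(key=Fragment.key)
    params = {"min_helix": min_helix, "min_strand": min_strand,
              "sheet_max_ca_dist": sheet_max_ca_dist, "sheet_min_frac": sheet_min_frac,
              "windows": vars(windows) if not isinstance(windows, SSWindows)
              else {k: list(v) for k, v in windows.__dict__.items()}}
    return ScaffoldLibrary(fragments=fragments, build_params=params)


def build_library(paths: list, **kwargs) -> ScaffoldLibrary:
    """Parse PDB files and build a library; unparseable files are skipped with
    a warning, zero parseable inputs is an error."""
    structures = []
    for p in paths:
        try:
            structures.append(parse_pdb(p))
        except (IOError, ValueError) as exc:
            warnings.warn(f"skipping {p}: {exc}")
    if not structures:
        raise ValueError("no parseable input structures")
    return build_library_from_structures(structures, **kwargs)


# ---------------------------------------------------------------------------
# Persistence (.sclib.jsonl)


def _fragment_record(frag: Fragment) -> dict:
    return {
        "source_id": frag.source_id,
        "chain_id": frag.chain_id,
        "ss_type": frag.ss_type,
        "start": frag.start,
        "end": frag.end,
        "sequence": frag.sequence,
        "residues": [
            {"name": r.name, "seq_id": r.seq_id, "icode": r.icode,
             "atoms": [[a.name, a.element, round(float(a.coords[0]), 4),
                        round(float(a.coords[1]), 4), round(float(a.coords[2]), 4)]
                       for a in r.atoms]}
            for r in frag.residues
        ],
    }


def _fragment_from_record(rec: dict) -> Fragment:
    residues = [
        Residue(name=r["name"], seq_id=r["seq_id"], chain_id=rec["chain_id"],
                icode=r.get("icode", ""),
                atoms=[Atom(name=a[0], element=a[1], coords=np.array(a[2:5]))
                       for a in r["atoms"]])
        for r in rec["residues"]
    ]
    return Fragment(source_id=rec["source_id"], chain_id=rec["chain_id"],
                    ss_type=rec["ss_type"], start=rec["start"], end=rec["end"],
                    residues=residues)


def save_library(lib: ScaffoldLibrary, path) -> None:
    with open(path, "w") as fh:
        header = {"format": "sclib", "version": LIBRARY_FORMAT_VERSION,
                  "params": lib.build_params, "counts": lib.counts}
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for frag in sorted(lib.fragments, key=Fragment.key):
            fh.write(json.dumps(_fragment_record(frag), sort_keys=True) + "\n")


def load_library(path) -> ScaffoldLibrary:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty library file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: line 1: bad header ({exc})") from exc
    if header.get("format") != "sclib":
        raise ValueError(f"{path}: not a scaffold library file")
    if header.get("version") != LIBRARY_FORMAT_VERSION:
        raise ValueError(f"{path}: library format version {header.get('version')} "
                         f"≠ supported {LIBRARY_FORMAT_VERSION}")
    fragments = []
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            fragments.append(_fragment_from_record(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError) as exc:
            raise ValueError(f"{path}: line {i}: bad fragment record ({exc})") from exc
    if not fragments:
        warnings.warn(f"{path}: header-only library (0 fragments)")
    lib = ScaffoldLibrary(fragments=fragments, build_params=header.get("params", {}))
    expected = header.get("counts")
    if expected is not None and expected != lib.counts:
        raise ValueError(f"{path}: header counts {expected} ≠ actual {lib.counts}")
    return lib
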