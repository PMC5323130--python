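"""Ideal side-chain placement from CCD residue templates.

Side chains are attached to an existing backbone by superposing the ideal
residue's N/CA/C triad onto the target backbone triad and copying the heavy
side-chain atoms (CB included).  The templates come from the chemical
component dictionary bundled with biotite, so the geometry is the standard
idealized one (roughly an extended rotamer); no rotamer sampling is done.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from biotite.structure.info import residue as _ccd_residue

from .structcore import Atom, Residue, kabsch_superpose

__all__ = ["sidechain_template", "mutate_residue"]

_BACKBONE = ("N", "CA", "C")


@lru_cache(maxsize=64)
def sidechain_template(res_name: str) -> tuple[np.ndarray, list[tuple[str, str, np.ndarray]]]:
    """Return (backbone N/CA/C coords, [(atom name, element, coords), ...]) for
    the heavy side-chain atoms of an ideal residue."""
    arr = _ccd_residue(res_name.upper())
    if arr is None:
        raise KeyError(f"no ideal template for residue {res_name!r}")
    names = list(arr.atom_name)
    idx = {n: i for i, n in enumerate(names)}
    for bb in _BACKBONE:
        if bb not in idx:
            raise KeyError(f"template {res_name}: missing backbone atom {bb}")
    bb_coords = np.array([arr.coord[idx[n]] for n in _BACKBONE], dtype=float)
    side = []
    for i, n in enumerate(names):
        if n in ("N", "CA", "C", "O", "OXT") or arr.element[i] == "H":
            continue
        side.append((n, str(arr.element[i]).capitalize(), np.array(arr.coord[i], dtype=float)))
    return bb_coords, side


def mutate_residue(res: Residue, new_name: str) -> Residue:
    """Replace a residue's side chain by the ideal side chain of ``new_name``.

    Backbone atoms (N, CA, C, O) are untouched; existing side-chain atoms are
    discarded.  GLY simply loses its side chain.
    """
    bb = {}
    for n in _BACKBONE:
        a = res.atom(n)
        if a is None:
            raise ValueError(f"residue {res.chain_id}/{res.seq_id}: missing backbone atom {n}")
        bb[n] = a.coords
    new_atoms = [a.copy() for a in res.atoms if a.name in ("N", "CA", "C", "O", "OXT")]
    if new_name.upper() != "GLY":
        tmpl_bb, side = sidechain_template(new_name)
        tf = kabsch_superpose(tmpl_bb, np.array([bb[n] for n in _BACKBONE]))
        for name, element, xyz in side:
            new_atoms.append(Atom(name=name, element=element, coords=tf.apply(xyz)))
    return Residue(name=new_name.upper(), seq_id=res.seq_id, chain_id=res.chain_id,
                   atoms=new_atoms, icode=res.icode)
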