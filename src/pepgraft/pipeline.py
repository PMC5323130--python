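"""End-to-end design pipeline: graft → pair → link → score → select.

The pipeline takes a scaffold library and an anchor set, screens every
type-compatible fragment against each anchor group, clash-filters scaffold
pairs, closes each pair into a continuous peptide, assigns sequence, scores
the interface, applies the secondary-structure and anchor-orientation
filters, and returns the top-k designs together with a provenance manifest
(per-stage counts, config, seeds) sufficient to reproduce every design.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import pepprops
from .grafting import (AnchorSet, GraftMatch, ScaffoldPair, pair_scaffolds,
                       screen_fragment)
from .linker import (DesignedPeptide, LoopBuildSpec, assign_linker_sequence,
                     ccd_close, choose_topology, fix_exposed_hydrophobics,
                     linker_length, validate_continuity)
from .scaffoldlib import ScaffoldLibrary
from .scoring import ScoreWeights, filter_designs, rank_and_select, score_interface
from .structcore import Structure, write_pdb

__all__ = ["PipelineConfig", "validate_config", "run_pipeline", "PipelineResult"]


@dataclass
class PipelineConfig:
    rmsd_cutoff: float = 2.0  # Å, anchor-superposition screen
    clash_scale: float = 0.75  # vdW scale of the steric filter
    min_helix: int = 6
    min_strand: int = 3
    spaced_tol: float = 2.0  # Å window on spaced-anchor Cα–Cα distance
    sasa_threshold: float = 0.4  # relative side-chain SASA counted as exposed
    sasa_points: int = 240  # sphere points during sequence design
    ss_min_frac: float = 0.6
    anchor_dev_max: float = 2.5  # Å
    top_k: int = 4  # designs selected for "synthesis"
    seed: int = 0
    closure_tol: float = 0.15
    max_iter: int = 300
    best_per_fragment: bool = True  # keep only the best-RMSD map per fragment
    max_designs: int = 40  # beam width: pairs are linked in best-RMSD order
    # until this many designs are built (desk-scale cap; 0 = unlimited)
    cluster_rmsd: float = 0.75  # Å; designs whose anchor-bearing backbones
    # coincide below this are redundant — the best-anchor-fidelity
    # representative is kept (standard design clustering; 0 disables)
    weight_hbond: float = 2.0
    weight_clash: float = 10.0
    weight_buried: float = 0.05

    _RANGES = {
        "rmsd_cutoff": (0.0, 10.0), "clash_scale": (0.0, 2.0),
        "min_helix": (1, 100), "min_strand": (1, 100),
        "spaced_tol": (0.0, 10.0), "sasa_threshold": (0.0, 1.0),
        "sasa_points": (10, 10000), "ss_min_frac": (0.0, 1.0),
        "anchor_dev_max": (0.0, 100.0), "top_k": (1, 10000),
        "closure_tol": (0.0, 1.0), "max_iter": (0, 100000),
        "max_designs": (0, 1000000), "cluster_rmsd": (0.0, 10.0),
    }

    def __post_init__(self) -> None:
        for key, (lo, hi) in self._RANGES.items():
            v = getattr(self, key)
            if not lo <= v <= hi:
                raise ValueError(f"config {key}={v} outside [{lo}, {hi}]")

    def weights(self) -> ScoreWeights:
        return ScoreWeights(hbond=self.weight_hbond, clash=self.weight_clash,
                            buried=self.weight_buried)

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items()}


def validate_config(path) -> PipelineConfig:
    """Load a YAML/JSON config; unknown keys are rejected, ranges checked,
    missing keys take the documented defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    valid = set(PipelineConfig.__dataclass_fields__) - {"_RANGES"}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    designs: list[DesignedPeptide]  # ranked, top-k
    all_designs: list[DesignedPeptide]
    manifest: dict

    @property
    def counts(self) -> dict:
        return self.manifest["counts"]


def _anchor_reference(anchors: AnchorSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Donor-frame (backbone N/CA/C triad, side-chain centroid) per anchor."""
    ref = {}
    for g in anchors.groups.values():
        for a in g.anchors:
            res = anchors.donor_residue(a)
            triad = np.array([res.atom(x).coords for x in ("N", "CA", "C")])
            sc = res.sidechain_atoms()
            centroid = (np.mean([at.coords for at in sc], axis=0) if sc
                        else res.atom("CA").coords.copy())
            ref[a.label()] = (triad, centroid)
    return ref


def _annotate_anchor_positions(pep: DesignedPeptide, pair: ScaffoldPair,
                               first_match: GraftMatch, anchors: AnchorSet,
                               n_first: int, n_linker: int) -> None:
    keep: list[int] = []
    positions: dict[str, int] = {}
    for match, offset in ((pair.match_a, None), (pair.match_b, None)):
        is_first = match is first_match
        base = 0 if is_first else n_first + n_linker
        group = anchors.groups[match.group_label]
        for anchor, idx in zip(group.anchors, match.position_map):
            pos = base + idx + 1
            positions[anchor.label()] = pos
            if anchor.keep_original:
                keep.append(pos)
    pep.anchor_positions = positions
    pep.keep_original_positions = tuple(sorted(keep))


def _anchor_backbone(pep: DesignedPeptide) -> np.ndarray:
    """Concatenated N/CA/C coordinates of the anchor-bearing residues, in a
    fixed label order (all designs live in the receptor frame, so direct
    coordinate RMSD is meaningful)."""
    pts = []
    for label in sorted(pep.anchor_positions):
        res = pep.residues[pep.anchor_positions[label] - 1]
        for name in ("N", "CA", "C"):
            pts.append(res.atom(name).coords)
    return np.array(pts)


def _cluster_designs(designs: list[DesignedPeptide],
                     cluster_rmsd: float) -> list[DesignedPeptide]:
    """Greedy leader clustering on anchor-backbone RMSD.

    Designs are visited in order of anchor-superposition fidelity (sum of
    the two match RMSDs, ties by id); a design joins an existing cluster if
    its anchor backbone lies within ``cluster_rmsd`` of the cluster leader,
    otherwise it founds a new cluster.  Leaders are returned."""
    def fidelity(d: DesignedPeptide):
        return (d.provenance["rmsd_a"] + d.provenance["rmsd_b"],
                d.provenance["id"])

    leaders: list[tuple[np.ndarray, DesignedPeptide]] = []
    for d in sorted(designs, key=fidelity):
        bb = _anchor_backbone(d)
        redundant = False
        for lead_bb, _lead in leaders:
            if bb.shape == lead_bb.shape:
                rmsd = float(np.sqrt(np.mean(np.sum((bb - lead_bb) ** 2, axis=1))))
                if rmsd < cluster_rmsd:
                    redundant = True
                    break
        if not redundant:
            leaders.append((bb, d))
    return [d for _bb, d in leaders]


def run_pipeline(config: PipelineConfig, library: ScaffoldLibrary,
                 anchors: AnchorSet, outdir=None) -> PipelineResult:
    """Execute the full design pipeline; see module docstring.

    Exactly two anchor groups are expected (one per scaffold of the pair).
    Any stage producing zero survivors terminates cleanly with partial
    counts in the manifest.
    """
    group_labels = list(anchors.groups)
    if len(group_labels) != 2:
        raise ValueError("pipeline expects exactly two anchor groups")
    counts: dict = {}
    manifest = {"config": config.to_dict(), "counts": counts, "designs": []}

    # stage 1: screen fragments per group
    matches: dict[str, list[GraftMatch]] = {}
    total_maps: dict[str, int] = {}
    for gl in group_labels:
        group = anchors.groups[gl]
        found: list[GraftMatch] = []
        for frag in library.fragments:
            if frag.ss_type != group.ss_type:
                continue
            ms = screen_fragment(frag, group, anchors,
                                 rmsd_cutoff=config.rmsd_cutoff,
                                 spaced_tol=config.spaced_tol)
            total_maps[gl] = total_maps.get(gl, 0) + len(ms)
            if config.best_per_fragment and ms:
                ms = ms[:1]
            found.extend(ms)
        found.sort(key=lambda m: (m.rmsd, m.id()))
        matches[gl] = found
        counts[f"matches_{gl}"] = len(found)
        counts[f"maps_{gl}"] = total_maps.get(gl, 0)
    if not all(matches.values()):
        counts["stage_failed"] = "screening"
        return PipelineResult([], [], manifest)

    # stage 2: pair + clash filter
    m1, m2 = matches[group_labels[0]], matches[group_labels[1]]
    counts["pairs_possible"] = len(m1) * len(m2)
    pairs = pair_scaffolds(m1, m2, anchors.receptor, scale=config.clash_scale)
    counts["pairs_clash_free"] = len(pairs)
    if not pairs:
        counts["stage_failed"] = "pairing"
        return PipelineResult([], [], manifest)

    # stage 3: link into continuous peptides (best-RMSD pairs first, up to
    # the design beam width)
    designs: list[DesignedPeptide] = []
    closures_attempted = closures_ok = 0
    pairs = sorted(pairs, key=lambda p: (p.match_a.rmsd + p.match_b.rmsd, p.id()))
    for pair in pairs:
        if config.max_designs and len(designs) >= config.max_designs:
            break
        first, second, gap = choose_topology(pair.match_a.grafted,
                                             pair.match_b.grafted)
        first_match = pair.match_a if first is pair.match_a.grafted else pair.match_b
        try:
            n = linker_length(gap)
        except ValueError:
            continue
        pep = None
        for n_try in (n, n + 1, n + 2):
            if n_try > 8:
                break
            closures_attempted += 1
            res = ccd_close(first, second, LoopBuildSpec(
                n_linker=n_try, max_iter=config.max_iter,
                closure_tol=config.closure_tol, seed=config.seed))
            if res.success:
                closures_ok += 1
                pep = res.peptide
                break
        if pep is None:
            continue
        _annotate_anchor_positions(pep, pair, first_match, anchors,
                                   n_first=len(first.residues),
                                   n_linker=pep.provenance["n_linker"])
        pep.provenance.update({"id": f"design_{len(designs):03d}",
                               "pair": pair.id(), "gap": round(gap, 3),
                               "rmsd_a": round(pair.match_a.rmsd, 4),
                               "rmsd_b": round(pair.match_b.rmsd, 4)})
        pep = assign_linker_sequence(pep, anchors.receptor,
                                     exposure_threshold=config.sasa_threshold,
                                     n_points=config.sasa_points)
        pep = fix_exposed_hydrophobics(pep, anchors.receptor,
                                       exposure_threshold=config.sasa_threshold,
                                       n_points=config.sasa_points)
        designs.append(pep)
    counts["closures_attempted"] = closures_attempted
    counts["closures_succeeded"] = closures_ok
    counts["designs_built"] = len(designs)
    if not designs:
        counts["stage_failed"] = "linking"
        return PipelineResult([], [], manifest)

    # stage 3b: cluster structurally redundant designs — many scaffolds
    # present the anchor constellation with essentially the same backbone;
    # the representative with the best anchor-superposition fidelity is kept
    if config.cluster_rmsd > 0:
        designs = _cluster_designs(designs, config.cluster_rmsd)
    counts["designs_after_clustering"] = len(designs)

    # stage 4: score, filter, rank
    for pep in designs:
        pep.scores["interface"] = score_interface(pep, anchors.receptor,
                                                  clash_scale=config.clash_scale)
        pep.scores["continuity_violations"] = validate_continuity(pep)
    kept, reasons = filter_designs(designs, _anchor_reference(anchors),
                                   ss_min_frac=config.ss_min_frac,
                                   anchor_dev_max=config.anchor_dev_max)
    counts["designs_kept"] = len(kept)
    manifest["filter_reasons"] = reasons
    pool = kept if kept else []
    if not pool:
        counts["stage_failed"] = "filtering"
        return PipelineResult([], designs, manifest)
    ranked = rank_and_select(pool, k=config.top_k, weights=config.weights())
    counts["designs_selected"] = len(ranked)

    for rank, pep in enumerate(ranked, start=1):
        sc = pep.scores["interface"]
        manifest["designs"].append({
            "rank": rank,
            "id": pep.provenance["id"],
            "sequence": pep.sequence,
            "mw": round(pepprops.peptide_mw(pep.sequence), 2),
            "anchor_positions": pep.anchor_positions,
            "pair": pep.provenance["pair"],
            "n_linker": pep.provenance["n_linker"],
            "contact_score": round(sc.contact_score, 3),
            "hbond_count": sc.hbond_count,
            "clash_penalty": sc.clash_penalty,
            "buried_proxy": round(sc.buried_proxy, 2),
            "total": round(sc.total(config.weights()), 3),
        })

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        for pep in ranked:
            cx = Structure(id=pep.provenance["id"])
            cx.chains["P"] = [r.copy() for r in pep.residues]
            for cid, ch in anchors.receptor.chains.items():
                cx.chains[cid] = [r.copy() for r in ch]
            write_pdb(cx, outdir / f"{pep.provenance['id']}.pdb")
    return PipelineResult(ranked, designs, manifest)
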