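# pepgraft

De novo design of peptide binders by hotspot anchor grafting.

Protein–protein interfaces are dominated by a few hotspot residues. Given a
complex structure and a list of such *anchor* residues on the natural
ligand, pepgraft builds short peptides that present the same anchor
constellation on rigid helix/strand scaffolds: it harvests scaffold
fragments from structures, superposes them onto the anchors over the
corresponding Cα/Cβ atoms (keeping matches with RMSD < 2.0 Å), transplants
the anchor side chains, removes sterically incompatible scaffold pairs
(heavy-atom distance < 0.75 × the sum of van der Waals radii), fuses each
surviving pair into one continuous peptide by CCD loop closure, assigns a
polar sequence to the non-anchor positions, and ranks the designs by a
geometric interface score. The motivating application is peptide inhibitors
of the hPD-1/hPD-L1 immune checkpoint, where five hPD-L1 residues (Y56,
R113, A121, D122, Y123) serve as anchors; the package also ships the
published peptide panel from that campaign together with average-mass and
alanine-scan utilities, and a steady-state SPR module that fits
RU(C) = Rmax·C/(KD + C) and simulates competitive binding.

The audience is structural bioinformaticians prototyping anchor-grafting
design protocols, and anyone needing its self-contained building blocks
(Kabsch superposition, torsion-window secondary structure, Shrake–Rupley
SASA, CCD closure, Langmuir fitting) without a molecular-modelling suite.

## Worked example

Everything below runs on synthetic inputs generated by the package — no
external structure files needed.

```python
from pepgraft import fixtures as fx
from pepgraft.grafting import Anchor, AnchorGroup, AnchorSet
from pepgraft.scaffoldlib import build_library_from_structures
from pepgraft.pipeline import PipelineConfig, run_pipeline

# a toy receptor + docked donor with 5 planted anchors, and 20 decoys
toy = fx.make_toy_complex(seed=0)
library = build_library_from_structures(
    [toy.donor] + fx.make_decoy_library_structures(20, seed=1))

groups = {
    label: AnchorGroup(label=label, ss_type=g["ss_type"],
                       contiguity=g["contiguity"],
                       anchors=[Anchor(a["chain"], a["seq_id"], a["name"],
                                       a["keep_original"])
                                for a in g["anchors"]])
    for label, g in toy.anchor_spec["groups"].items()}
anchors = AnchorSet(receptor=toy.receptor, donor=toy.donor, groups=groups)

result = run_pipeline(PipelineConfig(seed=7), library, anchors)
top = result.designs[0]
print(top.sequence, top.provenance["pair"])
print(result.counts)
```

prints (library: 11 helices, 20 sheet-paired strands):

```
SYRSSSSRSDSSEADYS toydonor_s0:H:1-11@1,7|toydonor_s0:S:1-5@0,1,2
{'matches_helix_group': 10, 'maps_helix_group': 146,
 'matches_strand_group': 20, 'maps_strand_group': 36,
 'pairs_possible': 200, 'pairs_clash_free': 200,
 'closures_attempted': 45, 'closures_succeeded': 40,
 'designs_built': 40, 'designs_after_clustering': 1,
 'designs_kept': 1, 'designs_selected': 1}
```

The top-ranked 17-mer was built from the donor's own helix (anchor
positions 1 and 7) and first hairpin strand (positions 0–2) — the planted
ground truth — with its five anchors at positions 2/8 (helix Tyr/Arg) and
14/15/16 (strand Ala/Asp/Tyr), zero steric clashes with the receptor, and
a continuous backbone. The per-stage counts show the funnel: 200 candidate
pairs, 40 linked designs, 1 structurally distinct design after clustering.

Sequence utilities reproduce the published peptide masses:

```python
>>> from pepgraft.pepprops import peptide_mw, alanine_mutant, PeptideRecord
>>> peptide_mw("GNWDYNSQRAQLYNQ")          # the best published binder
1856.9284
>>> alanine_mutant(PeptideRecord(name="Ar5Y_4",
...                              sequence="GNWDYNSQRAQLYNQ"), 3).mw
1741.794                                    # W3A, printed value 1741.81
```

and the SPR module recovers binding constants from titrations:

```python
>>> from pepgraft.sprfit import make_isotherm, fit_steady_state
>>> iso = fit_steady_state(make_isotherm(kd=1.38, rmax=100,
...     concs=[0.098, 0.195, 0.39, 0.78, 1.56, 3.13, 6.25, 12.5]))
>>> round(iso.fitted_kd, 4)
1.38
```

A `pepgraft` console script exposes the same functionality
(`build-library`, `graft`, `design`, `mw`, `mutants`, `spr-fit`,
`spr-sim`, `make-fixtures`); an anchor specification for the
hPD-1/hPD-L1 system ships as package data
(`src/pepgraft/data/pd1_anchors.yaml`, expecting PDB entry 4ZQK alongside).

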