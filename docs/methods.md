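# Methods

pepgraft implements a four-stage de novo peptide binder design workflow
built on the hotspot theory of protein–protein interfaces: a handful of
interface residues (anchors) contribute most of the binding free energy, so
a small peptide that presents the same anchor constellation on a rigid
scaffold can compete with the full-length ligand. The concrete use case is
the design of peptides that bind the immune checkpoint receptor hPD-1 by
transplanting five hPD-L1 hotspot residues (Y56, R113, A121, D122, Y123)
onto helix and strand scaffolds.

## Pipeline model

1. **Scaffold library.** Helix and strand fragments are harvested from
   structures. Secondary structure is assigned from backbone torsions:
   H iff φ ∈ [−100°, −30°] and ψ ∈ [−80°, −5°]; E iff φ ∈ [−180°, −40°]
   and ψ ∈ [90°, 180°] ∪ [−180°, −170°]; otherwise C. Fragments are
   maximal single-label runs (helix ≥ 6 residues, strand ≥ 3, both
   configurable). Strands are kept only when sheet-paired: at least half of
   a strand's residues must have a Cα within 5.5 Å of a Cα of a different
   strand fragment of the same structure — a cheap geometric surrogate for
   inter-strand hydrogen bonding that avoids any dependence on H-bond
   energy conventions. Torsion windows rather than H-bond-based assignment
   are adequate here because the fragments this library exists to supply
   are regular, near-ideal segments by construction.

2. **Grafting.** Anchors are split into groups, each carried by one
   scaffold (here: a contiguous strand triple and a spaced helix pair). For
   each candidate assignment of anchors to fragment positions — a sliding
   window for contiguous groups; for spaced pairs, all index pairs whose
   Cα–Cα distance lies within ±2 Å of the donor's, in both chain directions
   — the fragment's Cα/Cβ atoms are superposed onto the anchor Cα/Cβ atoms
   by least-squares rigid superposition (Kabsch, SVD with determinant
   correction; reflections never returned). Matches with RMSD < 2.0 Å
   (strict) are kept. A glycine at a mapped scaffold position contributes
   Cα only, and the anchor's Cβ is dropped from the correspondence.
   Side chains are transplanted rigidly: the scaffold backbone is carried
   through the match transform and the donor anchor's side-chain heavy
   atoms (Cβ included) are copied at their donor coordinates, preserving
   the donor's validated interaction geometry without a rotamer library.
   One anchor may be tagged keep-original (the alanine case): a methyl
   side chain adds nothing beyond backbone contacts, so the scaffold's own
   residue is retained there and may contribute new interactions.

3. **Pairing and clash filter.** Matches from the two groups are combined;
   two heavy atoms clash when their distance is smaller than 0.75 × the sum
   of their Bondi van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80 Å;
   table overridable). A match that clashes with the receptor never enters
   any pair; pairs whose fragments clash with each other are removed. The
   k-d-tree-accelerated counter is exact (it only prunes pairs beyond the
   largest possible threshold) and is tested against the quadratic loop.

4. **Linking, sequence, scoring, selection.** See below.

## Loop closure (CCD)

The fragment pair is ordered so the smaller C→N terminus gap comes first;
the linker length is ceil(gap / 3.3 Å) clamped to [1, 8] (3.3 Å per residue
is a conservative extended-chain rise; fully extended is ~3.8 Å). A linker
of glycine backbones is grown from the first fragment with ideal geometry
(N–Cα 1.458, Cα–C 1.525, C–N 1.329 Å; the angle set shared with the
fixture builders), plus a duplicate copy of the second fragment's first
backbone triad. Cyclic coordinate descent then applies, at each step, the
single torsion rotation (upstream ψ, linker φ/ψ, duplicate φ) that
maximally reduces the RMSD of the duplicate triad to the second fragment's
actual triad — so the closure error is non-increasing within an attempt by
construction. Closure succeeds when the splice bond C–N is within 1.33 ±
0.15 Å *and* the seating triad is within the same tolerance (0.15 Å
matches the chain-continuity criterion of 1.33 ± 0.15 Å and ω within
180 ± 20°); the second fragment is then rigidly re-seated onto the
converged triad. Loose seating tolerances were observed to lever the far
end of the second fragment by ~2 Å, which is why the triad criterion is
part of success.

CCD stalls are local minima, so closure restarts from four canonical
torsion basins (extended, helical, polyproline-II-like, and a second
extended variant) and, failing those, from seeded random jitters. All
canonical basins are evaluated and the most precisely closed solution wins:
empirically the final closure error tracks how well a rebuilt loop matches
an excised native loop, so preferring the tightest closure also prefers
native-like geometry. On cut-and-rebuild benchmarks (three residues excised
from a continuous helix–loop–strand chain at 20 seeded positions) closure
succeeds in 100% of cases with rebuilt-loop Cα RMSD ≤ 1.9 Å.

## Sequence assignment

Design is fixed-backbone and deliberately conservative, because side chains
are single idealized rotamers (ideal residue geometry from the chemical
component dictionary, attached by N/Cα/C superposition) with no repacking:

* anchors and keep-original positions are never redesigned;
* every other position is assigned from the polar alphabet
  {S, N, Q, D, E, K, R, T, G}: buried positions (relative side-chain SASA
  in the complex < 0.05 / < 0.2) become Gly / Ser; exposed positions take
  the candidate with (fewest clashes at 0.9 × vdW — stricter than the 0.75
  design threshold precisely because nothing can relax — then any
  hydrogen-bond partner within 3.5 Å of receptor N/O, then the smallest
  side chain, then alphabetic order). Preferring "any H-bond, then small"
  rather than "most H-bond atoms" stops long frozen rotamers (Arg/Glu)
  from being planted purely to farm interface contacts;
* a final pass replaces any remaining non-anchor hydrophobic with relative
  side-chain SASA > 0.4 by the clash-minimizing polar residue.

Relative side-chain SASA is the residue's side-chain area divided by its
area in an extended Gly-X-Gly tripeptide, both computed with the package's
own Shrake–Rupley sampler (960 deterministic golden-spiral sphere points,
probe 1.4 Å; 240 points during design for speed). The sampler is
cross-checked against an independent implementation and against the
closed-form area of an isolated atom.

## Interface score, filters, ranking

The interface score is a transparent geometric surrogate, not an energy:
`total = contact + 2·hbonds − 10·clashes + 0.05·buried`, where contact
sums w(d) = 1 for d ≤ 4 Å falling linearly to 0 at 6 Å over cross-interface
heavy-atom pairs; hbonds counts N/O pairs ≤ 3.5 Å with a base–donor–acceptor
angle > 120° (heavy atoms only, so either partner may act as donor);
clashes is the 0.75-scale count (zero for any design that survived
grafting); buried is the SASA lost on complexation. The weights are
plumbing, config-exposed, and carry no claim of force-field parity — they
exist to order candidate designs deterministically.

Designs are then clustered: many scaffolds present the anchor constellation
with essentially the same backbone, and such designs are redundant. Greedy
leader clustering on the direct RMSD of anchor-residue N/Cα/C coordinates
(threshold 0.75 Å; all designs share the receptor frame) visits designs in
order of anchor-superposition fidelity, so each cluster is represented by
the design that reproduces the anchor geometry best.

Two post-hoc filters codify the usual visual inspection: a design is
rejected when under 60% of its non-linker residues are helix/strand, or
when any anchor's side-chain orientation deviates more than 2.5 Å from the
donor-defined position. Because transplanted side-chain atoms are donor
copies and literally cannot drift, deviation is measured by re-attachment:
the donor residue's backbone triad is superposed onto the design residue's
triad and the donor side-chain centroid carried through; the displacement
from the donor centroid then measures how faithfully the design's backbone
presents the side chain. Ranking is a stable sort by total score
(descending), ties broken by hydrogen-bond count then sequence.

## Peptide properties

Molecular weight is the average (isotope-abundance-weighted) mass of the
free, unmodified peptide: Σ standard average residue masses + 18.0153 for
one water. Computed masses of the 15 published hPD-1-binder peptides agree
with the printed values within 0.02 g/mol, with one documented exception:
the two single-Tyr→Ala mutants of the best binder are chemically identical
(the same multiset of residues) yet are printed 1.00 g/mol apart; the
table is carried as printed and only the consistent value is asserted.
Alanine-scan mutants recompute mass from the same table, so the mass shift
equals mass(Ala) − mass(X) exactly. Experimental KD and purity columns are
annotations, never computed.

## Steady-state SPR analysis

The 1:1 steady-state (Langmuir) isotherm RU(C) = Rmax·C/(KD + C) is fitted
by bounded nonlinear least squares restarted from a decade grid of initial
KD guesses spanning the concentration range — the standard guard against
local minima in this two-parameter problem. Titrations require ≥ 4 points
spanning ≥ 10-fold in concentration; data without curvature (response
linear in C) are flagged and the KD reported only as a lower bound.
Noiseless synthetic titrations are recovered to < 10⁻⁶ relative error;
with signal-proportional 5% Gaussian noise ("relative" mode of the
generator — the natural error model for an SPR trace) the median relative
KD error over 200 seeded replicates is ~7%. The competition model solves
the pre-incubation equilibrium exactly (quadratic mass action for the
receptor–inhibitor complex) and reports immobilized-ligand occupancy by the
remaining free receptor, normalized to the inhibitor-free signal.

## Synthetic benchmark and what it does (not) show

All test inputs are generated: ideal poly-Ala helices/strands/hairpins from
NeRF internal-coordinate building, and a toy receptor–donor complex. The
toy receptor is two close-packed five-helix patches, one under each anchor
site, with empty space under the linker path: binding epitopes are local,
and an artificial continuous slab would reward arbitrary backbones for
draping across it. The donor (a 12-residue helix carrying the spaced
Tyr/Arg pair and a two-strand hairpin carrying the contiguous
Ala/Asp/Tyr triple) uses deterministically wobbled torsions — real
anchor-bearing segments are never ideal, and with an ideal donor any
regular fragment would be an exactly equivalent carrier, leaving "the
planted pair" undefined. The donor sits at a packing optimum (closest
heavy-atom contact 2.8 Å, clash-free at 0.75 × vdW). Decoy scaffolds are
regular rods with per-fragment-constant torsions drawn from the assignment
windows but kept ≥ 10° from the donor's values.

On this benchmark the full pipeline, with the planted fragments hidden
among 20 decoys, ranks a design built from the planted pair first, with
anchor superposition RMSD ≈ 0 and zero receptor clashes. This demonstrates
that the pipeline's stages compose correctly and that its filters and
ranking prefer native-like geometry when one exists. It does *not*
demonstrate performance on real structures: real libraries are far larger
and more diverse, real interfaces are not built to a known optimum, real
side chains repack, and the geometric score is not an energy. Problem
sizes throughout (20 decoys, 40-design beam, 20 loop cuts, 200 fit
replicates) are the package's default desk-scale study conditions.

## Numerical choices and degenerate inputs

* Strict inequalities at both screening thresholds (RMSD < 2.0;
  d < 0.75·(rᵢ+rⱼ)), so exact ties pass the distance test and fail the
  RMSD test.
* Kabsch requires ≥ 3 point pairs and rejects all-coincident inputs;
  rank-deficient (collinear) configurations are solved but flagged.
* Undefined backbone torsions (termini, missing atoms) are `None`, never a
  sentinel; such residues are labelled coil.
* Altloc resolution keeps the highest occupancy (ties → 'A'); hydrogens,
  waters and HETATM records are dropped on parse.
* All randomness flows through seeded `numpy` generators; identical inputs
  and seeds give identical outputs, including byte-identical saved
  libraries and manifests.

## Known limitations

* No mmCIF parsing; no crystallographic symmetry; no hydrogens.
* Side chains are single idealized rotamers; no repacking or minimization;
  the interface score is geometric, not thermodynamic.
* Single-curve isotherm fits (replicates are averaged upstream); no
  kinetic (kon/koff) analysis, no reference-channel corrections.
* Anchor groups of more than two spaced anchors are not enumerated
  (contiguous groups may be any size).
* Hotspot prediction is out of scope: anchors are user input.
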