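# Anchor specification for designing hPD-1 binding peptides from the
# hPD-1/hPD-L1 complex (PDB entry 4ZQK: chain A = hPD-L1, chain B = hPD-1).
#
# The five hPD-L1 hotspot residues are split into two graft groups: a spaced
# pair carried by a helix scaffold and a contiguous triple carried by a
# sheet-paired strand scaffold.  A121 is tagged keep_original: its methyl
# side chain contributes only backbone-level contacts, so the scaffold's own
# residue is retained at that position.
#
# The PDB files are not bundled; place 4zqk.pdb next to this file (or pass
# pre-parsed structures to pepgraft.grafting.load_anchor_spec).
receptor:
  pdb: 4zqk.pdb
  chain: B            # hPD-1, kept fixed
donor:
  pdb: 4zqk.pdb       # hPD-L1 chain A donates the anchors
groups:
  helix_group:
    ss_type: H
    contiguity: spaced
    anchors:
      - {chain: A, seq_id: 56,  name: TYR, keep_original: false}
      - {chain: A, seq_id: 113, name: ARG, keep_original: false}
  strand_group:
    ss_type: E
    contiguity: contiguous
    anchors:
      - {chain: A, seq_id: 121, name: ALA, keep_original: true}
      - {chain: A, seq_id: 122, name: ASP, keep_original: false}
      - {chain: A, seq_id: 123, name: TYR, keep_original: false}
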