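import numpy as np
import pytest

from pepgraft import fixtures as fx
from pepgraft.grafting import (Anchor, AnchorGroup, GraftError, clash_check,
                               enumerate_position_maps, pair_scaffolds,
                               screen_fragment)
from pepgraft.scaffoldlib import extract_fragments
from pepgraft.sidechains import mutate_residue
from pepgraft.structcore import Atom, RigidTransform


def brute_force_clashes(atoms_a, atoms_b, scale=0.75):
    n = 0
    for a in atoms_a:
        for b in atoms_b:
            if np.linalg.norm(a.coords - b.coords) < scale * (a.vdw + b.vdw):
                n += 1
    return n


def atoms_at(points, element="C"):
    return [Atom(name="CA", element=element, coords=np.asarray(p, float))
            for p in points]


class TestEnumeratePositionMaps:
    def test_contiguous_windows(self, anchor_set):
        group = anchor_set.groups["strand_group"]
        strands = [f for f in extract_fragments(anchor_set.donor)
                   if f.ss_type == "E"]
        frag = strands[0]  # 4 residues
        maps = enumerate_position_maps(frag, group, anchor_set)
        assert maps == [(i, i + 1, i + 2) for i in range(len(frag) - 2)]

    def test_spaced_distance_window(self, anchor_set, ideal_helix):
        group = anchor_set.groups["helix_group"]
        (frag,) = extract_fragments(ideal_helix)
        a1, a2 = (anchor_set.donor_residue(a).atom("CA").coords
                  for a in group.anchors)
        d_donor = np.linalg.norm(a1 - a2)
        ca = frag.ca_coords()
        maps = enumerate_position_maps(frag, group, anchor_set)
        assert maps, "ideal helix should offer compatible index pairs"
        for i, j in maps:
            assert abs(np.linalg.norm(ca[i] - ca[j]) - d_donor) <= 2.0
        # both directions present
        assert any(i > j for i, j in maps) and any(i < j for i, j in maps)

    def test_fragment_shorter_than_group_is_empty(self, anchor_set, hairpin):
        group = anchor_set.groups["strand_group"]
        strand = [f for f in extract_fragments(hairpin)][0]
        short = type(strand)(source_id="x", chain_id="A", ss_type="E",
                             start=0, end=2, residues=strand.residues[:2])
        assert enumerate_position_maps(short, group, anchor_set) == []

    def test_type_mismatch_errors(self, anchor_set, ideal_helix):
        (frag,) = extract_fragments(ideal_helix)
        with pytest.raises(ValueError):
            enumerate_position_maps(frag, anchor_set.groups["strand_group"],
                                    anchor_set)


class TestScreenFragment:
    def test_self_recovery(self, anchor_set, donor_library):
        """The donor's own anchor-bearing fragments match their anchors at
        numerically zero RMSD."""
        helix = donor_library.helices()[0]
        ms = screen_fragment(helix, anchor_set.groups["helix_group"], anchor_set)
        assert ms and ms[0].rmsd <= 1e-6
        strand = donor_library.strands()[0]
        ms = screen_fragment(strand, anchor_set.groups["strand_group"], anchor_set)
        assert ms and ms[0].rmsd <= 1e-6

    def test_rigid_offset_invariance(self, anchor_set, donor_library):
        helix = donor_library.helices()[0]
        base = screen_fragment(helix, anchor_set.groups["helix_group"], anchor_set)
        moved = helix.copy()
        for r in moved.residues:
            for a in r.atoms:
                a.coords = a.coords + np.array([3.0, 0.0, 0.0])
        shifted = screen_fragment(moved, anchor_set.groups["helix_group"],
                                  anchor_set)
        assert len(base) == len(shifted)
        for m0, m1 in zip(base, shifted):
            assert m1.rmsd == pytest.approx(m0.rmsd, abs=1e-9)

    def test_cutoff_is_strict(self, anchor_set, donor_library):
        helix = donor_library.helices()[0]
        ms = screen_fragment(helix, anchor_set.groups["helix_group"], anchor_set,
                             rmsd_cutoff=1e-9)
        # even self-recovery fails a cutoff below its numerical rmsd floor
        assert all(m.rmsd < 1e-9 for m in ms)


class TestGraftSidechains:
    def test_anchor_residues_transplanted(self, anchor_set, donor_library):
        strand = donor_library.strands()[0]
        m = screen_fragment(strand, anchor_set.groups["strand_group"],
                            anchor_set)[0]
        names = [m.grafted.residues[i].name for i in m.position_map]
        assert names == ["ALA", "ASP", "TYR"]  # keep-original ALA + grafted D/Y

    def test_backbone_is_scaffolds_own(self, anchor_set, donor_library):
        strand = donor_library.strands()[0]
        m = screen_fragment(strand, anchor_set.groups["strand_group"],
                            anchor_set)[0]
        # transform applied to the scaffold backbone, not donor's backbone
        for idx, orig in zip(m.position_map, m.position_map):
            res = m.grafted.residues[idx]
            expected = m.transform.apply(
                strand.residues[idx].atom("N").coords[None, :])[0]
            assert np.allclose(res.atom("N").coords, expected, atol=1e-9)

    def test_keep_original_preserves_tryptophan(self, toy, anchor_set):
        """A scaffold residue superposed onto the keep-original anchor stays
        what it was — e.g. a bulky aromatic is retained, not alanized."""
        hp = fx.make_beta_hairpin(5, seed=3, chain_id="A")
        hp.chains["A"][2] = mutate_residue(hp.chains["A"][2], "TRP")
        frag = [f for f in extract_fragments(hp) if f.start == 1][0]
        ms = screen_fragment(frag, anchor_set.groups["strand_group"], anchor_set)
        for m in ms:
            kept_idx = m.position_map[0]  # first anchor is the keep-original one
            if kept_idx == 1:  # scaffold TRP position mapped onto it
                assert m.grafted.residues[kept_idx].name == "TRP"

    def test_self_graft_recovers_donor_geometry(self, anchor_set, donor_library):
        strand = donor_library.strands()[0]
        m = screen_fragment(strand, anchor_set.groups["strand_group"],
                            anchor_set)[0]
        for anchor, idx in zip(anchor_set.groups["strand_group"].anchors,
                               m.position_map):
            donor_res = anchor_set.donor_residue(anchor)
            res = m.grafted.residues[idx]
            for sc in donor_res.sidechain_atoms():
                assert np.abs(res.atom(sc.name).coords - sc.coords).max() <= 1e-3

    def test_missing_donor_sidechain_raises(self, toy):
        from tests.conftest import make_anchor_set

        broken = toy.donor.copy()
        asp = broken.get_residue("S", 3)
        asp.atoms = [a for a in asp.atoms if a.name != "OD1"]
        aset = make_anchor_set(type(toy)(receptor=toy.receptor, donor=broken,
                                         anchor_spec=toy.anchor_spec))
        strand = extract_fragments(broken)[1]
        with pytest.raises(GraftError, match="OD1"):
            screen_fragment(strand, aset.groups["strand_group"], aset)


class TestClashCheck:
    def test_two_carbons_just_inside_threshold(self):
        a = atoms_at([[0.0, 0.0, 0.0]])
        b = atoms_at([[2.40, 0.0, 0.0]])
        assert clash_check(a, b, scale=0.75) == 1  # threshold 2.55 Å

    def test_two_carbons_outside_threshold(self):
        a = atoms_at([[0.0, 0.0, 0.0]])
        b = atoms_at([[2.60, 0.0, 0.0]])
        assert clash_check(a, b, scale=0.75) == 0

    def test_tie_at_exact_threshold_passes(self):
        # strict inequality: d == scale·(ri+rj) is not a clash
        a = atoms_at([[0.0, 0.0, 0.0]])
        b = atoms_at([[2.55, 0.0, 0.0]])
        assert clash_check(a, b, scale=0.75) == 0

    def test_grid_equals_brute_force(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            pts = rng.uniform(0, 12, size=(200, 3))
            a = atoms_at(pts[:100])
            b = atoms_at(pts[100:])
            assert clash_check(a, b) == brute_force_clashes(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        a = atoms_at(rng.uniform(0, 8, size=(40, 3)))
        b = atoms_at(rng.uniform(0, 8, size=(60, 3)))
        assert clash_check(a, b) == clash_check(b, a)

    def test_scale_limits(self):
        rng = np.random.default_rng(5)
        a = atoms_at(rng.uniform(0, 5, size=(10, 3)))
        b = atoms_at(rng.uniform(0, 5, size=(10, 3)))
        assert clash_check(a, b, scale=0.0) == 0
        d_max = max(np.linalg.norm(x.coords - y.coords) for x in a for y in b)
        huge = d_max / (2 * 1.52) + 1.0
        assert clash_check(a, b, scale=huge) == 100  # every pair clashes

    def test_monotone_in_scale(self):
        rng = np.random.default_rng(9)
        a = atoms_at(rng.uniform(0, 6, size=(30, 3)))
        b = atoms_at(rng.uniform(0, 6, size=(30, 3)))
        counts = [clash_check(a, b, scale=s) for s in (0.3, 0.5, 0.75, 1.0, 1.5)]
        assert counts == sorted(counts)


class TestPairScaffolds:
    def test_native_pair_survives(self, anchor_set, donor_library):
        m1 = screen_fragment(donor_library.helices()[0],
                             anchor_set.groups["helix_group"], anchor_set)[:1]
        m2 = screen_fragment(donor_library.strands()[0],
                             anchor_set.groups["strand_group"], anchor_set)[:1]
        pairs = pair_scaffolds(m1, m2, anchor_set.receptor)
        assert len(pairs) == 1 and pairs[0].clash_free

    def test_receptor_clashing_match_never_pairs(self, anchor_set, donor_library):
        m1 = screen_fragment(donor_library.helices()[0],
                             anchor_set.groups["helix_group"], anchor_set)[:1]
        m2 = screen_fragment(donor_library.strands()[0],
                             anchor_set.groups["strand_group"], anchor_set)[:1]
        # bury the helix inside the receptor core
        buried = m1[0]
        core = np.mean([a.coords for r in anchor_set.receptor.residues()
                        for a in r.atoms], axis=0)
        offset = core - buried.grafted.residues[5].atom("CA").coords
        for r in buried.grafted.residues:
            for a in r.atoms:
                a.coords = a.coords + offset
        assert pair_scaffolds([buried], m2, anchor_set.receptor) == []

    def test_count_conservation(self, anchor_set, full_library):
        m1, m2 = [], []
        for f in full_library.fragments:
            for label, group in anchor_set.groups.items():
                if f.ss_type != group.ss_type:
                    continue
                ms = screen_fragment(f, group, anchor_set)[:1]
                (m1 if label == "helix_group" else m2).extend(ms)
        pairs = pair_scaffolds(m1, m2, anchor_set.receptor)
        assert len(pairs) <= len(m1) * len(m2)


class TestFilterMonotonicity:
    def test_rmsd_cutoff_monotone(self, anchor_set, full_library):
        group = anchor_set.groups["helix_group"]
        frag = full_library.helices()[0]
        counts = [len(screen_fragment(frag, group, anchor_set, rmsd_cutoff=c))
                  for c in (0.1, 0.5, 1.0, 2.0, 4.0)]
        assert counts == sorted(counts)
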