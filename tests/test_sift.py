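"""Interaction fingerprints: contact detection, bit matrix, occupancy."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from posetriage import (HBondParams, LigandPose, build_sift, detect_hbonds,
                        detect_hydrophobic, occupancy_profile,
                        proximal_residues, StructureError)
from posetriage.structio import Atom, ReceptorStructure, Residue
from posetriage.sift import SiftMatrix, SIFT_KINDS
from tests.conftest import embedded


def residue_at(coords_names, resseq=1, resname="GLY", chain="A"):
    atoms = [Atom(i + 1, name, el, np.array(xyz, float))
             for i, (name, el, xyz) in enumerate(coords_names)]
    return Residue(chain, resseq, "", resname, atoms)


def single_residue_receptor(coords_names, **kw):
    return ReceptorStructure([residue_at(coords_names, **kw)])


def ligand_at(offset):
    pose = LigandPose(embedded("[NH3+][C@@H](Cc1ccccc1)C(=O)[O-]"), "phe", 0)
    return pose.transformed(np.eye(3), np.asarray(offset, float))


# ---------------------------------------------------------------------------
# proximal residues
# ---------------------------------------------------------------------------

def test_distant_ligand_has_empty_universe(phe_pose):
    rec = single_residue_receptor([("O", "O", [100.0, 0, 0])])
    far = phe_pose.transformed(np.eye(3), np.array([-100.0, 0, 0]))
    assert proximal_residues(far, rec) == []


def test_exactly_five_angstrom_is_included(phe_pose):
    # anchor the max-x heavy atom at the origin so the probe distance is an
    # exact 5.0 in floating point
    xyz = phe_pose.heavy_coords()
    anchor = xyz[np.argmax(xyz[:, 0])]
    pose = phe_pose.transformed(np.eye(3), -anchor)
    rec = single_residue_receptor([("O", "O", [5.0, 0.0, 0.0])])
    assert proximal_residues(pose, rec) == [("A", 1, "")]
    rec6 = single_residue_receptor([("O", "O", [5.0001, 0.0, 0.0])])
    assert proximal_residues(pose, rec6) == []


def test_empty_receptor_is_an_error(phe_pose):
    with pytest.raises(StructureError, match="empty receptor"):
        proximal_residues(phe_pose, ReceptorStructure([], title="x"))


def test_proximal_set_matches_allpairs_scan(planted, pocket):
    ps, _ = planted
    pose = ps.poses[0]
    got = set(proximal_residues(pose, pocket))
    lig = pose.heavy_coords()
    expect = {res.key for res in pocket.residues
              if cdist(lig, res.heavy_coords()).min() <= 5.0}
    assert got == expect


# ---------------------------------------------------------------------------
# hydrogen bonds
# ---------------------------------------------------------------------------

def carbonyl_receptor(o_pos, c_dir=(1.0, 0, 0), resseq=1):
    """A backbone carbonyl acceptor at o_pos."""
    o = np.asarray(o_pos, float)
    c = o + 1.23 * np.asarray(c_dir) / np.linalg.norm(c_dir)
    return single_residue_receptor([("C", "C", c), ("O", "O", o)], resseq=resseq)


def test_planted_donated_hbond_detected(phe_pose):
    # place an acceptor O 2.9 A along one N-H direction: D-H...A ~ 180 deg
    mol = phe_pose.mol
    n = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N"][0]
    h = [b.GetIdx() for b in mol.GetAtomWithIdx(n).GetNeighbors()
         if b.GetAtomicNum() == 1][0]
    xyz = phe_pose.coords()
    u = (xyz[h] - xyz[n]) / np.linalg.norm(xyz[h] - xyz[n])
    rec = carbonyl_receptor(xyz[n] + 2.9 * u, c_dir=np.cross(u, [0, 0, 1.0]))
    records = detect_hbonds(phe_pose, rec)
    assert len(records) == 1
    r = records[0]
    assert r.kind == "hbond_ligand_donates"
    assert r.ligand_atom == n
    assert r.distance == pytest.approx(2.9, abs=1e-6)
    assert r.angle > 160


def test_beyond_cutoff_no_record(phe_pose):
    mol = phe_pose.mol
    n = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N"][0]
    h = [b.GetIdx() for b in mol.GetAtomWithIdx(n).GetNeighbors()
         if b.GetAtomicNum() == 1][0]
    xyz = phe_pose.coords()
    u = (xyz[h] - xyz[n]) / np.linalg.norm(xyz[h] - xyz[n])
    rec = carbonyl_receptor(xyz[n] + 3.6 * u)
    assert detect_hbonds(phe_pose, rec) == []


def test_bad_angle_rejected(phe_pose):
    # acceptor opposite to all N-H vectors: D...A short but D-H...A < 120
    mol = phe_pose.mol
    n = [a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "N"][0]
    hs = [b.GetIdx() for b in mol.GetAtomWithIdx(n).GetNeighbors()
          if b.GetAtomicNum() == 1]
    xyz = phe_pose.coords()
    u = sum((xyz[h] - xyz[n]) / np.linalg.norm(xyz[h] - xyz[n]) for h in hs)
    u /= np.linalg.norm(u)
    rec = carbonyl_receptor(xyz[n] - 3.0 * u)
    records = [r for r in detect_hbonds(phe_pose, rec) if r.ligand_atom == n]
    assert records == []


def test_bm1_pose_has_five_backbone_hbonds(bm1_pose, pocket):
    """The consensus mode plants five amino-acid-moiety hydrogen bonds to
    backbone groups: two accepted by the carboxylate, three donated by the
    ammonium."""
    records = [r for r in detect_hbonds(bm1_pose, pocket) if r.backbone]
    assert len(records) == 5
    accepts = [r for r in records if r.kind == "hbond_ligand_accepts"]
    donates = [r for r in records if r.kind == "hbond_ligand_donates"]
    assert len(accepts) == 2
    assert len(donates) == 3
    carbox_o = set()
    for r in accepts:
        carbox_o.add(r.ligand_atom)
    # both acceptors are (distinct) carboxylate oxygens
    els = [a.GetSymbol() for a in bm1_pose.mol.GetAtoms()]
    assert all(els[i] == "O" for i in carbox_o) and len(carbox_o) == 2
    # all three donations come from the ammonium nitrogen
    assert {r.ligand_atom for r in donates} == {
        next(i for i, e in enumerate(els) if e == "N")}


def test_records_are_translation_rotation_invariant(bm1_pose, pocket):
    sig = {(r.kind, r.ligand_atom, r.residue_key) for r in detect_hbonds(bm1_pose, pocket)}
    theta = 0.7
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    t = np.array([3.0, -2.0, 5.0])
    pose2 = bm1_pose.transformed(rot, t)
    moved = ReceptorStructure([
        Residue(res.chain, res.resseq, res.icode, res.resname,
                [Atom(a.serial, a.name, a.element, rot @ a.coords + t)
                 for a in res.atoms]) for res in pocket.residues])
    sig2 = {(r.kind, r.ligand_atom, r.residue_key) for r in detect_hbonds(pose2, moved)}
    assert sig == sig2


# ---------------------------------------------------------------------------
# hydrophobic contacts
# ---------------------------------------------------------------------------

def _ring_atom(pose):
    return next(a.GetIdx() for a in pose.mol.GetAtoms() if a.GetIsAromatic())


def test_apolar_pair_within_cutoff(phe_pose):
    i = _ring_atom(phe_pose)
    pos = phe_pose.coords()[i]
    rec = single_residue_receptor([("CD1", "C", pos + [3.8, 0, 0])], resname="LEU")
    recs = detect_hydrophobic(phe_pose, rec)
    assert any(r.ligand_atom == i for r in recs)


def test_apolar_pair_beyond_cutoff(phe_pose):
    xyz = phe_pose.heavy_coords()
    # a probe 4.6 A from the nearest heavy atom never registers
    i = _ring_atom(phe_pose)
    pos = phe_pose.coords()[i]
    direction = pos - xyz.mean(axis=0)
    direction /= np.linalg.norm(direction)
    probe = pos + 4.6 * direction
    if cdist(xyz, probe[None]).min() >= 4.5:
        rec = single_residue_receptor([("CD1", "C", probe)], resname="LEU")
        assert detect_hydrophobic(phe_pose, rec) == []


def test_polar_contact_is_not_hydrophobic(phe_pose):
    i = _ring_atom(phe_pose)
    pos = phe_pose.coords()[i]
    # a serine-like hydroxyl O next to a ring carbon: polar atom, no record
    rec = single_residue_receptor([("OG", "O", pos + [3.5, 0, 0])], resname="SER")
    assert detect_hydrophobic(phe_pose, rec) == []


# ---------------------------------------------------------------------------
# fingerprint matrix and occupancy
# ---------------------------------------------------------------------------

def test_empty_records_all_zero():
    keys = [("a", 0), ("a", 1)]
    uni = [("A", 1, "")]
    m = build_sift([], keys, uni)
    assert m.bits.shape == (2, 3)
    assert m.bits.sum() == 0


def test_single_record_sets_one_bit(bm1_pose, pocket):
    records = detect_hbonds(bm1_pose, pocket)[:1]
    uni = proximal_residues(bm1_pose, pocket)
    m = build_sift(records, [bm1_pose.key], uni)
    assert m.bits.sum() == 1


def test_record_outside_universe_is_an_error(bm1_pose, pocket):
    records = detect_hbonds(bm1_pose, pocket)
    with pytest.raises(StructureError, match="outside universe"):
        build_sift(records, [bm1_pose.key], [("Z", 999, "")])


def test_matrix_equals_per_pose_bruteforce(small_planted, pocket):
    ps, _ = small_planted
    poses = ps.poses[:3]
    uni = sorted({k for p in poses for k in proximal_residues(p, pocket)})
    records = []
    for p in poses:
        records += detect_hbonds(p, pocket)
        records += detect_hydrophobic(p, pocket)
    m = build_sift(records, [p.key for p in poses], uni)
    cidx = m.column_index()
    for p in poses:
        hb = detect_hbonds(p, pocket)
        hyd = detect_hydrophobic(p, pocket)
        row = np.zeros(len(m.columns), dtype=np.uint8)
        for r in hb + hyd:
            row[cidx[(r.residue_key, r.kind)]] = 1
        np.testing.assert_array_equal(m.bits[m.pose_keys.index(p.key)], row)


def test_every_record_is_within_the_proximal_universe(small_planted, pocket):
    ps, _ = small_planted
    for p in ps.poses[:20]:
        uni = set(proximal_residues(p, pocket))
        for r in detect_hbonds(p, pocket) + detect_hydrophobic(p, pocket):
            assert r.residue_key in uni


def test_occupancy_extremes_and_rounding():
    keys = [("a", i) for i in range(9)]
    uni = [("A", 1, "")]
    bits = np.zeros((9, 3), dtype=np.uint8)
    bits[:, 0] = 1          # all poses
    bits[:5, 1] = 1         # 5 of 9
    m = SiftMatrix(keys, [(("A", 1, ""), k) for k in SIFT_KINDS], bits)
    prof = occupancy_profile(m, keys, "all")
    assert prof.percent[(("A", 1, ""), "hbond_ligand_donates")] == 100.0
    assert prof.percent[(("A", 1, ""), "hbond_ligand_accepts")] == 55.6
    assert prof.percent[(("A", 1, ""), "hydrophobic")] == 0.0


def test_empty_subset_is_an_error():
    m = SiftMatrix([("a", 0)], [(("A", 1, ""), "hydrophobic")],
                   np.zeros((1, 1), np.uint8))
    with pytest.raises(StructureError, match="empty"):
        occupancy_profile(m, [])


def test_occupancy_separates_modes_from_decoys(planted, pocket):
    """The planted interactions discriminate consensus poses from decoys:
    every planted hydrogen-bond bit is 100% occupied in mode poses and rare
    in decoys."""
    ps, truth = planted
    poses = ps.by_ligand["pchloro"]
    uni = sorted({k for p in poses for k in proximal_residues(p, pocket)})
    records = []
    for p in poses:
        records += detect_hbonds(p, pocket)
    m = build_sift(records, [p.key for p in poses], uni)
    mode = [p.key for p in poses if truth.mode_of[p.key] != "decoy"]
    decoy = [p.key for p in poses if truth.mode_of[p.key] == "decoy"]
    prof_m = occupancy_profile(m, mode, "mode")
    prof_d = occupancy_profile(m, decoy, "decoy")
    col = (("A", 66, ""), "hbond_ligand_accepts")
    assert prof_m.percent[col] == 100.0
    assert prof_d.percent[col] < 50.0


def test_occupancy_invariant_to_duplicating_complement_rows():
    keys = [("a", 0), ("a", 1), ("b", 0)]
    bits = np.array([[1], [0], [1]], dtype=np.uint8)
    cols = [(("A", 1, ""), "hydrophobic")]
    m1 = SiftMatrix(keys, cols, bits)
    m2 = SiftMatrix(keys + [("c", 9)], cols,
                    np.vstack([bits, bits[2:3]]))
    subset = [("a", 0), ("a", 1)]
    assert occupancy_profile(m1, subset).percent == occupancy_profile(m2, subset).percent
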