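"""Halogen contact census, sigma-hole classification, ring positions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posetriage import (HalogenContact, LigandPose, ScaffoldDefinition,
                        StructureError, Thresholds, classify_contact,
                        find_halogen_contacts, frequency_analysis,
                        match_scaffold, ring_position, select_qm_candidates)
from posetriage.structio import Atom, ReceptorStructure, Residue
from tests.conftest import embedded


def carbonyl_receptor(o_pos, c_pos, resseq=401):
    return ReceptorStructure([Residue("A", resseq, "", "GLY", [
        Atom(1, "C", "C", np.asarray(c_pos, float)),
        Atom(2, "O", "O", np.asarray(o_pos, float))])])


def make_contact(element="Cl", d=3.0, theta_sigma=165.0, theta_acceptor=120.0,
                 partner="O"):
    return HalogenContact(
        pose_key=("lig", 0), x_atom=5, x_element=element, carbon_atom=4,
        residue_key=("A", 401, ""), residue_label="A:GLY401", partner_atom=1,
        partner_name="O", partner_element=partner, d_x_partner=d,
        theta_sigma=theta_sigma, theta_acceptor=theta_acceptor)


# ---------------------------------------------------------------------------
# census
# ---------------------------------------------------------------------------

def test_pose_without_halogens_gives_empty_census(phe_pose):
    rec = carbonyl_receptor([0, 0, 0], [1.23, 0, 0])
    assert find_halogen_contacts(phe_pose, rec) == []


def test_planted_iodine_contact_geometry(diiodotyr_pose):
    """An I...O=C contact planted at 3.2 A with a 170 deg sigma-hole angle is
    reported with exactly those values."""
    mol = diiodotyr_pose.mol
    xyz = diiodotyr_pose.coords()
    i_idx = next(a.GetIdx() for a in mol.GetAtoms() if a.GetSymbol() == "I")
    c_idx = mol.GetAtomWithIdx(i_idx).GetNeighbors()[0].GetIdx()
    axis = (xyz[i_idx] - xyz[c_idx]) / np.linalg.norm(xyz[i_idx] - xyz[c_idx])
    # 170 deg: tilt the O slightly off the C-X extension
    perp = np.cross(axis, [0.0, 0.0, 1.0])
    perp /= np.linalg.norm(perp)
    u = math.cos(math.radians(10.0)) * axis + math.sin(math.radians(10.0)) * perp
    o = xyz[i_idx] + 3.2 * u
    c_carb = o + 1.23 * perp
    rec = carbonyl_receptor(o, c_carb)
    contacts = [c for c in find_halogen_contacts(diiodotyr_pose, rec)
                if c.x_atom == i_idx and c.partner_element == "O"]
    assert len(contacts) == 1
    assert contacts[0].d_x_partner == pytest.approx(3.2, abs=1e-2)
    assert contacts[0].theta_sigma == pytest.approx(170.0, abs=1e-2)


def test_census_matches_allpairs_scan(planted, pocket):
    ps, _ = planted
    pose = next(p for p in ps if p.ligand_id == "diiodotyr")
    got = {(c.x_atom, c.residue_key, c.partner_name)
           for c in find_halogen_contacts(pose, pocket)}
    # oracle: brute force over all halogen/polar-partner pairs
    from posetriage import assign_atom_classes
    classes = assign_atom_classes(pose)
    xyz = pose.coords()
    expect = set()
    for i, el in enumerate(classes.halogen):
        if el is None:
            continue
        for res in pocket.residues:
            for j, a in enumerate(res.atoms):
                polar_heavy = a.element in ("O", "N", "S")
                polar_h = a.is_hydrogen and any(
                    (not b.is_hydrogen) and b.element in ("O", "N", "S") and
                    np.linalg.norm(b.coords - a.coords) < 1.2 for b in res.atoms)
                if (polar_heavy or polar_h) and \
                        np.linalg.norm(xyz[i] - a.coords) <= 4.5:
                    expect.add((i, res.key, a.name))
    assert got == expect


# ---------------------------------------------------------------------------
# classification (printed criteria, strict inequalities)
# ---------------------------------------------------------------------------

def test_preoptimisation_chloro_geometry_passes():
    c = classify_contact(make_contact("Cl", d=2.91, theta_sigma=162.4,
                                      theta_acceptor=95.0))
    assert c.classification == "xbond"
    assert all(v is True for v in c.trace.values() if isinstance(v, bool))


def test_postoptimisation_chloro_geometry_fails_both_criteria():
    c = classify_contact(make_contact("Cl", d=3.93, theta_sigma=128.3,
                                      theta_acceptor=95.0))
    assert c.classification == "fail"
    assert c.trace["d<3.27"] is False
    assert c.trace["theta_sigma>150.0"] is False


def test_distance_boundary_is_strict():
    assert classify_contact(make_contact("Cl", d=3.27)).classification == "fail"
    assert classify_contact(make_contact("Cl", d=3.2699)).classification == "xbond"
    assert classify_contact(make_contact("Br", d=3.37)).classification == "fail"
    assert classify_contact(make_contact("I", d=3.50)).classification == "fail"
    assert classify_contact(make_contact("I", d=3.4999)).classification == "xbond"


def test_fluorine_never_donates():
    c = classify_contact(make_contact("F", d=2.5, theta_sigma=175.0))
    assert c.classification == "fail"
    assert "F excluded" in str(c.trace.get("reason"))


def test_unsupported_partner_element():
    c = classify_contact(make_contact("Cl", partner="C"))
    assert c.classification == "fail"
    assert "unsupported acceptor" in str(c.trace.get("reason"))


def test_x_as_acceptor_uses_printed_lower_bound():
    # d(X...H) > 2.8 as printed: a 3.0 A contact with good angles passes,
    # a 2.5 A one fails; flipping the direction flag inverts that
    good = make_contact("Cl", d=3.0, theta_sigma=120.0, theta_acceptor=150.0,
                        partner="H")
    short = make_contact("Cl", d=2.5, theta_sigma=120.0, theta_acceptor=150.0,
                         partner="H")
    assert classify_contact(good).classification == "x_as_acceptor"
    assert classify_contact(short).classification == "fail"
    flipped = Thresholds(xh_bound_is_lower=False)
    assert classify_contact(short, flipped).classification == "x_as_acceptor"


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.sampled_from(["Cl", "Br", "I"]),
       st.floats(2.5, 4.4), st.floats(95.0, 180.0),
       st.floats(0.2, 1.0), st.floats(0.0, 25.0))
def test_classification_is_monotone(el, d, theta, dd, dtheta):
    """Decreasing the distance or increasing the sigma-hole angle never
    flips a passing halogen bond to fail."""
    base = classify_contact(make_contact(el, d=d, theta_sigma=theta))
    if base.classification == "xbond":
        closer = classify_contact(make_contact(el, d=max(d - dd, 0.1),
                                               theta_sigma=min(theta + dtheta, 180.0)))
        assert closer.classification == "xbond"


def test_geometry_invariant_under_rigid_motion(planted, pocket):
    ps, _ = planted
    pose = next(p for p in ps if p.ligand_id == "diiodotyr")
    base = {(c.x_atom, c.residue_key, c.partner_name):
            (c.d_x_partner, c.theta_sigma, c.theta_acceptor)
            for c in find_halogen_contacts(pose, pocket)}
    theta = 1.1
    rot = np.array([[1, 0, 0], [0, np.cos(theta), -np.sin(theta)],
                    [0, np.sin(theta), np.cos(theta)]])
    t = np.array([-4.0, 1.0, 2.0])
    pose2 = pose.transformed(rot, t)
    moved = ReceptorStructure([
        Residue(r.chain, r.resseq, r.icode, r.resname,
                [Atom(a.serial, a.name, a.element, rot @ a.coords + t)
                 for a in r.atoms]) for r in pocket.residues])
    after = {(c.x_atom, c.residue_key, c.partner_name):
             (c.d_x_partner, c.theta_sigma, c.theta_acceptor)
             for c in find_halogen_contacts(pose2, moved)}
    assert base.keys() == after.keys()
    for k in base:
        np.testing.assert_allclose(
            [v for v in base[k] if v is not None],
            [v for v in after[k] if v is not None], atol=1e-5)


def test_xbond_trace_is_all_true(planted, pocket):
    ps, _ = planted
    for p in ps.by_ligand["iodotyr"][:10]:
        for c in find_halogen_contacts(p, pocket):
            classify_contact(c)
            if c.classification == "xbond":
                assert all(v is True for v in c.trace.values()
                           if isinstance(v, bool))


# ---------------------------------------------------------------------------
# ring positions
# ---------------------------------------------------------------------------

def _position_of(smiles, element="I"):
    pose = LigandPose(embedded(smiles), "x", 0)
    m = match_scaffold(pose, ScaffoldDefinition())
    idx = next(a.GetIdx() for a in pose.mol.GetAtoms() if a.GetSymbol() == element)
    return ring_position(pose, idx, m)


def test_meta_iodine():
    assert _position_of("[NH3+][C@@H](Cc1cc(I)c(O)cc1)C(=O)[O-]", "I") == "meta"


def test_para_chlorine():
    assert _position_of("N[C@@H](Cc1ccc(Cl)cc1)C(=O)O", "Cl") == "para"


def test_ortho_bromine():
    assert _position_of("[NH3+][C@@](C)(Cc1c(Br)cccc1)C(=O)[O-]", "Br") == "ortho"


def test_aliphatic_chlorine():
    assert _position_of("[NH3+][C@@H](Cc1cc(CCCl)ccc1)C(=O)[O-]", "Cl") == "aliphatic"


def test_ring_positions_match_shortest_path_oracle(library, scaffold):
    """Graph-distance oracle around the scaffold ring."""
    import networkx as nx

    for mol in library:
        pose = LigandPose(mol, mol.GetProp("ligand_id"), 0)
        m = match_scaffold(pose, scaffold)
        ring = [m.correspondence[i] for i in range(6, 12)]
        attach = m.correspondence[6]
        g = nx.cycle_graph(6)
        order = {a: i for i, a in enumerate(ring)}
        for a in pose.mol.GetAtoms():
            if a.GetSymbol() not in ("F", "Cl", "Br", "I"):
                continue
            nb = a.GetNeighbors()[0]
            got = ring_position(pose, a.GetIdx(), m)
            if not nb.GetIsAromatic():
                assert got == "aliphatic"
            else:
                dist = nx.shortest_path_length(g, order[nb.GetIdx()], order[attach])
                assert got == {1: "ortho", 2: "meta", 3: "para"}[dist]


def test_missing_atom_is_an_error(phe_pose, scaffold):
    m = match_scaffold(phe_pose, scaffold)
    with pytest.raises(StructureError):
        ring_position(phe_pose, 9999, m)


# ---------------------------------------------------------------------------
# frequency analysis and QM candidate selection
# ---------------------------------------------------------------------------

def _classified_contacts(ps, pocket):
    out = []
    sd = ScaffoldDefinition()
    for p in ps:
        cs = find_halogen_contacts(p, pocket)
        if cs:
            m = match_scaffold(p, sd)
            for c in cs:
                classify_contact(c)
                c.ring_position = ring_position(p, c.x_atom, m)
        out += cs
    return out


def test_no_passing_contacts_gives_zero_percentages(small_planted, pocket_degraded):
    ps, _ = small_planted
    contacts = [c for c in _classified_contacts(ps, pocket_degraded)]
    passing = [c for c in contacts if c.classification == "xbond"]
    assert passing == []
    by_pos, by_partner = frequency_analysis(ps, contacts)
    assert (by_pos["percent"] == 0.0).all()
    assert by_partner.empty


def test_frequencies_match_planted_ground_truth(planted, pocket):
    ps, truth = planted
    contacts = _classified_contacts(ps, pocket)
    by_pos, by_partner = frequency_analysis(ps, contacts)
    # only the meta iodines carry planted halogen bonds: 80 of 100 poses of
    # each iodinated ligand are mode-anchored and the X-bond is planted in
    # consensus-mode poses only
    row = by_pos[(by_pos.ring_position == "meta") & (by_pos.element == "I")]
    expect_poses = sum(1 for k, m in truth.mode_of.items()
                       if k[0] in ("iodotyr", "diiodotyr"))
    expect_hits = sum(1 for k, v in truth.planted_xbonds.items() if v)
    assert int(row.n_poses.iloc[0]) == expect_poses
    assert int(row.n_with_contact.iloc[0]) == expect_hits
    assert float(row.percent.iloc[0]) == pytest.approx(
        100.0 * expect_hits / expect_poses, abs=0.05)
    # partner tally equals a brute-force count over passing records
    n_pass = sum(1 for c in contacts if c.classification in ("xbond", "x_as_acceptor"))
    assert int(by_partner.n_passing_contacts.sum()) == n_pass


def test_select_best_energy_pose(planted, pocket):
    ps, truth = planted
    contacts = _classified_contacts(ps, pocket)
    passing_keys = {c.pose_key for c in contacts if c.classification == "xbond"}
    csc = [p for p in ps if truth.mode_of[p.key] != "decoy"]
    energies = {p.key: -7.0 - 0.01 * p.pose_id for p in ps}
    selected, unselected = select_qm_candidates(csc, contacts, energies)
    assert set(selected) == {"iodotyr", "diiodotyr"}
    for lig, key in selected.items():
        cands = [p.key for p in csc if p.ligand_id == lig and p.key in passing_keys]
        assert key == min(cands, key=lambda k: energies[k])
    assert sorted(unselected) == sorted(set(ps.ligand_ids) - set(selected))


def test_missing_energy_is_an_error(planted, pocket):
    ps, truth = planted
    contacts = _classified_contacts(ps.by_ligand["iodotyr"][:5], pocket)
    csc = ps.by_ligand["iodotyr"][:5]
    with pytest.raises(KeyError, match="missing energy"):
        select_qm_candidates(csc, contacts, {})
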