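"""Halogen contact census, geometric classification and pose triage.

A C-bound halogen X (Cl, Br, I) can donate a halogen bond through its
electropositive sigma-hole, roughly collinear with the C-X axis, to an
electron-rich acceptor (O, N, S); perpendicular to that axis it can instead
accept a polar contact from an H-bond donor. Contacts are classified with
strict inequalities:

* X-bond (donor):  d(Cl...O) < 3.27 A, d(Br...O) < 3.37 A, d(I...O) < 3.50 A;
  sigma-hole angle C-X...acceptor > 150 deg; acceptor-side angle > 90 deg.
* X as acceptor:   d(X...H) > 2.8 A (implemented exactly as printed, with the
  bound direction exposed as a configurable flag -- see ``Thresholds``);
  C-X...H > 90 deg; (donor heavy)-H...X > 120 deg.

Fluorine is never an X-bond donor candidate (the donor strength order
I > Br > Cl ends at F); its contacts are recorded in the census but classify
as fail. The acceptor-side angle generalises the printed carbonyl case
(C=O...X) by using the partner's heaviest attached atom; the generalisation
is noted in the criteria trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import (HALOGENS, LigandPose, PoseSet, ReceptorStructure,
                       Residue, StructureError, assign_atom_classes)
from .scaffold import ScaffoldMatch
from .sift import angle_deg, _typed_residues

SEARCH_CUTOFF = 4.5  # A; > largest distance criterion + slack, so near
                     # misses still appear in the census

#: atomic masses used only to pick a partner's heaviest attached atom
_MASS = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
         "P": 30.974, "S": 32.06, "Cl": 35.45, "Br": 79.904, "I": 126.904}


@dataclass
class Thresholds:
    """Geometric criteria for halogen-contact classification.

    Distances in Angstrom, angles in degrees; comparisons are strict, exactly
    as printed. ``xh_bound_is_lower`` keeps the unusual printed reading of
    d(X...H) > 2.8 A as a lower bound; flip it to treat 2.8 A as an upper
    bound instead (do not silently "fix" data built against one convention).
    """

    xo_max: dict[str, float] = field(default_factory=lambda: {"Cl": 3.27, "Br": 3.37, "I": 3.50})
    xh_bound: float = 2.8
    xh_bound_is_lower: bool = True
    sigma_angle_min: float = 150.0
    acceptor_angle_min: float = 90.0
    cxh_angle_min: float = 90.0
    ohx_angle_min: float = 120.0
    search_cutoff: float = SEARCH_CUTOFF

    def __post_init__(self) -> None:
        vals = list(self.xo_max.values()) + [self.xh_bound, self.sigma_angle_min,
                                             self.acceptor_angle_min, self.cxh_angle_min,
                                             self.ohx_angle_min, self.search_cutoff]
        if any(v <= 0 for v in vals):
            raise ValueError("thresholds must be positive")
        if "F" in self.xo_max:
            raise ValueError("F has no X-bond donor threshold (F is excluded as a donor)")


@dataclass
class HalogenContact:
    """One X...partner contact with full geometry and classification trace."""

    pose_key: tuple[str, int]
    x_atom: int
    x_element: str
    carbon_atom: int
    residue_key: tuple[str, int, str]
    residue_label: str
    partner_atom: int
    partner_name: str
    partner_element: str
    d_x_partner: float
    theta_sigma: float            # angle C-X...partner, at X
    theta_acceptor: float | None  # angle (partner's heaviest neighbour)-partner...X
    classification: str = "unclassified"   # xbond | x_as_acceptor | fail | unclassified
    trace: dict[str, bool | str] = field(default_factory=dict)
    ring_position: str = ""

    def __post_init__(self) -> None:
        if self.x_element not in HALOGENS:
            raise StructureError(f"contact on non-halogen element {self.x_element!r}")
        if self.d_x_partner <= 0:
            raise StructureError("non-positive contact distance")
        for ang in (self.theta_sigma, self.theta_acceptor):
            if ang is not None and not (0.0 <= ang <= 180.0):
                raise StructureError(f"angle {ang} outside [0, 180]")


def find_halogen_contacts(pose: LigandPose, r: ReceptorStructure,
                          search_cutoff: float = SEARCH_CUTOFF) -> list[HalogenContact]:
    """Census of all (X, partner) pairs within ``search_cutoff``.

    Partners are residue O/N/S heavy atoms and polar hydrogens; geometry is
    computed for every pair and classification is applied separately.
    """
    classes = assign_atom_classes(pose)
    lig_xyz = pose.coords()
    contacts: list[HalogenContact] = []
    x_atoms = [(i, el) for i, el in enumerate(classes.halogen) if el is not None]
    if not x_atoms:
        return contacts

    for xi, el in x_atoms:
        carbons = [b.GetIdx() for b in pose.mol.GetAtomWithIdx(xi).GetNeighbors()
                   if b.GetAtomicNum() == 6]
        if not carbons:
            raise StructureError(f"halogen atom {xi} ({el}) has no bonded carbon")
        ci = carbons[0]
        for res, _rc, neigh, rxyz in _typed_residues(r):
            for rj, ratom in enumerate(res.atoms):
                is_polar_heavy = ratom.element in ("O", "N", "S")
                is_polar_h = ratom.is_hydrogen and any(
                    res.atoms[k].element in ("O", "N", "S") for k in neigh[rj])
                if not (is_polar_heavy or is_polar_h):
                    continue
                d = float(np.linalg.norm(lig_xyz[xi] - rxyz[rj]))
                if d > search_cutoff:
                    continue
                theta_sigma = angle_deg(lig_xyz[ci], lig_xyz[xi], rxyz[rj])
                theta_acc = None
                heavy_neigh = [k for k in neigh[rj] if not res.atoms[k].is_hydrogen]
                if heavy_neigh:
                    anchor = max(heavy_neigh, key=lambda k: _MASS.get(res.atoms[k].element, 0.0))
                    theta_acc = angle_deg(rxyz[anchor], rxyz[rj], lig_xyz[xi])
                contacts.append(HalogenContact(
                    pose.key, xi, el, ci, res.key, res.label, rj, ratom.name,
                    ratom.element, round(d, 6), round(theta_sigma, 6),
                    None if theta_acc is None else round(theta_acc, 6)))
    return contacts


def classify_contact(c: HalogenContact, t: Thresholds | None = None) -> HalogenContact:
    """Classify a contact as xbond / x_as_acceptor / fail, recording every
    threshold comparison in the trace."""
    t = t or Thresholds()
    trace: dict[str, bool | str] = {}
    if c.partner_element in ("O", "N", "S"):
        if c.x_element == "F":
            trace["reason"] = "F excluded as X-bond donor"
            c.classification, c.trace = "fail", trace
            return c
        dmax = t.xo_max[c.x_element]
        trace[f"d<{dmax}"] = c.d_x_partner < dmax
        trace[f"theta_sigma>{t.sigma_angle_min}"] = c.theta_sigma > t.sigma_angle_min
        if c.theta_acceptor is None:
            trace["acceptor_angle"] = "unavailable (isolated partner)"
            acc_ok = True
        else:
            acc_ok = c.theta_acceptor > t.acceptor_angle_min
            trace[f"theta_acceptor>{t.acceptor_angle_min}"] = acc_ok
            if c.partner_element != "O":
                trace["acceptor_angle_rule"] = "generalised to heaviest attached atom"
        passed = trace[f"d<{dmax}"] and trace[f"theta_sigma>{t.sigma_angle_min}"] and acc_ok
        c.classification = "xbond" if passed else "fail"
    elif c.partner_element == "H":
        if t.xh_bound_is_lower:
            trace[f"d>{t.xh_bound}"] = c.d_x_partner > t.xh_bound
            d_ok = c.d_x_partner > t.xh_bound
        else:
            trace[f"d<{t.xh_bound}"] = c.d_x_partner < t.xh_bound
            d_ok = c.d_x_partner < t.xh_bound
        trace[f"theta_CXH>{t.cxh_angle_min}"] = c.theta_sigma > t.cxh_angle_min
        if c.theta_acceptor is None:
            trace["donor_angle"] = "unavailable (isolated H)"
            ang_ok = False
        else:
            ang_ok = c.theta_acceptor > t.ohx_angle_min
            trace[f"theta_DHX>{t.ohx_angle_min}"] = ang_ok
        passed = d_ok and trace[f"theta_CXH>{t.cxh_angle_min}"] and ang_ok
        c.classification = "x_as_acceptor" if passed else "fail"
    else:
        trace["reason"] = f"unsupported acceptor element {c.partner_element}"
        c.classification = "fail"
    c.trace = trace
    return c


RING_POSITIONS = ("ortho", "meta", "para", "aliphatic", "other")


def ring_position(pose: LigandPose, x_atom: int, match: ScaffoldMatch) -> str:
    """Position of a halogen substituent relative to the scaffold attachment.

    On the scaffold's six-membered aromatic ring, graph distance from the
    attachment carbon classifies the substituted carbon: 1 -> ortho,
    2 -> meta, 3 -> para. Halogens on other aromatic rings are ``other``;
    halogens on sp3 carbons are ``aliphatic``.
    """
    mol = pose.mol
    if x_atom >= mol.GetNumAtoms():
        raise StructureError(f"atom {x_atom} not in pose {pose.key}")
    atom = mol.GetAtomWithIdx(x_atom)
    carbons = [b for b in atom.GetNeighbors() if b.GetAtomicNum() == 6]
    if not carbons:
        raise StructureError(f"halogen atom {x_atom} has no bonded carbon")
    c = carbons[0]
    if not c.GetIsAromatic():
        return "aliphatic"

    # the scaffold ring atoms and the attachment carbon (ring atom bonded to
    # the benzylic CH2 of the scaffold)
    scaffold_atoms = set(match.correspondence)
    ring_info = mol.GetRingInfo()
    scaffold_ring = None
    for ring in ring_info.AtomRings():
        ring_set = set(ring)
        if len(ring) == 6 and ring_set <= scaffold_atoms and \
                all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            scaffold_ring = ring
            break
    if scaffold_ring is None:
        return "other"
    if c.GetIdx() not in scaffold_ring:
        return "other"
    attachment = None
    for i in scaffold_ring:
        for b in mol.GetAtomWithIdx(i).GetNeighbors():
            if b.GetIdx() in scaffold_atoms and b.GetIdx() not in scaffold_ring \
                    and b.GetAtomicNum() == 6:
                attachment = i
        if attachment is not None:
            break
    if attachment is None:
        return "other"
    # graph distance around the 6-ring
    pos = {a: i for i, a in enumerate(scaffold_ring)}
    dist = abs(pos[c.GetIdx()] - pos[attachment])
    dist = min(dist, 6 - dist)
    return {1: "ortho", 2: "meta", 3: "para"}.get(dist, "other")


def frequency_analysis(ps: PoseSet, contacts: Iterable[HalogenContact],
                       positions: dict[tuple[str, int], dict[int, str]] | None = None,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frequency of passing halogen contacts by ring position and element.

    Returns ``(by_position, by_partner)``: per (ring position, element), the
    number and percentage of poses with >= 1 passing contact -- the
    denominator is the pose count of ligands decorated at that position with
    that element -- and the per-residue partner tally over passing contacts.
    """
    if len(ps) == 0:
        raise StructureError("empty pose set")
    contacts = list(contacts)
    passing = [c for c in contacts if c.classification in ("xbond", "x_as_acceptor")]

    # which (position, element) slots does each ligand carry?
    slot_of_contact = {}
    for c in contacts:
        pos = c.ring_position or (positions or {}).get(c.pose_key, {}).get(c.x_atom, "other")
        slot_of_contact[id(c)] = (pos, c.x_element)
    ligand_slots: dict[str, set[tuple[str, str]]] = {lid: set() for lid in ps.ligand_ids}
    from .scaffold import ScaffoldDefinition, match_scaffold
    sd = ScaffoldDefinition()
    for lid, poses in ps.by_ligand.items():
        p = poses[0]
        classes = assign_atom_classes(p)
        try:
            m = match_scaffold(p, sd)
        except Exception:
            m = None
        for i, el in enumerate(classes.halogen):
            if el is None:
                continue
            pos = ring_position(p, i, m) if m is not None else "other"
            ligand_slots[lid].add((pos, el))

    rows = []
    all_slots = sorted({s for slots in ligand_slots.values() for s in slots})
    for pos, el in all_slots:
        eligible = [p.key for p in ps.poses if (pos, el) in ligand_slots[p.ligand_id]]
        hit_keys = {c.pose_key for c in passing if slot_of_contact[id(c)] == (pos, el)}
        n_hit = len(hit_keys & set(eligible))
        pct = 100.0 * n_hit / len(eligible) if eligible else 0.0
        rows.append({"ring_position": pos, "element": el, "n_poses": len(eligible),
                     "n_with_contact": n_hit, "percent": round(pct, 1)})
    by_position = pd.DataFrame(rows, columns=["ring_position", "element", "n_poses",
                                              "n_with_contact", "percent"])

    tally: dict[str, int] = {}
    for c in passing:
        tally[c.residue_label] = tally.get(c.residue_label, 0) + 1
    by_partner = pd.DataFrame(sorted(tally.items()), columns=["residue", "n_passing_contacts"])
    return by_position, by_partner


def select_qm_candidates(csc_poses: Sequence[LigandPose],
                         contacts: Iterable[HalogenContact],
                         energies: dict[tuple[str, int], float],
                         ) -> tuple[dict[str, tuple[str, int]], list[str]]:
    """Per ligand, pick the best-energy pose with >= 1 passing contact.

    ``energies`` maps pose key -> binding energy (kcal/mol, lower is better).
    Returns (selected pose per ligand, ligands left unselected because no
    pose passes the geometric criteria).
    """
    passing_keys = {c.pose_key for c in contacts
                    if c.classification in ("xbond", "x_as_acceptor")}
    by_ligand: dict[str, list[LigandPose]] = {}
    for p in csc_poses:
        by_ligand.setdefault(p.ligand_id, []).append(p)
    selected: dict[str, tuple[str, int]] = {}
    unselected: list[str] = []
    for lid, poses in by_ligand.items():
        candidates = [p for p in poses if p.key in passing_keys]
        if not candidates:
            unselected.append(lid)
            continue
        for p in candidates:
            if p.key not in energies:
                raise KeyError(f"missing energy for candidate pose {p.key}")
        best = min(candidates, key=lambda p: (energies[p.key], p.pose_id))
        selected[lid] = best.key
    return selected, unselected
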