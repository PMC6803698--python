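"""Synthetic receptors, ligand libraries, pose sets and charge models with
planted ground truth.

The generator emulates the data shape of a transporter docking study: eight
halogenated amino-acid ligands sharing a phenylalanine core, a small binding
pocket presenting exposed backbone donors/acceptors on one face (the
amino-acid binding site, ABS) and an apolar wall on the other (the side-chain
binding site, SBS) plus one backbone carbonyl positioned as a halogen-bond
acceptor, and ~100 poses per ligand distributed over two planted binding
modes plus random decoys.

Planted interactions are constructed with a safety margin (>= 0.2 A / 5 deg
inside the detection thresholds) and every mode-anchored pose is verified
with the production detectors: the detected interaction set must equal the
planted set at tightened thresholds and acquire nothing new at loosened
thresholds; offending jitter draws are redrawn. The generator therefore
closes the loop through the same code paths the analysis uses, rather than
trusting construction arithmetic.

All randomness flows from one seeded NumPy generator; equal seeds reproduce
byte-identical SDF/PDB output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolTransforms

from .structio import (Atom, LigandPose, PoseSet, ReceptorStructure, Residue,
                       StructureError, assign_atom_classes)
from .scaffold import (ScaffoldDefinition, match_scaffold, scaffold_rmsd,
                       _rmsd)
from .sift import HBondParams, detect_hbonds, detect_hydrophobic
from .halogen import Thresholds, classify_contact, find_halogen_contacts
from .esp import ChargeModel, ScalarGrid, BOHR_PER_ANGSTROM


class SynthError(RuntimeError):
    """Raised when generation or planted-geometry verification fails."""


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

#: default halogen decoration plan: (name, ring slots, alpha-methyl) -- a
#: library shaped like the iodo-tyrosines, bromo/chloro phenylalanines and
#: chloroethyl (aliphatic halogen) analogues of the transporter SAR series
DEFAULT_DECORATIONS: list[tuple[str, dict[str, str], bool]] = [
    ("iodotyr",      {"m1": "I", "p": "OH"}, False),
    ("diiodotyr",    {"m1": "I", "m2": "I", "p": "OH"}, False),
    ("obromo_ame",   {"o1": "Br"}, True),
    ("pbromo_ame",   {"p": "Br"}, True),
    ("fluoro_ame",   {"m1": "F", "p": "OH"}, True),
    ("pchloro",      {"p": "Cl"}, False),
    ("mchloroethyl", {"m1": "ClEt"}, False),
    ("pchloroethyl", {"p": "ClEt"}, False),
]

PLANT_MARGIN_D = 0.2     # A inside/outside every distance threshold
PLANT_MARGIN_ANGLE = 5.0  # deg inside/outside every angular threshold


@dataclass
class SynthConfig:
    seed: int = 0
    n_ligands: int = 8
    poses_per_ligand: int = 100
    n_modes: int = 2
    jitter_sigma: float = 0.5      # A; translation scale of the rigid jitter
    decoy_fraction: float = 0.2
    cluster_height: float = 2.0    # A; the clustering height the plants respect
    decorations: list[tuple[str, dict[str, str], bool]] = field(
        default_factory=lambda: list(DEFAULT_DECORATIONS))
    max_tries: int = 500

    def __post_init__(self) -> None:
        if self.n_ligands < 1:
            raise SynthError("need at least one ligand")
        if self.n_ligands > len(self.decorations):
            raise SynthError("not enough decorations for n_ligands")
        if not (0.0 <= self.decoy_fraction < 1.0):
            raise SynthError("decoy_fraction must be in [0, 1)")
        if self.n_modes not in (1, 2):
            raise SynthError("n_modes must be 1 or 2")


@dataclass
class GroundTruth:
    """Planted labels: per pose a mode or decoy, the planted interactions,
    and per ligand its halogen decoration map."""

    mode_of: dict[tuple[str, int], str] = field(default_factory=dict)
    planted_hbonds: dict[tuple[str, int], list[dict]] = field(default_factory=dict)
    planted_xbonds: dict[tuple[str, int], list[dict]] = field(default_factory=dict)
    decorations: dict[str, list[dict]] = field(default_factory=dict)

    def non_decoy_keys(self) -> list[tuple[str, int]]:
        return [k for k, m in self.mode_of.items() if m != "decoy"]

    def to_json(self, path: str | Path) -> None:
        def enc_key(k):
            return f"{k[0]}|{k[1]}"
        doc = {
            "mode_of": {enc_key(k): v for k, v in sorted(self.mode_of.items())},
            "planted_hbonds": {enc_key(k): v for k, v in sorted(self.planted_hbonds.items())},
            "planted_xbonds": {enc_key(k): v for k, v in sorted(self.planted_xbonds.items())},
            "decorations": self.decorations,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        doc = json.loads(Path(path).read_text())

        def dec_key(s):
            lig, pid = s.rsplit("|", 1)
            return (lig, int(pid))
        return cls(
            mode_of={dec_key(k): v for k, v in doc["mode_of"].items()},
            planted_hbonds={dec_key(k): v for k, v in doc["planted_hbonds"].items()},
            planted_xbonds={dec_key(k): v for k, v in doc["planted_xbonds"].items()},
            decorations=doc["decorations"])


# ---------------------------------------------------------------------------
# ligand library
# ---------------------------------------------------------------------------

_SLOT_SMILES = {"": "", "I": "(I)", "Br": "(Br)", "Cl": "(Cl)", "F": "(F)",
                "OH": "(O)", "ClEt": "(CCCl)"}


def _ligand_smiles(slots: dict[str, str], alpha_methyl: bool) -> str:
    s = {k: _SLOT_SMILES[slots.get(k, "")] for k in ("o1", "m1", "p", "m2", "o2")}
    ring = f"c1c{s['o1']}c{s['m1']}c{s['p']}c{s['m2']}c{s['o2']}1"
    if alpha_methyl:
        # alpha-quaternary stereocentre fixed to the L-like configuration
        return f"[NH3+][C@@](C)(C{ring})C(=O)[O-]"
    return f"[NH3+][C@@H](C{ring})C(=O)[O-]"


def make_ligand_library(cfg: SynthConfig) -> tuple[list[Chem.Mol], GroundTruth]:
    """Build the halogen-decorated amino-acid ligands with 3-D coordinates.

    Every molecule carries explicit hydrogens, one embedded conformer and the
    properties ``ligand_id`` / ``decoration``. All ligands match the
    phenylalanine scaffold pattern (self-checked via match_scaffold).
    """
    sd = ScaffoldDefinition()
    truth = GroundTruth()
    mols = []
    for idx in range(cfg.n_ligands):
        name, slots, ame = cfg.decorations[idx]
        seen = [k for k, v in slots.items() if v]
        if len(seen) != len(set(seen)):
            raise SynthError(f"ligand {name}: duplicate substitution on one position")
        smi = _ligand_smiles(slots, ame)
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise SynthError(f"ligand {name}: invalid decoration {slots}")
        mol = Chem.AddHs(mol)
        params = AllChem.ETKDGv3()
        params.randomSeed = int((cfg.seed * 1009 + idx * 7919) % (2 ** 31 - 1))
        if AllChem.EmbedMolecule(mol, params) != 0:
            raise SynthError(f"ligand {name}: embedding failed")
        AllChem.MMFFOptimizeMolecule(mol)
        mol.SetProp("ligand_id", name)
        mol.SetProp("decoration", json.dumps(slots, sort_keys=True))
        pose = LigandPose(mol, name, 0)
        match_scaffold(pose, sd)  # raises if the decoration broke the core
        mols.append(mol)
        truth.decorations[name] = [
            {"position": {"m1": "meta", "m2": "meta", "o1": "ortho", "o2": "ortho",
                          "p": "para"}[k] if v != "ClEt" else "aliphatic",
             "element": "Cl" if v == "ClEt" else v}
            for k, v in sorted(slots.items()) if v in ("I", "Br", "Cl", "F", "ClEt")]
    return mols, truth


# ---------------------------------------------------------------------------
# canonical reference frame and geometry
# ---------------------------------------------------------------------------

# scaffold-order indices (see PHENYLALANINE_SMARTS atom order)
S_N, S_CA, S_C, S_O1, S_O2, S_CB = 0, 1, 2, 3, 4, 5
S_RING = (6, 7, 8, 9, 10, 11)   # C1 (attach), C2, C3, C4, C5, C6
_REFERENCE_SEED = 20_251_101


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform R, t with R @ mobile_i + t ~= target_i."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return r, tc - r @ mc


def _reference_molecule() -> tuple[Chem.Mol, tuple[int, ...]]:
    """The canonical L-phenylalanine zwitterion conformer, in a deterministic
    frame (CA at origin, amino nitrogen on -x, ring roughly in +y)."""
    mol = Chem.AddHs(Chem.MolFromSmiles("[NH3+][C@@H](Cc1ccccc1)C(=O)[O-]"))
    params = AllChem.ETKDGv3()
    params.randomSeed = _REFERENCE_SEED
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise SynthError("reference embedding failed")
    AllChem.MMFFOptimizeMolecule(mol)
    match = match_scaffold(LigandPose(mol, "ref", 0), ScaffoldDefinition()).correspondence

    conf = mol.GetConformer()
    xyz = np.asarray(conf.GetPositions(), float)
    ca = xyz[match[S_CA]]
    e1 = xyz[match[S_N]] - ca
    e1 /= -np.linalg.norm(e1)          # N sits on -x
    ring_c = xyz[[match[i] for i in S_RING]].mean(axis=0) - ca
    e2 = ring_c - np.dot(ring_c, e1) * e1
    e2 /= np.linalg.norm(e2)
    e3 = np.cross(e1, e2)
    rot = np.vstack([e1, e2, e3])
    new = (xyz - ca) @ rot.T
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, new[i].tolist())
    return mol, match


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to u."""
    probe = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(u, probe)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    return _unit(np.cross(u, probe))


@dataclass
class _RefGeometry:
    """Anchor coordinates of the reference pose the pocket is built around."""

    mol: Chem.Mol
    match: tuple[int, ...]
    xyz: np.ndarray
    n: np.ndarray
    o1: np.ndarray
    o2: np.ndarray
    c_carboxyl: np.ndarray
    cb: np.ndarray
    ca: np.ndarray
    ring: np.ndarray                # (6, 3), C1..C6
    ring_centroid: np.ndarray
    nh_dirs: list[np.ndarray]       # three N-H unit vectors
    meta_axes: dict[str, tuple[np.ndarray, np.ndarray]]  # slot -> (C_meta, radial)


def _reference_geometry() -> _RefGeometry:
    mol, match = _reference_molecule()
    xyz = np.asarray(mol.GetConformer().GetPositions(), float)
    ring = xyz[[match[i] for i in S_RING]]
    centroid = ring.mean(axis=0)
    n_idx = match[S_N]
    nh = [ _unit(xyz[h.GetIdx()] - xyz[n_idx])
           for h in mol.GetAtomWithIdx(n_idx).GetNeighbors() if h.GetAtomicNum() == 1]
    meta = {}
    for slot, ring_pos in (("m1", 2), ("m2", 4)):   # C3 and C5
        c_meta = ring[ring_pos]
        radial = _unit(c_meta - centroid)
        meta[slot] = (c_meta, radial)
    return _RefGeometry(
        mol=mol, match=match, xyz=xyz, n=xyz[n_idx], o1=xyz[match[S_O1]],
        o2=xyz[match[S_O2]], c_carboxyl=xyz[match[S_C]], cb=xyz[match[S_CB]],
        ca=xyz[match[S_CA]], ring=ring, ring_centroid=centroid, nh_dirs=nh,
        meta_axes=meta)


# planted contact distances (margins inside the 3.5 A / 3.5 A-element criteria)
_HB_D = 2.85          # A, planted D...A
_XB_D = 3.05          # A, planted I...O
_C_I = 2.10           # A, aromatic C-I bond length


# ---------------------------------------------------------------------------
# pocket construction
# ---------------------------------------------------------------------------

def _gly_donor(resseq: int, target: np.ndarray, u: np.ndarray,
               chain: str = "A") -> Residue:
    """Backbone N-H donor aimed at a ligand acceptor along u (unit, pointing
    from the ligand atom outward)."""
    p = _perp(u)
    n = target + _HB_D * u
    h = n - 1.01 * u
    d1 = _unit(u + 0.9 * p)
    ca = n + 1.47 * d1
    c = ca + 1.52 * u
    o = c + 1.23 * d1
    serial = resseq * 10
    atoms = [Atom(serial + 1, "N", "N", n), Atom(serial + 2, "H", "H", h),
             Atom(serial + 3, "CA", "C", ca), Atom(serial + 4, "C", "C", c),
             Atom(serial + 5, "O", "O", o)]
    return Residue(chain, resseq, "", "GLY", atoms)


def _carbonyl_acceptor(resseq: int, donor_heavy: np.ndarray, u: np.ndarray,
                       resname: str = "GLY", chain: str = "A",
                       extra: list[Atom] | None = None) -> Residue:
    """Backbone carbonyl O placed along a donor direction u; the carbonyl C
    sits so that the acceptor-side angle (C=O...donor) is ~120 deg."""
    p = _perp(u)
    o = donor_heavy + _HB_D * u
    c = o + 1.23 * _unit(0.5 * u + 0.866 * p)
    serial = resseq * 10
    atoms = [Atom(serial + 2, "C", "C", c), Atom(serial + 3, "O", "O", o)]
    if extra:
        atoms += extra
    return Residue(chain, resseq, "", resname, atoms)


def _leu_blob(resseq: int, center: np.ndarray, chain: str = "A") -> Residue:
    """An apolar side-chain fragment: four tetrahedrally arranged carbons."""
    t = 1.53 / math.sqrt(3.0)
    offs = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    names = ["CB", "CG", "CD1", "CD2"]
    serial = resseq * 10
    atoms = [Atom(serial + i, nm, "C", center + off)
             for i, (nm, off) in enumerate(zip(names, offs), start=1)]
    return Residue(chain, resseq, "", "LEU", atoms)


def _phe_ring_atoms(centroid: np.ndarray, normal: np.ndarray,
                    serial0: int) -> list[Atom]:
    p1 = _perp(normal)
    p2 = np.cross(normal, p1)
    names = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
    atoms = []
    for i, nm in enumerate(names):
        ang = math.radians(60.0 * i)
        pos = centroid + 1.39 * (math.cos(ang) * p1 + math.sin(ang) * p2)
        atoms.append(Atom(serial0 + i, nm, "C", pos))
    return atoms


def make_pocket(cfg: SynthConfig, degraded: bool = False) -> ReceptorStructure:
    """Build the synthetic binding pocket around the reference placement.

    ABS face: two backbone N-H donors aimed at the carboxylate oxygens and
    three backbone carbonyls accepting the ammonium hydrogens; a further
    backbone carbonyl sits on the meta-halogen sigma-hole axis as the X-bond
    acceptor. SBS face: apolar blobs against the benzylic edge and the two
    meta-substituent tips, plus an aromatic ring within cation-pi range of
    the ammonium.

    ``degraded=True`` yields the interaction-poor variant used to probe
    feature loss: the X-bond acceptor is pushed off-axis, the benzylic wall
    is removed and the cation-pi ring is dropped.
    """
    g = _reference_geometry()
    residues: list[Residue] = []

    u1 = _unit(g.o1 - g.c_carboxyl)
    u2 = _unit(g.o2 - g.c_carboxyl)
    residues.append(_gly_donor(66, g.o1, u1))
    residues.append(_gly_donor(67, g.o2, u2))

    h1, h2, h3 = g.nh_dirs
    residues.append(_carbonyl_acceptor(63, g.n, h1))
    residues.append(_carbonyl_acceptor(255, g.n, h3))

    # residue 252: backbone carbonyl accepting the second ammonium H; in the
    # intact pocket it also presents an aromatic ring within cation-pi range
    extra = None
    if not degraded:
        pi_dir = _unit(g.n - g.ring_centroid)
        pi_centroid = g.n + 4.6 * pi_dir
        extra = _phe_ring_atoms(pi_centroid, pi_dir, 2526)
    residues.append(_carbonyl_acceptor(252, g.n, h2, resname="PHE" if extra else "GLY",
                                       extra=extra))

    # X-bond acceptor on the m1 sigma-hole axis (meta C-I extension)
    c_meta, radial = g.meta_axes["m1"]
    x_ref = c_meta + _C_I * radial
    o401 = x_ref + _XB_D * radial
    if degraded:
        o401 = o401 + 2.5 * _perp(radial)
    p = _perp(radial)
    c401 = o401 + 1.23 * _unit(0.5 * radial + 0.866 * p)
    residues.append(Residue("A", 401, "", "GLY", [
        Atom(4012, "C", "C", c401), Atom(4013, "O", "O", o401)]))

    # SBS wall near the benzylic carbon (cluster anchor for ring + CB),
    # pulled toward the CA side so it stays clear of the meta positions
    if not degraded:
        w = _unit(np.cross(g.ring[0] - g.cb, g.ca - g.cb))
        back = _unit(g.cb - g.ring_centroid)
        residues.append(_leu_blob(140, g.cb + 4.0 * w + 1.3 * back))

    # apolar partners at the two meta-substituent tips: two carbons pointing
    # away from the ring, close to the halogen but clear of the ring carbons
    # so the halogen forms its own hydrophobic cluster
    for resseq, slot in ((405, "m1"), (62, "m2")):
        c_meta, radial = g.meta_axes[slot]
        tip = c_meta + _C_I * radial
        m = _perp(radial)
        if slot == "m2":
            m = -m
        u = _unit(0.5 * radial + 0.866 * m)
        center = tip + 3.9 * u
        serial = resseq * 10
        residues.append(Residue("A", resseq, "", "LEU", [
            Atom(serial + 1, "CD1", "C", center),
            Atom(serial + 2, "CD2", "C", center + 1.53 * u)]))

    residues.sort(key=lambda r: r.resseq)
    return ReceptorStructure(residues, title="synthetic pocket (degraded)" if degraded
                             else "synthetic pocket")


# ---------------------------------------------------------------------------
# pose planting
# ---------------------------------------------------------------------------

def _snap_torsions(mol: Chem.Mol, match: tuple[int, ...], ref: _RefGeometry) -> None:
    """Make the scaffold-internal torsions match the reference conformer so
    that every ligand presents the amino-acid moiety identically."""
    conf = mol.GetConformer()
    ref_conf = ref.mol.GetConformer()
    rm = ref.match

    def ref_dihedral(i, j, k, l):
        return rdMolTransforms.GetDihedralDeg(ref_conf, rm[i], rm[j], rm[k], rm[l])

    # carboxylate orientation, side-chain chi1/chi2
    rdMolTransforms.SetDihedralDeg(conf, match[S_N], match[S_CA], match[S_C],
                                   match[S_O1], ref_dihedral(S_N, S_CA, S_C, S_O1))
    rdMolTransforms.SetDihedralDeg(conf, match[S_N], match[S_CA], match[S_CB],
                                   match[S_RING[0]],
                                   ref_dihedral(S_N, S_CA, S_CB, S_RING[0]))
    rdMolTransforms.SetDihedralDeg(conf, match[S_CA], match[S_CB], match[S_RING[0]],
                                   match[S_RING[1]],
                                   ref_dihedral(S_CA, S_CB, S_RING[0], S_RING[1]))
    # ammonium torsion: rotate the NH3 group as a unit
    h_lig = [a.GetIdx() for a in mol.GetAtomWithIdx(match[S_N]).GetNeighbors()
             if a.GetAtomicNum() == 1]
    h_ref = [a.GetIdx() for a in ref.mol.GetAtomWithIdx(rm[S_N]).GetNeighbors()
             if a.GetAtomicNum() == 1]
    if h_lig and h_ref:
        target = rdMolTransforms.GetDihedralDeg(ref_conf, rm[S_CB], rm[S_CA],
                                                rm[S_N], h_ref[0])
        rdMolTransforms.SetDihedralDeg(conf, match[S_CB], match[S_CA], match[S_N],
                                       h_lig[0], target)


def _align_to_reference(mol: Chem.Mol, match: tuple[int, ...],
                        ref: _RefGeometry) -> None:
    conf = mol.GetConformer()
    xyz = np.asarray(conf.GetPositions(), float)
    mobile = xyz[list(match)]
    target = ref.xyz[list(ref.match)]
    r, t = _kabsch(mobile, target)
    new = xyz @ r.T + t
    for i in range(mol.GetNumAtoms()):
        conf.SetAtomPosition(i, new[i].tolist())


def _maybe_flip_ring(mol: Chem.Mol, match: tuple[int, ...],
                     ref: _RefGeometry) -> None:
    """If the ligand carries exactly one meta halogen, place it on the
    X-bond-acceptor side of the ring (the two meta slots are related by the
    phenyl flip, so this is a pure relabelling of an equivalent geometry)."""
    classes = assign_atom_classes(LigandPose(Chem.Mol(mol), "tmp", 0))
    conf = mol.GetConformer()
    xyz = np.asarray(conf.GetPositions(), float)
    c_m1, radial = ref.meta_axes["m1"]
    x_site = c_m1 + _C_I * radial
    meta_idx = []
    for i, el in enumerate(classes.halogen):
        if el is None:
            continue
        nb = mol.GetAtomWithIdx(i).GetNeighbors()[0]
        if nb.GetIsAromatic() and nb.GetIdx() in match:
            meta_c1, meta_c2 = match[S_RING[2]], match[S_RING[4]]
            if nb.GetIdx() in (meta_c1, meta_c2):
                meta_idx.append(i)
    if len(meta_idx) != 1:
        return
    d_now = np.linalg.norm(xyz[meta_idx[0]] - x_site)
    if d_now < 1.5:
        return
    # flip the ring about the C1-C4 axis: rotate chi2 by 180 deg
    cur = rdMolTransforms.GetDihedralDeg(conf, match[S_CA], match[S_CB],
                                         match[S_RING[0]], match[S_RING[1]])
    rdMolTransforms.SetDihedralDeg(conf, match[S_CA], match[S_CB],
                                   match[S_RING[0]], match[S_RING[1]], cur + 180.0)


_TIGHT_HB = HBondParams(distance=3.5 - PLANT_MARGIN_D, angle=120.0 + PLANT_MARGIN_ANGLE)
_LOOSE_HB = HBondParams(distance=3.5 + PLANT_MARGIN_D, angle=120.0 - PLANT_MARGIN_ANGLE)


def _margin_thresholds(sign: float) -> Thresholds:
    m_d, m_a = sign * PLANT_MARGIN_D, sign * PLANT_MARGIN_ANGLE
    return Thresholds(
        xo_max={"Cl": 3.27 - m_d, "Br": 3.37 - m_d, "I": 3.50 - m_d},
        xh_bound=2.8 + m_d, sigma_angle_min=150.0 + m_a,
        acceptor_angle_min=90.0 + m_a, cxh_angle_min=90.0 + m_a,
        ohx_angle_min=120.0 + m_a)


_TIGHT_X = _margin_thresholds(+1.0)
_LOOSE_X = _margin_thresholds(-1.0)


def _hbond_signature(pose: LigandPose, pocket: ReceptorStructure,
                     params: HBondParams) -> set[tuple]:
    recs = detect_hbonds(pose, pocket, params)
    return {(r.kind, r.ligand_atom, r.residue_key, r.residue_atom_name) for r in recs}


def _xbond_signature(pose: LigandPose, pocket: ReceptorStructure,
                     thr: Thresholds) -> set[tuple]:
    out = set()
    for c in find_halogen_contacts(pose, pocket):
        c = classify_contact(c, thr)
        if c.classification in ("xbond", "x_as_acceptor"):
            out.add((c.x_atom, c.residue_key, c.partner_name, c.classification))
    return out


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = math.radians(rng.uniform(0.0, max_angle_deg))
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + math.sin(ang) * k + (1 - math.cos(ang)) * (k @ k)


def _ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    while True:
        v = rng.uniform(-radius, radius, size=3)
        if np.dot(v, v) <= radius * radius:
            return v


def plant_poses(ligands: Sequence[Chem.Mol], pocket: ReceptorStructure,
                cfg: SynthConfig) -> tuple[PoseSet, GroundTruth]:
    """Generate the planted pose set.

    Per ligand: mode-anchored poses (reference scaffold placement per mode
    plus rigid jitter) and uniform random decoys. Every mode pose is verified
    with the production detectors against the planted interaction set at
    margin-tightened and margin-loosened thresholds and redrawn on failure;
    its scaffold deviation from the mode reference is capped at just under
    half the clustering height, which guarantees intra-mode pairwise RMSD
    below the clustering height and keeps modes separable.
    """
    ref = _reference_geometry()
    sd = ScaffoldDefinition()
    rng = np.random.default_rng(cfg.seed)
    global_cap = cfg.cluster_height / 2.0 - 0.05

    n_decoy = int(round(cfg.poses_per_ligand * cfg.decoy_fraction))
    n_mode_total = cfg.poses_per_ligand - n_decoy
    per_mode = [n_mode_total // cfg.n_modes] * cfg.n_modes
    per_mode[0] += n_mode_total - sum(per_mode)

    poses: list[LigandPose] = []
    truth = GroundTruth()

    for mol0 in ligands:
        lig_id = mol0.GetProp("ligand_id")
        truth.decorations.setdefault(lig_id, json.loads(mol0.GetProp("decoration"))
                                     if mol0.HasProp("decoration") else [])
        # mode reference conformers
        rmsd_cap = global_cap
        bases: list[Chem.Mol] = []
        mol = Chem.Mol(mol0)
        match = match_scaffold(LigandPose(mol, lig_id, 0), sd).correspondence
        _snap_torsions(mol, match, ref)
        _align_to_reference(mol, match, ref)
        _maybe_flip_ring(mol, match, ref)
        _align_to_reference(mol, match, ref)
        bases.append(mol)
        if cfg.n_modes == 2:
            # the second mode keeps the amino-acid moiety (and its planted
            # hydrogen bonds) fixed and swings the side chain away; scan the
            # chi1 rotation for the placement best separated from mode 1
            # under the scaffold's automorphism-minimised RMSD, then require
            # separation above twice the clustering height so that, with the
            # per-pose deviation cap below, no cross-mode pose pair can fall
            # under the clustering height
            base1 = LigandPose(Chem.Mol(mol), lig_id, -1)
            m1 = match_scaffold(base1, sd)
            cur = rdMolTransforms.GetDihedralDeg(mol.GetConformer(), match[S_N],
                                                 match[S_CA], match[S_CB],
                                                 match[S_RING[0]])
            cur2 = rdMolTransforms.GetDihedralDeg(mol.GetConformer(), match[S_CA],
                                                  match[S_CB], match[S_RING[0]],
                                                  match[S_RING[1]])
            candidates = []
            for delta in range(100, 261, 20):
                for delta2 in (0.0, 60.0, 90.0):
                    mol2 = Chem.Mol(mol)
                    rdMolTransforms.SetDihedralDeg(mol2.GetConformer(), match[S_N],
                                                   match[S_CA], match[S_CB],
                                                   match[S_RING[0]], cur + delta)
                    rdMolTransforms.SetDihedralDeg(mol2.GetConformer(), match[S_CA],
                                                   match[S_CB], match[S_RING[0]],
                                                   match[S_RING[1]], cur2 + delta2)
                    p2 = LigandPose(Chem.Mol(mol2), lig_id, -2)
                    sep = scaffold_rmsd(base1, p2, m1, match_scaffold(p2, sd))
                    candidates.append((sep, (delta, delta2), mol2))
            candidates.sort(key=lambda t: (-t[0], t[1]))
            chosen = None
            for sep, delta, mol2 in candidates:
                if sep <= 2.0 * cfg.cluster_height:
                    break
                p2 = LigandPose(Chem.Mol(mol2), lig_id, -2)
                hb = _hbond_signature(p2, pocket, _TIGHT_HB)
                if len(hb) < 5 or _hbond_signature(p2, pocket, _LOOSE_HB) != hb:
                    continue
                if _xbond_signature(p2, pocket, _TIGHT_X) != \
                        _xbond_signature(p2, pocket, _LOOSE_X):
                    continue
                chosen = (sep, mol2)
                break
            if chosen is None:
                raise SynthError(f"{lig_id}: no mode-2 placement separates the "
                                 "modes beyond twice the clustering height")
            sep, mol2 = chosen
            bases.append(mol2)
            rmsd_cap = min(rmsd_cap, (sep - cfg.cluster_height) / 2.0 - 0.05)

        base_poses = [LigandPose(Chem.Mol(b), lig_id, -1 - k) for k, b in enumerate(bases)]
        base_matches = [match_scaffold(p, sd) for p in base_poses]

        # planted interaction sets, from the detectors at tightened margins
        planted_hb = [_hbond_signature(p, pocket, _TIGHT_HB) for p in base_poses]
        planted_x = [_xbond_signature(p, pocket, _TIGHT_X) for p in base_poses]
        for k, p in enumerate(base_poses):
            if _hbond_signature(p, pocket, _LOOSE_HB) != planted_hb[k]:
                raise SynthError(f"{lig_id} mode {k + 1}: base pose has marginal "
                                 "hydrogen-bond geometry")
            if _xbond_signature(p, pocket, _LOOSE_X) != planted_x[k]:
                raise SynthError(f"{lig_id} mode {k + 1}: base pose has marginal "
                                 "halogen-contact geometry")
            if len(planted_hb[k]) < 5:
                raise SynthError(f"{lig_id} mode {k + 1}: only {len(planted_hb[k])} "
                                 "backbone hydrogen bonds planted (expected >= 5)")

        pose_id = 0
        for k, base in enumerate(bases):
            base_pose = base_poses[k]
            base_match = base_matches[k]
            centroid = base_pose.coords()[list(base_match.correspondence)].mean(axis=0)
            for _ in range(per_mode[k]):
                for attempt in range(cfg.max_tries):
                    rot = _random_rotation(rng, 8.0 * cfg.jitter_sigma)
                    trans = _ball(rng, 2.0 * cfg.jitter_sigma)
                    shift = centroid - rot @ centroid + trans
                    cand = base_pose.transformed(rot, shift)
                    cand.pose_id = pose_id
                    cm = match_scaffold(cand, sd)
                    if scaffold_rmsd(cand, base_pose, cm, base_match) > rmsd_cap:
                        continue
                    if _hbond_signature(cand, pocket, _TIGHT_HB) != planted_hb[k]:
                        continue
                    if _hbond_signature(cand, pocket, _LOOSE_HB) != planted_hb[k]:
                        continue
                    if _xbond_signature(cand, pocket, _TIGHT_X) != planted_x[k]:
                        continue
                    if _xbond_signature(cand, pocket, _LOOSE_X) != planted_x[k]:
                        continue
                    break
                else:
                    raise SynthError(
                        f"{lig_id} mode {k + 1}: planted-geometry verification "
                        f"failed {cfg.max_tries} times (sigma={cfg.jitter_sigma})")
                key = (lig_id, pose_id)
                truth.mode_of[key] = f"mode_{k + 1}"
                truth.planted_hbonds[key] = [
                    {"kind": s[0], "ligand_atom": s[1], "residue": list(s[2]),
                     "residue_atom": s[3]} for s in sorted(planted_hb[k])]
                truth.planted_xbonds[key] = [
                    {"x_atom": s[0], "residue": list(s[1]), "partner": s[2],
                     "class": s[3]} for s in sorted(planted_x[k])]
                poses.append(cand)
                pose_id += 1

        # decoys: uniform random rigid placements, kept well away from both
        # mode references so they can never join a mode cluster at the cut,
        # and free of passing halogen contacts (their ground truth plants
        # nothing, so a chance sigma-hole hit would mislabel them)
        box_lo = ref.xyz.min(axis=0) - 3.0
        box_hi = ref.xyz.max(axis=0) + 3.0
        for _ in range(n_decoy):
            for attempt in range(cfg.max_tries):
                rot = _random_rotation(rng, 360.0)
                target = rng.uniform(box_lo, box_hi)
                base_pose0 = base_poses[0]
                centroid0 = base_pose0.heavy_coords().mean(axis=0)
                shift = target - rot @ centroid0
                cand = base_pose0.transformed(rot, shift)
                cand.pose_id = pose_id
                cm = match_scaffold(cand, sd)
                far = all(scaffold_rmsd(cand, bp, cm, bm) > cfg.cluster_height + rmsd_cap + 0.25
                          for bp, bm in zip(base_poses, base_matches))
                if far and not _xbond_signature(cand, pocket, _LOOSE_X):
                    break
            else:
                raise SynthError(f"{lig_id}: decoy placement failed")
            key = (lig_id, pose_id)
            truth.mode_of[key] = "decoy"
            truth.planted_hbonds[key] = []
            truth.planted_xbonds[key] = []
            poses.append(cand)
            pose_id += 1

    return PoseSet(poses), truth


def reference_pose(mol: Chem.Mol, ligand_id: str | None = None) -> LigandPose:
    """The jitter-free mode-1 placement of one library ligand: scaffold
    torsions snapped to the reference conformer, rigidly aligned into the
    pocket frame, meta halogen (if single) on the X-bond-acceptor side."""
    ref = _reference_geometry()
    sd = ScaffoldDefinition()
    lig_id = ligand_id or (mol.GetProp("ligand_id") if mol.HasProp("ligand_id") else "ligand")
    m = Chem.Mol(mol)
    match = match_scaffold(LigandPose(m, lig_id, 0), sd).correspondence
    _snap_torsions(m, match, ref)
    _align_to_reference(m, match, ref)
    _maybe_flip_ring(m, match, ref)
    _align_to_reference(m, match, ref)
    return LigandPose(m, lig_id, 0)


# ---------------------------------------------------------------------------
# synthetic energies
# ---------------------------------------------------------------------------

def make_energy_table(ps: PoseSet, truth: GroundTruth, seed: int = 0):
    """Mock per-pose energy records (docking-score scale and an optimised
    scale correlated with it), component-consistent with the dG identity.

    Decoys score worse than mode-anchored poses on average; the second
    source exists for mode poses only, mimicking the selective refinement
    of consensus-cluster poses.
    """
    from .energetics import EnergyRecord

    rng = np.random.default_rng(seed + 77)
    g_protein = -12_000.0
    records = []
    for p in ps.poses:
        mode = truth.mode_of.get(p.key, "decoy")
        g_ligand = -100.0 - 3.0 * (sum(map(ord, p.ligand_id)) % 7)
        base = -9.0 if mode != "decoy" else -5.5
        dg = base + rng.normal(0.0, 1.2)
        records.append(EnergyRecord(
            p.key, "glide", g_complex=g_protein + g_ligand + dg,
            g_protein=g_protein, g_ligand=g_ligand, dg_bind=dg))
        if mode != "decoy":
            dg2 = dg - 2.5 + rng.normal(0.0, 0.8)
            records.append(EnergyRecord(
                p.key, "qmmm", g_complex=g_protein + g_ligand + dg2,
                g_protein=g_protein, g_ligand=g_ligand, dg_bind=dg2))
    return records


# ---------------------------------------------------------------------------
# charge-model fixtures
# ---------------------------------------------------------------------------

def make_charge_model(kind: str, params: dict | None = None,
                      ) -> tuple[ChargeModel, dict]:
    """Analytic charge-model fixtures for the surface-potential stack.

    kinds: ``gaussian_atom`` (spherical Gaussian density with known
    isodensity radius), ``dipole`` (two opposite point charges),
    ``sigma_hole_mimic`` (a neutral C-X-like pair with a positive cap charge
    on the C->X axis). Returns (model, metadata incl. analytic references).
    """
    p = dict(params or {})
    meta: dict = {"kind": kind}
    if kind == "gaussian_atom":
        n_e = float(p.get("n_electrons", 10.0))
        sigma = float(p.get("sigma", 1.0))
        z = int(p.get("z", round(n_e)))
        spacing = float(p.get("spacing", 0.25))
        iso = float(p.get("iso", 0.001))
        peak = n_e * (2.0 * math.pi * sigma ** 2) ** -1.5
        if peak <= iso:
            raise SynthError("density peak below isovalue: not normalizable at this iso")
        r_iso = sigma * math.sqrt(2.0 * math.log(peak / iso))
        half = r_iso + 6.0 * spacing + 1.0
        n = int(2 * half / spacing) + 1
        ax = -half + spacing * np.arange(n)
        xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
        rho = n_e * (2 * math.pi * sigma ** 2) ** -1.5 * \
            np.exp(-(xx ** 2 + yy ** 2 + zz ** 2) / (2 * sigma ** 2))
        grid = ScalarGrid(np.full(3, -half), np.full(3, spacing), rho)
        cm = ChargeModel(nuclei=[(z, np.zeros(3))], density=grid, elements=["O"])
        meta["isodensity_radius"] = r_iso
        return cm, meta
    if kind == "dipole":
        q = float(p.get("q", 1.0))
        d = float(p.get("d", 2.0))
        cm = ChargeModel(partial_charges=[(q, np.array([0.0, 0.0, d / 2])),
                                          (-q, np.array([0.0, 0.0, -d / 2]))])
        meta["moment"] = q * d
        return cm, meta
    if kind == "sigma_hole_mimic":
        q_cap = float(p.get("q_cap", 0.15))
        cap_d = float(p.get("cap_distance", 0.5))     # bohr beyond X
        d_cx = float(p.get("c_x_distance", 3.4))      # bohr
        x_pos = np.zeros(3)
        c_pos = np.array([-d_cx, 0.0, 0.0])
        cm = ChargeModel(
            nuclei=[(6, c_pos), (17, x_pos)],
            electron_points=[(6.0, c_pos), (17.0, x_pos)],
            partial_charges=[(q_cap, x_pos + np.array([cap_d, 0.0, 0.0])),
                             (-q_cap, x_pos - np.array([cap_d, 0.0, 0.0]))],
            elements=["C", "Cl"])
        meta["axis"] = np.array([1.0, 0.0, 0.0])
        return cm, meta
    raise SynthError(f"unknown charge-model kind {kind!r}")


# ---------------------------------------------------------------------------
# one-call convenience
# ---------------------------------------------------------------------------

def generate(cfg: SynthConfig, out_dir: str | Path | None = None,
             ) -> tuple[ReceptorStructure, PoseSet, GroundTruth]:
    """Library + pocket + planted poses; optionally write pocket.pdb,
    ligands.sdf, poses.sdf and truth.json into ``out_dir``."""
    from .structio import write_poses, write_receptor

    ligands, _ = make_ligand_library(cfg)
    pocket = make_pocket(cfg)
    ps, truth = plant_poses(ligands, pocket, cfg)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_receptor(pocket, out / "pocket.pdb")
        lig_set = PoseSet([LigandPose(m, m.GetProp("ligand_id"), 0) for m in ligands])
        write_poses(lig_set, out / "ligands.sdf")
        write_poses(ps, out / "poses.sdf",
                    extra_props={k: {"mode": truth.mode_of[k]} for k in truth.mode_of})
        truth.to_json(out / "truth.json")
    return pocket, ps, truth
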