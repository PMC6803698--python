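"""Structure input/output and atom typing.

Reads receptor structures (PDB) and docking pose sets (SDF), and assigns the
medicinal-chemistry atom classes (donor, acceptor, hydrophobic, halogen,
cationic, aromatic) that every downstream detector consumes.

Conventions
-----------
* Coordinates are Angstrom throughout; poses and receptor share one frame and
  are never superposed unless an operation says so.
* Hydrogens are accepted if present; detectors fall back to heavy-atom-only
  geometry when they are absent.
* SDF dialect: V2000 primary, V3000 accepted on read; formal charges come
  from ``M  CHG`` lines (RDKit handles both).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem

logger = logging.getLogger(__name__)

#: elements recognised in receptor and ligand structures
KNOWN_ELEMENTS = frozenset(
    "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Fe Zn Se Br I".split()
)

HALOGENS = frozenset({"F", "Cl", "Br", "I"})

#: single-bond covalent radii (Angstrom), used only for receptor connectivity
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "Se": 1.20,
}

#: backbone atom names of a polypeptide residue
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "H", "HA", "OXT", "H1", "H2", "H3"})


class StructureError(ValueError):
    """Raised for malformed or inconsistent structural input."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Atom:
    """One atom with coordinates in the shared receptor frame (Angstrom)."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    formal_charge: int = 0
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} ({self.name}): non-finite coordinates")
        if self.element not in KNOWN_ELEMENTS:
            raise StructureError(f"atom {self.serial} ({self.name}): unknown element {self.element!r}")
        self.is_hydrogen = self.element == "H"


@dataclass
class Residue:
    """A receptor residue; (chain, resseq, icode) is its unique key."""

    chain: str
    resseq: int
    icode: str
    resname: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"residue {self.key} has no atoms")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.resseq, self.icode)

    @property
    def label(self) -> str:
        icode = self.icode.strip()
        return f"{self.chain}:{self.resname}{self.resseq}{icode}"

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float)

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class ReceptorStructure:
    """An ordered collection of residues sharing one coordinate frame."""

    residues: list[Residue]
    title: str = ""

    def __post_init__(self) -> None:
        keys = [r.key for r in self.residues]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise StructureError(f"duplicate residue keys: {dupes}")

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, key: tuple[str, int, str]) -> Residue:
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(key)

    def heavy_coords(self) -> np.ndarray:
        return np.vstack([r.heavy_coords() for r in self.residues])


class LigandPose:
    """One docked conformation of one ligand.

    Wraps an RDKit molecule (with a single conformer) so that substructure
    matching, atom typing and file round-trips reuse the standard toolkit,
    while exposing the plain atom/bond views the rest of the package uses.
    """

    def __init__(self, mol: Chem.Mol, ligand_id: str, pose_id: int,
                 properties: dict[str, str] | None = None):
        if mol.GetNumConformers() != 1:
            raise StructureError(f"pose {ligand_id}/{pose_id}: expected exactly one conformer")
        self.mol = mol
        self.ligand_id = str(ligand_id)
        self.pose_id = int(pose_id)
        self.properties: dict[str, str] = dict(properties or {})
        self._check_connected()

    def _check_connected(self) -> None:
        heavy = [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]
        if not heavy:
            raise StructureError(f"pose {self.key}: no heavy atoms")
        frags = Chem.GetMolFrags(self.mol)
        heavy_frags = {tuple(f) for f in frags if any(i in set(f) for i in heavy)}
        if len(heavy_frags) > 1:
            raise StructureError(f"pose {self.key}: heavy-atom graph is disconnected")

    @property
    def key(self) -> tuple[str, int]:
        return (self.ligand_id, self.pose_id)

    @property
    def n_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    def coords(self) -> np.ndarray:
        return np.asarray(self.mol.GetConformer().GetPositions(), dtype=float)

    def heavy_indices(self) -> list[int]:
        return [a.GetIdx() for a in self.mol.GetAtoms() if a.GetAtomicNum() > 1]

    def heavy_coords(self) -> np.ndarray:
        return self.coords()[self.heavy_indices()]

    @property
    def atoms(self) -> list[Atom]:
        xyz = self.coords()
        out = []
        for a in self.mol.GetAtoms():
            out.append(Atom(serial=a.GetIdx(), name=f"{a.GetSymbol()}{a.GetIdx()}",
                            element=a.GetSymbol(), coords=xyz[a.GetIdx()],
                            formal_charge=a.GetFormalCharge()))
        return out

    @property
    def bonds(self) -> list[tuple[int, int, float]]:
        return [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                for b in self.mol.GetBonds()]

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        """Return a rigidly transformed copy (x -> R x + t)."""
        mol = Chem.Mol(self.mol)
        conf = mol.GetConformer()
        xyz = self.coords() @ np.asarray(rotation).T + np.asarray(translation)
        for i in range(mol.GetNumAtoms()):
            conf.SetAtomPosition(i, xyz[i].tolist())
        return LigandPose(mol, self.ligand_id, self.pose_id, dict(self.properties))


@dataclass
class PoseSet:
    """All poses of one docking run; (ligand_id, pose_id) is unique."""

    poses: list[LigandPose]
    by_ligand: dict[str, list[LigandPose]] = field(init=False)

    def __post_init__(self) -> None:
        keys = [p.key for p in self.poses]
        if len(keys) != len(set(keys)):
            raise StructureError("duplicate (ligand_id, pose_id) in pose set")
        self.by_ligand = {}
        for p in self.poses:
            self.by_ligand.setdefault(p.ligand_id, []).append(p)

    def __len__(self) -> int:
        return len(self.poses)

    def __iter__(self):
        return iter(self.poses)

    @property
    def ligand_ids(self) -> list[str]:
        return list(self.by_ligand)


@dataclass
class AtomClassTable:
    """Per-atom interaction classes, a pure function of graph + elements."""

    hbond_donor_heavy: np.ndarray      # bool, heavy N/O bearing >= 1 H
    hbond_acceptor: np.ndarray         # bool
    hydrophobic: np.ndarray            # bool
    halogen: list[str | None]          # element symbol for F/Cl/Br/I, else None
    cationic: np.ndarray               # bool
    aromatic_ring_member: np.ndarray   # bool

    def __post_init__(self) -> None:
        for i, x in enumerate(self.halogen):
            if x is not None and x not in HALOGENS:
                raise StructureError(f"atom {i}: halogen flag with element {x!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_receptor(path: str | Path) -> ReceptorStructure:
    """Read a receptor from PDB.

    Residues keep file order, hydrogens are retained, and alternate locations
    are resolved to the highest-occupancy conformer.
    """
    import gemmi

    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"{path}: PDB parse error: {exc}") from exc

    residues: list[Residue] = []
    serial = 0
    for model in st:
        for chain in model:
            for res in chain:
                atoms: dict[str, Atom] = {}
                occ: dict[str, float] = {}
                for at in res:
                    serial += 1
                    if at.name in atoms and at.occ <= occ[at.name]:
                        continue  # keep highest-occupancy altloc
                    el = at.element.name
                    atoms[at.name] = Atom(serial=serial, name=at.name, element=el,
                                          coords=np.array([at.pos.x, at.pos.y, at.pos.z]))
                    occ[at.name] = at.occ
                if atoms:
                    residues.append(Residue(chain=chain.name, resseq=res.seqid.num,
                                            icode=res.seqid.icode.strip() or "",
                                            resname=res.name, atoms=list(atoms.values())))
        break  # first model only
    if not residues:
        raise StructureError(f"{path}: no atoms")
    return ReceptorStructure(residues=residues, title=st.name or path.stem)


def write_receptor(receptor: ReceptorStructure, path: str | Path) -> None:
    """Write a receptor as a minimal single-chain-per-residue PDB file."""
    lines = []
    serial = 0
    for res in receptor.residues:
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} {res.resname:>3s} {res.chain:1s}"
                f"{res.resseq:4d}{res.icode or ' ':1s}   "
                f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


LIGAND_ID_PROP = "ligand_id"
POSE_ID_PROP = "pose_id"


def read_poses(path: str | Path, ligand_prop: str = LIGAND_ID_PROP) -> PoseSet:
    """Read an SDF pose file; one :class:`LigandPose` per record.

    The ligand identity comes from the SDF property ``ligand_prop`` and falls
    back to the molecule title (with a logged warning). Pose ids are taken
    from the ``pose_id`` property when present, else assigned sequentially
    within each ligand.
    """
    path = Path(path)
    if not path.exists():
        raise StructureError(f"{path}: no such file")
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise StructureError(f"{path}: {exc}") from exc
    poses: list[LigandPose] = []
    counters: dict[str, int] = {}
    for irec, mol in enumerate(supplier):
        if mol is None:
            raise StructureError(f"{path}: record {irec + 1} failed to parse")
        props = mol.GetPropsAsDict(includePrivate=False)
        if ligand_prop in props:
            lig = str(props[ligand_prop])
        else:
            lig = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            logger.warning("%s: record %d lacks %r property; falling back to title %r",
                           path, irec + 1, ligand_prop, lig)
        if not lig:
            raise StructureError(f"{path}: record {irec + 1} has no ligand id and no title")
        if POSE_ID_PROP in props:
            pid = int(props[POSE_ID_PROP])
        else:
            pid = counters.get(lig, 0)
        counters[lig] = pid + 1
        poses.append(LigandPose(mol, lig, pid,
                                {k: str(v) for k, v in props.items()}))
    if not poses:
        raise StructureError(f"{path}: no records")
    return PoseSet(poses)


def write_poses(ps: PoseSet, path: str | Path,
                extra_props: dict[tuple[str, int], dict[str, str]] | None = None) -> None:
    """Write poses to SDF (V2000), carrying ligand/pose ids and any extra
    per-pose properties such as ``cluster_id`` / ``csc_label``."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for p in ps.poses:
            mol = Chem.Mol(p.mol)
            mol.SetProp("_Name", f"{p.ligand_id}_{p.pose_id}")
            for k, v in p.properties.items():
                mol.SetProp(k, str(v))
            mol.SetProp(LIGAND_ID_PROP, p.ligand_id)
            mol.SetProp(POSE_ID_PROP, str(p.pose_id))
            if extra_props and p.key in extra_props:
                for k, v in extra_props[p.key].items():
                    mol.SetProp(k, str(v))
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# atom typing
# ---------------------------------------------------------------------------

def _residue_connectivity(res: Residue) -> list[set[int]]:
    """Distance-based connectivity for receptor residues (no bonds in PDB)."""
    xyz = res.coords()
    n = len(res.atoms)
    neigh: list[set[int]] = [set() for _ in range(n)]
    if n == 1:
        return neigh
    d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
    for i in range(n):
        ri = COVALENT_RADII.get(res.atoms[i].element, 0.77)
        for j in range(i + 1, n):
            rj = COVALENT_RADII.get(res.atoms[j].element, 0.77)
            if d[i, j] <= ri + rj + 0.40:
                neigh[i].add(j)
                neigh[j].add(i)
    return neigh


def assign_atom_classes(obj: LigandPose | Residue) -> AtomClassTable:
    """Assign interaction classes to every atom of a pose or residue.

    Rules (deterministic, force-field free):

    * donor heavy atom: N or O bearing at least one hydrogen;
    * acceptor: N or O with an available lone pair -- quaternary/positively
      charged N and amide N (donor-only) are excluded;
    * hydrophobic: C or S with no attached N/O/F and no formal charge, plus
      all halogens (halogens play the dual hydrophobic/X-bond donor role);
    * cationic: N with formal charge +1, or a primary amine N (assumed
      protonated at physiological pH);
    * aromatic ring member: perceived aromatic atoms (ligands) or atoms of
      template aromatic rings (residues).
    """
    if isinstance(obj, LigandPose):
        return _ligand_classes(obj)
    return _residue_classes(obj)


def _ligand_classes(pose: LigandPose) -> AtomClassTable:
    mol = pose.mol
    n = mol.GetNumAtoms()
    donor = np.zeros(n, bool)
    acceptor = np.zeros(n, bool)
    hydrophobic = np.zeros(n, bool)
    halogen: list[str | None] = [None] * n
    cationic = np.zeros(n, bool)
    aromatic = np.zeros(n, bool)

    for a in mol.GetAtoms():
        i = a.GetIdx()
        el = a.GetSymbol()
        if el not in KNOWN_ELEMENTS:
            raise StructureError(f"atom {i}: unknown element {el!r}")
        nh = a.GetTotalNumHs(includeNeighbors=True)
        heavy_neigh = [b for b in a.GetNeighbors() if b.GetAtomicNum() > 1]
        if a.GetIsAromatic():
            aromatic[i] = True
        if el in ("N", "O"):
            if nh >= 1:
                donor[i] = True
            if el == "O":
                acceptor[i] = True
            else:
                quaternary = a.GetFormalCharge() > 0 or a.GetTotalDegree() >= 4
                amide = any(
                    b.GetSymbol() == "C" and any(
                        c.GetSymbol() == "O" and
                        mol.GetBondBetweenAtoms(b.GetIdx(), c.GetIdx()).GetBondTypeAsDouble() == 2.0
                        for c in b.GetNeighbors())
                    for b in heavy_neigh)
                if not quaternary and not amide:
                    acceptor[i] = True
            if a.GetFormalCharge() == 1 and el == "N":
                cationic[i] = True
            elif el == "N" and not a.GetIsAromatic() and nh >= 2 and \
                    len(heavy_neigh) == 1 and heavy_neigh[0].GetSymbol() == "C" and \
                    not heavy_neigh[0].GetIsAromatic():
                cationic[i] = True  # primary aliphatic amine, assumed protonated
        elif el in HALOGENS:
            halogen[i] = el
            hydrophobic[i] = True
        elif el in ("C", "S"):
            polar_attached = any(b.GetSymbol() in ("N", "O", "F") or b.GetFormalCharge() != 0
                                 for b in heavy_neigh)
            if not polar_attached and a.GetFormalCharge() == 0:
                hydrophobic[i] = True
    return AtomClassTable(donor, acceptor, hydrophobic, halogen, cationic, aromatic)


#: side-chain aromatic ring atom names of template residues
AROMATIC_RING_NAMES = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}


def _residue_classes(res: Residue) -> AtomClassTable:
    n = len(res.atoms)
    donor = np.zeros(n, bool)
    acceptor = np.zeros(n, bool)
    hydrophobic = np.zeros(n, bool)
    halogen: list[str | None] = [None] * n
    cationic = np.zeros(n, bool)
    aromatic = np.zeros(n, bool)
    neigh = _residue_connectivity(res)
    ring_names = AROMATIC_RING_NAMES.get(res.resname, ())

    for i, a in enumerate(res.atoms):
        el = a.element
        if el not in KNOWN_ELEMENTS:
            raise StructureError(f"atom {a.serial} ({a.name}): unknown element {el!r}")
        if a.name in ring_names:
            aromatic[i] = True
        if el in ("N", "O"):
            has_h = any(res.atoms[j].is_hydrogen for j in neigh[i])
            if has_h:
                donor[i] = True
            if el == "O":
                acceptor[i] = True
            else:
                # amide N (bonded to a carbonyl C) is donor-only
                amide = any(
                    res.atoms[j].element == "C" and any(
                        res.atoms[k].element == "O" and
                        np.linalg.norm(res.atoms[k].coords - res.atoms[j].coords) < 1.30
                        for k in neigh[j])
                    for j in neigh[i])
                n_h = sum(1 for j in neigh[i] if res.atoms[j].is_hydrogen)
                if n_h >= 3:
                    cationic[i] = True
                elif not amide:
                    acceptor[i] = True
        elif el in HALOGENS:
            halogen[i] = el
            hydrophobic[i] = True
        elif el in ("C", "S"):
            polar_attached = any(res.atoms[j].element in ("N", "O", "F") for j in neigh[i])
            if not polar_attached:
                hydrophobic[i] = True
    return AtomClassTable(donor, acceptor, hydrophobic, halogen, cationic, aromatic)
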