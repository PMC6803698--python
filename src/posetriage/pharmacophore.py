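"""Structure-based pharmacophore derivation from an annotated pose.

The feature taxonomy follows the transporter-ligand convention: hydrogen bond
donors (HBD) and acceptors (HBA) as vectors from the ligand atom toward the
residue partner, hydrophobic spheres (H) on contiguous clusters of contacting
apolar atoms, a positive ionizable group (PI) for a cationic centre engaged
in a cation-pi interaction, and a halogen bond donor vector (XBD) along the
C-X axis of a passing halogen bond. Receptor heavy atoms near the ligand
become excluded volumes.

Every feature traces back to the interaction record(s) that induced it, so
the model is a deterministic function of the interaction annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .structio import (AtomClassTable, LigandPose, ReceptorStructure, Residue,
                       assign_atom_classes, AROMATIC_RING_NAMES)
from .sift import InteractionRecord, angle_deg
from .halogen import HalogenContact

FeatureKind = Literal["HBD", "HBA", "H", "PI", "XBD"]

H_SPHERE_RADIUS = 1.5        # A
VECTOR_TOLERANCE_RADIUS = 1.0  # A
H_CLUSTER_MERGE = 2.0        # A; non-bonded apolar atoms this close co-cluster
CATION_PI_DISTANCE = 6.0     # A, cation to ring centroid
PI_PI_DISTANCE = 5.5         # A, centroid to centroid
PI_PI_EDGE_FACE_ANGLE = 60.0  # deg, interplanar angle for edge-to-face
EXCLUDED_VOLUME_SHELL = 5.0  # A
EXCLUDED_VOLUME_RADIUS = 1.5  # A


@dataclass
class Feature:
    kind: FeatureKind
    position: np.ndarray
    direction: np.ndarray | None = None
    radius: float = VECTOR_TOLERANCE_RADIUS
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, float)
        vector_kind = self.kind in ("HBD", "HBA", "XBD")
        if vector_kind:
            if self.direction is None:
                raise ValueError(f"{self.kind} feature requires a direction")
            d = np.asarray(self.direction, float)
            self.direction = d / np.linalg.norm(d)
        elif self.direction is not None:
            raise ValueError(f"{self.kind} feature must not carry a direction")
        if not self.provenance:
            raise ValueError("every feature must trace to >= 1 interaction")


@dataclass
class PharmacophoreModel:
    features: list[Feature]
    excluded_volumes: list[tuple[np.ndarray, float]] = field(default_factory=list)


@dataclass
class RingInteraction:
    """A cation-pi or pi-pi annotation (not a SIFt bit)."""

    kind: Literal["cation_pi", "pi_pi"]
    ligand_atoms: tuple[int, ...]
    residue_key: tuple[str, int, str]
    distance: float
    interplanar_angle: float | None = None


def _residue_rings(res: Residue) -> list[np.ndarray]:
    names = AROMATIC_RING_NAMES.get(res.resname)
    if not names:
        return []
    coords = [a.coords for a in res.atoms if a.name in names]
    if len(coords) < 5:
        return []
    return [np.array(coords)]


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    return vt[2]


def detect_ring_interactions(pose: LigandPose, r: ReceptorStructure,
                             classes: AtomClassTable | None = None,
                             ) -> list[RingInteraction]:
    """Cation-pi and pi-pi contacts between a pose and receptor aromatics.

    Cation-pi: cationic ligand atom within 6.0 A of an aromatic residue ring
    centroid. pi-pi (edge-to-face): ligand/residue ring centroids within
    5.5 A with interplanar angle >= 60 deg.
    """
    classes = classes or assign_atom_classes(pose)
    xyz = pose.coords()
    out: list[RingInteraction] = []

    lig_rings = []
    for ring in pose.mol.GetRingInfo().AtomRings():
        if all(pose.mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            lig_rings.append(tuple(ring))

    for res in r.residues:
        for ring_coords in _residue_rings(res):
            centroid = ring_coords.mean(axis=0)
            normal = _ring_normal(ring_coords)
            for i in np.where(classes.cationic)[0]:
                d = float(np.linalg.norm(xyz[i] - centroid))
                if d <= CATION_PI_DISTANCE:
                    out.append(RingInteraction("cation_pi", (int(i),), res.key, round(d, 3)))
            for ring in lig_rings:
                lc = xyz[list(ring)].mean(axis=0)
                d = float(np.linalg.norm(lc - centroid))
                if d > PI_PI_DISTANCE:
                    continue
                ln = _ring_normal(xyz[list(ring)])
                cosang = abs(float(np.dot(ln, normal)))
                ang = float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))
                if ang >= PI_PI_EDGE_FACE_ANGLE:
                    out.append(RingInteraction("pi_pi", ring, res.key, round(d, 3),
                                               round(ang, 2)))
    return out


def _hydrophobic_clusters(pose: LigandPose, atom_indices: Sequence[int]) -> list[list[int]]:
    """Group contacting apolar atoms: bonded pairs or pairs within 2.0 A
    merge into one cluster (union-find over the contact-atom subgraph)."""
    atoms = sorted(set(atom_indices))
    if not atoms:
        return []
    parent = {i: i for i in atoms}

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    xyz = pose.coords()
    aset = set(atoms)
    for b in pose.mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in aset and j in aset:
            union(i, j)
    for ii, i in enumerate(atoms):
        for j in atoms[ii + 1:]:
            if np.linalg.norm(xyz[i] - xyz[j]) <= H_CLUSTER_MERGE:
                union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in atoms:
        clusters.setdefault(find(i), []).append(i)
    return [sorted(c) for c in sorted(clusters.values(), key=lambda c: c[0])]


def derive_features(pose: LigandPose,
                    hbonds: Iterable[InteractionRecord],
                    hydrophobics: Iterable[InteractionRecord],
                    halogen_contacts: Iterable[HalogenContact],
                    ring_interactions: Iterable[RingInteraction] = (),
                    classes: AtomClassTable | None = None) -> PharmacophoreModel:
    """Derive the pharmacophore feature set from detected interactions.

    Mapping: ligand-donated H-bond -> HBD vector (donor heavy atom toward the
    residue acceptor); ligand-accepted -> HBA vector; contacting apolar atoms
    grouped into contiguous clusters -> one H sphere per cluster centroid;
    cationic atom engaged in a cation-pi contact -> PI; passing halogen bond
    -> XBD vector along C-X. An empty interaction set yields an empty model.
    """
    classes = classes or assign_atom_classes(pose)
    xyz = pose.coords()
    features: list[Feature] = []

    # one directional feature per hydrogen bond: the amino group donating to
    # three different backbone carbonyls yields three HBD vectors
    seen_vec: set[tuple[str, int, tuple, str]] = set()
    for rec in sorted((r for r in hbonds
                       if r.kind in ("hbond_ligand_donates", "hbond_ligand_accepts")),
                      key=lambda r: (r.kind, r.ligand_atom, r.residue_key, r.residue_atom)):
        dedup = (rec.kind, rec.ligand_atom, rec.residue_key, rec.residue_atom_name)
        if dedup in seen_vec:
            continue
        seen_vec.add(dedup)
        fk = "HBD" if rec.kind == "hbond_ligand_donates" else "HBA"
        features.append(Feature(fk, xyz[rec.ligand_atom],
                                _partner_direction(rec, pose), provenance=[rec]))

    hyd_atoms = [rec.ligand_atom for rec in hydrophobics if rec.kind == "hydrophobic"]
    hyd_by_atom: dict[int, list[InteractionRecord]] = {}
    for rec in hydrophobics:
        if rec.kind == "hydrophobic":
            hyd_by_atom.setdefault(rec.ligand_atom, []).append(rec)
    for cluster in _hydrophobic_clusters(pose, hyd_atoms):
        prov = [r for a in cluster for r in hyd_by_atom[a]]
        features.append(Feature("H", xyz[cluster].mean(axis=0), None,
                                radius=H_SPHERE_RADIUS, provenance=prov))

    for ri in ring_interactions:
        if ri.kind == "cation_pi":
            i = ri.ligand_atoms[0]
            if classes.cationic[i]:
                if not any(f.kind == "PI" and np.allclose(f.position, xyz[i])
                           for f in features):
                    features.append(Feature("PI", xyz[i], None,
                                            radius=VECTOR_TOLERANCE_RADIUS,
                                            provenance=[ri]))

    for c in halogen_contacts:
        if c.classification != "xbond":
            continue
        direction = xyz[c.x_atom] - xyz[c.carbon_atom]
        features.append(Feature("XBD", xyz[c.x_atom], direction, provenance=[c]))

    return PharmacophoreModel(features=features)


def _partner_direction(rec: InteractionRecord, pose: LigandPose) -> np.ndarray:
    """Direction from the ligand atom toward the residue partner; falls back
    to the outward direction from the molecular centroid when the partner
    coordinate is not resolvable from the record alone."""
    if getattr(rec, "partner_coords", None) is not None:
        return np.asarray(rec.partner_coords, float) - pose.coords()[rec.ligand_atom]
    return pose.coords()[rec.ligand_atom] - pose.heavy_coords().mean(axis=0)


def excluded_volumes(pose: LigandPose, r: ReceptorStructure,
                     shell: float = EXCLUDED_VOLUME_SHELL,
                     radius: float = EXCLUDED_VOLUME_RADIUS,
                     ) -> list[tuple[np.ndarray, float]]:
    """One sphere per receptor heavy atom within ``shell`` of any ligand
    heavy atom."""
    lig = pose.heavy_coords()
    spheres = []
    for res in r.residues:
        for a in res.heavy_atoms():
            if float(cdist(lig, a.coords[None, :]).min()) <= shell:
                spheres.append((a.coords.copy(), radius))
    return spheres


def count_by_kind(model: PharmacophoreModel) -> dict[str, int]:
    counts = {k: 0 for k in ("HBD", "HBA", "H", "PI", "XBD")}
    for f in model.features:
        counts[f.kind] += 1
    return counts


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def model_to_dict(model: PharmacophoreModel) -> dict:
    return {
        "features": [
            {"kind": f.kind, "position": [round(float(v), 4) for v in f.position],
             "direction": None if f.direction is None
             else [round(float(v), 4) for v in f.direction],
             "radius": f.radius, "n_interactions": len(f.provenance)}
            for f in model.features],
        "excluded_volumes": [
            {"center": [round(float(v), 4) for v in c], "radius": rad}
            for c, rad in model.excluded_volumes],
        "counts": count_by_kind(model),
    }


def write_model(model: PharmacophoreModel, json_path: str | Path,
                csv_path: str | Path | None = None) -> None:
    d = model_to_dict(model)
    Path(json_path).write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    if csv_path is not None:
        rows = [{"kind": f["kind"], "x": f["position"][0], "y": f["position"][1],
                 "z": f["position"][2], "radius": f["radius"]} for f in d["features"]]
        rows += [{"kind": "EV", "x": v["center"][0], "y": v["center"][1],
                  "z": v["center"][2], "radius": v["radius"]}
                 for v in d["excluded_volumes"]]
        pd.DataFrame(rows, columns=["kind", "x", "y", "z", "radius"]).to_csv(csv_path, index=False)
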