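"""Structural interaction fingerprints (SIFt) and occupancy profiles.

For every pose, typed ligand-residue contacts are detected inside a 5 A
heavy-atom neighbourhood and folded into a per-pose bit vector over
(residue, interaction-kind) columns; occupancy profiles then report, for a
named pose subset (e.g. CSC vs residual), the percentage of poses carrying
each bit.

Geometric criteria (conventional crystallographic choices; all cutoffs
inclusive):

* hydrogen bond: D...A <= 3.5 A and, when the donor hydrogen is explicit,
  D-H...A >= 120 deg; with no hydrogens, every heavy neighbour R of the donor
  must satisfy R-D...A >= 90 deg (excludes buried head-on contacts);
* hydrophobic: apolar heavy-atom pair <= 4.5 A, one bit per residue.

pi-pi and cation-pi contacts are handled by the pharmacophore module and are
deliberately not SIFt bits: the fingerprint counts hydrogen-bond and
hydrophobic interactions only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .structio import (AtomClassTable, LigandPose, ReceptorStructure, Residue,
                       StructureError, assign_atom_classes, BACKBONE_NAMES)

Kind = Literal["hbond_ligand_donates", "hbond_ligand_accepts", "hydrophobic", "proximal"]

HBOND_DISTANCE = 3.5       # A, D...A
HBOND_ANGLE = 120.0        # deg, D-H...A, explicit-H criterion
HBOND_HEAVY_ANGLE = 90.0   # deg, R-D...A, heavy-atom fallback
HYDROPHOBIC_DISTANCE = 4.5  # A
PROXIMAL_CUTOFF = 5.0      # A, binding-site universe


@dataclass
class HBondParams:
    distance: float = HBOND_DISTANCE
    angle: float = HBOND_ANGLE
    heavy_angle: float = HBOND_HEAVY_ANGLE


@dataclass
class InteractionRecord:
    """One typed ligand-residue contact with its defining geometry."""

    pose_key: tuple[str, int]
    residue_key: tuple[str, int, str]
    residue_label: str
    kind: Kind
    distance: float
    angle: float | None = None
    ligand_atom: int = -1
    residue_atom: int = -1          # index into residue.atoms
    residue_atom_name: str = ""
    backbone: bool | None = None    # residue partner on backbone vs side chain
    partner_coords: np.ndarray | None = None


def angle_deg(a: np.ndarray, vertex: np.ndarray, c: np.ndarray) -> float:
    """Angle a-vertex-c in degrees."""
    u = np.asarray(a, float) - np.asarray(vertex, float)
    v = np.asarray(c, float) - np.asarray(vertex, float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("degenerate angle: coincident points")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def proximal_residues(pose: LigandPose, r: ReceptorStructure,
                      cutoff: float = PROXIMAL_CUTOFF) -> list[tuple[str, int, str]]:
    """Residues with >= 1 heavy atom within ``cutoff`` (inclusive) of >= 1
    ligand heavy atom, in receptor order."""
    if len(r.residues) == 0:
        raise StructureError("empty receptor")
    lig = pose.heavy_coords()
    out = []
    for res in r.residues:
        d = cdist(lig, res.heavy_coords())
        if float(d.min()) <= cutoff:
            out.append(res.key)
    return out


def _typed_residues(r: ReceptorStructure):
    """Atom classes and connectivity per residue, cached on the receptor."""
    from .structio import _residue_connectivity

    cache = getattr(r, "_typing_cache", None)
    if cache is None:
        cache = [(res, assign_atom_classes(res), _residue_connectivity(res),
                  res.coords()) for res in r.residues]
        r._typing_cache = cache  # type: ignore[attr-defined]
    return cache


def _attached_hydrogens(pose: LigandPose, idx: int) -> list[int]:
    return [b.GetIdx() for b in pose.mol.GetAtomWithIdx(idx).GetNeighbors()
            if b.GetAtomicNum() == 1]


def _heavy_neighbors(pose: LigandPose, idx: int) -> list[int]:
    return [b.GetIdx() for b in pose.mol.GetAtomWithIdx(idx).GetNeighbors()
            if b.GetAtomicNum() > 1]


def _res_attached(res: Residue, neigh: list[set[int]], i: int,
                  hydrogens: bool) -> list[int]:
    want = (lambda a: a.is_hydrogen) if hydrogens else (lambda a: not a.is_hydrogen)
    return [j for j in neigh[i] if want(res.atoms[j])]


def _hbond_geometry_ok(d_coord: np.ndarray, a_coord: np.ndarray,
                       h_coords: list[np.ndarray], heavy_coords: list[np.ndarray],
                       params: HBondParams) -> tuple[bool, float | None]:
    """Apply the angular criterion; returns (ok, best D-H...A angle or None)."""
    if h_coords:
        best = -1.0
        for h in h_coords:
            ang = angle_deg(d_coord, h, a_coord)  # D-H...A angle at H
            best = max(best, ang)
        return best >= params.angle, best
    for rcoord in heavy_coords:
        if angle_deg(rcoord, d_coord, a_coord) < params.heavy_angle:
            return False, None
    return True, None


def detect_hbonds(pose: LigandPose, r: ReceptorStructure,
                  params: HBondParams | None = None,
                  classes: AtomClassTable | None = None,
                  universe: Sequence[tuple[str, int, str]] | None = None,
                  ) -> list[InteractionRecord]:
    """Detect ligand-residue hydrogen bonds in both directions.

    Direction is recorded from the ligand's point of view
    (``hbond_ligand_donates`` vs ``hbond_ligand_accepts``), along with whether
    the residue partner is a backbone or side-chain atom.
    """
    params = params or HBondParams()
    lc = classes or assign_atom_classes(pose)
    if universe is None:
        universe = proximal_residues(pose, r)
    universe_set = set(universe)
    lig_xyz = pose.coords()
    lig_polar = [i for i in range(pose.n_atoms)
                 if lc.hbond_donor_heavy[i] or lc.hbond_acceptor[i]]
    records: list[InteractionRecord] = []

    for res, rc, neigh, rxyz in _typed_residues(r):
        if res.key not in universe_set:
            continue
        for i in lig_polar:
            for rj, ratom in enumerate(res.atoms):
                if ratom.is_hydrogen or not (rc.hbond_acceptor[rj] or rc.hbond_donor_heavy[rj]):
                    continue
                d = float(np.linalg.norm(lig_xyz[i] - rxyz[rj]))
                if d > params.distance:
                    continue
                # ligand donates
                if lc.hbond_donor_heavy[i] and rc.hbond_acceptor[rj]:
                    h = [lig_xyz[k] for k in _attached_hydrogens(pose, i)]
                    heavies = [lig_xyz[k] for k in _heavy_neighbors(pose, i)]
                    ok, ang = _hbond_geometry_ok(lig_xyz[i], rxyz[rj], h, heavies, params)
                    if ok:
                        records.append(InteractionRecord(
                            pose.key, res.key, res.label, "hbond_ligand_donates",
                            round(d, 6), None if ang is None else round(ang, 3),
                            i, rj, ratom.name, ratom.name in BACKBONE_NAMES,
                            rxyz[rj].copy()))
                # ligand accepts
                if lc.hbond_acceptor[i] and rc.hbond_donor_heavy[rj]:
                    h = [rxyz[k] for k in _res_attached(res, neigh, rj, hydrogens=True)]
                    heavies = [rxyz[k] for k in _res_attached(res, neigh, rj, hydrogens=False)]
                    ok, ang = _hbond_geometry_ok(rxyz[rj], lig_xyz[i], h, heavies, params)
                    if ok:
                        records.append(InteractionRecord(
                            pose.key, res.key, res.label, "hbond_ligand_accepts",
                            round(d, 6), None if ang is None else round(ang, 3),
                            i, rj, ratom.name, ratom.name in BACKBONE_NAMES,
                            rxyz[rj].copy()))
    return records


def detect_hydrophobic(pose: LigandPose, r: ReceptorStructure,
                       cutoff: float = HYDROPHOBIC_DISTANCE,
                       classes: AtomClassTable | None = None,
                       universe: Sequence[tuple[str, int, str]] | None = None,
                       ) -> list[InteractionRecord]:
    """One record per apolar (ligand atom, residue atom) pair within
    ``cutoff``; the fingerprint later aggregates them to one bit per residue."""
    lc = classes or assign_atom_classes(pose)
    if universe is None:
        universe = proximal_residues(pose, r)
    universe_set = set(universe)
    lig_xyz = pose.coords()
    lig_idx = np.where(lc.hydrophobic)[0]
    records: list[InteractionRecord] = []
    for res, rc, neigh, rxyz in _typed_residues(r):
        if res.key not in universe_set:
            continue
        res_idx = np.where(rc.hydrophobic)[0]
        if len(lig_idx) == 0 or len(res_idx) == 0:
            continue
        d = cdist(lig_xyz[lig_idx], rxyz[res_idx])
        ii, jj = np.where(d <= cutoff)
        for a, b in zip(ii, jj):
            rj = int(res_idx[b])
            records.append(InteractionRecord(
                pose.key, res.key, res.label, "hydrophobic",
                round(float(d[a, b]), 6), None,
                int(lig_idx[a]), rj, res.atoms[rj].name,
                res.atoms[rj].name in BACKBONE_NAMES, rxyz[rj].copy()))
    return records


@dataclass
class SiftMatrix:
    """Dense 0/1 interaction matrix: rows poses, columns (residue, kind)."""

    pose_keys: list[tuple[str, int]]
    columns: list[tuple[tuple[str, int, str], str]]  # (residue key, kind)
    bits: np.ndarray

    def column_index(self) -> dict[tuple[tuple[str, int, str], str], int]:
        return {c: i for i, c in enumerate(self.columns)}


SIFT_KINDS = ("hbond_ligand_donates", "hbond_ligand_accepts", "hydrophobic")


def build_sift(records: Iterable[InteractionRecord],
               pose_keys: Sequence[tuple[str, int]],
               universe: Sequence[tuple[str, int, str]]) -> SiftMatrix:
    """Fold contact records into the 0/1 fingerprint matrix.

    The column universe is (residue x kind) over the shared proximal-residue
    universe, ordered by (chain, resseq, icode, kind) so every pose of one
    analysis shares identical columns.
    """
    uni = sorted(set(universe))
    columns = [(rk, kind) for rk in uni for kind in SIFT_KINDS]
    cindex = {c: i for i, c in enumerate(columns)}
    pindex = {k: i for i, k in enumerate(pose_keys)}
    bits = np.zeros((len(pose_keys), len(columns)), dtype=np.uint8)
    for rec in records:
        if rec.kind == "proximal":
            continue
        col = (rec.residue_key, rec.kind)
        if col not in cindex:
            raise StructureError(f"record references residue outside universe: {rec.residue_key}")
        if rec.pose_key not in pindex:
            raise StructureError(f"record references unknown pose {rec.pose_key}")
        bits[pindex[rec.pose_key], cindex[col]] = 1
    return SiftMatrix(list(pose_keys), columns, bits)


@dataclass
class OccupancyProfile:
    """Percentage of poses in a named subset carrying each interaction bit."""

    subset_name: str
    n_poses: int
    percent: dict[tuple[tuple[str, int, str], str], float]


def occupancy_profile(m: SiftMatrix, subset: Sequence[tuple[str, int]],
                      name: str = "subset") -> OccupancyProfile:
    """Occupancy = 100 x (poses with bit) / |subset|, to 1 decimal."""
    subset = list(subset)
    if not subset:
        raise StructureError("empty pose subset")
    pindex = {k: i for i, k in enumerate(m.pose_keys)}
    rows = [pindex[k] for k in subset]
    frac = m.bits[rows].mean(axis=0)
    percent = {c: round(100.0 * float(f), 1) for c, f in zip(m.columns, frac)}
    return OccupancyProfile(name, len(subset), percent)
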