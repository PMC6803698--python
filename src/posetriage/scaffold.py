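"""Common-scaffold clustering of docking poses.

Poses of ligands sharing a core scaffold are clustered by the in-place RMSD of
the scaffold heavy atoms (no superposition: docking poses share the receptor
frame, and the question is positional, not conformational, similarity).
Complete-linkage agglomeration cut at a height (default 2.0 A) yields pose
clusters; clusters containing at least ``min_ligands`` of the docked ligands
(default 6 of 8) are labelled common scaffold clusters (CSCs), the rest are
residual.

The RMSD is minimised over the scaffold's graph automorphisms (e.g. the
two-fold flip of a phenyl ring) so that chemically equivalent numberings do
not inflate distances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from rdkit import Chem
from scipy.spatial.distance import cdist

from .structio import LigandPose, PoseSet, StructureError


class ScaffoldError(ValueError):
    """Raised when a pose does not embed the scaffold or inputs disagree."""


#: 2-amino-3-phenylpropanoic acid core (12 heavy atoms), tolerant of
#: protonation state (neutral amine or ammonium; acid or carboxylate) and of
#: alpha substitution (alpha-methyl analogues still match).
PHENYLALANINE_SMARTS = (
    "[NX3,NX4][CX4]([CX3](~[OX1,OX2])~[OX1,OX2])[CH2]c1ccccc1"
)


@dataclass
class ScaffoldDefinition:
    """The shared substructure, as a SMARTS pattern with >= 3 heavy atoms."""

    smarts: str = PHENYLALANINE_SMARTS
    name: str = "2-amino-3-phenylpropanoic acid"

    def __post_init__(self) -> None:
        self.query = Chem.MolFromSmarts(self.smarts)
        if self.query is None:
            raise ScaffoldError(f"invalid scaffold SMARTS: {self.smarts!r}")
        if self.query.GetNumAtoms() < 3:
            raise ScaffoldError("scaffold must have >= 3 heavy atoms for a well-defined RMSD")

    @property
    def n_atoms(self) -> int:
        return self.query.GetNumAtoms()


@dataclass
class ScaffoldMatch:
    """Ordered correspondence scaffold index -> pose atom index, plus all
    alternative correspondences induced by scaffold symmetry."""

    ligand_id: str
    correspondence: tuple[int, ...]
    automorphisms: list[tuple[int, ...]]

    def __post_init__(self) -> None:
        if len(set(self.correspondence)) != len(self.correspondence):
            raise ScaffoldError("scaffold correspondence is not injective")
        if self.correspondence not in self.automorphisms:
            self.automorphisms = [self.correspondence] + list(self.automorphisms)


def match_scaffold(pose: LigandPose, s: ScaffoldDefinition) -> ScaffoldMatch:
    """Embed the scaffold in a ligand pose.

    Returns the canonical correspondence (RDKit's first match) together with
    every symmetry-equivalent correspondence on the same atom set. All mapped
    atoms are heavy by construction of the pattern.
    """
    matches = pose.mol.GetSubstructMatches(s.query, uniquify=False, maxMatches=10000)
    if not matches:
        raise ScaffoldError(f"scaffold not found in ligand {pose.ligand_id!r}")
    for m in matches:
        if any(pose.mol.GetAtomWithIdx(i).GetAtomicNum() == 1 for i in m):
            raise ScaffoldError(f"scaffold match in {pose.ligand_id!r} touches a hydrogen")
    canon = matches[0]
    atom_set = frozenset(canon)
    autos = [m for m in matches if frozenset(m) == atom_set]
    return ScaffoldMatch(pose.ligand_id, canon, autos)


def _rmsd(a: np.ndarray, b: np.ndarray) -> float:
    d = a - b
    return float(np.sqrt(np.mean(np.sum(d * d, axis=1))))


def scaffold_rmsd(a: LigandPose, b: LigandPose,
                  ma: ScaffoldMatch, mb: ScaffoldMatch) -> float:
    """In-place RMSD (A) over scaffold heavy atoms, minimised over the
    scaffold automorphism pairings; symmetric in (a, b)."""
    if len(ma.correspondence) != len(mb.correspondence):
        raise ScaffoldError("mismatched scaffold sizes")
    xa = a.coords()[list(ma.correspondence)]
    xb_all = b.coords()
    best = np.inf
    for g in mb.automorphisms:
        best = min(best, _rmsd(xa, xb_all[list(g)]))
    return best


@dataclass
class RmsdMatrix:
    """Symmetric scaffold-RMSD matrix over a pose list."""

    pose_keys: list[tuple[str, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        n = len(self.pose_keys)
        if v.shape != (n, n):
            raise ScaffoldError(f"matrix shape {v.shape} does not match {n} poses")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ScaffoldError("RMSD matrix is not symmetric")
        if np.any(v < -1e-12) or np.any(np.abs(np.diag(v)) > 1e-9):
            raise ScaffoldError("RMSD matrix has negative entries or non-zero diagonal")
        self.values = v


def pairwise_matrix(ps: PoseSet, s: ScaffoldDefinition) -> RmsdMatrix:
    """Full symmetric scaffold-RMSD matrix over all poses of all ligands.

    All poses are clustered jointly; a pose that does not embed the scaffold
    is an error naming the pose.
    """
    matches: list[ScaffoldMatch] = []
    for p in ps.poses:
        try:
            matches.append(match_scaffold(p, s))
        except ScaffoldError as exc:
            raise ScaffoldError(f"pose {p.key}: {exc}") from exc

    n = len(ps.poses)
    k = s.n_atoms
    # flatten canonical scaffold coordinates once; automorphism-minimise by
    # stacking each alternative ordering of the second pose
    canon = np.empty((n, 3 * k))
    for i, (p, m) in enumerate(zip(ps.poses, matches)):
        canon[i] = p.coords()[list(m.correspondence)].ravel()

    # group automorphisms by their permutation relative to the canonical
    # correspondence: the relative pairing is what matters for each pose pair
    perms: set[tuple[int, ...]] = set()
    alt_coords: dict[tuple[int, ...], np.ndarray] = {}
    for i, (p, m) in enumerate(zip(ps.poses, matches)):
        base = {atom: s_i for s_i, atom in enumerate(m.correspondence)}
        for g in m.automorphisms:
            perm = tuple(base[atom] for atom in g)  # scaffold index permutation
            perms.add(perm)
    for perm in perms:
        x = np.empty((n, 3 * k))
        for i, (p, m) in enumerate(zip(ps.poses, matches)):
            base = {atom: s_i for s_i, atom in enumerate(m.correspondence)}
            applicable = None
            for g in m.automorphisms:
                if tuple(base[atom] for atom in g) == perm:
                    applicable = g
                    break
            if applicable is None:
                applicable = m.correspondence  # perm not realised for this pose
            x[i] = p.coords()[list(applicable)].ravel()
        alt_coords[perm] = x

    best = None
    for perm, x in alt_coords.items():
        d = cdist(canon, x)
        best = d if best is None else np.minimum(best, d)
    rmsd = best / np.sqrt(k)
    rmsd = np.minimum(rmsd, rmsd.T)
    np.fill_diagonal(rmsd, 0.0)
    return RmsdMatrix([p.key for p in ps.poses], rmsd)


@dataclass
class ClusterPartition:
    """Complete-linkage clusters of poses with CSC/residual labels."""

    clusters: list[list[tuple[str, int]]]
    labels: dict[int, str] = field(default_factory=dict)  # cluster idx -> CSC | residual
    height: float = 2.0
    min_ligands: int = 6
    n_ligands: int = 8

    def n_poses(self) -> int:
        return sum(len(c) for c in self.clusters)

    def pose_counts(self) -> dict[str, int]:
        counts = {"CSC": 0, "residual": 0}
        for i, c in enumerate(self.clusters):
            counts[self.labels.get(i, "residual")] += len(c)
        return counts

    def cluster_of(self) -> dict[tuple[str, int], int]:
        return {k: i for i, c in enumerate(self.clusters) for k in c}


def complete_linkage(m: RmsdMatrix, height: float = 2.0) -> ClusterPartition:
    """Agglomerative complete-linkage clustering cut at ``height``.

    Clusters are the maximal merge-tree nodes whose cophenetic distance is
    <= height. Ties between equal-linkage merges are broken by the smallest
    (lexicographic) pair of current cluster indices, making the result
    deterministic across platforms.
    """
    d = m.values.copy()
    n = d.shape[0]
    if n == 0:
        raise ScaffoldError("empty distance matrix")
    clusters: list[list[int] | None] = [[i] for i in range(n)]
    n_active = n
    np.fill_diagonal(d, np.inf)
    while n_active > 1:
        flat = np.argmin(d)
        i_min, j_min = np.unravel_index(flat, d.shape)  # row-major => lexicographic tie-break
        if d[i_min, j_min] > height:
            break
        a, b = sorted((int(i_min), int(j_min)))
        clusters[a] = clusters[a] + clusters[b]  # type: ignore[operator]
        clusters[b] = None
        # Lance-Williams update for complete linkage: new distance is the max
        d[a, :] = np.maximum(d[a, :], d[b, :])
        d[:, a] = d[a, :]
        d[a, a] = np.inf
        d[b, :] = np.inf
        d[:, b] = np.inf
        n_active -= 1
    result = [sorted(c) for c in clusters if c is not None]
    result.sort(key=lambda c: c[0])
    keyed = [[m.pose_keys[i] for i in c] for c in result]
    return ClusterPartition(clusters=keyed, height=height)


def label_csc(p: ClusterPartition,
              ligand_of: Callable[[tuple[str, int]], str] | None = None,
              min_ligands: int = 6, n_ligands: int = 8) -> ClusterPartition:
    """Label clusters: CSC iff they contain poses of >= ``min_ligands``
    distinct ligands; everything else is residual."""
    if ligand_of is None:
        ligand_of = lambda key: key[0]
    labels: dict[int, str] = {}
    for i, cluster in enumerate(p.clusters):
        ligands = set()
        for key in cluster:
            lig = ligand_of(key)
            if lig is None:
                raise ScaffoldError(f"pose {key}: unknown ligand")
            ligands.add(lig)
        labels[i] = "CSC" if len(ligands) >= min_ligands else "residual"
    return ClusterPartition(clusters=p.clusters, labels=labels, height=p.height,
                            min_ligands=min_ligands, n_ligands=n_ligands)


def pose_separation(a: LigandPose, b: LigandPose) -> tuple[float | None, float]:
    """In-place all-heavy-atom RMSD and centre-of-mass distance between two
    poses.

    The RMSD pairs atoms by index and requires equal heavy-atom counts (same
    ligand); on a mismatch it is reported as None while the COM distance --
    the unweighted heavy-atom centroid distance -- is still returned.
    """
    xa, xb = a.heavy_coords(), b.heavy_coords()
    com = float(np.linalg.norm(xa.mean(axis=0) - xb.mean(axis=0)))
    if xa.shape != xb.shape:
        return None, com
    return _rmsd(xa, xb), com
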