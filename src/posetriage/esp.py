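"""Molecular electrostatic potential on isodensity surfaces.

The potential of a charge distribution,

    V(r) = sum_A Z_A / |R_A - r|  -  integral rho(r') dr' / |r' - r|,

is evaluated either from explicit point sources (nuclei, point electrons,
signed partial charges) or from an electron-density grid by trapezoidal
quadrature, with the singular cell replaced by the analytic potential of a
uniformly charged box. Mapped onto the rho = 0.001 au isodensity surface
(extracted marching-cubes style) it becomes V_S(r); its local most positive
and most negative values are V_S,max and V_S,min, assigned per atom by
nearest-atom lookup. For a C-bound halogen the halogen-assigned most positive
local value is the sigma-hole potential.

Internal units are atomic (bohr, hartree); reported potentials are kcal/mol
(627.509 kcal/mol per hartree), to 2 decimals.

The package never runs SCF itself: quantum densities/potentials arrive as
externally produced Gaussian cube files. For halogenated ligands without a
quantum backend, :func:`ligand_charge_model` builds a documented *empirical*
model -- MMFF94 atomic charges plus a fixed anisotropy dipole on each C-X
axis, with a single-zeta valence Slater promolecule density for the surface.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

HARTREE_TO_KCAL = 627.509
BOHR_PER_ANGSTROM = 1.8897261254578281
SINGULAR_TOL = 1e-6  # bohr

_SYMBOL_TO_Z = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "P": 15, "S": 16,
                "Cl": 17, "Br": 35, "I": 53}
_Z_TO_SYMBOL = {v: k for k, v in _SYMBOL_TO_Z.items()}


class EspError(ValueError):
    """Raised for invalid charge models, grids or evaluation points."""


# ---------------------------------------------------------------------------
# grids and charge models
# ---------------------------------------------------------------------------

@dataclass
class ScalarGrid:
    """A regular axis-aligned scalar lattice (origin/spacing in bohr)."""

    origin: np.ndarray          # (3,)
    spacing: np.ndarray         # (3,)
    values: np.ndarray          # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float).reshape(3)
        self.spacing = np.asarray(self.spacing, float).reshape(3)
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 3:
            raise EspError("grid values must be 3-dimensional")
        if np.any(self.spacing <= 0):
            raise EspError("grid spacing must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def integral(self) -> float:
        """Trapezoidal integral of the grid (e.g. total electron count)."""
        w = [np.ones(n) for n in self.shape]
        for a in range(3):
            w[a][0] = w[a][-1] = 0.5
        wt = w[0][:, None, None] * w[1][None, :, None] * w[2][None, None, :]
        return float((self.values * wt).sum() * np.prod(self.spacing))

    def interpolate(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at Cartesian points (bohr)."""
        from scipy.interpolate import RegularGridInterpolator

        interp = RegularGridInterpolator(
            tuple(self.axis_coords(a) for a in range(3)), self.values,
            bounds_error=True)
        try:
            return interp(np.atleast_2d(points))
        except ValueError as exc:
            raise EspError(f"points outside grid: {exc}") from exc


@dataclass
class ChargeModel:
    """Nuclei plus an electron representation (point charges or a density
    grid), optionally extended with signed partial charges for empirical
    models."""

    nuclei: list[tuple[int, np.ndarray]] = field(default_factory=list)
    electron_points: list[tuple[float, np.ndarray]] = field(default_factory=list)
    partial_charges: list[tuple[float, np.ndarray]] = field(default_factory=list)
    density: ScalarGrid | None = None
    elements: list[str] | None = None     # per-nucleus symbols, if known

    def __post_init__(self) -> None:
        for z, _ in self.nuclei:
            if not (isinstance(z, (int, np.integer)) and z > 0):
                raise EspError(f"nuclear charge must be a positive integer, got {z!r}")
        for q, _ in self.electron_points:
            if q < 0:
                raise EspError("electron point charges are positive magnitudes "
                               "(interpreted with negative sign)")

    def source_points(self) -> np.ndarray:
        """All point-source positions (for singularity checks)."""
        pts = [p for _, p in self.nuclei] + [p for _, p in self.electron_points] \
            + [p for _, p in self.partial_charges]
        return np.array(pts, float).reshape(-1, 3)

    def net_charge(self) -> float:
        q = sum(z for z, _ in self.nuclei) - sum(q for q, _ in self.electron_points) \
            + sum(q for q, _ in self.partial_charges)
        if self.density is not None:
            q -= self.density.integral()
        return float(q)

    def atom_positions(self) -> np.ndarray:
        return np.array([p for _, p in self.nuclei], float).reshape(-1, 3)


def combine(models: Sequence[ChargeModel]) -> ChargeModel:
    """Union of charge models (potentials add linearly)."""
    out = ChargeModel()
    for m in models:
        if m.density is not None:
            raise EspError("combine() supports point-source models only")
        out.nuclei += [(z, np.array(p, float)) for z, p in m.nuclei]
        out.electron_points += [(q, np.array(p, float)) for q, p in m.electron_points]
        out.partial_charges += [(q, np.array(p, float)) for q, p in m.partial_charges]
    return out


# ---------------------------------------------------------------------------
# potential evaluation
# ---------------------------------------------------------------------------

def _uniform_box_potential(rel: np.ndarray, half: np.ndarray) -> float:
    """Potential at a point of a unit-density box.

    ``rel`` is the evaluation point relative to the box centre, ``half`` the
    box half-extents (bohr). Closed form of the Newtonian potential of a
    right rectangular prism, valid inside and outside the box.
    """
    eps = 1e-300
    xs = [half[0] * s - rel[0] for s in (-1.0, 1.0)]
    ys = [half[1] * s - rel[1] for s in (-1.0, 1.0)]
    zs = [half[2] * s - rel[2] for s in (-1.0, 1.0)]
    total = 0.0
    for i, x in enumerate(xs):
        for j, y in enumerate(ys):
            for k, z in enumerate(zs):
                r = math.sqrt(x * x + y * y + z * z)
                # (-1)^(number of lower integration limits); principal-value
                # arctan keeps the formula valid inside the box
                sign = -((-1.0) ** (i + j + k))
                term = 0.0
                term += x * y * math.log(max(z + r, eps))
                term += y * z * math.log(max(x + r, eps))
                term += z * x * math.log(max(y + r, eps))
                if x * r != 0.0:
                    term -= 0.5 * x * x * math.atan(y * z / (x * r))
                if y * r != 0.0:
                    term -= 0.5 * y * y * math.atan(z * x / (y * r))
                if z * r != 0.0:
                    term -= 0.5 * z * z * math.atan(x * y / (z * r))
                total += sign * term
    return total


def _density_term(grid: ScalarGrid, points: np.ndarray) -> np.ndarray:
    """Electronic integral by trapezoidal quadrature.

    Nodes within half a cell of the evaluation point are replaced by the
    analytic potential of a uniformly charged cell carrying the node density.
    """
    nx, ny, nz = grid.shape
    ax = [grid.axis_coords(a) for a in range(3)]
    w = [np.ones(n) for n in grid.shape]
    for a in range(3):
        w[a][0] = w[a][-1] = 0.5
    wt = (w[0][:, None, None] * w[1][None, :, None] * w[2][None, None, :]).ravel()
    nodes = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
    rho = grid.values.ravel()
    dv = float(np.prod(grid.spacing))
    half = grid.spacing / 2.0

    out = np.empty(len(points))
    for ip, p in enumerate(points):
        d = np.linalg.norm(nodes - p, axis=1)
        near = np.all(np.abs(nodes - p) <= half[None, :] + 1e-12, axis=1)
        far = ~near
        val = float(np.sum(wt[far] * rho[far] * dv / d[far]))
        for idx in np.where(near)[0]:
            val += float(rho[idx] * wt[idx] *
                         _uniform_box_potential(p - nodes[idx], half))
        out[ip] = val
    return out


def esp_at_points(cm: ChargeModel, points: np.ndarray) -> np.ndarray:
    """Electrostatic potential (au) at Cartesian points (bohr)."""
    points = np.atleast_2d(np.asarray(points, float))
    src = cm.source_points()
    if len(src):
        d = np.linalg.norm(points[:, None, :] - src[None, :, :], axis=-1)
        if np.any(d < SINGULAR_TOL):
            raise EspError("singular evaluation point (within 1e-6 bohr of a source)")
    v = np.zeros(len(points))
    if cm.nuclei:
        zs = np.array([z for z, _ in cm.nuclei], float)
        pos = np.array([p for _, p in cm.nuclei], float)
        v += (zs[None, :] / np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=-1)).sum(axis=1)
    if cm.electron_points:
        qs = np.array([q for q, _ in cm.electron_points], float)
        pos = np.array([p for _, p in cm.electron_points], float)
        v -= (qs[None, :] / np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=-1)).sum(axis=1)
    if cm.partial_charges:
        qs = np.array([q for q, _ in cm.partial_charges], float)
        pos = np.array([p for _, p in cm.partial_charges], float)
        v += (qs[None, :] / np.linalg.norm(points[:, None, :] - pos[None, :, :], axis=-1)).sum(axis=1)
    if cm.density is not None:
        v -= _density_term(cm.density, points)
    return v


def esp_at_point(cm: ChargeModel, r: Sequence[float]) -> float:
    """Potential (au) at one point (bohr); errors on singular evaluation."""
    return float(esp_at_points(cm, np.asarray(r, float).reshape(1, 3))[0])


# ---------------------------------------------------------------------------
# cube files
# ---------------------------------------------------------------------------

def write_cube(grid: ScalarGrid, path: str | Path,
               atoms: Sequence[tuple[int, np.ndarray]] = (),
               comment: str = "posetriage scalar grid") -> None:
    """Write a Gaussian cube file (bohr units, z-fastest data order)."""
    lines = [comment, "cube written by posetriage"]
    lines.append(f"{len(atoms):5d}{grid.origin[0]:12.6f}{grid.origin[1]:12.6f}{grid.origin[2]:12.6f}")
    for a in range(3):
        vec = [0.0, 0.0, 0.0]
        vec[a] = grid.spacing[a]
        lines.append(f"{grid.shape[a]:5d}{vec[0]:12.6f}{vec[1]:12.6f}{vec[2]:12.6f}")
    for z, p in atoms:
        lines.append(f"{z:5d}{float(z):12.6f}{p[0]:12.6f}{p[1]:12.6f}{p[2]:12.6f}")
    flat = grid.values.reshape(grid.shape[0] * grid.shape[1], grid.shape[2])
    for row in flat:
        for start in range(0, len(row), 6):
            lines.append("".join(f"{v:13.5E}" for v in row[start:start + 6]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_cube(path: str | Path) -> tuple[ScalarGrid, list[tuple[int, np.ndarray]]]:
    """Read a Gaussian cube file; returns (grid, atoms as (Z, xyz bohr))."""
    tokens = Path(path).read_text().split("\n")
    if len(tokens) < 6:
        raise EspError(f"{path}: truncated cube file")
    header = tokens[2].split()
    natoms = int(header[0])
    origin = np.array(header[1:4], float)
    shape = []
    spacing = []
    for a in range(3):
        parts = tokens[3 + a].split()
        n = int(parts[0])
        if n <= 0:
            raise EspError(f"{path}: cube axes must use positive (bohr) counts")
        vec = np.array(parts[1:4], float)
        off = [0, 1, 2]
        off.remove(a)
        if np.any(np.abs(vec[off]) > 1e-9):
            raise EspError(f"{path}: only axis-aligned cubes are supported")
        shape.append(n)
        spacing.append(vec[a])
    atoms = []
    for i in range(abs(natoms)):
        parts = tokens[6 + i].split()
        atoms.append((int(parts[0]), np.array(parts[2:5], float)))
    data = np.fromstring(" ".join(tokens[6 + abs(natoms):]), sep=" ")
    expect = shape[0] * shape[1] * shape[2]
    if data.size != expect:
        raise EspError(f"{path}: expected {expect} grid values, found {data.size}")
    grid = ScalarGrid(origin, np.array(spacing), data.reshape(shape))
    return grid, atoms


# ---------------------------------------------------------------------------
# isosurface extraction and extrema
# ---------------------------------------------------------------------------

@dataclass
class IsoSurface:
    """Triangulated isodensity surface with optional per-vertex V_S values."""

    vertices: np.ndarray               # (n, 3) bohr
    faces: np.ndarray                  # (m, 3) vertex indices
    isovalue: float
    vs: np.ndarray | None = None       # kcal/mol per vertex
    atoms: list[tuple[str, np.ndarray]] | None = None  # (element, xyz bohr)
    nearest_atom: np.ndarray | None = None

    def assign_atoms(self, atoms: list[tuple[str, np.ndarray]]) -> None:
        """Nearest-atom assignment of every surface vertex."""
        self.atoms = atoms
        pos = np.array([p for _, p in atoms], float)
        d = np.linalg.norm(self.vertices[:, None, :] - pos[None, :, :], axis=-1)
        self.nearest_atom = d.argmin(axis=1)

    def vertex_neighbors(self) -> list[set[int]]:
        neigh: list[set[int]] = [set() for _ in range(len(self.vertices))]
        for tri in self.faces:
            a, b, c = (int(x) for x in tri)
            neigh[a].update((b, c))
            neigh[b].update((a, c))
            neigh[c].update((a, b))
        return neigh


def extract_isosurface(grid: ScalarGrid, iso: float = 0.001) -> IsoSurface:
    """Polygonise the ``rho = iso`` surface of a density grid.

    The grid must enclose the contour (boundary values below iso); an
    isovalue above the grid maximum yields an empty surface with a warning.
    """
    from skimage import measure

    vmax = float(grid.values.max())
    if iso > vmax:
        warnings.warn(f"isovalue {iso} above grid maximum {vmax:.3e}: empty surface")
        return IsoSurface(np.zeros((0, 3)), np.zeros((0, 3), int), iso)
    boundary_max = max(
        float(grid.values[0].max()), float(grid.values[-1].max()),
        float(grid.values[:, 0].max()), float(grid.values[:, -1].max()),
        float(grid.values[:, :, 0].max()), float(grid.values[:, :, -1].max()))
    if boundary_max >= iso:
        raise EspError("grid too small: isodensity contour touches the grid boundary")
    verts, faces, _, _ = measure.marching_cubes(grid.values, level=iso,
                                                spacing=tuple(grid.spacing))
    verts = verts + grid.origin[None, :]
    return IsoSurface(verts, faces, iso)


def surface_potential(cm: ChargeModel, surf: IsoSurface,
                      esp_grid: ScalarGrid | None = None) -> IsoSurface:
    """Evaluate V_S (kcal/mol) at every surface vertex.

    Uses the charge model directly, or trilinear interpolation of a supplied
    potential grid (au) -- e.g. an externally computed ESP cube.
    """
    if len(surf.vertices) == 0:
        surf.vs = np.zeros(0)
        return surf
    if esp_grid is not None:
        v_au = esp_grid.interpolate(surf.vertices)
    else:
        v_au = esp_at_points(cm, surf.vertices)
    surf.vs = v_au * HARTREE_TO_KCAL
    if surf.atoms is None and cm.nuclei and cm.elements:
        surf.assign_atoms(list(zip(cm.elements, [p for _, p in cm.nuclei])))
    return surf


@dataclass
class SurfaceExtrema:
    """Local extrema of V_S on a surface, with per-atom assignment."""

    maxima: list[tuple[float, np.ndarray, int | None]]
    minima: list[tuple[float, np.ndarray, int | None]]
    vs_max: float
    vs_min: float
    per_atom_max: dict[int, tuple[float, np.ndarray]]
    flat: bool = False


def find_extrema(surf: IsoSurface) -> SurfaceExtrema:
    """Local extrema of V_S over the vertex adjacency graph.

    A vertex is a local maximum (minimum) when its value is >= (<=) every
    1-ring neighbour. A constant surface is flagged flat and reported as a
    single degenerate extremum. Values are reported to 2 decimals.
    """
    if surf.vs is None:
        raise EspError("surface potential not computed")
    if len(surf.vertices) < 4:
        raise EspError("surface has fewer than 4 vertices")
    vs = surf.vs
    if float(vs.max() - vs.min()) < 1e-9:
        atom = int(surf.nearest_atom[0]) if surf.nearest_atom is not None else None
        val = round(float(vs[0]), 2)
        e = [(val, surf.vertices[0], atom)]
        return SurfaceExtrema(e, list(e), val, val, {}, flat=True)

    neigh = surf.vertex_neighbors()
    maxima, minima = [], []
    for i, v in enumerate(vs):
        nb = neigh[i]
        if not nb:
            continue
        nbv = vs[list(nb)]
        atom = int(surf.nearest_atom[i]) if surf.nearest_atom is not None else None
        if v >= nbv.max():
            maxima.append((round(float(v), 2), surf.vertices[i], atom))
        elif v <= nbv.min():
            minima.append((round(float(v), 2), surf.vertices[i], atom))
    per_atom: dict[int, tuple[float, np.ndarray]] = {}
    for val, pos, atom in maxima:
        if atom is not None and (atom not in per_atom or val > per_atom[atom][0]):
            per_atom[atom] = (val, pos)
    return SurfaceExtrema(
        sorted(maxima, key=lambda t: -t[0]), sorted(minima, key=lambda t: t[0]),
        round(float(vs.max()), 2), round(float(vs.min()), 2), per_atom)


# ---------------------------------------------------------------------------
# empirical model for halogenated ligands
# ---------------------------------------------------------------------------

#: single-zeta valence Slater parameters: (principal quantum number, zeta
#: [1/bohr], valence electron count). Zetas follow the outermost-shell values
#: of standard single-zeta tabulations.
PROMOLECULE_PARAMS: dict[str, tuple[int, float, int]] = {
    "H": (1, 1.000, 1), "C": (2, 1.568, 4), "N": (2, 1.917, 5),
    "O": (2, 2.227, 6), "F": (2, 2.550, 7), "S": (3, 1.827, 6),
    "Cl": (3, 2.039, 7), "Br": (4, 2.257, 7), "I": (5, 2.320, 7),
}

#: fixed sigma-hole anisotropy dipole per halogen (atomic units of e*bohr),
#: oriented along C->X; magnitudes follow the polarizability order I > Br > Cl
#: (0.5, 0.75 and 1.0 debye). Fluorine carries no sigma-hole.
SIGMA_HOLE_DIPOLE = {"Cl": 0.50 * 0.3934303, "Br": 0.75 * 0.3934303,
                     "I": 1.00 * 0.3934303}
_DIPOLE_SPLIT = 0.30  # bohr between the +/- charges representing the dipole


_CORE_AMP = 0.05    # e/bohr^3; plugs the vanishing-valence hole at heavy cores
_CORE_WIDTH = 1.1   # bohr


def slater_density(element: str, r: np.ndarray) -> np.ndarray:
    """Spherically averaged atomic density (e/bohr^3).

    Valence shell as a single-zeta Slater orbital density; for elements with
    core electrons a tight Gaussian core term keeps the density above the
    0.001 au isovalue throughout the interior (the valence radial density
    alone vanishes at the nucleus as r^(2n-2), which would open spurious
    interior cavities under the outer isosurface). The core term is below
    1e-7 au at the 0.001 au surface, so the surface radius is valence-set.
    """
    if element not in PROMOLECULE_PARAMS:
        raise EspError(f"no promolecule parameters for element {element!r}")
    n, zeta, nval = PROMOLECULE_PARAMS[element]
    r = np.asarray(r, float)
    norm = (2.0 * zeta) ** (2 * n + 1) / math.factorial(2 * n)  # radial normalisation
    if n == 1:
        radial2 = norm * np.exp(-2.0 * zeta * r)
    else:
        radial2 = norm * np.power(r, 2 * n - 2) * np.exp(-2.0 * zeta * r)
    rho = nval * radial2 / (4.0 * math.pi)
    if n > 1:
        rho = rho + _CORE_AMP * np.exp(-((r / _CORE_WIDTH) ** 2))
    return rho


def slater_isodensity_radius(element: str, iso: float = 0.001) -> float:
    """Radius (bohr) where one atom's valence density equals ``iso``."""
    from scipy.optimize import brentq

    f = lambda r: float(slater_density(element, np.array([r]))[0]) - iso
    return float(brentq(f, 0.5, 15.0))


def promolecule_grid(elements: Sequence[str], coords_bohr: np.ndarray,
                     spacing: float = 0.35, margin: float = 6.0) -> ScalarGrid:
    """Superposed spherical-atom density on a regular grid around a molecule."""
    coords_bohr = np.asarray(coords_bohr, float)
    lo = coords_bohr.min(axis=0) - margin
    hi = coords_bohr.max(axis=0) + margin
    shape = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = [lo[a] + spacing * np.arange(shape[a]) for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([xx, yy, zz], axis=-1)
    rho = np.zeros(tuple(shape))
    for el, c in zip(elements, coords_bohr):
        r = np.linalg.norm(pts - c[None, None, None, :], axis=-1)
        rho += slater_density(el, r)
    return ScalarGrid(lo, np.full(3, spacing), rho)


def ligand_charge_model(mol, conf_id: int = -1) -> ChargeModel:
    """Empirical point-charge model of a ligand (signed MMFF94 charges plus
    sigma-hole anisotropy dipoles on every C-Cl/Br/I axis).

    This is an empirical approximation to a quantum ESP, adequate for
    qualitative sigma-hole analysis (sign, location, I > Br > Cl ordering);
    absolute magnitudes differ from DFT-derived surface potentials.
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    props = AllChem.MMFFGetMoleculeProperties(mol)
    if props is None:
        raise EspError("MMFF94 parameters unavailable for molecule")
    conf = mol.GetConformer(conf_id)
    xyz = np.asarray(conf.GetPositions(), float) * BOHR_PER_ANGSTROM
    charges = [props.GetMMFFPartialCharge(i) for i in range(mol.GetNumAtoms())]

    cm = ChargeModel(elements=[a.GetSymbol() for a in mol.GetAtoms()])
    # nuclei + an equal point-electron population: the net point sources are
    # then exactly the signed partial charges, while nucleus positions stay
    # available for per-atom surface assignment
    cm.nuclei = [(_SYMBOL_TO_Z[a.GetSymbol()], xyz[a.GetIdx()]) for a in mol.GetAtoms()]
    cm.electron_points = [(float(z), p) for z, p in cm.nuclei]
    cm.partial_charges = [(float(q), xyz[i]) for i, q in enumerate(charges)]

    for atom in mol.GetAtoms():
        el = atom.GetSymbol()
        if el not in SIGMA_HOLE_DIPOLE:
            continue
        carbons = [b for b in atom.GetNeighbors() if b.GetAtomicNum() == 6]
        if not carbons:
            continue
        x = xyz[atom.GetIdx()]
        c = xyz[carbons[0].GetIdx()]
        u = (x - c) / np.linalg.norm(x - c)
        q = SIGMA_HOLE_DIPOLE[el] / _DIPOLE_SPLIT
        cm.partial_charges.append((q, x + u * _DIPOLE_SPLIT / 2.0))
        cm.partial_charges.append((-q, x - u * _DIPOLE_SPLIT / 2.0))
    return cm


def halogen_vsmax(mol, conf_id: int = -1, iso: float = 0.001,
                  spacing: float = 0.35, margin: float = 6.0,
                  ) -> tuple[dict[int, float], SurfaceExtrema, IsoSurface]:
    """Sigma-hole surface analysis of one ligand conformer.

    Builds the promolecule density grid, extracts the ``iso`` surface, maps
    the empirical potential onto it and returns the most positive local V_S
    (kcal/mol) assigned to each halogen atom, keyed by atom index.
    """
    conf = mol.GetConformer(conf_id)
    xyz = np.asarray(conf.GetPositions(), float) * BOHR_PER_ANGSTROM
    elements = [a.GetSymbol() for a in mol.GetAtoms()]
    grid = promolecule_grid(elements, xyz, spacing=spacing, margin=margin)
    surf = extract_isosurface(grid, iso)
    cm = ligand_charge_model(mol, conf_id)
    surf.assign_atoms(list(zip(elements, xyz)))
    surf = surface_potential(cm, surf)
    ext = find_extrema(surf)
    out = {}
    for i, el in enumerate(elements):
        if el in ("F", "Cl", "Br", "I") and i in ext.per_atom_max:
            out[i] = ext.per_atom_max[i][0]
    return out, ext, surf
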