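"""Electrostatic potential evaluation, isosurface extraction, extrema."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from posetriage import (ChargeModel, EspError, ScalarGrid, esp_at_point,
                        esp_at_points, extract_isosurface, find_extrema,
                        read_cube, surface_potential, write_cube,
                        HARTREE_TO_KCAL)
from posetriage.esp import (_uniform_box_potential, ligand_charge_model,
                            halogen_vsmax, promolecule_grid,
                            slater_isodensity_radius, combine)
from posetriage.synthdata import make_charge_model
from tests.conftest import embedded


def random_point_model(rng, n_nuc=4, n_el=6):
    nuclei = [(int(rng.integers(1, 9)), rng.uniform(-3, 3, 3)) for _ in range(n_nuc)]
    electrons = [(float(rng.uniform(0.2, 2.0)), rng.uniform(-3, 3, 3))
                 for _ in range(n_el)]
    return ChargeModel(nuclei=nuclei, electron_points=electrons)


def direct_sum(cm: ChargeModel, r: np.ndarray) -> float:
    """Independent oracle: plain Python Coulomb sum."""
    v = 0.0
    for z, p in cm.nuclei:
        v += z / math.dist(r, p)
    for q, p in cm.electron_points:
        v -= q / math.dist(r, p)
    for q, p in cm.partial_charges:
        v += q / math.dist(r, p)
    return v


# ---------------------------------------------------------------------------
# point evaluation
# ---------------------------------------------------------------------------

def test_single_nucleus_coulomb():
    cm = ChargeModel(nuclei=[(1, np.zeros(3))])
    assert esp_at_point(cm, [1.0, 0, 0]) == 1.0
    assert esp_at_point(cm, [0, 2.0, 0]) == 0.5


def test_exact_cancellation():
    cm = ChargeModel(nuclei=[(1, np.zeros(3))],
                     electron_points=[(1.0, np.zeros(3))])
    assert esp_at_point(cm, [0.7, -0.3, 1.1]) == pytest.approx(0.0, abs=1e-15)


def test_matches_direct_sum_oracle_everywhere():
    rng = np.random.default_rng(42)
    cm = random_point_model(rng)
    for _ in range(20):
        r = rng.uniform(-6, 6, 3)
        if np.min(np.linalg.norm(cm.source_points() - r, axis=1)) < 0.1:
            continue
        assert esp_at_point(cm, r) == pytest.approx(direct_sum(cm, r), abs=1e-12)


def test_singular_evaluation_point_is_an_error():
    cm = ChargeModel(nuclei=[(1, np.zeros(3))])
    with pytest.raises(EspError, match="singular"):
        esp_at_point(cm, [0.0, 0.0, 1e-9])


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_potential_is_linear_in_the_sources(seed):
    rng = np.random.default_rng(seed)
    a = random_point_model(rng, 2, 2)
    b = random_point_model(rng, 2, 2)
    r = rng.uniform(4, 6, 3)
    v = esp_at_point(combine([a, b]), r)
    assert v == pytest.approx(esp_at_point(a, r) + esp_at_point(b, r), abs=1e-12)


def test_far_field_approaches_net_charge():
    rng = np.random.default_rng(7)
    cm = random_point_model(rng)
    q = cm.net_charge()
    r = np.array([100.0, 0.0, 0.0])
    assert 100.0 * esp_at_point(cm, r) == pytest.approx(q, rel=0.01)


# ---------------------------------------------------------------------------
# density quadrature
# ---------------------------------------------------------------------------

def gaussian_grid(n_e=2.0, sigma=0.6, spacing=0.3, half=4.8):
    n = int(2 * half / spacing) + 1
    ax = -half + spacing * np.arange(n)
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    rho = n_e * (2 * np.pi * sigma ** 2) ** -1.5 * \
        np.exp(-(xx ** 2 + yy ** 2 + zz ** 2) / (2 * sigma ** 2))
    return ScalarGrid(np.full(3, -half), np.full(3, spacing), rho)


def test_uniform_box_potential_matches_quadrature():
    half = np.array([0.2, 0.3, 0.25])
    for rel in (np.zeros(3), np.array([0.05, -0.1, 0.02]), np.array([1.0, 0.5, -0.4])):
        n = 60
        axes = [np.linspace(-h, h, n + 1) for h in half]
        centers = [(a[:-1] + a[1:]) / 2 for a in axes]
        X, Y, Z = np.meshgrid(*centers, indexing="ij")
        dv = np.prod([a[1] - a[0] for a in axes])
        d = np.sqrt((X - rel[0]) ** 2 + (Y - rel[1]) ** 2 + (Z - rel[2]) ** 2)
        numeric = float((dv / d).sum())
        assert _uniform_box_potential(rel, half) == pytest.approx(numeric, rel=2e-3)


def test_density_term_converges_to_point_charge():
    """A narrow Gaussian density behaves like a point electron away from it,
    and the quadrature error shrinks under grid refinement."""
    point = ChargeModel(nuclei=[(3, np.zeros(3))],
                        electron_points=[(2.0, np.zeros(3))])
    errors = []
    for spacing in (0.4, 0.2):
        cm = ChargeModel(nuclei=[(3, np.zeros(3))],
                         density=gaussian_grid(spacing=spacing))
        err = max(abs(esp_at_point(cm, [r, 0, 0]) - esp_at_point(point, [r, 0, 0]))
                  for r in (2.5, 4.0))
        errors.append(err)
    assert errors[1] < errors[0]
    assert errors[1] < 5e-4


def test_grid_integral_counts_electrons():
    g = gaussian_grid(n_e=10.0, sigma=1.0, spacing=0.25, half=6.0)
    assert g.integral() == pytest.approx(10.0, rel=0.01)


# ---------------------------------------------------------------------------
# cube files
# ---------------------------------------------------------------------------

def test_cube_roundtrip(tmp_path):
    g = gaussian_grid(spacing=0.6, half=2.4)
    atoms = [(8, np.array([0.1, -0.2, 0.3]))]
    write_cube(g, tmp_path / "t.cube", atoms=atoms)
    back, back_atoms = read_cube(tmp_path / "t.cube")
    np.testing.assert_allclose(back.origin, g.origin, atol=1e-6)
    np.testing.assert_allclose(back.spacing, g.spacing, atol=1e-6)
    assert back.shape == g.shape
    np.testing.assert_allclose(back.values, g.values, rtol=1e-4, atol=1e-12)
    assert back_atoms[0][0] == 8
    np.testing.assert_allclose(back_atoms[0][1], atoms[0][1], atol=1e-6)


# ---------------------------------------------------------------------------
# isosurface
# ---------------------------------------------------------------------------

def test_gaussian_isosurface_radius_matches_analytic_solve():
    cm, meta = make_charge_model("gaussian_atom",
                                 {"n_electrons": 10.0, "sigma": 1.0, "spacing": 0.25})
    surf = extract_isosurface(cm.density, 0.001)
    radii = np.linalg.norm(surf.vertices, axis=1)
    assert abs(radii.mean() - meta["isodensity_radius"]) < 0.25  # one spacing
    assert radii.std() < 0.1


def test_surface_area_converges_to_sphere():
    areas = []
    for spacing in (0.5, 0.25):
        cm, meta = make_charge_model("gaussian_atom",
                                     {"n_electrons": 10.0, "sigma": 1.0,
                                      "spacing": spacing})
        surf = extract_isosurface(cm.density, 0.001)
        v = surf.vertices
        tri = v[surf.faces]
        area = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum()
        areas.append(area)
    exact = 4 * np.pi * meta["isodensity_radius"] ** 2
    assert abs(areas[1] - exact) < abs(areas[0] - exact) + 1e-9
    assert areas[1] == pytest.approx(exact, rel=0.02)


def test_isovalue_above_maximum_warns_and_returns_empty():
    g = gaussian_grid(n_e=0.001, sigma=1.0)
    with pytest.warns(UserWarning, match="empty surface"):
        surf = extract_isosurface(g, 0.5)
    assert len(surf.vertices) == 0


def test_contour_touching_boundary_is_an_error():
    g = gaussian_grid(n_e=10.0, sigma=2.0, half=2.0)
    with pytest.raises(EspError, match="grid too small"):
        extract_isosurface(g, 0.001)


# ---------------------------------------------------------------------------
# surface potential and extrema
# ---------------------------------------------------------------------------

def spherical_surface_model():
    cm, _ = make_charge_model("gaussian_atom", {"n_electrons": 10.0, "sigma": 1.0,
                                                "spacing": 0.25})
    return extract_isosurface(cm.density, 0.001)


def test_zero_model_gives_zero_potential():
    surf = spherical_surface_model()
    surf = surface_potential(ChargeModel(), surf)
    assert np.all(surf.vs == 0.0)


def test_vertex_values_match_pointwise_recomputation():
    surf = spherical_surface_model()
    cm, _ = make_charge_model("dipole", {"q": 0.5, "d": 1.0})
    surf = surface_potential(cm, surf)
    idx = np.linspace(0, len(surf.vertices) - 1, 25).astype(int)
    for i in idx:
        expect = esp_at_point(cm, surf.vertices[i]) * HARTREE_TO_KCAL
        assert surf.vs[i] == pytest.approx(expect, abs=1e-9)


def test_dipole_antisymmetry_and_extrema_location():
    surf = spherical_surface_model()
    cm, _ = make_charge_model("dipole", {"q": 1.0, "d": 2.0})
    surf = surface_potential(cm, surf)
    surf.assign_atoms([("O", np.zeros(3))])
    ext = find_extrema(surf)
    # brute-force vertex scan: global max in the +z cap, min in the -z cap
    imax, imin = int(np.argmax(surf.vs)), int(np.argmin(surf.vs))
    assert surf.vertices[imax][2] > 0 and surf.vertices[imin][2] < 0
    assert ext.vs_max == round(float(surf.vs[imax]), 2)
    assert ext.vs_min == round(float(surf.vs[imin]), 2)
    assert ext.maxima[0][0] == ext.vs_max
    # mirror symmetry: V(+z) ~ -V(-z) to mesh-discretisation tolerance
    assert ext.vs_max == pytest.approx(-ext.vs_min, rel=0.02)


def test_dipole_midpoint_potential_is_zero():
    cm, _ = make_charge_model("dipole", {"q": 1.0, "d": 2.0})
    assert esp_at_point(cm, [5.0, 0.0, 0.0]) == pytest.approx(0.0, abs=1e-12)


def test_flat_surface_flagged():
    surf = spherical_surface_model()
    surf.vs = np.zeros(len(surf.vertices))
    ext = find_extrema(surf)
    assert ext.flat
    assert len(ext.maxima) == 1


def test_too_few_vertices_is_an_error():
    surf = spherical_surface_model()
    surf.vertices = surf.vertices[:3]
    surf.faces = np.zeros((1, 3), int)
    surf.vs = np.zeros(3)
    with pytest.raises(EspError, match="fewer than 4"):
        find_extrema(surf)


def test_sigma_hole_mimic_max_lies_on_cx_axis():
    """On a planted sigma-hole mimic the halogen-assigned maximum sits within
    15 degrees of the C-X bond extension."""
    cm, meta = make_charge_model("sigma_hole_mimic")
    elements = [el for el in cm.elements]
    coords = np.array([p for _, p in cm.nuclei])
    grid = promolecule_grid(elements, coords, spacing=0.3)
    surf = extract_isosurface(grid, 0.001)
    surf.assign_atoms(list(zip(elements, coords)))
    surf = surface_potential(cm, surf)
    ext = find_extrema(surf)
    x_idx = elements.index("Cl")
    val, pos = ext.per_atom_max[x_idx]
    u = pos - coords[x_idx]
    cos = np.dot(u, meta["axis"]) / np.linalg.norm(u)
    assert math.degrees(math.acos(np.clip(cos, -1, 1))) < 15.0
    assert val > 0


def test_extrema_invariant_under_rigid_rotation():
    cm, _ = make_charge_model("sigma_hole_mimic")
    elements = list(cm.elements)
    coords = np.array([p for _, p in cm.nuclei])

    def run(rot):
        c2 = coords @ rot.T
        model = ChargeModel(
            nuclei=[(z, rot @ p) for z, p in cm.nuclei],
            electron_points=[(q, rot @ p) for q, p in cm.electron_points],
            partial_charges=[(q, rot @ p) for q, p in cm.partial_charges],
            elements=elements)
        grid = promolecule_grid(elements, c2, spacing=0.3)
        surf = extract_isosurface(grid, 0.001)
        surf.assign_atoms(list(zip(elements, c2)))
        return find_extrema(surface_potential(model, surf))

    t = 0.9
    rot = np.array([[math.cos(t), -math.sin(t), 0],
                    [math.sin(t), math.cos(t), 0], [0, 0, 1.0]])
    e1, e2 = run(np.eye(3)), run(rot)
    assert e1.vs_max == pytest.approx(e2.vs_max, abs=0.15)
    assert e1.vs_min == pytest.approx(e2.vs_min, abs=0.15)


# ---------------------------------------------------------------------------
# empirical ligand models
# ---------------------------------------------------------------------------

def test_promolecule_radii_are_chemically_ordered():
    r = {el: slater_isodensity_radius(el) for el in ("F", "Cl", "Br", "I")}
    assert r["F"] < r["Cl"] < r["Br"] < r["I"]


def test_ligand_model_net_charge_matches_formal_charge():
    mol = embedded("N[C@@H](Cc1ccc(Cl)cc1)C(=O)O")
    cm = ligand_charge_model(mol)
    assert cm.net_charge() == pytest.approx(0.0, abs=1e-6)


def test_halogen_vsmax_reports_each_halogen(diiodotyr_pose):
    vmax, ext, surf = halogen_vsmax(diiodotyr_pose.mol, spacing=0.45)
    iod = [i for i, a in enumerate(diiodotyr_pose.mol.GetAtoms())
           if a.GetSymbol() == "I"]
    assert set(vmax) == set(iod)
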