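"""Shared fixtures: one fully planted synthetic study (8 ligands x 100 poses,
two binding modes, 20% decoys) generated once per session, plus small helper
molecules. All fixtures are seeded; nothing is read from disk."""

from __future__ import annotations

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from posetriage import (LigandPose, ScaffoldDefinition, SynthConfig,
                        make_ligand_library, make_pocket, plant_poses,
                        reference_pose)

SEED = 3


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig(seed=SEED, poses_per_ligand=100)


@pytest.fixture(scope="session")
def library(synth_cfg):
    mols, truth = make_ligand_library(synth_cfg)
    return mols


@pytest.fixture(scope="session")
def pocket(synth_cfg):
    return make_pocket(synth_cfg)


@pytest.fixture(scope="session")
def pocket_degraded(synth_cfg):
    return make_pocket(synth_cfg, degraded=True)


@pytest.fixture(scope="session")
def planted(library, pocket, synth_cfg):
    """The full 8 x 100 planted pose set with ground truth."""
    return plant_poses(library, pocket, synth_cfg)


@pytest.fixture(scope="session")
def small_planted(library, pocket):
    cfg = SynthConfig(seed=SEED, poses_per_ligand=10)
    return plant_poses(library, pocket, cfg)


@pytest.fixture(scope="session")
def bm1_pose(library):
    """Jitter-free consensus-mode pose of the diiodinated tyrosine analogue
    (the richest interaction inventory: 5 backbone H-bonds, cation-pi,
    halogen bond, three hydrophobic clusters)."""
    mol = next(m for m in library if m.GetProp("ligand_id") == "diiodotyr")
    return reference_pose(mol)


@pytest.fixture(scope="session")
def scaffold() -> ScaffoldDefinition:
    return ScaffoldDefinition()


def embedded(smiles: str, seed: int = 7, optimize: bool = True) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    if AllChem.EmbedMolecule(mol, params) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    if optimize:
        AllChem.MMFFOptimizeMolecule(mol)
    return mol


@pytest.fixture()
def phe_pose() -> LigandPose:
    return LigandPose(embedded("[NH3+][C@@H](Cc1ccccc1)C(=O)[O-]"), "phe", 0)


@pytest.fixture()
def diiodotyr_pose() -> LigandPose:
    return LigandPose(
        embedded("[NH3+][C@@H](Cc1cc(I)c(O)c(I)c1)C(=O)[O-]"), "dit", 0)
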