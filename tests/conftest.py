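import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from fcdg import synthdata
from fcdg.molgraph import from_rdkit


def mol_from_smiles(smiles: str, seed: int = 7) -> Chem.Mol:
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    AllChem.EmbedMolecule(mol, params)
    AllChem.MMFFOptimizeMolecule(mol)
    return mol


def sdf_from_smiles(smiles: str, path, seed: int = 7) -> str:
    path = str(path)
    writer = Chem.SDWriter(path)
    writer.write(mol_from_smiles(smiles, seed))
    writer.close()
    return path


@pytest.fixture(scope="session")
def chain2():
    return synthdata.make_fixture("chain2", seed=1)


@pytest.fixture(scope="session")
def ring3():
    return synthdata.make_fixture("ring3", seed=1)


@pytest.fixture(scope="session")
def butanol():
    """2-butanol with explicit hydrogens: 1 stereocenter, 1 prochiral CH2."""
    return from_rdkit(mol_from_smiles("CC(O)CC"))


def random_feasible_coords(fix, rng, scale=0.05):
    """True geometry plus a small perturbation (keeps most bounds satisfied)."""
    X = fix.true_geometry.coordinates
    return X + rng.normal(0.0, scale, X.shape)
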