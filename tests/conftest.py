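import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem

from pharmfunnel import Hypothesis, Molecule, PlantSpec, Site, plant_hypothesis


def embed(smiles: str, name: str, seed: int = 7) -> Molecule:
    """A Molecule with one ETKDG-embedded conformer (test helper)."""
    mol = Chem.AddHs(Chem.MolFromSmiles(smiles))
    if AllChem.EmbedMolecule(mol, randomSeed=seed) != 0:
        raise RuntimeError(f"embedding failed for {smiles}")
    return Molecule(name, Chem.RemoveHs(mol))


@pytest.fixture
def benzene() -> Molecule:
    return embed("c1ccccc1", "benzene")


@pytest.fixture
def bsu() -> Molecule:
    """1,3-diphenylurea (the BSU co-crystal ligand)."""
    return embed("O=C(Nc1ccccc1)Nc1ccccc1", "BSU")


@pytest.fixture
def planted() -> Hypothesis:
    return plant_hypothesis(PlantSpec(seed=11))


def random_hypothesis(rng: np.random.Generator, n_sites: int | None = None) -> Hypothesis:
    """A random valid hypothesis for property tests."""
    n = n_sites or int(rng.integers(1, 7))
    types = ["A", "D", "H", "R", "N", "P"]
    sites = []
    for _ in range(n):
        direction = None
        if rng.random() < 0.5:
            v = rng.normal(size=3)
            direction = v / np.linalg.norm(v)
        sites.append(
            Site(
                type=types[int(rng.integers(len(types)))],
                position=rng.uniform(-20, 20, 3),
                radius=float(rng.uniform(0.5, 3.0)),
                support=float(rng.uniform(0.1, 1.0)),
                direction=direction,
            )
        )
    return Hypothesis(
        id=f"hyp{rng.integers(1_000_000)}",
        frame="testframe",
        sites=sites,
        min_fraction=float(rng.uniform(0.05, 1.0)),
        tolerance=float(rng.uniform(0.5, 3.0)),
    )


def random_rigid_transform(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.uniform(-10, 10, 3)
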