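"""Structure/hypothesis I/O, PDB ligand extraction, and superposition."""

import numpy as np
import pytest
from rdkit import Chem
from rdkit.Chem import AllChem, Descriptors

from pharmfunnel import (
    Hypothesis,
    Site,
    extract_ligand,
    read_hypothesis,
    read_molecules,
    superpose,
    write_hypothesis,
)
from pharmfunnel.chemio import (
    EmptyInputError,
    HypothesisFormatError,
    InsufficientAnchorsError,
    LigandNotFoundError,
)

from conftest import random_hypothesis, random_rigid_transform

SCAFFOLD_SMILES = {
    "2a": "OC(=O)CCCCN1C(=O)Nc2ccccc2C1=O",
    "2b": "OC(=O)CCCCCN1C(=O)Nc2ccccc2C1=O",
    "2c": "OC(=O)CCCCCCN1C(=O)Nc2ccccc2C1=O",
}


# ---------------------------------------------------------------------------
# read_molecules


def test_read_single_smiles_record(tmp_path):
    p = tmp_path / "one.smi"
    p.write_text("c1ccccc1 benzene\n")
    mols = read_molecules(p, "smiles")
    assert len(mols) == 1
    assert mols[0].id == "benzene"
    assert mols[0].num_heavy_atoms == 6
    assert mols[0].num_conformers == 0


def test_scaffold_acids_parse_with_expected_formulas(tmp_path):
    p = tmp_path / "scaffolds.smi"
    p.write_text("".join(f"{smi} {name}\n" for name, smi in SCAFFOLD_SMILES.items()))
    mols = read_molecules(p, "smiles")
    assert [m.id for m in mols] == ["2a", "2b", "2c"]
    # homologous series: each extra CH2 adds 14.027 Da
    weights = [Descriptors.MolWt(m.mol) for m in mols]
    assert weights[0] == pytest.approx(262.26, abs=0.05)
    assert np.allclose(np.diff(weights), 14.027, atol=0.01)


def test_sdf_corrupt_record_skipped_and_counted(tmp_path, caplog):
    good = Chem.AddHs(Chem.MolFromSmiles("CCO"))
    AllChem.EmbedMolecule(good, randomSeed=3)
    block = Chem.MolToMolBlock(good)
    lines = block.splitlines()
    lines[3] = "999 99  0  0  0  0  0  0  0  0999 V2000"  # broken counts line
    corrupt = "\n".join(lines) + "\n"
    p = tmp_path / "three.sdf"
    p.write_text("$$$$\n".join([block, corrupt, block]) + "$$$$\n")
    with caplog.at_level("WARNING"):
        mols = read_molecules(p, "sdf")
    assert len(mols) == 2
    assert all(m.num_conformers == 1 for m in mols)
    assert sum("skipping" in r.message for r in caplog.records) == 1


def test_read_molecules_errors(tmp_path):
    with pytest.raises(FileNotFoundError):
        read_molecules(tmp_path / "absent.smi", "smiles")
    empty = tmp_path / "bad.smi"
    empty.write_text("not_a_smiles((((\n")
    with pytest.raises(EmptyInputError):
        read_molecules(empty, "smiles")


# ---------------------------------------------------------------------------
# extract_ligand


def _pdb_hetatm(serial, name, res, chain, resnum, x, y, z, element):
    return (
        f"HETATM{serial:5d} {name:<4s} {res:>3s} {chain}{resnum:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2s}"
    )


def _bsu_pdb(tmp_path, chains=("A",), offset=10.0):
    """Synthetic PDB with an embedded 1,3-diphenylurea copy per chain."""
    mol = Chem.AddHs(Chem.MolFromSmiles("O=C(Nc1ccccc1)Nc1ccccc1"))
    AllChem.EmbedMolecule(mol, randomSeed=5)
    mol = Chem.RemoveHs(mol)
    conf = mol.GetConformer()
    lines = []
    serial = 1
    for k, ch in enumerate(chains):
        for atom in mol.GetAtoms():
            pos = conf.GetAtomPosition(atom.GetIdx())
            el = atom.GetSymbol()
            lines.append(
                _pdb_hetatm(serial, f"{el}{atom.GetIdx()+1}", "BSU", ch, 501,
                            pos.x + k * offset, pos.y, pos.z, el)
            )
            serial += 1
        # a water that must never be returned
        lines.append(_pdb_hetatm(serial, "O", "HOH", ch, 900, 50.0, 50.0, 50.0, "O"))
        serial += 1
    path = tmp_path / "bsu.pdb"
    path.write_text("\n".join(lines) + "\nEND\n")
    return path


def test_extract_bsu_heavy_atom_count(tmp_path):
    path = _bsu_pdb(tmp_path)
    lig = extract_ligand(path, "BSU")
    assert lig.num_heavy_atoms == 16  # C13 N2 O1
    symbols = sorted(a.GetSymbol() for a in lig.mol.GetAtoms())
    assert symbols.count("C") == 13 and symbols.count("N") == 2 and symbols.count("O") == 1
    assert lig.num_conformers == 1


def test_extract_ligand_chain_selection(tmp_path, caplog):
    path = _bsu_pdb(tmp_path, chains=("A", "B"), offset=25.0)
    lig_a = extract_ligand(path, "BSU", chain="A")
    lig_b = extract_ligand(path, "BSU", chain="B")
    assert np.allclose(lig_b.conformers[0][:, 0] - lig_a.conformers[0][:, 0], 25.0)
    with caplog.at_level("WARNING"):
        default = extract_ligand(path, "BSU")
    assert np.allclose(default.conformers[0], lig_a.conformers[0])
    assert any("copies" in r.message for r in caplog.records)


def test_extract_ligand_coordinates_match_file_text(tmp_path):
    path = _bsu_pdb(tmp_path)
    lig = extract_ligand(path, "BSU")
    file_xyz = [
        (float(l[30:38]), float(l[38:46]), float(l[46:54]))
        for l in path.read_text().splitlines()
        if l.startswith("HETATM") and l[17:20].strip() == "BSU"
    ]
    got = {tuple(row) for row in lig.conformers[0]}
    assert got == set(file_xyz)  # bit-equal subset of the HETATM records


def test_extract_ligand_errors(tmp_path):
    path = tmp_path / "empty.pdb"
    path.write_text("ATOM      1  CA  ALA A   1      0.000   0.000   0.000  1.00  0.00           C\nEND\n")
    with pytest.raises(LigandNotFoundError):
        extract_ligand(path, "BSU")
    with pytest.raises(LigandNotFoundError):
        extract_ligand(_bsu_pdb(tmp_path), "HOH")


# ---------------------------------------------------------------------------
# superpose


def _anchors(n, seed=0):
    rng = np.random.default_rng(seed)
    return {("A", i, " "): rng.uniform(-10, 10, 3) for i in range(n)}


def test_superpose_identity():
    anchors = _anchors(10)
    R, t, rms = superpose(anchors, anchors)
    assert np.allclose(R, np.eye(3), atol=1e-9)
    assert np.allclose(t, 0.0, atol=1e-9)
    assert rms < 1e-12


def test_superpose_recovers_known_transform():
    ref = _anchors(12, seed=1)
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    shift = np.array([1.0, 2.0, 3.0])
    mobile = {k: Rz @ v + shift for k, v in ref.items()}
    R, t, rms = superpose(mobile, ref)
    assert rms < 1e-9
    assert np.allclose(R, Rz.T, atol=1e-9)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


def test_superpose_uses_only_common_anchors():
    ref = _anchors(20, seed=2)
    mobile = {k: v + 1.0 for k, v in list(ref.items())[:10]}
    # disjoint extras on the mobile side must be ignored
    mobile.update({("B", i, " "): np.zeros(3) for i in range(10)})
    R, t, rms = superpose(mobile, ref)
    assert rms < 1e-9  # pure translation on the 10 shared anchors


def test_superpose_insufficient_anchors():
    with pytest.raises(InsufficientAnchorsError):
        superpose(_anchors(2), _anchors(2, seed=5))


@pytest.mark.parametrize("seed", range(20))
def test_superpose_proper_rotation_on_degenerate_sets(seed):
    """det = +1 even for near-planar and mirror-degenerate anchor sets."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 8))
    pts = rng.uniform(-5, 5, (n, 3))
    pts[:, 2] *= 1e-9  # near-planar
    ref = {i: p for i, p in enumerate(pts)}
    mirrored = {i: p * np.array([1.0, 1.0, -1.0]) for i, p in enumerate(pts)}
    R, _, _ = superpose(mirrored, ref)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# hypothesis JSON round trip


@pytest.mark.parametrize("seed", range(100))
def test_hypothesis_json_round_trip(tmp_path, seed):
    h = random_hypothesis(np.random.default_rng(seed))
    path = tmp_path / "h.json"
    write_hypothesis(h, path)
    back = read_hypothesis(path)
    assert back.id == h.id and back.frame == h.frame
    assert back.min_fraction == h.min_fraction and back.tolerance == h.tolerance
    assert len(back.sites) == len(h.sites)
    for a, b in zip(back.sites, h.sites):
        assert a.type == b.type
        assert np.allclose(a.position, b.position, rtol=0, atol=1e-12)
        assert a.radius == b.radius and a.support == b.support
        if b.direction is None:
            assert a.direction is None
        else:
            assert np.allclose(a.direction, b.direction, atol=1e-12)


def test_hypothesis_missing_radius_names_field(tmp_path):
    h = random_hypothesis(np.random.default_rng(0), n_sites=2)
    path = tmp_path / "h.json"
    write_hypothesis(h, path)
    import json

    doc = json.loads(path.read_text())
    del doc["sites"][0]["radius"]
    path.write_text(json.dumps(doc))
    with pytest.raises(HypothesisFormatError, match="radius"):
        read_hypothesis(path)


def test_hypothesis_empty_sites_rejected(tmp_path):
    path = tmp_path / "h.json"
    path.write_text(
        '{"id": "x", "frame": "f", "build_params": {"min_fraction": 0.5, "tolerance": 2.0}, "sites": []}'
    )
    with pytest.raises(HypothesisFormatError):
        read_hypothesis(path)
    with pytest.raises(ValueError):
        Hypothesis(id="x", frame="f", sites=[], min_fraction=0.5, tolerance=2.0)


def test_sites_are_canonically_ordered():
    rng = np.random.default_rng(42)
    h = random_hypothesis(rng, n_sites=6)
    keys = [s.sort_key() for s in h.sites]
    assert keys == sorted(keys)
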