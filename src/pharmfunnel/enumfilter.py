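"""Combinatorial amide library enumeration and drug-likeness filtering.

A scaffold carboxylic acid is condensed with each primary/secondary amine of
a building-block list to give one amide per (scaffold, amine) pair; products
are canonicalized and deduplicated. Drug-likeness uses Lipinski's rule of
five: MW <= 500 Da, logP <= 5 (Crippen atom-contribution estimate),
H-bond donors <= 5 (N/O-H heavy atoms), H-bond acceptors <= 10 (N + O count).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from rdkit import Chem
from rdkit.Chem import AllChem, Crippen, Descriptors, Lipinski

logger = logging.getLogger(__name__)

#: the three quinazolinedione scaffold acids with 5-, 6-, 7-carbon N3 chains
SCAFFOLD_ACIDS: dict[str, str] = {
    "2a": "OC(=O)CCCCN1C(=O)Nc2ccccc2C1=O",
    "2b": "OC(=O)CCCCCN1C(=O)Nc2ccccc2C1=O",
    "2c": "OC(=O)CCCCCCN1C(=O)Nc2ccccc2C1=O",
}

_ACID_PATTERN = Chem.MolFromSmarts("[CX3](=O)[OX2H1]")
# couplable amine N: primary/secondary, not amide/sulfonamide, not aromatic n
_AMINE_PATTERN = Chem.MolFromSmarts(
    "[NX3;H2,H1;!$(N=*);!$(N[C,S]=[O,S,N]);!$([N]#*);!$([n])]"
)
_AMIDATION = AllChem.ReactionFromSmarts(
    "[C:1](=[O:2])[OX2H1].[NX3;H2,H1;!$(N=*);!$(N[C,S]=[O,S,N]);!$([n]):3]"
    ">>[C:1](=[O:2])[N:3]"
)


@dataclass(frozen=True)
class Scaffold:
    """A scaffold acid with exactly one carboxylic-acid coupling site."""

    id: str
    smiles: str

    def __post_init__(self) -> None:
        mol = Chem.MolFromSmiles(self.smiles)
        if mol is None:
            raise ValueError(f"scaffold {self.id}: SMILES does not parse")
        n_acid = len(mol.GetSubstructMatches(_ACID_PATTERN))
        if n_acid != 1:
            raise ValueError(
                f"scaffold {self.id}: expected exactly one -C(=O)OH group, found {n_acid}"
            )

    @property
    def mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.smiles)


@dataclass(frozen=True)
class LipinskiRecord:
    """Rule-of-five descriptors and the number of rules broken."""

    mw: float
    logp: float
    hbd: int
    hba: int
    violations: int


def default_scaffolds() -> list[Scaffold]:
    return [Scaffold(sid, smi) for sid, smi in SCAFFOLD_ACIDS.items()]


def _canonical_amine(smiles: str) -> Chem.Mol | None:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None or not mol.HasSubstructMatch(_AMINE_PATTERN):
        return None
    # renumber atoms canonically so "first amine site" is reproducible
    order = Chem.CanonicalRankAtoms(mol, breakTies=True)
    perm = [0] * mol.GetNumAtoms()
    for i, r in enumerate(order):
        perm[r] = i
    return Chem.RenumberAtoms(mol, perm)


def enumerate_products(
    scaffolds: list[Scaffold], amines: list[str]
) -> list[str]:
    """Enumerate amide products of every (scaffold, amine) pair.

    One product per pair, coupling at the scaffold's acid and the amine's
    first couplable nitrogen by canonical atom order; products are canonical
    SMILES, deduplicated with a logged count. Amines without a couplable
    amine group are skipped with a warning.
    """
    products: list[str] = []
    seen: set[str] = set()
    duplicates = 0
    failures = 0
    scaffold_mols = [(s.id, s.mol) for s in scaffolds]
    for smi in amines:
        amine = _canonical_amine(smi)
        if amine is None:
            failures += 1
            logger.warning("skipping non-amine or unparseable building block: %s", smi)
            continue
        for sid, smol in scaffold_mols:
            results = _AMIDATION.RunReactants((smol, amine))
            if not results:
                failures += 1
                logger.warning("amidation failed for scaffold %s + %s", sid, smi)
                continue
            prod = results[0][0]  # first product = first amine site by canonical order
            try:
                Chem.SanitizeMol(prod)
            except Exception:
                failures += 1
                continue
            canon = Chem.MolToSmiles(prod)
            if canon in seen:
                duplicates += 1
                continue
            seen.add(canon)
            products.append(canon)
    logger.info(
        "enumerated %d unique products (%d duplicate(s), %d failure(s)) "
        "from %d scaffold(s) x %d building block(s)",
        len(products), duplicates, failures, len(scaffolds), len(amines),
    )
    return products


def lipinski(mol: Chem.Mol | str) -> LipinskiRecord:
    """Rule-of-five record for a molecule (SMILES or RDKit mol)."""
    if isinstance(mol, str):
        parsed = Chem.MolFromSmiles(mol)
        if parsed is None:
            raise ValueError(f"SMILES does not parse: {mol!r}")
        mol = parsed
    mw = float(Descriptors.MolWt(mol))
    logp = float(Crippen.MolLogP(mol))
    hbd = int(Lipinski.NumHDonors(mol))
    hba = int(Lipinski.NOCount(mol))
    violations = sum([mw > 500.0, logp > 5.0, hbd > 5, hba > 10])
    return LipinskiRecord(mw=mw, logp=logp, hbd=hbd, hba=hba, violations=violations)


def filter_druglike(
    mols: list[Chem.Mol | str], max_violations: int = 0
) -> list[Chem.Mol | str]:
    """Keep molecules with at most ``max_violations`` rule-of-five violations.

    Input order is preserved; pass/fail counts are logged.
    """
    passing = [m for m in mols if lipinski(m).violations <= max_violations]
    logger.info(
        "Lipinski filter (max_violations=%d): %d/%d pass",
        max_violations, len(passing), len(mols),
    )
    return passing
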