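"""Pharmacophoric feature perception on 3D conformers.

Feature types follow the common pharmacophore alphabet:

====  =========================  ==========================================
code  meaning                    default perception rule
====  =========================  ==========================================
A     H-bond acceptor            N/O with an available lone pair: carbonyl,
                                 ether/hydroxyl O, pyridine-type aromatic N
                                 without H, nitrile N; amide N and charged
                                 atoms excluded. Position at the atom;
                                 direction from the mean of bonded heavy
                                 atoms toward the atom.
D     H-bond donor               N/O bearing >= 1 hydrogen; one feature per
                                 heavy atom, direction toward the first H.
R     aromatic ring              each smallest-set aromatic ring; position
                                 at the ring-atom centroid, direction along
                                 the ring normal.
H     hydrophobic group          each maximal connected set of >= 3
                                 aliphatic carbons bonding only to C, H, or
                                 halogen; position at the set centroid, no
                                 direction.
N     negative ionizable         carboxylic acids / anions (off by default)
P     positive ionizable         aliphatic primary amines / cations (off by
                                 default)
====  =========================  ==========================================

Atom-level rules are SMARTS patterns and can be overridden from a plain-text
rule file (`load_ruleset`); ring (R) and hydrophobic-group (H) perception are
geometric/graph rules parameterized by the rule set.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chemio import FEATURE_TYPES, Molecule

logger = logging.getLogger(__name__)

HALOGENS = frozenset({9, 17, 35, 53})


class GeometryRequiredError(ValueError):
    """Raised when an operation needs 3D coordinates the molecule lacks."""


@dataclass(frozen=True)
class Feature:
    """A perceived pharmacophoric point on one ligand conformer."""

    type: str
    position: np.ndarray
    direction: np.ndarray | None
    ligand_id: str
    atom_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float).reshape(3))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float).reshape(3)
            n = float(np.linalg.norm(d))
            if abs(n - 1.0) > 1e-6:
                raise ValueError("feature direction must be unit-norm")
            object.__setattr__(self, "direction", d)
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if not self.atom_indices:
            raise ValueError("atom_indices must be non-empty")
        if not np.isfinite(self.position).all():
            raise ValueError("feature position must be finite")

    def sort_key(self) -> tuple:
        x, y, z = self.position
        return (self.type, x, y, z)


# default atom-level SMARTS per feature type; each match's first atom is the
# feature atom
DEFAULT_PATTERNS: dict[str, tuple[str, ...]] = {
    "A": (
        "[OX1;+0]",                # carbonyl / N-oxide terminal O
        "[OX2;H0;+0;!$([o])]",     # ether / ester alkoxy O
        "[OX2;H1;+0]",             # hydroxyl O
        "[nX2;H0;+0]",             # pyridine-type aromatic N
        "[NX1;+0]",                # nitrile N
    ),
    "D": (
        "[#7;!H0;+0]",
        "[#8;!H0;+0]",
    ),
    "N": (
        "[OX2H1;$([OX2H1]C=O)]",   # carboxylic acid OH
        "[O-;!$([O-][N+])]",
        "[S-]",
    ),
    "P": (
        "[NX3;H2;+0;$(N[CX4])]",   # aliphatic primary amine
        "[N+;!$([N+][O-])]",
    ),
}


@dataclass(frozen=True)
class RuleSet:
    """Perception rules: SMARTS per atom-level type plus group parameters."""

    patterns: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_PATTERNS)
    )
    hydrophobic_min_size: int = 3
    include_ionizable: bool = False

    def __post_init__(self) -> None:
        for code, pats in self.patterns.items():
            if code not in ("A", "D", "N", "P"):
                raise ValueError(f"atom-level patterns allowed only for A/D/N/P, got {code!r}")
            for p in pats:
                if Chem.MolFromSmarts(p) is None:
                    raise ValueError(f"SMARTS pattern for {code} does not compile: {p!r}")

    def compiled(self, code: str) -> list[Chem.Mol]:
        return [Chem.MolFromSmarts(p) for p in self.patterns.get(code, ())]


DEFAULT_RULES = RuleSet()


def load_ruleset(path: str | Path, base: RuleSet = DEFAULT_RULES) -> RuleSet:
    """Load SMARTS overrides from a text file.

    Each non-comment line is ``<type code> <SMARTS>``; '#' starts a comment.
    Types present in the file replace that type's patterns; absent types keep
    the ``base`` rules.
    """
    overrides: dict[str, list[str]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        # '#' begins a comment only at a token boundary (SMARTS may contain '#')
        tokens = raw.split()
        for k, tok in enumerate(tokens):
            if tok.startswith("#"):
                tokens = tokens[:k]
                break
        if not tokens:
            continue
        if len(tokens) != 2:
            raise ValueError(f"line {lineno}: expected '<type> <SMARTS>'")
        code, smarts = tokens
        overrides.setdefault(code, []).append(smarts)
    patterns = dict(base.patterns)
    patterns.update({c: tuple(v) for c, v in overrides.items()})
    return replace(base, patterns=patterns)


# ---------------------------------------------------------------------------


def _prepare(molecule: Molecule, conf_id: int) -> tuple[Chem.Mol, np.ndarray]:
    mol = molecule.mol
    if mol.GetNumConformers() == 0:
        raise GeometryRequiredError(f"{molecule.id}: no 3D coordinates")
    molH = Chem.AddHs(mol, addCoords=True)
    coords = np.array(molH.GetConformer(conf_id).GetPositions(), dtype=float)
    return molH, coords


def _unit(v: np.ndarray) -> np.ndarray | None:
    n = float(np.linalg.norm(v))
    if n < 1e-8:
        return None
    return v / n


def _atom_features(
    code: str, molH: Chem.Mol, coords: np.ndarray, rules: RuleSet, ligand_id: str
) -> list[Feature]:
    atoms: set[int] = set()
    for patt in rules.compiled(code):
        for match in molH.GetSubstructMatches(patt):
            atoms.add(match[0])
    feats = []
    for idx in sorted(atoms):
        atom = molH.GetAtomWithIdx(idx)
        direction = None
        if code == "A":
            heavy = [n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() > 1]
            if heavy:
                direction = _unit(coords[idx] - coords[heavy].mean(axis=0))
        elif code == "D":
            hs = sorted(n.GetIdx() for n in atom.GetNeighbors() if n.GetAtomicNum() == 1)
            if hs:
                direction = _unit(coords[hs[0]] - coords[idx])
        feats.append(
            Feature(code, coords[idx], direction, ligand_id, (idx,))
        )
    return feats


def _ring_normal(ring_coords: np.ndarray) -> np.ndarray | None:
    centered = ring_coords - ring_coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    normal = vt[-1]
    # deterministic sign: largest-magnitude component positive
    k = int(np.argmax(np.abs(normal)))
    if normal[k] < 0:
        normal = -normal
    return _unit(normal)


def _aromatic_ring_features(molH: Chem.Mol, coords: np.ndarray, ligand_id: str) -> list[Feature]:
    feats = []
    for ring in molH.GetRingInfo().AtomRings():
        if not all(molH.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            continue
        idx = np.array(sorted(ring))
        centroid = coords[idx].mean(axis=0)
        feats.append(Feature("R", centroid, _ring_normal(coords[idx]), ligand_id, tuple(sorted(ring))))
    return feats


def _hydrophobic_features(
    molH: Chem.Mol, coords: np.ndarray, rules: RuleSet, ligand_id: str
) -> list[Feature]:
    # members: aliphatic carbons bonding only to C/H/halogen
    member = set()
    for atom in molH.GetAtoms():
        if atom.GetAtomicNum() != 6 or atom.GetIsAromatic():
            continue
        ok = all(
            n.GetAtomicNum() in HALOGENS or n.GetAtomicNum() in (1, 6)
            for n in atom.GetNeighbors()
        )
        if ok:
            member.add(atom.GetIdx())
    # connected components among members
    feats = []
    seen: set[int] = set()
    for start in sorted(member):
        if start in seen:
            continue
        comp, stack = [], [start]
        seen.add(start)
        while stack:
            i = stack.pop()
            comp.append(i)
            for n in molH.GetAtomWithIdx(i).GetNeighbors():
                j = n.GetIdx()
                if j in member and j not in seen:
                    seen.add(j)
                    stack.append(j)
        if len(comp) >= rules.hydrophobic_min_size:
            idx = np.array(sorted(comp))
            feats.append(Feature("H", coords[idx].mean(axis=0), None, ligand_id, tuple(sorted(comp))))
    return feats


def perceive_features(
    molecule: Molecule, rules: RuleSet = DEFAULT_RULES, conf_id: int = 0
) -> list[Feature]:
    """Perceive all pharmacophoric features on one conformer.

    The molecule must carry 3D coordinates (hydrogens are added with
    coordinates if implicit). The output is sorted by (type, x, y, z) and is
    deterministic for identical input.
    """
    molH, coords = _prepare(molecule, conf_id)
    feats: list[Feature] = []
    feats += _atom_features("A", molH, coords, rules, molecule.id)
    feats += _atom_features("D", molH, coords, rules, molecule.id)
    feats += _hydrophobic_features(molH, coords, rules, molecule.id)
    feats += _aromatic_ring_features(molH, coords, molecule.id)
    if rules.include_ionizable:
        feats += _atom_features("N", molH, coords, rules, molecule.id)
        feats += _atom_features("P", molH, coords, rules, molecule.id)
    return sorted(feats, key=Feature.sort_key)


def feature_counts(
    molecule: Molecule, rules: RuleSet = DEFAULT_RULES, conf_id: int = 0
) -> dict[str, int]:
    """Tally of perceived features per type (order-independent convenience)."""
    return dict(Counter(f.type for f in perceive_features(molecule, rules, conf_id)))
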