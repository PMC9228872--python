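"""Chemical structure and hypothesis I/O.

Reads SMILES / SDF (V2000) small-molecule files, extracts HETATM ligands from
wwPDB v3.3 fixed-width PDB files, superposes structures into a common frame
via alpha-carbon anchors, and round-trips pharmacophore hypotheses as JSON.

Coordinates are Angstrom everywhere. A hypothesis lives in the crystal frame
of a named reference complex (``Hypothesis.frame``).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

from .geometry import kabsch

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.warning")

FEATURE_TYPES = ("A", "D", "H", "N", "P", "R")

#: residue names never treated as extractable ligands
WATER_CODES = frozenset({"HOH", "WAT", "DOD", "H2O"})
ION_CODES = frozenset(
    {"NA", "CL", "K", "MG", "ZN", "CA", "MN", "FE", "FE2", "CU", "CU1",
     "NI", "CO", "CD", "HG", "BR", "IOD", "CS", "LI", "SR", "BA", "RB"}
)


class EmptyInputError(ValueError):
    """Raised when a file yields zero parseable records."""


class LigandNotFoundError(KeyError):
    """Raised when a requested HET code is absent from a PDB file."""


class InsufficientAnchorsError(ValueError):
    """Raised when fewer than 3 common anchor points exist for superposition."""


class HypothesisFormatError(ValueError):
    """Raised when a hypothesis JSON document violates the schema."""


@dataclass
class Molecule:
    """A chemical graph with zero or more 3D coordinate sets.

    Thin wrapper over an RDKit ``Mol``: the chemical graph and conformers
    live on ``mol``; ``id`` and ``source`` carry record provenance.
    """

    id: str
    mol: Chem.Mol
    source: str = ""

    @property
    def num_atoms(self) -> int:
        return self.mol.GetNumAtoms()

    @property
    def num_heavy_atoms(self) -> int:
        return self.mol.GetNumHeavyAtoms()

    @property
    def conformers(self) -> list[np.ndarray]:
        """All coordinate sets as (N, 3) float arrays, Angstrom."""
        return [np.array(c.GetPositions(), dtype=float) for c in self.mol.GetConformers()]

    @property
    def num_conformers(self) -> int:
        return self.mol.GetNumConformers()

    def validate(self) -> None:
        for c in self.conformers:
            if c.shape != (self.num_atoms, 3):
                raise ValueError(f"{self.id}: conformer shape {c.shape} != ({self.num_atoms}, 3)")
            if not np.isfinite(c).all():
                raise ValueError(f"{self.id}: non-finite coordinates")


@dataclass
class Site:
    """One consensus pharmacophoric site: a typed tolerance sphere."""

    type: str
    position: np.ndarray
    radius: float
    support: float
    direction: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown site type {self.type!r}")
        if not self.radius > 0:
            raise ValueError("site radius must be > 0")
        if not 0 < self.support <= 1:
            raise ValueError("site support must be in (0, 1]")
        if self.direction is not None:
            self.direction = np.asarray(self.direction, dtype=float).reshape(3)
            norm = float(np.linalg.norm(self.direction))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError("site direction must be unit-norm")

    def sort_key(self) -> tuple:
        x, y, z = self.position
        return (-self.support, self.type, x, y, z)


@dataclass
class Hypothesis:
    """An ordered set of consensus sites in a fixed receptor frame."""

    id: str
    frame: str
    sites: list[Site]
    min_fraction: float = 0.5
    tolerance: float = 2.0

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("hypothesis must contain at least one site")
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        self.sites = sorted(self.sites, key=Site.sort_key)

    @property
    def site_types(self) -> list[str]:
        return [s.type for s in self.sites]

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float)


# ---------------------------------------------------------------------------
# small-molecule reading


def _mol_from_smiles_line(line: str, index: int, source: str) -> Molecule | None:
    parts = line.split(None, 1)
    smiles = parts[0]
    name = parts[1].strip() if len(parts) > 1 else f"mol{index}"
    rdmol = Chem.MolFromSmiles(smiles)
    if rdmol is None:
        return None
    rdmol.SetProp("_Name", name)
    return Molecule(id=name, mol=rdmol, source=source)


def read_molecules(path: str | Path, format: str) -> list[Molecule]:
    """Read all records of a SMILES or SDF file.

    SMILES records carry zero conformers; SDF records carry the file's 3D
    coordinates. Unparseable records are skipped with a logged warning and
    record order is preserved.

    Raises
    ------
    FileNotFoundError
        if ``path`` does not exist.
    EmptyInputError
        if no record parses.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format.lower()
    mols: list[Molecule] = []
    skipped = 0
    if fmt == "smiles":
        for i, raw in enumerate(path.read_text().splitlines()):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            m = _mol_from_smiles_line(line, i, f"{path}:{i + 1}")
            if m is None:
                skipped += 1
                logger.warning("skipping unparseable SMILES record at %s:%d", path, i + 1)
            else:
                mols.append(m)
    elif fmt == "sdf":
        try:
            supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        except OSError as e:
            raise EmptyInputError(f"unreadable or empty SDF {path}: {e}") from e
        for i, rdmol in enumerate(supplier):
            if rdmol is None:
                skipped += 1
                logger.warning("skipping unparseable SDF record %d in %s", i, path)
                continue
            name = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") and rdmol.GetProp("_Name") else f"mol{i}"
            mols.append(Molecule(id=name, mol=rdmol, source=f"{path}#{i}"))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'smiles' or 'sdf'")
    if not mols:
        raise EmptyInputError(f"no parseable records in {path}")
    if skipped:
        logger.warning("%d unparseable record(s) skipped in %s", skipped, path)
    return mols


# ---------------------------------------------------------------------------
# PDB ligand extraction


def extract_ligand(pdb_path: str | Path, het_code: str, chain: str | None = None) -> Molecule:
    """Extract one HETATM ligand from a PDB file, in the crystal frame.

    Bond orders are guessed from interatomic distances (RDKit proximity
    bonding); waters and monoatomic ions are never returned. If several
    copies of the ligand exist and ``chain`` is unset, the first copy by
    chain order is taken and a warning logged.
    """
    pdb_path = Path(pdb_path)
    if not pdb_path.exists():
        raise FileNotFoundError(pdb_path)
    code = het_code.strip().upper()
    if code in WATER_CODES or code in ION_CODES:
        raise LigandNotFoundError(f"{code} is a water/ion, not an extractable ligand")

    by_chain: dict[str, list[str]] = {}
    for line in pdb_path.read_text().splitlines():
        if not line.startswith("HETATM"):
            continue
        resname = line[17:20].strip().upper()
        if resname != code:
            continue
        ch = line[21]
        by_chain.setdefault(ch, []).append(line)
    if not by_chain:
        raise LigandNotFoundError(f"HET code {code} not found in {pdb_path}")

    if chain is not None:
        if chain not in by_chain:
            raise LigandNotFoundError(f"HET code {code} has no copy in chain {chain!r}")
        picked = chain
    else:
        picked = sorted(by_chain)[0]
        if len(by_chain) > 1:
            logger.warning(
                "%s: %d copies of %s (chains %s); taking chain %s",
                pdb_path.name, len(by_chain), code, ",".join(sorted(by_chain)), picked,
            )

    block = "\n".join(by_chain[picked]) + "\nEND\n"
    rdmol = Chem.MolFromPDBBlock(block, sanitize=False, removeHs=False, proximityBonding=True)
    if rdmol is None:
        raise ValueError(f"could not build a molecule from {code} records in {pdb_path}")
    try:
        Chem.SanitizeMol(rdmol)
    except Exception:  # keep raw connectivity if valence guessing fails
        Chem.SanitizeMol(rdmol, Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
    return Molecule(id=f"{code}:{picked}", mol=rdmol, source=str(pdb_path))


# ---------------------------------------------------------------------------
# superposition


def ca_anchors(pdb_path: str | Path) -> dict[tuple[str, int, str], np.ndarray]:
    """Alpha-carbon anchor points keyed by (chain, residue number, icode).

    Alternate locations take the 'A' (or blank) conformer; later duplicates
    of a key are ignored.
    """
    anchors: dict[tuple[str, int, str], np.ndarray] = {}
    for line in Path(pdb_path).read_text().splitlines():
        if not line.startswith("ATOM"):
            continue
        if line[12:16].strip() != "CA":
            continue
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        key = (line[21], int(line[22:26]), line[26])
        if key in anchors:
            continue
        anchors[key] = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])], dtype=float
        )
    return anchors


def superpose(
    mobile: Mapping[object, np.ndarray] | str | Path,
    reference: Mapping[object, np.ndarray] | str | Path,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform taking ``mobile`` onto ``reference``.

    Both arguments are either mappings from anchor labels to 3-vectors, or
    PDB paths (anchored on alpha-carbons via :func:`ca_anchors`). Anchors are
    paired by label; at least 3 common labels are required. Returns
    ``(rotation, translation, rmsd)`` with a proper rotation (det = +1).
    """
    if not isinstance(mobile, Mapping):
        mobile = ca_anchors(mobile)
    if not isinstance(reference, Mapping):
        reference = ca_anchors(reference)
    common = sorted(set(mobile) & set(reference), key=repr)
    if len(common) < 3:
        raise InsufficientAnchorsError(
            f"only {len(common)} common anchor point(s); need at least 3"
        )
    P = np.array([mobile[k] for k in common], dtype=float)
    Q = np.array([reference[k] for k in common], dtype=float)
    return kabsch(P, Q)


# ---------------------------------------------------------------------------
# hypothesis JSON round trip


def write_hypothesis(h: Hypothesis, path: str | Path) -> None:
    """Serialize a hypothesis to the JSON schema (positions at full precision)."""
    doc = {
        "id": h.id,
        "frame": h.frame,
        "build_params": {"min_fraction": h.min_fraction, "tolerance": h.tolerance},
        "sites": [
            {
                "type": s.type,
                "position": [float(x) for x in s.position],
                "radius": float(s.radius),
                "support": float(s.support),
                "direction": None if s.direction is None else [float(x) for x in s.direction],
            }
            for s in h.sites
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def _require(doc: Mapping, key: str, context: str):
    if key not in doc:
        raise HypothesisFormatError(f"missing field {key!r} in {context}")
    return doc[key]


def read_hypothesis(path: str | Path) -> Hypothesis:
    """Read a hypothesis JSON document, validating the schema.

    Raises :class:`HypothesisFormatError` naming the offending field on any
    schema violation (including an empty sites list).
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise HypothesisFormatError(f"not valid JSON: {e}") from e
    hid = _require(doc, "id", "hypothesis")
    frame = _require(doc, "frame", "hypothesis")
    params = _require(doc, "build_params", "hypothesis")
    min_fraction = _require(params, "min_fraction", "build_params")
    tolerance = _require(params, "tolerance", "build_params")
    raw_sites = _require(doc, "sites", "hypothesis")
    if not isinstance(raw_sites, list) or not raw_sites:
        raise HypothesisFormatError("field 'sites' must be a non-empty list")
    sites = []
    for i, rs in enumerate(raw_sites):
        ctx = f"sites[{i}]"
        try:
            sites.append(
                Site(
                    type=_require(rs, "type", ctx),
                    position=_require(rs, "position", ctx),
                    radius=_require(rs, "radius", ctx),
                    support=_require(rs, "support", ctx),
                    direction=rs.get("direction"),
                )
            )
        except (TypeError, ValueError) as e:
            if isinstance(e, HypothesisFormatError):
                raise
            raise HypothesisFormatError(f"invalid {ctx}: {e}") from e
    try:
        return Hypothesis(
            id=hid, frame=frame, sites=sites,
            min_fraction=min_fraction, tolerance=tolerance,
        )
    except (TypeError, ValueError) as e:
        raise HypothesisFormatError(str(e)) from e
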