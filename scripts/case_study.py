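#!/usr/bin/env python
"""Rebuild a consensus pharmacophore from soluble-epoxide-hydrolase co-crystals.

NOT part of the test suite: this driver downloads 20 PDB entries from RCSB
(network required), so it is a convenience script for users who want to
reproduce the crystal-structure case study end to end:

1. download the complexes and superpose each onto the 5AI5 reference frame
   via shared alpha-carbon anchors;
2. extract each co-crystal ligand (largest HETATM residue unless a HET code
   is given), transform it into the reference frame, and perceive features;
3. build consensus hypotheses at loose (0.25 / 2.5 A) and default
   (0.5 / 2.0 A) parameters;
4. screen an example flexible quinazolinedione pentanamide against the
   loose model over a 50-conformer ensemble.

Chain/copy selection is the first copy by chain order (logged); protonation
is RDKit's default perception. Both choices are deliberate simplifications
and are printed with the results.

Usage:
    python scripts/case_study.py --out-dir scratch/case_study [--pdb-dir DIR]
"""

from __future__ import annotations

import argparse
import logging
import urllib.request
from pathlib import Path

import numpy as np
from rdkit import Chem

from pharmfunnel import (
    BuildParams,
    LigandSet,
    MatchParams,
    Molecule,
    build_hypothesis,
    perceive_features,
    screen_conformers,
    superpose,
    write_hypothesis,
)
from pharmfunnel.chemio import ca_anchors, extract_ligand
from pharmfunnel.features import DEFAULT_RULES, load_ruleset
from pharmfunnel.geometry import apply_transform

logging.basicConfig(level=logging.INFO)
log = logging.getLogger("case_study")

PDB_IDS = [
    "1EK2", "1VJ5", "3ANS", "3ANT", "3WKE", "4HAI", "4OCZ", "4OD0", "5AI5",
    "5AK5", "5AKE", "5ALG", "5ALP", "5ALU", "5ALZ", "5AM1", "6AUM", "6FR2",
    "6HGX", "6YL4",
]
REFERENCE = "5AI5"

#: example flexible screening compound: a quinazolinedione pentanamide of
#: 3-aminopyridine (negative-control analogue)
EXAMPLE_COMPOUND = "O=C(Nc1cccnc1)CCCCN1C(=O)Nc2ccccc2C1=O"

_SKIP_HET = {"HOH", "WAT", "DOD", "SO4", "PO4", "GOL", "EDO", "PEG", "ACT",
             "DMS", "FMT", "MPD", "TRS", "NO3", "CIT", "EPE", "MES", "PG4",
             "NA", "CL", "K", "MG", "ZN", "CA"}


def fetch(pdb_id: str, pdb_dir: Path) -> Path:
    path = pdb_dir / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        log.info("downloading %s", url)
        urllib.request.urlretrieve(url, path)
    return path


def largest_het_code(pdb_path: Path) -> str | None:
    counts: dict[str, int] = {}
    for line in pdb_path.read_text().splitlines():
        if line.startswith("HETATM"):
            res = line[17:20].strip().upper()
            if res not in _SKIP_HET:
                counts[res] = counts.get(res, 0) + 1
    return max(counts, key=counts.get) if counts else None


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--pdb-dir", type=Path, default=Path("scratch/pdb"))
    ap.add_argument("--out-dir", type=Path, default=Path("scratch/case_study"))
    ap.add_argument("--rules", type=Path, help="SMARTS rule-set override file")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.pdb_dir.mkdir(parents=True, exist_ok=True)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    rules = load_ruleset(args.rules) if args.rules else DEFAULT_RULES

    ref_path = fetch(REFERENCE, args.pdb_dir)
    ref_anchors = ca_anchors(ref_path)
    ligands = []
    for pdb_id in PDB_IDS:
        try:
            path = fetch(pdb_id, args.pdb_dir)
            het = largest_het_code(path)
            if het is None:
                log.warning("%s: no candidate ligand, skipping", pdb_id)
                continue
            lig = extract_ligand(path, het)
            R, t, rms = superpose(ca_anchors(path), ref_anchors)
            log.info("%s: ligand %s, CA-superposition rmsd %.2f A", pdb_id, het, rms)
            conf = lig.mol.GetConformer()
            for i, p in enumerate(apply_transform(lig.conformers[0], R, t)):
                conf.SetAtomPosition(i, tuple(p))
            feats = perceive_features(Molecule(pdb_id, lig.mol), rules)
            ligands.append((pdb_id, feats))
        except Exception as e:  # per-entry failures must not kill the run
            log.warning("%s: skipped (%s)", pdb_id, e)

    log.info("%d/%d ligands perceived", len(ligands), len(PDB_IDS))
    ligset = LigandSet(ligands=ligands, frame=REFERENCE)
    for tag, params in (
        ("loose", BuildParams(0.25, 2.5)),
        ("default", BuildParams(0.5, 2.0)),
    ):
        hyp = build_hypothesis(ligset, params, hypothesis_id=f"seh-{tag}")
        out = args.out_dir / f"hypothesis_{tag}.json"
        write_hypothesis(hyp, out)
        print(f"{tag} ({params.min_fraction}, {params.tolerance} A): "
              f"{len(hyp.sites)} site(s) {''.join(s.type for s in hyp.sites)} -> {out}")

    loose = build_hypothesis(ligset, BuildParams(0.25, 2.5))
    compound = Molecule("example", Chem.MolFromSmiles(EXAMPLE_COMPOUND))
    res = screen_conformers(
        compound, loose,
        MatchParams(min_match=3, max_confs=50, seed=args.seed), rules,
    )
    if res is None:
        print("example compound: no conformer matches >= 3 sites")
    else:
        print(f"example compound: best {res.matched_count}/{len(loose.sites)} sites, "
              f"fit score {res.fit_score:.2f} (conformer {res.conformer_id})")


if __name__ == "__main__":
    main()
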