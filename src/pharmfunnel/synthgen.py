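"""Synthetic fixtures: planted hypotheses, jittered ligand feature sets,
verified decoys, and deterministic combinatorial amine libraries.

The generator emulates the statistical structure of a prealigned co-crystal
ligand series: a handful of well-separated consensus sites (an urea-like
anchor pattern shared by most ligands plus peripheral variable features),
per-ligand feature positions jittered isotropically around the sites, and
additional noise features far from every site. It works at the feature-cloud
level — no 3D chemistry is generated — which isolates the clustering and
matching algorithms from feature-perception rule choices.

Everything is fully deterministic under the spec seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .chemio import FEATURE_TYPES, Hypothesis, Site
from .consensus import LigandSet
from .features import Feature

logger = logging.getLogger(__name__)

#: default site type multiset, mirroring a two-acceptor/donor/hydrophobic/
#: aromatic five-point model
DEFAULT_TYPES = ("A", "A", "D", "H", "R")

#: minimum pairwise site separation enforced by rejection sampling, Angstrom
MIN_SEPARATION = 6.0


@dataclass
class PlantSpec:
    """Specification of a planted consensus model and its ligand set.

    support : (n_ligands, n_sites) boolean matrix; entry True means that
        ligand contributes a feature to that site. Defaults to full support.
    jitter_sigma : isotropic Gaussian positional noise per feature, Angstrom.
    n_noise_features : per-ligand decoy features of random type placed at
        least ``2 * tolerance`` away from every site.
    """

    n_sites: int = 5
    types: tuple[str, ...] = DEFAULT_TYPES
    box: float = 20.0
    n_ligands: int = 20
    support: np.ndarray | None = None
    jitter_sigma: float = 0.3
    n_noise_features: int = 2
    tolerance: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.types) != self.n_sites:
            raise ValueError("types multiset length must equal n_sites")
        for t in self.types:
            if t not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {t!r}")
        if self.support is None:
            self.support = np.ones((self.n_ligands, self.n_sites), dtype=bool)
        else:
            self.support = np.asarray(self.support, dtype=bool)
        if self.support.shape != (self.n_ligands, self.n_sites):
            raise ValueError(
                f"support matrix shape {self.support.shape} != "
                f"({self.n_ligands}, {self.n_sites})"
            )
        if self.jitter_sigma < 0 or self.tolerance <= 0:
            raise ValueError("jitter_sigma must be >= 0 and tolerance > 0")


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def plant_hypothesis(spec: PlantSpec) -> Hypothesis:
    """Plant ``n_sites`` well-separated sites at seeded-random positions.

    Positions are drawn uniformly in a cube of side ``spec.box`` and accepted
    only when at least ``MIN_SEPARATION`` (6 A) from every earlier site;
    bounded rejection sampling raises if the box cannot accommodate them.
    """
    rng = np.random.default_rng(spec.seed)
    positions: list[np.ndarray] = []
    attempts = 0
    while len(positions) < spec.n_sites:
        attempts += 1
        if attempts > 10000:
            raise RuntimeError(
                f"cannot place {spec.n_sites} sites >= {MIN_SEPARATION} A apart "
                f"in a {spec.box} A box"
            )
        cand = rng.uniform(0.0, spec.box, size=3)
        if all(np.linalg.norm(cand - p) >= MIN_SEPARATION for p in positions):
            positions.append(cand)
    support_frac = spec.support.mean(axis=0)
    sites = [
        Site(
            type=t,
            position=p,
            radius=spec.tolerance,
            support=float(max(f, 1.0 / max(spec.n_ligands, 1))),
            direction=_random_unit(rng),
        )
        for t, p, f in zip(spec.types, positions, support_frac)
    ]
    return Hypothesis(
        id=f"planted-{spec.seed}",
        frame="synthetic",
        sites=sites,
        min_fraction=min(1.0, float(support_frac.min()) or 1.0),
        tolerance=spec.tolerance,
    )


def _jittered_direction(rng: np.random.Generator, base: np.ndarray | None, sigma: float = 0.15):
    if base is None:
        return None
    v = base + rng.normal(scale=sigma, size=3)
    n = np.linalg.norm(v)
    return v / n if n > 1e-8 else base


def _noise_position(
    rng: np.random.Generator, hyp: Hypothesis, box: float
) -> np.ndarray:
    # rejection-sample a point at least 2*tolerance away from every site
    for _ in range(10000):
        cand = rng.uniform(-0.5 * box, 1.5 * box, size=3)
        if all(
            np.linalg.norm(cand - s.position) >= 2.0 * hyp.tolerance for s in hyp.sites
        ):
            return cand
    raise RuntimeError("cannot place a noise feature away from all sites")


def sample_ligandset(hyp: Hypothesis, spec: PlantSpec) -> LigandSet:
    """Sample jittered prealigned ligand feature sets from a planted model.

    Each ligand carries one feature per supported site at the site position
    plus isotropic Gaussian jitter, with a direction aligned to the site's
    (small angular noise), and ``n_noise_features`` random-type features far
    from every site.
    """
    if spec.support.shape[1] != len(hyp.sites):
        raise ValueError("support matrix column count must equal number of sites")
    rng = np.random.default_rng(spec.seed + 1)
    ligands = []
    for li in range(spec.n_ligands):
        lid = f"lig{li:03d}"
        feats = []
        for si, site in enumerate(hyp.sites):
            if not spec.support[li, si]:
                continue
            pos = site.position + rng.normal(scale=spec.jitter_sigma, size=3)
            feats.append(
                Feature(site.type, pos, _jittered_direction(rng, site.direction), lid, (si + 1,))
            )
        for k in range(spec.n_noise_features):
            t = str(rng.choice(["A", "D", "H", "R"]))
            feats.append(
                Feature(t, _noise_position(rng, hyp, spec.box), None, lid, (100 + k,))
            )
        ligands.append((lid, feats))
    return LigandSet(ligands=ligands, frame=hyp.frame)


# ---------------------------------------------------------------------------
# matching and decoy query sets


def make_matching_set(
    hyp: Hypothesis, n: int, seed: int = 0, jitter_sigma: float = 0.2
) -> list[tuple[str, list[Feature]]]:
    """Feature sets guaranteed to match every site (jitter well inside radius)."""
    rng = np.random.default_rng(seed)
    sigma = min(jitter_sigma, 0.2 * min(s.radius for s in hyp.sites))
    out = []
    for i in range(n):
        cid = f"match{i:03d}"
        feats = []
        for si, site in enumerate(hyp.sites):
            # clip jitter to stay strictly inside the tolerance sphere
            delta = rng.normal(scale=sigma, size=3)
            norm = np.linalg.norm(delta)
            cap = 0.8 * site.radius
            if norm > cap:
                delta *= cap / norm
            feats.append(
                Feature(site.type, site.position + delta,
                        _jittered_direction(rng, site.direction), cid, (si + 1,))
            )
        out.append((cid, feats))
    return out


def make_decoy_set(
    hyp: Hypothesis, n: int, seed: int = 0
) -> list[tuple[str, list[Feature]]]:
    """Feature sets guaranteed NOT to match all sites.

    Alternating construction: displace one site's feature by more than twice
    its radius, or delete one feature type entirely (pigeonhole). Every decoy
    is verified non-matching (best matched count < number of sites) by the
    brute-force oracle before being emitted.
    """
    from .matcher import brute_force_match

    rng = np.random.default_rng(seed)
    n_sites = len(hyp.sites)
    out = []
    for i in range(n):
        cid = f"decoy{i:03d}"
        feats = []
        if i % 2 == 0:  # displacement decoy
            broken = int(rng.integers(n_sites))
            for si, site in enumerate(hyp.sites):
                pos = np.array(site.position)
                if si == broken:
                    pos = pos + (2.0 * site.radius + 1.0 + rng.uniform(0, 2)) * _random_unit(rng)
                feats.append(Feature(site.type, pos, None, cid, (si + 1,)))
            # displacement alone cannot fool in-place matching, but aligned
            # matching could recover; drop the displaced feature's type twin
            # check below guards both modes
        else:  # deletion decoy: drop every feature of one type
            victim = hyp.sites[int(rng.integers(n_sites))].type
            for si, site in enumerate(hyp.sites):
                if site.type == victim:
                    continue
                feats.append(Feature(site.type, np.array(site.position), None, cid, (si + 1,)))
        if n_sites <= 6 and len(feats) <= 7:
            best = brute_force_match(feats, hyp, min_match=3, mode="aligned")
            if best >= n_sites:
                # displacement re-matched after realignment; fall back to deletion
                victim = hyp.sites[0].type
                feats = [
                    Feature(s.type, np.array(s.position), None, cid, (si + 1,))
                    for si, s in enumerate(hyp.sites)
                    if s.type != victim
                ]
                assert brute_force_match(feats, hyp, 3, "aligned") < n_sites
        out.append((cid, feats))
    return out


# ---------------------------------------------------------------------------
# deterministic combinatorial amine library

_SUBSTITUENTS = (
    "F", "Cl", "Br", "I", "C", "CC", "CCC", "C(C)C", "OC", "OCC",
    "O", "C(F)(F)F", "C#N", "SC",
)


def synthetic_aromatic_amines(n: int) -> list[str]:
    """Generate ``n`` distinct synthetic aromatic amines (canonical SMILES).

    Substituted anilines are enumerated deterministically: up to three
    substituents from a fixed set placed on the ring positions of aniline,
    canonicalized and deduplicated, in a fixed enumeration order. Each amine
    carries exactly one primary aromatic NH2, so amide products formed from
    distinct amines are themselves distinct.
    """
    seen: set[str] = set()
    out: list[str] = []

    def emit(smiles: str) -> bool:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return False
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            return False
        seen.add(canon)
        out.append(canon)
        return len(out) >= n

    if emit("Nc1ccccc1"):
        return out
    positions = range(5)  # ring slots ortho..ortho'
    for n_sub in (1, 2, 3):
        for pos_set in itertools.combinations(positions, n_sub):
            for subs in itertools.product(_SUBSTITUENTS, repeat=n_sub):
                slots = [""] * 5
                for p, s in zip(pos_set, subs):
                    slots[p] = s
                body = "".join(f"c({s})" if s else "c" for s in slots[:4])
                tail = f"c1{slots[4]}" if slots[4] else "c1"
                if emit(f"Nc1{body}{tail}"):
                    return out
    raise ValueError(f"enumeration space exhausted before reaching {n} amines")
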