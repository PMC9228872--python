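"""Matching conformers and poses against a pharmacophore hypothesis.

Two modes mirror the two stages of a screening funnel:

``aligned``
    The query may sit in any frame. A correspondence graph is built whose
    nodes are type-compatible (feature, site) pairs and whose edges require
    the internal distances to agree within the sum of the two site radii (a
    triangle-inequality bound, so no feasible assignment is pruned). Cliques
    of sufficient size are superposed onto the sites by Kabsch and verified:
    every matched feature must land inside its site's tolerance sphere.

``inplace``
    The query is already in the hypothesis frame (e.g. a docking pose). The
    maximum-cardinality, minimum-total-distance injective type-respecting
    assignment is found by optimal bipartite matching; no realignment and no
    conformational search.

A brute-force enumerator over all injective type-respecting assignments
serves as the test oracle for both modes.

Direction vectors never affect match feasibility (no angular tolerance is
imposed); they only enter the fit score.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdMolAlign
from scipy.optimize import linear_sum_assignment

from .chemio import Hypothesis, Molecule
from .features import Feature
from .geometry import apply_transform, kabsch

logger = logging.getLogger(__name__)

__all__ = [
    "MatchParams", "MatchResult", "generate_conformers", "match_inplace",
    "match_aligned", "fit_score", "kabsch", "brute_force_match",
    "screen_conformers",
]

#: infeasible-edge cost; dwarfs any achievable sum of pair distances so the
#: Hungarian solution maximizes cardinality before minimizing distance
_INFEASIBLE = 1.0e9

#: heavy-atom RMSD below which two conformers are considered duplicates
DUPLICATE_RMSD = 0.5


@dataclass(frozen=True)
class MatchParams:
    """Screening-stage matching parameters."""

    min_match: int = 3
    mode: str = "aligned"
    max_confs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_match < 3:
            raise ValueError("min_match must be >= 3")
        if self.mode not in ("aligned", "inplace"):
            raise ValueError("mode must be 'aligned' or 'inplace'")
        if self.max_confs < 1:
            raise ValueError("max_confs must be >= 1")


@dataclass
class MatchResult:
    """An injective feature-to-site assignment with its alignment and score."""

    assignment: list[tuple[int, int]]
    rotation: np.ndarray
    translation: np.ndarray
    pair_distances: list[float]
    matched_count: int
    rmsd_match: float
    fit_score: float
    conformer_id: int | str | None = None
    pair_cosines: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        fi = [a for a, _ in self.assignment]
        si = [b for _, b in self.assignment]
        if len(set(fi)) != len(fi) or len(set(si)) != len(si):
            raise ValueError("assignment must be injective in both coordinates")
        if self.matched_count != len(self.assignment):
            raise ValueError("matched_count must equal |assignment|")
        if not 0.0 <= self.fit_score <= 1.0 + 1e-12:
            raise ValueError("fit_score must lie in [0, 1]")

    def summary(self) -> dict:
        return {
            "matched_count": self.matched_count,
            "rmsd_match": self.rmsd_match,
            "fit_score": self.fit_score,
            "conformer_id": self.conformer_id,
        }


# ---------------------------------------------------------------------------
# conformer generation


def generate_conformers(molecule: Molecule, max_confs: int = 50, seed: int = 0) -> Molecule:
    """Generate up to ``max_confs`` relaxed conformers (deterministic per seed).

    Distance-geometry embedding (ETKDGv3) followed by MMFF relaxation;
    near-duplicate conformers (heavy-atom RMSD < 0.5 A after optimal
    superposition) are pruned, keeping the lower-energy member. An embedding
    failure yields a molecule with zero conformers and a logged warning, not
    an exception.
    """
    mol = Chem.AddHs(Chem.Mol(molecule.mol))
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    params.numThreads = 1
    ids = AllChem.EmbedMultipleConfs(mol, numConfs=int(max_confs), params=params)
    if len(ids) == 0:
        logger.warning("%s: conformer embedding failed", molecule.id)
        out = Chem.RemoveHs(mol)
        out.RemoveAllConformers()
        return Molecule(id=molecule.id, mol=out, source=molecule.source)
    energies = []
    results = AllChem.MMFFOptimizeMoleculeConfs(mol, maxIters=500)
    for conf_id, (converged, energy) in zip(ids, results):
        energies.append((float(energy) if energy is not None else np.inf, int(conf_id)))
    energies.sort()

    heavy = Chem.RemoveHs(Chem.Mol(mol))
    kept: list[int] = []
    for _, cid in energies:
        dup = False
        for kcid in kept:
            if rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=kcid) < DUPLICATE_RMSD:
                dup = True
                break
        if not dup:
            kept.append(cid)
    out = Chem.RemoveHs(Chem.Mol(mol))
    out.RemoveAllConformers()
    for new_id, cid in enumerate(kept):
        conf = Chem.Conformer(heavy.GetConformer(cid))
        conf.SetId(new_id)
        out.AddConformer(conf, assignId=False)
    return Molecule(id=molecule.id, mol=out, source=molecule.source)


# ---------------------------------------------------------------------------
# scoring


def _score(rmsd_match: float, tolerance: float, cosines: list[float]) -> float:
    pos = max(0.0, 1.0 - rmsd_match / tolerance)
    if cosines:
        v = float(np.mean([max(0.0, c) for c in cosines]))
    else:
        v = 1.0
    return 0.5 * pos + 0.5 * v


def fit_score(result: MatchResult, hyp: Hypothesis) -> float:
    """Dimensionless fit in [0, 1].

    ``0.5 * max(0, 1 - rmsd/tolerance) + 0.5 * V`` where V averages
    ``max(0, cos theta)`` over matched pairs carrying directions on both
    sides (V = 1 when no such pair exists).
    """
    return _score(result.rmsd_match, hyp.tolerance, result.pair_cosines)


def _pair_cosines(
    features: list[Feature],
    hyp: Hypothesis,
    assignment: list[tuple[int, int]],
    rotation: np.ndarray,
) -> list[float]:
    cosines = []
    for fi, si in assignment:
        fd = features[fi].direction
        sd = hyp.sites[si].direction
        if fd is None or sd is None:
            continue
        cosines.append(float(np.clip(np.dot(rotation @ fd, sd), -1.0, 1.0)))
    return cosines


def _build_result(
    features: list[Feature],
    hyp: Hypothesis,
    assignment: list[tuple[int, int]],
    rotation: np.ndarray,
    translation: np.ndarray,
    conformer_id=None,
) -> MatchResult:
    dists = []
    for fi, si in assignment:
        p = apply_transform(features[fi].position[None, :], rotation, translation)[0]
        dists.append(float(np.linalg.norm(p - hyp.sites[si].position)))
    rmsd_match = float(np.sqrt(np.mean(np.square(dists)))) if dists else 0.0
    cosines = _pair_cosines(features, hyp, assignment, rotation)
    score = _score(rmsd_match, hyp.tolerance, cosines)
    for d, (fi, si) in zip(dists, assignment):
        if d > hyp.sites[si].radius + 1e-9:
            raise AssertionError("internal error: reported pair distance exceeds site radius")
    return MatchResult(
        assignment=sorted(assignment),
        rotation=rotation,
        translation=translation,
        pair_distances=dists,
        matched_count=len(assignment),
        rmsd_match=rmsd_match,
        fit_score=score,
        conformer_id=conformer_id,
        pair_cosines=cosines,
    )


# ---------------------------------------------------------------------------
# in-place matching


def match_inplace(
    features: list[Feature], hyp: Hypothesis, min_match: int = 3
) -> MatchResult | None:
    """Match a pose already in the hypothesis frame (no realignment).

    Maximum-cardinality injective type-respecting assignment with every pair
    distance within its site radius; among maximum-cardinality assignments
    the minimum total distance is taken (optimal bipartite matching).
    Returns ``None`` if fewer than ``min_match`` sites can be matched.
    """
    nf, ns = len(features), len(hyp.sites)
    if nf == 0 or ns == 0:
        return None
    dim = max(nf, ns)
    cost = np.full((dim, dim), _INFEASIBLE, dtype=float)
    for i, f in enumerate(features):
        for j, s in enumerate(hyp.sites):
            if f.type != s.type:
                continue
            d = float(np.linalg.norm(f.position - s.position))
            if d <= s.radius:
                cost[i, j] = d
    rows, cols = linear_sum_assignment(cost)
    assignment = [
        (int(i), int(j))
        for i, j in zip(rows, cols)
        if i < nf and j < ns and cost[i, j] < _INFEASIBLE
    ]
    if len(assignment) < min_match:
        return None
    return _build_result(features, hyp, assignment, np.eye(3), np.zeros(3))


# ---------------------------------------------------------------------------
# aligned matching (correspondence-graph clique search)


def _correspondence_graph(features: list[Feature], hyp: Hypothesis) -> nx.Graph:
    g = nx.Graph()
    nodes = [
        (i, j)
        for i, f in enumerate(features)
        for j, s in enumerate(hyp.sites)
        if f.type == s.type
    ]
    g.add_nodes_from(nodes)
    for a in range(len(nodes)):
        i1, j1 = nodes[a]
        for b in range(a + 1, len(nodes)):
            i2, j2 = nodes[b]
            if i1 == i2 or j1 == j2:
                continue
            df = np.linalg.norm(features[i1].position - features[i2].position)
            ds = np.linalg.norm(hyp.sites[j1].position - hyp.sites[j2].position)
            slack = hyp.sites[j1].radius + hyp.sites[j2].radius
            if abs(df - ds) <= slack:
                g.add_edge(nodes[a], nodes[b])
    return g


def _verify_assignment(
    features: list[Feature], hyp: Hypothesis, nodes: tuple[tuple[int, int], ...]
) -> MatchResult | None:
    """Kabsch-superpose the candidate pairs onto their sites and verify."""
    if len(nodes) < 3:
        return None
    P = np.array([features[i].position for i, _ in nodes])
    Q = np.array([hyp.sites[j].position for _, j in nodes])
    R, t, _ = kabsch(P, Q)
    moved = apply_transform(P, R, t)
    for (fi, si), p in zip(nodes, moved):
        if np.linalg.norm(p - hyp.sites[si].position) > hyp.sites[si].radius:
            return None
    return _build_result(features, hyp, list(nodes), R, t)


def match_aligned(
    features: list[Feature], hyp: Hypothesis, min_match: int = 3
) -> MatchResult | None:
    """Match a query in an arbitrary frame by clique search + superposition.

    Maximal cliques of the correspondence graph are examined largest-first;
    a clique verifies when Kabsch superposition places every matched feature
    inside its site's tolerance sphere. Because the distance-compatibility
    edge test is necessary but not sufficient, a failing clique's subsets
    are also examined (branch-and-bound on the best verified size) so that
    no feasible assignment is missed. The best verified result by
    (matched_count, fit_score, lexicographic assignment) is returned, or
    ``None`` if nothing of size >= ``min_match`` verifies.
    """
    if min_match < 3:
        raise ValueError("aligned matching requires min_match >= 3 (rigid superposition)")
    g = _correspondence_graph(features, hyp)
    if g.number_of_nodes() < min_match:
        return None
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(g) if len(c) >= min_match]
    cliques.sort(key=lambda c: (-len(c), c))
    best: MatchResult | None = None
    tried: set[tuple] = set()
    for clique in cliques:
        floor = max(min_match, best.matched_count if best else 0)
        if len(clique) < floor:
            continue
        for size in range(len(clique), floor - 1, -1):
            found_at_size = False
            for subset in itertools.combinations(clique, size):
                if subset in tried:
                    continue
                tried.add(subset)
                res = _verify_assignment(features, hyp, subset)
                if res is None:
                    continue
                found_at_size = True
                if (
                    best is None
                    or (res.matched_count, res.fit_score, [(-a, -b) for a, b in res.assignment])
                    > (best.matched_count, best.fit_score, [(-a, -b) for a, b in best.assignment])
                ):
                    best = res
            if found_at_size:
                break  # smaller subsets cannot beat this clique's result
    return best


# ---------------------------------------------------------------------------
# brute-force oracle


def brute_force_match(
    features: list[Feature], hyp: Hypothesis, min_match: int = 3, mode: str = "aligned"
) -> int:
    """Exhaustive best matched-count over injective type-respecting maps.

    Test oracle only; bounded to <= 7 features and <= 6 sites. The aligned
    variant runs a Kabsch superposition per candidate assignment.
    """
    if len(features) > 7 or len(hyp.sites) > 6:
        raise ValueError("brute force bounded to <= 7 features and <= 6 sites")
    nf, ns = len(features), len(hyp.sites)
    best = 0
    lo = 3 if mode == "aligned" else 1
    for k in range(min(nf, ns), max(lo, 1) - 1, -1):
        if k <= best:
            break
        for fsub in itertools.combinations(range(nf), k):
            for ssub in itertools.permutations(range(ns), k):
                pairs = tuple(zip(fsub, ssub))
                if any(features[i].type != hyp.sites[j].type for i, j in pairs):
                    continue
                if mode == "aligned":
                    if _verify_assignment(features, hyp, pairs) is not None:
                        best = max(best, k)
                        break
                else:
                    ok = all(
                        np.linalg.norm(features[i].position - hyp.sites[j].position)
                        <= hyp.sites[j].radius
                        for i, j in pairs
                    )
                    if ok:
                        best = max(best, k)
                        break
            if best == k:
                break
    return best if best >= min_match else 0


# ---------------------------------------------------------------------------
# conformer-ensemble screening


def screen_conformers(
    molecule: Molecule,
    hyp: Hypothesis,
    params: MatchParams,
    rules=None,
) -> MatchResult | None:
    """Best aligned match of a molecule over its generated conformer ensemble."""
    from .features import DEFAULT_RULES, perceive_features

    rules = rules or DEFAULT_RULES
    ensemble = generate_conformers(molecule, params.max_confs, params.seed)
    best: MatchResult | None = None
    for conf in ensemble.mol.GetConformers():
        feats = perceive_features(ensemble, rules, conf_id=conf.GetId())
        res = match_aligned(feats, hyp, params.min_match)
        if res is None:
            continue
        res.conformer_id = conf.GetId()
        if best is None or (res.matched_count, res.fit_score) > (best.matched_count, best.fit_score):
            best = res
    return best
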