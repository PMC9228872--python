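"""Consensus hypothesis building from prealigned ligand feature sets.

Same-type features pooled across N prealigned ligands are grouped by
average-linkage agglomerative clustering, cut so that no merge happens at a
linkage distance above the tolerance. A cluster becomes a consensus site iff
the fraction of *distinct* ligands contributing a feature reaches
``min_fraction`` — a ligand with two nearby donors cannot double-vote.

Average linkage (rather than single linkage) is used deliberately: with
single linkage, chains of features across a binding pocket can merge into
one diffuse cluster even though the extremes are far beyond tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .chemio import FEATURE_TYPES, Hypothesis, Site
from .features import Feature

logger = logging.getLogger(__name__)


@dataclass
class LigandSet:
    """Feature sets of N prealigned ligands sharing one coordinate frame."""

    ligands: list[tuple[str, list[Feature]]]
    frame: str = ""

    def __post_init__(self) -> None:
        ids = [lid for lid, _ in self.ligands]
        if len(set(ids)) != len(ids):
            raise ValueError("ligand ids must be unique")
        if not self.ligands:
            raise ValueError("ligand set must contain at least one ligand")

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    def pooled(self) -> list[Feature]:
        """All features of all ligands, tagged with their ligand ids."""
        out = []
        for lid, feats in self.ligands:
            for f in feats:
                if f.ligand_id != lid:
                    f = Feature(f.type, f.position, f.direction, lid, f.atom_indices)
                out.append(f)
        return out


@dataclass(frozen=True)
class BuildParams:
    """Consensus build parameters.

    min_fraction : minimum fraction of ligands supporting a site, in (0, 1].
    tolerance : clustering cut distance and site radius, Angstrom.
    max_sites : optional cap; keeps the top-k sites by support.
    """

    min_fraction: float = 0.5
    tolerance: float = 2.0
    max_sites: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.min_fraction <= 1:
            raise ValueError("min_fraction must be in (0, 1]")
        if not self.tolerance > 0:
            raise ValueError("tolerance must be > 0")
        if self.max_sites is not None and self.max_sites < 1:
            raise ValueError("max_sites must be >= 1")


@dataclass
class Cluster:
    """One same-type feature cluster with its distinct-ligand support."""

    members: list[Feature]
    centroid: np.ndarray = field(init=False)
    support_ligands: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        pos = np.array([f.position for f in self.members], dtype=float)
        self.centroid = pos.mean(axis=0)
        self.support_ligands = frozenset(f.ligand_id for f in self.members)

    @property
    def support_count(self) -> int:
        return len(self.support_ligands)


def cluster_features(pool: list[Feature], tolerance: float) -> list[Cluster]:
    """Average-linkage clustering of one feature type at the given tolerance.

    No merge occurs at a linkage distance above ``tolerance``. The result is
    deterministic under input order: features are first sorted canonically.
    An empty pool yields an empty list.
    """
    if not pool:
        return []
    types = {f.type for f in pool}
    if len(types) > 1:
        raise ValueError(f"pool must contain a single feature type, got {sorted(types)}")
    feats = sorted(pool, key=Feature.sort_key)
    if len(feats) == 1:
        return [Cluster([feats[0]])]
    X = np.array([f.position for f in feats], dtype=float)
    Z = linkage(pdist(X), method="average")
    labels = fcluster(Z, t=tolerance, criterion="distance")
    groups: dict[int, list[Feature]] = {}
    for f, lab in zip(feats, labels):
        groups.setdefault(int(lab), []).append(f)
    clusters = [Cluster(members) for members in groups.values()]
    clusters.sort(key=lambda c: (-len(c.members), tuple(c.centroid)))
    return clusters


def _mean_direction(members: list[Feature]) -> np.ndarray | None:
    dirs = [f.direction for f in members if f.direction is not None]
    if len(dirs) * 2 < len(members):
        return None
    mean = np.mean(dirs, axis=0)
    n = float(np.linalg.norm(mean))
    if n < 1e-8:
        return None
    return mean / n


def build_hypothesis(
    ligset: LigandSet,
    params: BuildParams = BuildParams(),
    hypothesis_id: str = "consensus",
) -> Hypothesis:
    """Build the consensus hypothesis from a prealigned ligand set.

    Per feature type, clusters from :func:`cluster_features`; a cluster
    survives iff its distinct-ligand support fraction reaches
    ``params.min_fraction``. Site position is the member centroid, radius the
    build tolerance, direction the normalized mean of member directions when
    at least half the members carry one. Overlapping same-type sites
    (centroid distance < tolerance) are merged keeping the higher support.

    Raises
    ------
    ValueError
        for an empty ligand set or if no cluster survives the threshold.
    """
    n = ligset.n_ligands
    pooled = ligset.pooled()
    sites: list[Site] = []
    for ftype in FEATURE_TYPES:
        pool = [f for f in pooled if f.type == ftype]
        survivors: list[tuple[float, Cluster]] = []
        for cl in cluster_features(pool, params.tolerance):
            support = cl.support_count / n
            if support >= params.min_fraction:
                survivors.append((support, cl))
        # merge overlapping same-type survivors, higher support wins
        survivors.sort(key=lambda sc: (-sc[0], tuple(sc[1].centroid)))
        kept: list[tuple[float, Cluster]] = []
        for support, cl in survivors:
            if any(
                np.linalg.norm(cl.centroid - kc.centroid) < params.tolerance
                for _, kc in kept
            ):
                continue
            kept.append((support, cl))
        for support, cl in kept:
            sites.append(
                Site(
                    type=ftype,
                    position=cl.centroid,
                    radius=params.tolerance,
                    support=support,
                    direction=_mean_direction(cl.members),
                )
            )
    if not sites:
        raise ValueError(
            f"no consensus site reaches min_fraction={params.min_fraction} "
            f"at tolerance={params.tolerance}"
        )
    sites.sort(key=Site.sort_key)
    if params.max_sites is not None:
        sites = sites[: params.max_sites]
    logger.info(
        "consensus: %d ligands -> %d site(s) [%s] at (min_fraction=%g, tolerance=%g)",
        n, len(sites), "".join(s.type for s in sites), params.min_fraction, params.tolerance,
    )
    return Hypothesis(
        id=hypothesis_id,
        frame=ligset.frame,
        sites=sites,
        min_fraction=params.min_fraction,
        tolerance=params.tolerance,
    )
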