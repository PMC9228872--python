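"""Matching engine: Kabsch, conformers, in-place and aligned matching."""

import numpy as np
import pytest

from pharmfunnel import (
    Feature,
    Hypothesis,
    MatchParams,
    Site,
    brute_force_match,
    fit_score,
    generate_conformers,
    kabsch,
    match_aligned,
    match_inplace,
)
from pharmfunnel.geometry import apply_transform
from pharmfunnel.matcher import MatchResult

from conftest import embed, random_rigid_transform

TYPES = ["A", "D", "H", "R"]


def feat(t, pos, direction=None, lid="q", idx=1):
    return Feature(t, np.asarray(pos, dtype=float), direction, lid, (idx,))


def simple_hypothesis(positions, types=None, radius=1.0, tolerance=2.0):
    types = types or TYPES[: len(positions)]
    sites = [Site(t, np.asarray(p, float), radius, 1.0) for t, p in zip(types, positions)]
    return Hypothesis("h", "f", sites, min_fraction=1.0, tolerance=tolerance)


def random_instance(seed):
    rng = np.random.default_rng(seed)
    ns, nf = int(rng.integers(3, 7)), int(rng.integers(3, 8))
    hyp = Hypothesis(
        "h", "f",
        [Site(TYPES[int(rng.integers(4))], rng.uniform(0, 12, 3),
              float(rng.uniform(1.0, 2.5)), 1.0) for _ in range(ns)],
        min_fraction=1.0, tolerance=2.0,
    )
    feats = [feat(TYPES[int(rng.integers(4))], rng.uniform(0, 12, 3), idx=i) for i in range(nf)]
    return feats, hyp


# ---------------------------------------------------------------------------
# kabsch


def test_kabsch_identity():
    P = np.random.default_rng(0).uniform(0, 5, (6, 3))
    R, t, rms = kabsch(P, P)
    assert np.allclose(R, np.eye(3), atol=1e-12)
    assert np.allclose(t, 0, atol=1e-12)
    assert rms < 1e-12


def test_kabsch_recovers_rotation():
    rng = np.random.default_rng(1)
    P = rng.uniform(-5, 5, (8, 3))
    Rz = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    Q = P @ Rz.T + np.array([3.0, -1.0, 2.0])
    R, t, rms = kabsch(P, Q)
    assert rms < 1e-9
    assert np.allclose(R, Rz, atol=1e-9)


def test_kabsch_rejects_mirror_of_chiral_points():
    P = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    Q = P * np.array([1.0, 1.0, -1.0])  # mirror image
    R, t, rms = kabsch(P, Q)
    assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
    assert rms > 0.1  # reflection disallowed, so it cannot superpose


def test_kabsch_requires_three_points():
    P = np.zeros((2, 3))
    with pytest.raises(ValueError):
        kabsch(P, P)


# ---------------------------------------------------------------------------
# generate_conformers


def test_benzene_is_rigid():
    out = generate_conformers(embed("c1ccccc1", "benzene"), max_confs=20, seed=3)
    assert out.num_conformers == 1


def test_conformer_determinism_and_cap():
    flexible = embed("CCCCCC(=O)Nc1ccccc1", "amide")
    a = generate_conformers(flexible, max_confs=50, seed=7)
    b = generate_conformers(flexible, max_confs=50, seed=7)
    assert a.num_conformers == b.num_conformers <= 50
    for ca, cb in zip(a.conformers, b.conformers):
        assert np.allclose(ca, cb, atol=1e-12)


# ---------------------------------------------------------------------------
# match_inplace


def test_inplace_perfect_match(planted):
    feats = [feat(s.type, s.position, s.direction, idx=i) for i, s in enumerate(planted.sites)]
    res = match_inplace(feats, planted, min_match=5)
    assert res.matched_count == 5
    assert res.rmsd_match == pytest.approx(0.0, abs=1e-12)
    assert res.fit_score == pytest.approx(1.0, abs=1e-9)
    assert np.allclose(res.rotation, np.eye(3))


def test_inplace_tolerance_boundary():
    hyp = simple_hypothesis([[0, 0, 0], [8, 0, 0], [0, 8, 0], [8, 8, 0]], radius=1.5)
    feats = [feat(s.type, s.position, idx=i) for i, s in enumerate(hyp.sites)]
    # push one feature just past its radius
    feats[0] = feat(hyp.sites[0].type, hyp.sites[0].position + [1.6, 0, 0], idx=0)
    res = match_inplace(feats, hyp, min_match=3)
    assert res.matched_count == 3
    assert 0 not in [si for _, si in res.assignment]


@pytest.mark.parametrize("seed", range(100))
def test_inplace_equals_brute_force(seed):
    feats, hyp = random_instance(seed)
    bf = brute_force_match(feats, hyp, min_match=3, mode="inplace")
    res = match_inplace(feats, hyp, min_match=3)
    assert (res.matched_count if res else 0) == bf


# ---------------------------------------------------------------------------
# match_aligned


@pytest.mark.parametrize("seed", range(100))
def test_aligned_equals_brute_force(seed):
    feats, hyp = random_instance(seed + 10_000)
    bf = brute_force_match(feats, hyp, min_match=3, mode="aligned")
    res = match_aligned(feats, hyp, min_match=3)
    assert (res.matched_count if res else 0) == bf


@pytest.mark.parametrize("seed", range(10))
def test_aligned_rigid_invariance(seed, planted):
    """matched_count and rmsd are invariant under rigid motion of the query."""
    rng = np.random.default_rng(seed)
    base = [
        feat(s.type, s.position + rng.normal(scale=0.2, size=3), idx=i)
        for i, s in enumerate(planted.sites)
    ]
    ref = match_aligned(base, planted, min_match=5)
    assert ref is not None and ref.matched_count == 5
    R, t = random_rigid_transform(rng)
    moved = [
        feat(f.type, apply_transform(f.position[None], R, t)[0], idx=i)
        for i, f in enumerate(base)
    ]
    res = match_aligned(moved, planted, min_match=5)
    assert res.matched_count == ref.matched_count
    assert res.rmsd_match == pytest.approx(ref.rmsd_match, abs=1e-6)


def test_aligned_rejects_mirror_of_chiral_set():
    """A 4-point chiral arrangement cannot match its mirror at tight radius."""
    P = 6.0 * np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    hyp = simple_hypothesis(P, types=["A", "D", "H", "R"], radius=0.5)
    mirror = P * np.array([1.0, 1.0, -1.0])
    feats = [feat(t, p, idx=i) for i, (t, p) in enumerate(zip(["A", "D", "H", "R"], mirror))]
    res = match_aligned(feats, hyp, min_match=3)
    assert res is None or res.matched_count < 4


@pytest.mark.parametrize("seed", range(50))
def test_tolerance_monotonicity(seed):
    """Uniformly inflating site radii never decreases matched_count."""
    feats, hyp = random_instance(seed + 20_000)
    for factor in (1.5, 2.0):
        bigger = Hypothesis(
            hyp.id, hyp.frame,
            [Site(s.type, s.position, s.radius * factor, s.support, s.direction)
             for s in hyp.sites],
            min_fraction=hyp.min_fraction, tolerance=hyp.tolerance,
        )
        for fn in (match_inplace, match_aligned):
            small = fn(feats, hyp, 3)
            large = fn(feats, bigger, 3)
            assert (large.matched_count if large else 0) >= (small.matched_count if small else 0)


@pytest.mark.parametrize("seed", range(30))
def test_mode_consistency(seed):
    """An in-frame pose matching k sites in place matches >= k aligned."""
    feats, hyp = random_instance(seed + 30_000)
    inp = match_inplace(feats, hyp, 3)
    if inp is None:
        return
    ali = match_aligned(feats, hyp, 3)
    assert ali is not None and ali.matched_count >= inp.matched_count


def test_pair_distances_within_radius(planted):
    rng = np.random.default_rng(5)
    feats = [
        feat(s.type, s.position + rng.normal(scale=0.3, size=3), idx=i)
        for i, s in enumerate(planted.sites)
    ]
    for fn in (match_inplace, match_aligned):
        res = fn(feats, planted, 3)
        assert res is not None
        for d, (_, si) in zip(res.pair_distances, res.assignment):
            assert d <= planted.sites[si].radius + 1e-9


# ---------------------------------------------------------------------------
# fit_score


def _result(rmsd, cosines):
    return MatchResult(
        assignment=[(0, 0), (1, 1), (2, 2)],
        rotation=np.eye(3), translation=np.zeros(3),
        pair_distances=[0.0, 0.0, 0.0], matched_count=3,
        rmsd_match=rmsd, fit_score=0.0, pair_cosines=cosines,
    )


def test_fit_score_formula():
    hyp = simple_hypothesis([[0, 0, 0], [8, 0, 0], [0, 8, 0]], tolerance=2.0)
    assert fit_score(_result(0.0, [1.0, 1.0]), hyp) == pytest.approx(1.0)
    assert fit_score(_result(2.0, []), hyp) == pytest.approx(0.5)  # rmsd = tolerance
    # rmsd = tolerance/2, one pair at 60 degrees: 0.5*0.5 + 0.5*0.5
    assert fit_score(_result(1.0, [0.5]), hyp) == pytest.approx(0.5)
    # anti-aligned directions clamp at zero, never negative
    assert fit_score(_result(0.0, [-1.0]), hyp) == pytest.approx(0.5)


def test_brute_force_bounds_and_trivia(planted):
    assert brute_force_match([], planted, 3) == 0
    feats = [feat(s.type, s.position, idx=i) for i, s in enumerate(planted.sites[:3])]
    small = Hypothesis("h", "f", list(planted.sites[:3]),
                       min_fraction=1.0, tolerance=planted.tolerance)
    assert brute_force_match(feats, small, 3) == 3
    with pytest.raises(ValueError):
        brute_force_match([feat("A", [0, 0, 0], idx=i) for i in range(8)], planted, 3)


def test_match_params_validation():
    with pytest.raises(ValueError):
        MatchParams(min_match=2)
    with pytest.raises(ValueError):
        MatchParams(mode="sideways")
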