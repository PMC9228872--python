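# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `pharmfunnel`. Everything stated here is computed by the
package's test suite or by `scripts/acceptance.py`; nothing is quoted from
external measurements.

## Feature perception

A conformer is reduced to typed points by an explicit rule set
(`features.RuleSet`), versioned in code and overridable from a plain-text
SMARTS file, so a screening campaign can be tuned without code changes.

- **A (acceptor)** — N/O with an available lone pair: carbonyl O, ether and
  hydroxyl O, pyridine-type aromatic N without hydrogen, nitrile N. Amide
  nitrogens and positively charged atoms are excluded. Position at the
  atom; direction from the mean of bonded heavy atoms toward the atom (the
  lone-pair side).
- **D (donor)** — any N/O bearing at least one hydrogen; *one feature per
  heavy atom*, not per hydrogen, matching the granularity of a tolerance
  sphere; direction toward the first hydrogen (lowest atom index after
  hydrogens are added with coordinates).
- **R (ring)** — every smallest-set ring whose atoms are all aromatic;
  position at the ring-atom centroid; direction along the ring normal
  (smallest singular vector of the centered ring coordinates), sign-fixed
  so the largest-magnitude component is positive — normals are axial, so
  only the line matters.
- **H (hydrophobic)** — each maximal connected set of ≥ 3 aliphatic carbons
  whose members bond only to C, H or halogen; position at the set centroid;
  no direction. Halogens are compatible substituents but never seed a group
  alone. A group centroid (rather than per-atom features) was chosen
  because a tolerance sphere of build radius already subsumes the extent of
  a typical alkyl cluster.
- **N/P (ionizable)** — carboxylates/anions and primary aliphatic
  amines/cations; implemented but off by default, since the target
  five-point model uses only A, D, H, R.

Feature positions and directions are equivariant under rigid motion of the
conformer (tested to 1e-9), and perception is deterministic: output sorted
by (type, x, y, z).

## Consensus clustering

Same-type features pooled over N prealigned ligands are clustered by
**average-linkage** agglomerative clustering (SciPy `linkage`/`fcluster`),
cut so no merge occurs above the tolerance t. Average linkage was chosen
over single linkage deliberately: single linkage chains features across a
pocket, merging clusters whose extremes are far beyond t. A brute-force
dendrogram construction in the tests cross-checks the SciPy path.

A cluster becomes a site iff distinct-ligand support / N ≥ *min_fraction*.
Support counts **ligands, not features** — a ligand with two nearby donors
votes once. Site position = member centroid; radius = build tolerance (no
separate screening radius is defined); direction = normalized mean of
member directions when at least half the members carry one, else null.
Overlapping same-type survivors (centroid distance < t) merge keeping the
higher support. Sites are canonically ordered (support desc, type, x, y, z)
so ligand input order never matters. All surviving sites are emitted; a
five-point outcome is obtained through parameters, never a hard-coded k.

Defaults are (min_fraction 0.5, tolerance 2.0 Å); the loose setting
(0.25, 2.5 Å) is what recovers a five-point A·A·D·H·R model from a
20-ligand series — both in the synthetic recovery experiments and, with
the caveat below, on real co-crystal series.

## Matching

**In-place** (receptor frame): the maximum-cardinality, minimum-total-
distance injective type-respecting assignment is found with the Hungarian
algorithm on a square-padded cost matrix; infeasible pairs (type mismatch
or distance > radius) carry a cost of 1e9, which dwarfs any feasible sum
so cardinality dominates. Identity transform; no conformational search.

**Aligned** (any frame): a correspondence graph has a node per
type-compatible (feature, site) pair and an edge when
|d(fᵢ,fⱼ) − d(sᵢ,sⱼ)| ≤ rᵢ + rⱼ. The bound is the triangle inequality for
any rigid placement with both pairs matched, so pruning is sound (no false
negatives). Maximal cliques (NetworkX) of size ≥ min_match are visited
largest-first; each candidate is superposed by Kabsch and verified: every
matched feature must land inside its site's sphere. Because the edge test
is necessary but not sufficient, a maximal clique can fail verification
while one of its subsets verifies; verification therefore descends into
subsets with branch-and-bound on the best verified size. This keeps the
clique search exactly equivalent to brute-force enumeration (checked on
100 random instances per mode). Ties break by (matched_count desc,
fit_score desc, lexicographically smallest assignment) for fully
deterministic output.

Kabsch superposition always returns a **proper rotation** (SVD with sign
correction), so enantiomeric feature arrangements do not match — verified
on mirrored tetrahedral fixtures. Aligned matching requires min_match ≥ 3
(a rigid transform is underdetermined below that).

Direction vectors never affect feasibility — no angular tolerance is
imposed — they enter only the fit score:
`0.5·max(0, 1 − rmsd/t) + 0.5·V`, with V the mean of max(0, cos θ) over
matched pairs carrying directions on both sides, and V = 1 when no such
pair exists. The score is a documented, stable open formula; it is *not* a
reimplementation of any proprietary screening score, and comparisons with
published proprietary scores should be ordinal at most.

**Conformers**: ETKDGv3 distance-geometry embedding + MMFF relaxation
(RDKit), single-threaded and seeded for determinism; near-duplicates
(heavy-atom best RMSD < 0.5 Å) pruned keeping the lower-energy member;
default cap 50 conformers. An embedding failure flags the record (zero
conformers) rather than aborting a screen.

## Funnel

Stage 1 screens every compound in aligned mode over its ensemble; only
stage-1 passers are looked up in the externally produced pose file; stage 2
screens each pose in place and keeps the best pose by (matched_count,
fit_score). min_match defaults to *all* sites at both stages — the
restrictive interpretation — and is user-settable (e.g. to observe a 4-of-5
near-miss as a negative control). Docking itself is out of scope by
design: the contract is the SDF pose interface, which keeps the toolkit
fully open. Reports are written with fixed float formatting so identical
inputs give byte-identical files.

## Synthetic data generator

`synthgen` emulates the statistical structure of a prealigned co-crystal
ligand series at the *feature-cloud* level: `n_sites` well-separated sites
(rejection-sampled, pairwise ≥ 6 Å, in a 20 Å box; default type multiset
{A, A, D, H, R}), per-ligand features at supported sites plus isotropic
Gaussian jitter (default σ = 0.3 Å, the scale of coordinate error across
superposed crystal structures), per-ligand noise features placed ≥ 2t from
every site, and default N = 20 ligands with a (ligand × site) boolean
support matrix. Decoy query sets alternate between displacing one site's
feature by > 2·radius and deleting one feature type (pigeonhole); every
decoy is verified non-matching by the brute-force oracle before emission.
The deterministic aniline enumerator supplies arbitrarily many distinct
single-NH₂ aromatic amines for combinatorial-enumeration tests.

What the generator does *not* emulate: real 3D chemistry (bonded geometry,
torsional correlation between features of one ligand), receptor clashes,
anisotropic binding-site constraints, or perception noise. Passing the
synthetic suites therefore demonstrates the correctness of clustering,
matching and funnel logic — not that the default SMARTS rules reproduce any
particular proprietary feature grammar on real ligands. That grammar is
unpublished; the rule-set override file is the supported tuning mechanism
for real case studies, and `scripts/case_study.py` (network required)
documents one end-to-end attempt with its simplifications (first ligand
copy by chain order, default protonation).

## Enumeration and filtering

Amide coupling is an RDKit reaction template (acid + primary/secondary
amine → amide); amines are renumbered to canonical atom order first so
"first amine site" is reproducible for polyfunctional amines. Products are
canonical SMILES, deduplicated with logged counts; the cardinality law
|unique products| = |scaffolds| · |amines| holds for unique couplable
inputs. Lipinski descriptors are standard RDKit implementations (MolWt,
Crippen logP — an atom-contribution estimate — NumHDonors, N+O count);
default max_violations = 0 (strict). Tautomer/stereoisomer expansion and
ADME property prediction are out of scope, so post-filter library sizes are
not comparable to pipelines that include them.

## Problem sizes and numerical choices

The acceptance script uses: the full 3 × 2924 enumeration (8772 products);
100 random matcher instances (≤ 7 features, ≤ 6 sites — within the
brute-force oracle's factorial bound); 50 planted-recovery seeds at N = 20
ligands; 100 random configurations per monotonicity law; a 10-compound
funnel fixture (3 matchers + 7 decoys). These sizes give stable statistics
(recovery and agreement rates are 100% across tested seeds) while keeping
the whole run under a minute. Tolerances in tests: 1e-9 for rigid-geometry
identities, 1e-6 for rigid-invariance of match results, 0.5 Å for planted
centroid recovery.

## Known limitations

- Feature perception is rule-based and deliberately simple; conformer-
  dependent donor/acceptor strengths, metal binders and ring puckering are
  not modeled.
- PDB ligand extraction guesses bonds by interatomic distance; formal bond
  orders on extracted ligands may be wrong for unusual chemistry (features
  are robust to this where aromaticity survives sanitization).
- The aligned matcher's subset descent is exponential in clique size in the
  worst case; in practice cliques are bounded by the site count (≤ 6 in all
  intended uses).
- mmCIF input, excluded-volume features, flexible (torsional) alignment and
  docking are out of scope.
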