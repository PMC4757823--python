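# Methods

This note documents the models, parameters and numerical choices behind
`morscreen`, and what the synthetic benchmarks do and do not demonstrate.

## Interaction perception and classification

A pose is a set of heavy-atom points, each carrying interaction roles
(HBA, HBD, cationic, anionic, hydrophobic, aromatic); the pocket is a set
of labelled functional-group anchors (carboxylate, hydroxyl, ammonium,
amide, indole-NH, imidazole), each with the roles its chemistry supports.
Contacts are perceived by role pairing and distance:

* ionic — cationic↔anionic pairing within **5.5 Å** (charged-group
  centroid distance);
* hydrogen bond — donor↔acceptor pairing within **3.5 Å** heavy-atom
  distance, with a 120° D–H…A angle test applied only when explicit
  hydrogens are present (role-typed point sets carry none, so the test is
  distance-only there).

These cutoffs are conventional interaction-profiler values; the source
screening study reports contacts without printing thresholds, so they are
package defaults, configurable via `GeometryParams`.  Perception is
deterministic and invariant under a rigid motion applied jointly to pose
and pocket; pose and pocket must share one Ångström frame (a unit mismatch
is undetectable by construction).

The binder rule is a conjunction: (Asp147, ionic) **and** (Tyr148, hbond).
The function rule marks any binder with ≥1 additional polar contact on
{Lys233, Gln124, Glu229, Asn150, Trp318, Tyr128} as antagonist-like.  The
published additional-residue list contains both "Glu229" and "Gln229" —
almost certainly one residue printed two ways; the default set keeps
Glu229 and accepts "Gln229" as an alias (configurable).  His297 is
deliberately excluded from both rules (its H-bonding is often
water-mediated and not consistently present in actives), as are
hydrophobic contacts; a separate water-mediated channel exists on the
fingerprint but never feeds the rules.

## Pharmacophore matching

A model has F typed features with tolerance spheres (default radius
**1.5 Å** for all kinds) and exclusion volumes (default radius **1.0 Å**).
Atom eligibility per feature kind: PI ↔ cationic, NI ↔ anionic,
HBA ↔ acceptor, HBD ↔ donor, H ↔ hydrophobic carbon (≥3 bonds from any
heteroatom when typed from a molecule), Ar ↔ aromatic ring centroid.

Matching enumerates injective, type-compatible feature↔atom
correspondences (depth-first, scarcest feature first).  Each complete
correspondence is scored by Kabsch least-squares rigid superposition of
the matched atoms onto the feature centers; it is accepted iff every
deviation dᵢ ≤ tᵢ and no heavy atom of the aligned conformer lies strictly
inside any exclusion volume.  Fitness = ½(m/F) + ½(1 − mean dᵢ/tᵢ); the
best-fitness accepted correspondence is reported.  With
`min_features_required < F`, feature subsets down to that size are also
searched (the fitness term m/F then penalises partial matches).  Ring
centroids are pseudo-points excluded from the exclusion-volume test.
Directional features apply a 45° cone test only when a direction and a
partner proxy exist; otherwise matching is sphere-only.  The fitness
definition is this package's own — published fitness values from
proprietary matchers are not comparable.

A second matcher (`match_conformer_exhaustive`) enumerates the same space
by plain permutation products with no ordering heuristics; it exists as an
independent oracle and the tests require exact agreement on random
instances (≤6 features, ≤12 atoms).

## Shape overlay and ComboScore

Every heavy atom is a spherical Gaussian p·exp(−α|r−c|²) with p = 2.7 and
α chosen so the Gaussian's integral equals a **1.7 Å** hard sphere
(α ≈ 0.81 Å⁻²); colour features use 1.0 Å Gaussians.  Overlap volumes use
only pairwise cross terms with the closed form
p²(π/2α)^{3/2}·exp(−α d²/2) — a documented first-order approximation with
no inclusion–exclusion corrections.  Shape Tanimoto
= O_AB/(O_AA+O_BB−O_AB); colour Tanimoto is computed identically within
each colour kind and defined as 0 when either side has no colour features;
ComboScore is their unweighted sum (0–2), matching the convention in which
published cutoffs (1.02–1.65) fall between 1 and 2.

Overlay optimization: initial alignments are centroid superposition
combined with the four proper principal-axis sign flips; each start is
refined by Nelder–Mead simplex over the six rigid-body degrees of freedom
(rotation vector + translation, max 200 iterations, function tolerance
1e-4, parameter tolerance 1e-3), and the best result is kept, never below
the best unrefined start.  Principal axes of degenerate (collinear/planar)
point sets are completed deterministically by eigendecomposition with a
fixed sign convention.  The optimizer is validated against an exhaustive
Euler-grid rotation search (10° steps) on small toys.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *study conditions* of a retrospective MOR
benchmark — 45 agonists, 47 antagonists, 148 inactives (N = 240), activity
cutoffs ≤5 nM (active) and ≥1000 nM (inactive) — with abstract role-typed
point sets rather than chemically valid molecules, because every
downstream rule operates at the interaction-type level.

* **Toy pocket**: the nine named anchors at fixed positions ≥8 Å apart, so
  a planted contact can never register at a neighbouring anchor.
* **Poses**: agonist-like poses place a cationic atom 3.2 Å from Asp147
  and a donor 2.8 Å from Tyr148; antagonist-like poses add an acceptor
  2.8 Å from Lys233; non-binders break the Asp147 contact (9 Å).  Gaussian
  jitter (default sd **0.2 Å**) models coordinate noise; the planted
  geometry margins guarantee correct classification up to a documented
  safe bound of **0.4 Å**, beyond which a warning is raised.
* **Benchmark libraries**: per-model hit plans are planted exactly.
  Pharmacophore ensembles use *nested* models — model k requires three
  shared base features plus k stacked extras of distinct kinds, and a
  compound carries exactly the extras for the models it must hit, so
  per-model retrievals are exact by construction.  Shape ensembles use
  mutually dissimilar canonical queries whose single colour feature has a
  kind unique within the ensemble; since all cutoffs exceed 1.0 and
  disjoint colour kinds give colour Tanimoto 0, a conformer planted for
  one query can never reach another query's cutoff.  Class labels are
  shuffled over the id sequence; affinities are drawn consistently with
  the class cutoffs.
* Published ensemble retrieval counts are planted as the union plans; the
  per-model splits are not printed anywhere and are fixed package choices.

Passing the planted benchmarks therefore demonstrates that the screening,
union, ranking and enrichment machinery is correct — not that the models
would enrich real chemistry; no force fields, sterics, conformational
strain or assay noise are modelled.

## Enrichment statistics

EF = (TP/n)/(A/N), undefined at n = 0; maxEF = N/A (or min(n,A)/n · N/A at
fixed hitlist size).  Displayed values round half-away-from-zero to one
decimal.  Because the %maxEF convention in published tables is internally
inconsistent (some values match a rounded-EF ratio, some an unrounded
one), both variants are reported and neither is treated as authoritative.
AUC is the midrank Mann–Whitney statistic; for binary hit/non-hit screens
all non-hits share a score below every hit score and the tie block is
handled by midranks.  AUCs published for proprietary ranked scores are not
reproducible from counts and are validated here only through properties
(perfect separation → 1, all ties → 0.5, brute-force pair agreement).

## Reference model fixtures

The six published pharmacophore models and seven shape queries are shipped
as builders that reproduce their exact feature/exclusion-volume censuses
and ComboScore cutoffs.  Their 3D geometries were never published;
coordinates here are schematic (well-separated feature sites, exclusion
volumes on an 8 Å Fibonacci shell) and deliberately validated **only** by
census and cutoff, never by screening outcome, to avoid implying a
geometric fidelity the sources do not support.

## Pharmacology

Cheng–Prusoff Ki = IC50/(1 + [L]/Kd); the reference configuration is
[³H]DAMGO displacement at [L] = 1 nM with Kd = 1.59 nM (divisor 1.6289).
Concentration–response curves are fitted as a 4-parameter logistic in
log₁₀ concentration (bottom, top, log EC50, Hill slope) by
Levenberg–Marquardt least squares with quartile-heuristic initialisation;
the Hill slope is free by default with a fixed-slope option, a supplied
basal response is subtracted before normalisation by default, and flat or
unconstrained data raise a convergence error with diagnostics.  At the
contract design of 8 points and 5% proportional noise, one curve carries
enough information to localise log₁₀ EC50 to about ±0.07 (1σ), so the
recovery tests assert the ±0.1 bound on a seed-grid median rather than on
a single draw.  Dose ratio and Ke follow the single-antagonist-
concentration null equation Ke = [a]/(DR − 1), undefined at DR ≤ 1; full
Schild regression over multiple antagonist concentrations is out of scope.

## Novelty

Morgan fingerprints (radius 2, counts folded to 2048 bits) approximate
ECFP4; absolute Tanimoto values are hash-dependent and not comparable
across packages, so published five-decimal similarity values are treated
as qualitative.  "Overall similarity" is the mean over all query×reference
pairs, with the nearest-neighbour mean reported alongside as the
alternative reading.

## Problem sizes and determinism

Default test and acceptance runs use the 240-compound benchmark, 500
classification poses, 100 random matcher-oracle instances and ~25k-point
rotation grids — sizes chosen so the full pipeline (four benchmark
generations, four screens, validation) completes in about a minute on one
CPU.  All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); there is no global random state, and repeated
runs are bit-identical.
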