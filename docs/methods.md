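# Methods

`sarmap` analyses a *complete* bioactivity panel: every compound screened
against every target, with percent inhibition recorded per
compound-instance (a compound at one assay concentration).  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic benchmark does and does not demonstrate.

## Activity calls and panel statistics

A cell is **active** when inhibition ≥ threshold (default 50%, boundary
inclusive).  Raw values outside [0, 100] are accepted — they occur in real
assays — and binarized by the same rule, with a logged warning.  The
mid-band fraction (default half-open interval [40, 60)) measures how many
cells sit near the threshold, i.e. how sensitive the binarization is; the
boundaries are configurable because the convention is genuinely ambiguous.
Promiscuous instances are flagged at mean + 3·SD of per-instance target
counts, using the population SD since this is a descriptive statistic over
the entire panel, not an inference from a sample.

Instances of the same compound at the two concentrations are deliberately
counted as distinct throughout: a strong inhibitor (active at both 1 µM and
10 µM) contributes its substructure features twice to a target's active
set, encoding potency ordinally without using the raw percentages.

## Enrichment profiles

For each target, each substructure feature *i* gets

    E_i = f_A / f_I                    if f_A > 0 and f_I > 0
    E_i = (f_A + 1) / (f_I + 2)        otherwise (Laplacian correction)

where f_A (f_I) is the number of active (inactive) compound-instances whose
compound contains the feature.  The correction is applied **only** at zero
counts; an always-corrected variant exists behind a flag for sensitivity
analysis.  Frequencies are raw counts, not proportions: the ratio is then a
true odds-style enrichment when active and inactive sets have similar
sizes, and we note that relative-frequency normalization would change E
when they do not.  Features absent from all of a target's compounds still
receive E = 0.5, so all profiles share one vocabulary (sorted
lexicographically for determinism).

Feature sets are binary per compound — a feature counts once per compound
however many times the substructure occurs inside the molecule.  When
computed from structures, features are Morgan/ECFP-style hashed atom
environments at diameter 4 bonds (radius 2) via RDKit; the identifiers are
stable across runs.  All downstream code consumes an abstract
compound→feature-set table, so precomputed tables work identically.

## Distances

* **Enrichment (Manhattan)**: Σ|p_i − q_i| / n_features between profiles.
* **Tanimoto**: D = 1 − c/(n_a + n_b − c) on binary per-target bioactivity
  fingerprints (one bit per instance).  Two all-zero fingerprints are
  defined as distance 0 with a warning; in the pipeline zero-active targets
  are removed before this can matter.
* **Hamming**: raw disagreement counts (a length-normalized option exists);
  counts are computed by integer matrix products so they are exact.

## Neighbor joining

Classic Saitou–Nei agglomeration on the distance matrix: join the pair
minimizing Q(i,j) = (n−2)d(i,j) − r_i − r_j, branch lengths by the standard
formulas, final three nodes joined in one unrooted trifurcation.  Ties on Q
are broken by the lowest (i, j) in current node order, so output Newick is
byte-deterministic.  Negative branch lengths are retained by default
(matching classic distance-tree programs); `clamp_negative=True` clamps to
zero and transfers the length to the sibling so the joined pair's total
distance is preserved.  Patristic (leaf-to-leaf path-length) matrices can be
normalized by their maximum to the conventional 0–1 scale used for
sequence-based trees.  On additive inputs the implementation recovers
topology exactly and reproduces the input distances to 1e-8 (property-tested
against randomly generated binary trees, and cross-checked against
scikit-bio's independent NJ implementation).

## SAC series and the neighborhood rule

For a common target, every other target contributes (shared-active
percentage, distance).  Three normalizations of the shared count are
supported: by the common target's actives, by the variable target's actives
(default, and the least biased: it does not systematically favor variable
targets with many actives), or by the size of the union of both active sets
("both"; a sum-of-totals variant exists as `both_sum`).

Each series is rescaled **multiplicatively** so its mean distance is 0.5 and
its mean percentage is 50 (the "SAC score").  Multiplicative rescaling is
the only reading consistent with SAC scores above 200: an additive shift of
percentages bounded by 100 cannot exceed 150 when centering to 50.  Scaling
is idempotent and exact to 1e-9 by construction.

A quadratic y = ax² + bx + c is fitted by unweighted least squares;
**neighborhood behavior** requires slope 2ax + b negative at x = 0.40 and
x = 0.67 *and* R² > 0.2.  Degenerate series (fewer than 3 points, all-equal
x, or an unscalable all-zero percentage series from a target sharing no
actives) are classified outliers with an explicit reason.  The R² > 0.2 bar
is far above what i.i.d. noise achieves at n ≈ 200 (E[R²] ≈ 0.01), which the
calibration test verifies by simulation.

Distances enter the series directly from the distance matrix, not from tree
path lengths (tree-based distances can be substituted by passing a
patristic matrix).  Evaluation points 0.40/0.67 are on the scaled axis.

The **exclusion filter** drops targets whose shared_total — active
instances also active on ≥ 1 other target, each counted once — is ≤ 16, in
one pass on the unfiltered panel.  Stage 2 of the pipeline rebuilds
everything (feature vocabulary, profiles, distances, trees, SAC) from the
kept panel, so stage-2 results are those of a self-contained smaller panel.

## Embedding

SMACOF majorization on the Hamming distance matrix, minimizing raw stress;
each Guttman step provably does not increase stress, so the recorded trace
is non-increasing.  Reported stress is normalized:
sqrt(Σ(d̂ − δ)² / Σδ²) over unordered pairs.  Stopping: per-step normalized
stress change < 0.00005 or 5000 steps.  Because a single random start can
stall in a local optimum, the embedding keeps the best of `n_init = 4`
seeded starts (all derived from the one run seed, so results remain
deterministic).  On a 5-point configuration that is exactly realizable in
the plane the embedding reaches normalized stress < 0.01 and reproduces the
input distances within 1%.

## Synthetic panels

The generator emulates a mid-size full-matrix screen with known truth.
Defaults: 6 clusters × 8 targets, plus 3 sparse targets and 1 zero-active
target (52 targets), 150 compounds at 1 and 10 µM (300 instances).

* **Chemotypes**: each cluster has a disjoint 12-feature signature (an
  overlap parameter plants cross-reactive chemotypes); every compound adds
  8 background features from a 300-feature pool.  Four pan-inhibitors carry
  a slice of every signature and hit any target with probability 0.9.
* **Activity**: clusters sit on a relatedness axis — by default a related
  core with a few remote clusters — and a compound's activity probability
  on a target decays geometrically (factor 0.45 per unit separation) from
  0.8 at separation zero, floored at the 0.02 background rate, times a
  per-target sensitivity multiplier U(0.6, 1).  A flat two-level design
  (on-cluster vs off-cluster only) was rejected: it yields a bimodal
  distance distribution with almost no mass beyond scaled distance 0.6,
  where the fixed 0.67 evaluation point of the neighborhood rule makes even
  perfectly monotone series look convex.  The gradient layout reproduces
  the continuous, right-skewed distance spread the rule presumes.
* **Concentrations**: a compound active at 1 µM is always active at 10 µM
  (nested draws; the low-concentration rate is 0.6 of the high one).
* **Values**: actives drawn U(60, 100), inactives U(0, 40), with 2%
  mid-band contamination drawn on the correct side of the 50% threshold
  ([50, 60) and [40, 50) respectively) so planted truth is exactly
  recoverable by binarization — this exercises the mid-band statistic
  without corrupting ground-truth labels.
* **Sparse targets** are thinned compound-by-compound (both concentrations
  at once, preserving nesting) until shared_total ≤ 16, so they are exactly
  the targets the exclusion filter should remove.  All randomness flows
  from a single seeded generator.

On the default panel (seed 0) this yields ~18% active cells and ~1.9%
mid-band values, within-cluster enrichment distances ~0.76× the
between-cluster mean, and the qualitative orderings of the real analysis:
variable-normalization neighborhood fraction > union > common, Tanimoto
metric fraction highest, and a stage-2 fraction at or above stage 1 after
excluding the sparse and zero-active targets.

## What the synthetic benchmark does not show

Feature ids are abstract; no molecular realism (the chemistry backend is
tested separately on real SMILES).  Assay noise is uniform within bands,
uncorrelated across targets, with no plate or batch structure.  Cluster
memberships are crisp, while real target families overlap.  Absolute
neighborhood fractions on the 52-target default panel (~47% in stage 1) are
well below those reported for large real kinase panels; the package's
guarantees are therefore about orderings, invariants and exact formula
behavior, not about reproducing any particular panel's percentages.

## Numerical conventions

Double precision throughout; distance matrices validated symmetric with
zero diagonal; TSV serialization uses round-trip float precision (reading
uses the round-trip parser — the default is off by 1 ulp).  Quadratic fits
use `numpy.polyfit`; R² is defined as 0 for constant-y series.  Problem
sizes in tests (52 targets, 300 instances, 200 random NJ trees of 5–20
leaves, 500 classifier-calibration replicates) were chosen so the full
suite exercises every guarantee in a few seconds.
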