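# Methods

## Model

A secondary-metabolite profile is a vector of non-negative quantities over
a compound set; a compound is characterized by the set of enzymes (or, in
the coarse variant, chemical classes or other traits) involved in its
biosynthesis. The package's distance between two profiles is a weighted
generalized UniFrac over a tree built from compound-level Sørensen
dissimilarities, so two samples are close when the *branches* — shared
biosynthetic machinery — carrying their abundance overlap, not only when
the compounds themselves coincide.

Assumptions worth making explicit:

* Enzyme incidence is binary. Using an enzyme twice in a pathway counts
  once; there is no notion of flux or enzyme copy number.
* Compounds with identical feature sets are biosynthetically
  indistinguishable. They merge at height 0 and swapping one for the other
  (at equal quantity) changes no sample distance. This is intended
  behaviour for multi-product enzymes, not an edge case.
* The dendrogram is a surrogate phylogeny. Hierarchical clustering of
  Sørensen dissimilarities is a heuristic embedding of enzyme overlap into
  a tree; no claim of evolutionary history is attached to its internal
  nodes.
* Samples enter UniFrac as relative abundances, so the measure compares
  compositions, not absolute emission rates. Presence/absence data are
  handled identically (quantities of 1).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.5 | generalized-UniFrac exponent on edge mass (dimensionless, 0–1). 1 recovers classical normalized weighted UniFrac; 0.5 tempers the dominance of abundant lineages. |
| `linkage` | `complete` | agglomeration rule for the compound dendrogram; the conventional default of the clustering routines this workflow descends from. |
| `height_scale` | 0.5 | factor applied to merge heights when the dendrogram becomes a tree. At 0.5 the tip-to-tip path length equals the cophenetic merge height. UniFrac is invariant under uniform branch rescaling (numerator and denominator are both linear in edge length — a tested property), so this choice cannot affect sample distances. |
| `w` | scanned; 0.878 as CLI starting value | merge weight between standardized class-based distance and standardized Bray–Curtis. Data-set specific; `scan_weight` should be rerun per study. |
| `step` | 0.001 | w-grid resolution, fine enough to resolve an optimum to three decimals. |
| `n_perm` | 999 | permutations for Mantel / factor-fit p-values; the add-one rule keeps p ≥ 1/(n_perm+1). |
| NMDS `k`, `n_starts` | 2, 20 | ordination dimensions and random restarts; the best (lowest stress-1) configuration is kept, deterministic given the seed. |

## Numerical choices

* Edges with zero combined mass in a sample pair contribute to neither
  UniFrac sum (0/0 → drop). If *every* occupied edge has zero length the
  pair's distance is defined as 0; a tree whose edges are all zero-length
  is rejected as degenerate.
* Sørensen values come from boolean Dice dissimilarity, which is exactly
  1 − 2a/(2a+b+c); clustering heights are clipped at 0 against
  floating-point fuzz, preserving zero-height merges.
* Clustering ties are resolved by the agglomeration routine
  deterministically given the input compound order; ties between
  biosynthetically identical compounds merge at height 0, where the
  resolution order cannot affect any distance.
* Standardization divides by the matrix maximum and errors on all-zero
  matrices; `merge_dist` standardizes internally so it is idempotent on
  pre-standardized inputs.
* The w-scan evaluates the point Mantel correlation only (no permutations
  per grid point); ties in the profile resolve to the smaller w.
* Mantel p-values are one-sided with simultaneous row/column permutation
  of the second matrix; an exhaustive enumeration (n ≤ 8) provides the
  exact reference used in tests.
* NMDS uses isotonic-regression (non-metric) stress-1 minimization with
  weak-tie handling, via scikit-learn's MDS.

## Synthetic data

The package ships generators rather than data files; both are validated by
the same input checks as user data.

**Hypothetical profiles (deterministic).** 13 samples A–M over 13
compounds: 5 monoterpenes (α-/β-pinene sharing one terpene synthase,
β-phellandrene differing from them only in the terminal enzyme), 5
aromatics (including indole, which branches off the shared shikimate
backbone), 3 fatty-acid derivatives. Each pathway is a shared enzyme
backbone plus per-compound terminal enzymes, with a few nested chains
(benzyl alcohol extends benzaldehyde; the hexenyl ester extends the
alcohol). Profile pairs are engineered to exhibit the contrasts the
measure exists for: (C,D) same pathways without a single shared compound,
(E,F) a pinene swap, (G,H) one-third compound overlap within aromatics,
(I–L) identical supports at different quantities. Quantities are chosen
for structure, not to reproduce any published table entry-by-entry.

**Two-species floral scents (seeded).** Two species × 9 samples over a
40-compound pool partitioned 25/4/11 (exclusive-A / exclusive-B / shared)
across four pathways. Species have distinct pathway-level mean emissions —
A sesquiterpene-rich, B aromatics-leaning without MVA products, both
monoterpene-dominated — reflecting how confamiliar species differ by whole
pathway branches rather than by independent compounds. Per-compound
quantities are log-normal (σ_log = 0.8) with Bernoulli occupancy (0.9
shared, 0.7 exclusive compounds); every compound is forced into at least
one sample of each species that can emit it, making the 40/25/4/11
bookkeeping exact by construction rather than by chance.

What the generators do **not** emulate: detection-limit censoring and
co-elution artefacts of real GC-MS tables, correlated emission of
compounds sharing a terminal enzyme, day/plant covariates, and uncertainty
in the enzyme annotation itself. Tests passing on these fixtures show the
machinery is correct and that the measure behaves as designed on profiles
with known structure; they do not validate any biological claim about real
bouquets.

## Design decisions

* The linkage method and the height convention of the tree conversion are
  exposed as options because reasonable analysts differ here; defaults are
  complete linkage and halved heights. The rescaling-invariance property
  guarantees the height convention is cosmetic.
* α defaults to 0.5 (the balanced member of the generalized-UniFrac
  family) and is a flag everywhere, since the best exponent is a
  study-level choice.
* Compounds present in samples but missing from the feature matrix are a
  hard error by default with an explicit `drop_missing` escape hatch —
  silently dropping them would change distances invisibly.
* The Mantel test is implemented in-package (vectorized Pearson with a
  seeded generator) so that permutation results are reproducible from the
  CLI; the exhaustive enumeration and an independent UniFrac
  implementation serve as oracles in the test suite.
* Problem sizes in the test and acceptance runs (13-sample and 18-sample
  datasets, trees up to 8 leaves for oracle comparisons, 999 permutations)
  are the sizes the worked examples themselves use; they keep every check
  exact or tightly seeded.

## Limitations

* The quality of the distance is bounded by the enzyme annotation;
  postulated terminal enzymes inject expert judgement into the tree.
* The dendrogram step forces a hierarchical structure onto enzyme-sharing
  relations that are not perfectly nested (pathway cross-talk).
* With class-level features only, UniFrac discards compound identity
  entirely within a class; the merged distance reintroduces it only
  through Bray–Curtis, and the optimal merge weight does not transfer
  between datasets.
* Distances are compositional (relative abundance); total emission
  differences between samples are invisible by design.
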