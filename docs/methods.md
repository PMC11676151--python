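# Methods

This note documents the statistical procedures, the synthetic study the
package uses to validate them, and the design choices made where more than
one reasonable convention exists. It describes what the code computes;
every empirical claim here is recomputed by the test suite or by
`scripts/acceptance.py`.

## Pre-ranked enrichment

**Statistic.** For a ranked list of `N` genes with scores `s_1 ≥ … ≥ s_N`
(descending fold change; exact ties broken by ascending gene name so
rankings are platform-independent) and a gene set with `n_h` members in the
list, the running sum increments by `|s_i|^w / Σ_members |s|^w` at member
genes and decrements by `1/(N − n_h)` elsewhere. It therefore starts and
ends at zero; the enrichment score (ES) is the extremum of largest
magnitude, with the positive extremum preferred on an exact tie. The
leading edge is the set of members at or before the positive peak (at or
after the trough for negative ES). The weight exponent defaults to `w = 1`
(the classic weighted setting; `w = 0` reduces to the unweighted
Kolmogorov–Smirnov walk). Sets that do not intersect the ranked list, or
cover it entirely, cannot be scored and are reported separately rather
than silently dropped.

**Null and significance.** Pre-ranked input has no per-sample phenotype to
permute, so the null is gene-label permutation: `n_perm` (default 1000)
random same-size draws from the ranked list's genes. One permutation of
positions is shared across all sets — a draw of size `n_h` reads the first
`n_h` entries of each permuted row — which makes the null loop a single
vectorized pass exploiting that the running sum is piecewise linear between
member positions (maxima occur at members, minima just before them).

The p-value is two-sided on magnitude:
`p = (#{|ES_null| ≥ |ES|} + 1) / (n_perm + 1)`. Both enrichment directions
are biologically interesting here (sensitizing sets are expected at the
top, but depleted sets are reportable), and because the observed |ES| is
exchangeable with the null |ES| values under gene-label permutation, this p
is uniform under the null — a property the acceptance checks verify by
simulation. The pseudo-count keeps `p ≥ 1/(n_perm+1)`, so reported zeros
are impossible.

NES divides ES by the mean magnitude of same-sign null ES values (sets of
different sizes become comparable). The FDR q is the sign-stratified
pooled-null ratio in the style of the original GSEA procedure: for a
positive `NES*`, q = (fraction of pooled positive null NES ≥ NES*) /
(fraction of observed positive NES ≥ NES*), clipped to [0, 1], mirrored for
negative NES, and made monotone by a cumulative minimum from the least
extreme NES inward (as in Benjamini–Hochberg, a more extreme score never
receives a larger q).

**Screen-level filter.** A pathway is called significant in a screen when
`p < 0.05` and `q ≤ 0.25`. Screens with fewer than 300 hits carry less
power, and their FDR cutoff relaxes to `q ≤ 0.40`; both cutoffs and the
hit-count threshold are configurable.

**Over-representation.** For a plain gene list (no ranking), each set is
tested with the hypergeometric upper tail `P(X ≥ k)` in the database's
declared universe, and Benjamini–Hochberg q-values are computed across all
sets. The universe is the database's generative universe, not the union of
set members: shrinking the universe to annotated genes would silently
inflate significance. Query genes outside the universe are dropped with a
logged warning.

## Cross-screen integration

Recurrence counts, for every pathway, the screens in which it passed the
filter; the `k ≥ 3` slice is the default weak-point candidate list, with
`k ≥ 4` and `k ≥ 5` as stricter nested views.

Gene-set collections name overlapping slices of biology, so several
pathways can be significant off the same screen hits. Merging builds a
graph over significant pathways, connecting two when the Jaccard index of
their pooled leading-edge genes (union over screens) reaches a threshold
(default 0.5), and takes connected components as meta-pathways. Merging is
therefore transitive: if A matches B and B matches C, all three merge even
when A and C overlap weakly. This is deliberate — the alternative (clique
merging) is order-dependent — and the threshold is exposed because the
right granularity is collection-specific. No specific merge (e.g. an
Akt-mTOR umbrella) is hard-coded.

The complementary gene-level funnel takes genes hit in at least 2 screens
(a screen's hit list is its full ranked list, which contains sensitizing
hits only) and keeps those belonging to at least one database set; the
funneled list feeds the over-representation test. The library-size check is
a plain Pearson correlation between library size and hit count with the
two-sided t-transform p on `n − 2` degrees of freedom.

## Synergy-set diversity

For one therapeutic with curated synergizing drugs, the analysis:

1. applies the exclusion rules (control: drop synergizers whose annotated
   mechanism equals the control's own target pathway, which would deflate
   its diversity; test: drop synergizers inhibiting *other* weak-point
   pathways, which would inflate it); a record left with fewer than two
   drugs is skipped and reported;
2. computes the Euclidean distance matrix of the included drugs' signature
   columns;
3. embeds it with classical (Torgerson) MDS — double-center `−D²/2` with
   `J = I − 11ᵀ/n`, eigendecompose, scale the top eigenvectors by the
   square roots of their non-negative eigenvalues. The full eigenvalue
   spectrum is returned, and each result records the fraction of distance
   variance the 2-D embedding captures. Axis signs are fixed by making each
   axis's largest-magnitude coordinate positive, so coordinates are
   deterministic. The embedding is computed per therapeutic (each plot
   stands alone), not globally;
4. scores diversity as the mean of the `n(n−1)/2` pairwise distances, and
5. compares the test and control score vectors with a two-sided
   pooled-variance Student's t-test (df = `n_test + n_control − 2`; with
   the standard 4-vs-4 design, df = 6). Zero pooled variance with equal
   means returns `p = 1` by convention; with unequal means it is an error
   rather than a fake infinity.

**Scoring space.** The diversity score defaults to distances in the full
signature space (`distance_space="full"`), with the 2-D MDS coordinates
kept for plotting and available as the scoring space
(`distance_space="mds"`). The default is deliberate: when a therapeutic's
drugs spread over `k ≥ 4` roughly equidistant mechanisms they sit near a
regular simplex, and a plane captures only about `2/(k−1)` of that squared
spread, while a two-cluster (essentially one-dimensional) configuration
embeds almost losslessly. Scoring in 2-D therefore *compresses genuinely
diverse sets more than narrow ones* and can flatten or even invert a real
diversity ordering; the full-space distances have no such distortion. The
per-record `variance_explained_2d` field makes the 2-D loss auditable, and
the MDS mode exists for strict plot-faithfulness. A convex-hull polygon
area is available as a secondary, plot-level diversity metric.

Profiles are used as ingested; an optional per-gene z-scoring switch
(`normalize`, off by default) covers signature collections on heterogeneous
scales.

**Distance form.** The score uses the rooted Euclidean distance. Rankings
of diversity scores are unchanged by any monotone transform applied
uniformly (e.g. squared distances), but reported magnitudes assume the
rooted form.

## The synthetic study

The generators produce data with exactly the structure the analysis
assumes, plus the planted truth, so recovery is checked without
re-inference. All randomness flows from a single integer seed through
`numpy`'s `SeedSequence`; identical configurations reproduce identical
bytes on disk.

* **Pathway database** — `n_pathways` (default 20) sets drawn uniformly
  from the universe with sizes uniform on a declared range (default
  10–40). One designated pair shares a controlled fraction of members
  (target Jaccard within ±0.05) so alias merging is testable; remaining
  overlap is hypergeometric background.
* **Screens** — each screen scores `hits_per_screen` (default 500) genes
  from a `n_genes_universe` = 2000 universe: Gaussian noise (sd 1) plus
  `planted_effect` added to the genes of that screen's planted pathways
  (default 3 pathways per screen at 3σ — strong enough to be found, weak
  enough that significance filtering does real work). Scores are abstract
  fold-change-like units; only the ranking matters downstream. Planted
  genes are always included in the hit list so ground truth is exact.
* **Profiles** — `n_mechanism_clusters` = 8 cluster centers with iid
  N(0, 1) entries over 300 genes; each of 4 drugs per cluster is its
  center plus N(0, 0.2²) noise, i.e. mechanism separation five times the
  within-mechanism spread — distinct but not degenerate clusters.
  Metadata is fixed (`SYNTH`, 24 h) to mirror a single-cell-line,
  single-timepoint signature slice. Values are continuous z-score-like
  signatures, not counts.
* **Synergy sets** — 4 test and 4 control therapeutics (the standard
  4-per-group design), each with 6 synergizers drawn from `breadth_test`
  = 6 vs `breadth_control` = 2 distinct mechanism clusters (clusters
  cycled so each contributes). Mechanism annotations are the true cluster
  labels; target-pathway names are disjoint from mechanism names, so the
  exclusion rules are exercised as no-ops and the planted effect is
  breadth alone.

What the synthetic data does *not* emulate: hairpin-level counts or
screen-level measurement error models (simulation starts at ranked
gene-level hits), correlated gene expression within real signatures,
unequal cluster sizes or separations, literature-curation noise in synergy
annotations, and batch structure across cell lines or timepoints. Passing
tests demonstrate that the machinery is correct and calibrated under its
own assumptions, not that real screens meet those assumptions.

## Numerical and design details

* Ranking ties: lexicographic by gene, everywhere, documented in the type.
* Permutation p floor: `1/(n_perm+1)`; n_perm below 100 is rejected.
* A pathway whose members all score exactly zero falls back to equal
  member increments (the unweighted walk) instead of dividing by zero.
* MDS validates symmetry, zero diagonal and non-negativity; negative
  eigenvalues (non-Euclidean input) are clipped to zero in coordinates but
  reported in the spectrum; an all-non-positive top spectrum is an error.
* Knife-edge ES sign ties (positive and negative extremum equal to within
  rounding) are resolved positive; different summation orders across code
  paths may resolve a genuine tie differently, which is why the
  equivalence tests compare magnitudes at ties.
* Group comparison uses Student's (pooled) rather than Welch's t — the
  two groups are scores from the same construction and sample sizes are
  tiny, where pooling is the convention.
* Problem sizes in the verification runs (50 seeds for recovery and
  effect detection, 200 replicates for the calibration checks, 1000
  permutations for recovery, 200 for calibration) were chosen to give
  stable rates while keeping a full verification run in the tens of
  seconds on one CPU.

## Known limitations

* Gene-label permutation ignores inter-gene correlation; on real screens
  its p-values are anti-conservative relative to phenotype permutation,
  which pre-ranked input cannot support.
* The sign-stratified FDR is a plug-in estimate; with few tested sets it
  is coarse (many exact zeros or ones).
* Alias merging by transitive closure can chain distinct biology through
  a shared hub pathway at permissive thresholds; inspect `metapathways.tsv`
  when lowering the threshold below the default.
* The t-test on 4-vs-4 diversity scores inherits the usual small-sample
  normality caveat; the calibration check shows its null p-values are
  close to uniform under the synthetic design, with a mild tail excess
  from score correlation induced by shared cluster centers.
* Diversity scores depend on the signature collection's scale; compare
  scores only within one profile matrix (the group comparison is always
  within-matrix).
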