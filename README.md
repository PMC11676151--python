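# weakpoints

Loss-of-function screens (shRNA, CRISPR) against different anti-cancer drugs
keep turning up the same genes: knocking them down sensitizes tumor cells to
treatments with completely unrelated mechanisms. The pathways these genes
belong to — proteasome, ribosome, spliceosome, transcription, cell cycle,
Akt-mTOR, tight junction — behave as generic *weak points* of the cancer
cell, and their inhibitors are prime candidates for combination therapy.

`weakpoints` is a Python package for running that inference end to end from
standard file formats, and for validating its central prediction — that
drugs which synergize with weak-point inhibitors are more *transcriptomically
diverse* than drugs synergizing with other therapeutics. It is aimed at
computational biologists integrating published knockdown screens with
connectivity-map-style drug signature collections.

## What it computes

1. **Pre-ranked gene-set enrichment** of each screen's fold-change-ranked
   sensitization hits. The statistic is the weighted Kolmogorov–Smirnov
   running sum: walking down the ranked list it rises by
   `|s_i|^w / Σ_hits |s|^w` at gene-set members and falls by `1/(N − n_hits)`
   elsewhere; the enrichment score ES is the extremum of largest magnitude,
   and the members before the peak form the leading edge. Significance comes
   from a gene-label permutation null (`p` two-sided on |ES| with a
   `+1/(n_perm+1)` pseudo-count), a normalized score
   `NES = ES / mean |same-sign null ES|`, and a sign-stratified pooled-null
   FDR. Screens keep pathways with `p < 0.05` and `q ≤ 0.25`
   (`q ≤ 0.40` for screens with fewer than 300 hits, which have less power).
2. **Cross-screen integration**: a recurrence table (pathways significant in
   ≥ k screens), merging of alias pathways whose pooled leading-edge genes
   overlap (Jaccard ≥ threshold, connected components — the mechanism behind
   umbrella calls such as grouping mTOR/VEGF/T-cell-signaling sets into one
   Akt-mTOR pathway), genes recurring in ≥ 2 screens funneled to those
   inside annotated pathways, and a hypergeometric over-representation test
   (Benjamini–Hochberg corrected) of the funneled genes.
3. **Synergy-set diversity**: for each therapeutic, the profiles of its
   curated synergizing drugs are compared by Euclidean distance
   `d(a,b) = sqrt(Σ_i (a_i − b_i)²)`; classical (Torgerson) MDS gives
   plot-ready 2-D coordinates; the diversity score is the mean pairwise
   distance; and test (weak-point inhibitor) vs control therapeutics are
   compared with a pooled-variance Student's t-test. Bias-guarding exclusion
   rules drop a control's synergizers that hit the control's own target
   pathway and a test therapeutic's synergizers that hit *other* weak-point
   pathways.
4. **Synthetic studies**: generators for screens with planted pathway
   enrichment, gene-set databases with controlled overlap, drug-signature
   matrices with mechanism-cluster structure, and synergy sets with planted
   diversity breadth — every generator returns its ground truth, so the
   whole pipeline is testable without any external download.

## Worked example

Simulate a complete study — 8 screens of 500 ranked hits over a
2000-gene universe with 3 planted pathways each, a 20-set pathway database,
32 drug profiles in 8 mechanism clusters, and 4 test + 4 control
therapeutics whose synergizers draw from 6 vs 2 clusters — then run the
diversity analysis:

```sh
weakpoints simulate --seed 7 --out-dir demo --overlap-fraction 0.5
weakpoints diversity --profiles demo/profiles.tsv \
    --profiles-metadata demo/profiles_meta.tsv \
    --synergy-sets demo/synergy_sets.tsv --out-dir demo/out
```

prints

```
t=56.284 df=6 p=2.11e-09 (test mean 24.787, control mean 16.728; 0 record(s) skipped)
```

i.e. the four test therapeutics' synergizer sets (mean pairwise signature
distance ≈ 24.8) are far more diverse than the controls' (≈ 16.7), and with
4 observations per group the pooled t-test on 6 degrees of freedom calls
the difference at p ≈ 2×10⁻⁹ — the planted analogue of a weak-point
validation. `demo/out/diversity.tsv` holds the per-therapeutic scores
together with the fraction of distance variance the 2-D plot embedding
captures, e.g.

```
therapeutic  class  n_included  n_excluded  diversity_score  variance_explained_2d
TEST_1       test   6           0           24.694           0.472
TEST_2       test   6           0           25.081           0.469
```

The full pipeline (enrichment → recurrence → merging → gene funneling →
diversity) runs from one YAML config:

```sh
weakpoints run-all --config demo/config.yaml --out-dir demo/out
```

See `weakpoints --help` for the `enrich` and `integrate` subcommands, and
`docs/methods.md` for the model, parameter and design details.

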