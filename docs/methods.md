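# Methods

## The shared-ratio statistic

For gene sets *A* and *B*, `shared_ratio` computes |A∩B| / min(|A|, |B|)
(the overlap coefficient). The statistic is defined uniformly with the
minimum in the denominator, so it is symmetric and well-defined when the two
sets have equal size. It is 1 exactly when the intersection equals the
smaller set's size, 0 exactly when the sets are disjoint, monotone under
adding a common element to both sets, and invariant under growing only the
larger set. Two empty sets have no ratio (an error); one empty set yields 0
with both sizes recorded, so filtered-to-empty target sets stay visible in
the output rather than vanishing.

Compared with Jaccard similarity, the min-denominator makes the statistic
insensitive to the size imbalance between a TF's target list (tens of genes)
and a DEG set (hundreds), which is the regime these analyses live in.
Alternative coefficients are deliberately not part of the analysis surface.

## Resampling nulls and the sign test

`null_ratio_distribution` samples regulators from a frame (default: every
regulator in the network, in sorted order) and computes each sampled
regulator's shared ratio with a fixed reference set. Sampling is without
replacement by default; a `replace` flag exists because the original
sampling scheme is not documented, as does an `exclude` list for removing
the focal regulator from its own null (not done by default). Null
distributions of this statistic are heavily zero-inflated — most regulator
pairs and most regulator/DEG combinations share nothing — so location tests
that assume continuity are avoided.

`sign_test_exceeds` is an exact binomial sign test: null samples strictly
below and strictly above the observed value are counted, ties are discarded,
and the below-count is referred to Binomial(n, ½). With
`alternative="greater"` the p-value is the upper tail of the below-count —
small when the observed ratio exceeds most of the null. With a zero observed
ratio against a zero-inflated null, every sample can tie; this raises a
degenerate-test error rather than returning a misleading p-value. The
default is one-sided because the scientific question is directional
(does the focal TF overlap *more* than random TFs); a two-sided option
exists.

`sample_tf_pairs` draws unique ordered pairs of distinct regulators without
replacement from the N·(N−1) possible ordered pairs, returning all of them
when fewer than requested exist (a 3-member family yields exactly 6 pairs).
Ordered pairs are the only convention consistent with that count; since the
ratio is symmetric, the ordering affects counts, never values. Pair indices
are drawn by rejection sampling with a seen-set, O(requested) regardless of
frame size.

Quartiles everywhere use linear interpolation between order statistics
(type 7, the R default); no convention was stated upstream, and type 7 is
what an R `summary()` of the same numbers would print.

## Homeolog triads

`triad_pairwise_ratios` computes the three pairwise ratios (A-B, A-D, B-D)
per syntenic 1:1:1 triad. Triads with any member absent from the network are
dropped with a logged count, so record count is exactly 3 × retained triads.
No genome filter applies here — the comparison needs all three subgenomes —
in contrast to DEG analyses against tetraploid data, where targets are
typically filtered to the A and B genomes.

`compare_movement_categories` runs Mann-Whitney rank-sum tests between
movement categories (Stable vs Mid 80, Stable vs Dynamic, Mid 80 vs
Dynamic), two-sided by default since the direction was not pre-registered; a
comparison's category labels come from the triad, and Unclassified triads
are excluded from the tests but kept in the all-homeolog distribution.
The `method` argument is passed to the rank-sum implementation ("auto"
selects the exact distribution only for small groups).

`target_genome_proportions` computes, per regulator, the fraction of its
targets on each subgenome, over targets with known genome only.
`genome_origin_association` compares these per-regulator proportion
distributions between TF-origin groups (A vs B, A vs D, B vs D, for each
target genome) with two-sample KS tests, Benjamini-Hochberg adjusted across
all tests of one invocation; stratifying by movement category adjusts within
stratum. Forming the KS samples from per-TF proportions (rather than
pooled per-target indicators) keeps the TF as the sampling unit; this
construction choice is not forced by anything upstream and is flagged here.

## Candidate regulators

`filter_degs` uses strict inequality (q < threshold), matching the
q < 0.05 convention. `scan_candidate_regulators` returns every regulator
whose shared ratio with a DEG set strictly exceeds the focal regulator's at
≥ 1 timepoint, labelled by which timepoints (the 12-only / 22-only / both
split); strictness means the focal TF can never be its own candidate. The
scan annotates, it does not re-test: no multiple-testing correction is
applied, because the candidate list is a ranking device, not an inference.

`senescence_fold_change` is (mean TPM over senescent samples + ε) /
(mean over non-senescent samples + ε) with ε = 0.01 TPM, replicates averaged
per tissue first so unbalanced tissues contribute equally. Both a ≥ 2 flag
(`twofold`) and a > 2 flag (`twofold_strict`) are reported, since "greater
than twofold" is ambiguous at the boundary. The upstream definition of the
fold change defers to prior work without an equation; this ratio-of-means
with pseudocount is this package's choice and is configurable.

`ranked_quartile_positions` bins subset members by rank position in the
q-sorted DEG list (four equal-size rank bins, remainder to earlier bins,
q-ties broken by gene id) — rank bins, not q-value quantiles, because the
question is where genes sit in the ranked list.

## The synthetic world

`synthdata` generates inputs whose structure every analysis stage can
recover:

| parameter | default | why |
|---|---|---|
| background TFs / genes | 3,000 / 20,000 | the real network's scale (3,384 TFs); sparse enough that two random TFs share ≈ nothing (expected pairwise overlap ≈ t²/n_genes ≈ 0.15 genes) |
| targets per TF | 30–80 | brackets the focal TF's 79 predicted targets |
| triads per category | 44 / 530 / 52 (Stable/Mid80/Dynamic) | equals the published 132 / 1,590 / 156 pairwise comparisons |
| category overlap means | 0.41 / 0.39 / 0.35 | the published category means |
| overlap concentration κ | 4.0 | Beta(mean·κ, (1−mean)·κ) per-triad overlap reproduces the published interquartile spread (≈ 0.2–0.6); κ=None plants the mean exactly |
| causal overlap r | 0.15 | the focal TF's 12 DAA overlap (12/79) |
| DEG sizes | 866 / 130 (12/22 DAA) | the published DEG counts |
| q model | Beta(0.5, 20) for DEGs, Uniform(0,1) otherwise | minimal mixture with an enriched near-zero peak; ~85% of DEG q-values fall below 0.05 |
| expression fold / noise | 2.5 / lognormal σ=0.1, 3 replicates | a clearly-detectable planted fold with realistic replicate scatter |

Planting is exact by construction: each triad draws one core of common
targets sized round(ρ·t) and mutually disjoint non-core targets, so every
within-triad pairwise ratio equals round(ρ·t)/t with no rejection sampling.
DEG membership includes exactly round(r·|targets|) causal targets, with the
random fill drawn outside the causal (and planted-candidate) target sets, so
planted overlaps are exact before q-value noise.

What the generator does **not** emulate: correlated q-values, hub structure
or family-dependent target sharing among background TFs, genome linkage
between a TF and its targets (background genomes are i.i.d.), expression
compositionality, or read-level noise. A green planted-recovery test
therefore establishes that the statistics recover the structure they are
designed to see — not that the model captures every property of real
networks. One consequence of the spec'd q-model worth knowing: non-DEG genes
carry Uniform(0,1) q-values, so thresholding at 0.05 admits ≈ 5% of the
background into the realized DEG set; recovered focal ratios sit slightly
off the planted value for this reason, and tests account for it.

## Numerical and reproducibility choices

* Top-N edge trimming breaks weight ties by lexicographic
  (regulator, target) order — deterministic and idempotent.
* One `numpy` Generator is seeded per pipeline run and consumed in a fixed
  stage order (per-timepoint DEG nulls → all-TF pairs → per-family pairs in
  sorted family order), so a single seed reproduces all outputs
  byte-for-byte; outputs carry version/seed/config-hash provenance headers.
* Gene identifiers are opaque, case-sensitive strings; genome labels come
  from the annotation table. A RefSeq-style identifier parser
  (`genome_from_refseq_id`) exists but is never applied implicitly.
* Regulators whose target set is empty after filtering are dropped from
  sampling frames with logged counts; analyses whose record set ends up
  empty raise an explicit empty-analysis error (CLI exit code 4).

## Known limitations

* The rank-sum and KS tests inherit their tie handling from scipy; with
  heavily discrete ratio distributions the "auto" method is asymptotic for
  all but small groups.
* With the realistic per-triad overlap spread (κ=4), the planted Stable >
  Mid 80 > Dynamic ordering of category means is a stochastic property at
  the published group sizes (the Stable and Dynamic groups are small); it is
  recovered essentially always only under exact-core planting (κ=None).
* Movement categories are consumed as input lists; deriving them from
  expression data belongs to the upstream study and is out of scope, as are
  network inference itself, pseudoalignment/differential-expression
  estimation, and ID conversion between annotation versions.
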