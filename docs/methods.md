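# Methods

## Data model

Four artifacts drive the pipeline. The **trait codebook** declares each
trait's kind; qualitative traits carry an ordered label→code encoding with
consecutive non-negative integer codes starting at 0 (binary traits 0/1),
quantitative traits carry units. The **germplasm register** lists
accessions with rank (species or cultivar), optional infrageneric section
(species only), and optional parent ids (cultivars). The **observation
table** holds one row per (germplasm, replicate leaf, trait). The
**trait matrix** is the germplasm-level aggregate used by all statistics:
replicate mean for quantitative traits, replicate mode for qualitative
traits with ties broken to the smallest code. Mean and smallest-code-mode
were chosen because both are deterministic and invariant to replicate
order; field protocols rarely state how replicate scores are collapsed, and
any defensible alternative (median, consensus) changes only values, not
contracts. Missing cells are errors, not imputed: the measurement protocol
this emulates scores every trait on every composite leaf sample. All files
are UTF-8 tab-separated text with `.` decimals; codebooks may be JSON.

Qualitative codes are treated as numeric ordinals downstream (they enter
standardization and Euclidean distance like quantitative values). This is
the standard practice in numerical-taxonomy studies of this kind; a Gower
distance is provided as an option for users who prefer scale-free mixed
handling, but it is off by default so that defaults match the reference
workflow.

## Screening indices

Simpson's D uses the unbiased pair form 1 − Σnᵢ(nᵢ−1)/[n(n−1)]: the
probability that two accessions drawn without replacement differ in level.
H is Shannon entropy in nats; E = H/ln k. Two interpretation choices were
genuinely open:

- **Hₖ = ln k with k the number of *declared* levels**, not observed
  levels. Declared k is deterministic (it does not change when a rare
  level drops out of a subset) and penalizes traits whose scale is mostly
  unused; a log message flags traits where observed < declared.
- **E of a single-level trait is defined as 0** (the trait carries no
  information) rather than 0/0.

CV̄ and CV use the sample standard deviation (ddof = 1) — the small-sample
convention appropriate to 30-leaf replicate sets; the population/sample
choice shifts CVs by < 2% at n = 30 and does not move any screening
decision that isn't already on the gate. All gates are inclusive (≥/≤) as
printed in the criteria. Degenerate inputs (zero germplasm mean, fewer
than 2 replicates, all-zero counts) raise errors naming the offender.

## PCA retention and the loading filter

PCA is computed on the trait **correlation** matrix of the standardized
germplasm-level matrix (not covariance — traits are dimensionless after
z-scoring), via symmetric eigendecomposition. Components with λ ≥ 0.90 are
retained; variance contribution is λ/p × 100. Eigenvector signs follow the
convention that each component's largest-magnitude entry is positive, so
output is stable across linear-algebra backends; the low-contribution
filter uses absolute values and is sign-invariant.

The result carries two trait × component matrices: the raw orthonormal
eigenvectors V (V diag(λ) Vᵀ reconstructs the correlation matrix, asserted
to 1e−8 in tests) and the **component loadings** A = V√λ, whose entries
are trait–component correlations. Published component tables in this
literature print A (entries like 0.95 and 0.93 in one column are impossible
for an orthonormal eigenvector), so the |loading| ≥ 0.60 significance
threshold operates on A, with a 1e−9 tolerance at the boundary. A trait
survives iff its maximum |loading| over the *retained* components reaches
the threshold.

## Correlation pruning

Pairs with |Pearson r| > 0.80 (strict) form a conflict graph. Because the
reference workflow picks survivors by observational convenience — a
criterion no statistic encodes — survivors are specified by an explicit
preference list. Among non-preferred vertices the highest-degree one is
removed first, ties broken alphabetically, until no conflict edge remains;
a conflict between two preferred traits keeps the earlier-listed one and
logs a warning. The greedy order is documented for determinism; on the
published six-pair example it attains the minimum removal (5 of 26), and a
brute-force minimum-removal oracle checks small instances in the tests.

## Clustering

Euclidean distances on the standardized final traits, Ward's criterion on
squared distances (Ward.D2), computed by scipy's linkage. Merge heights
use the distance-scale convention h = √(2·ΔESS) so a two-point merge
equals the points' Euclidean distance; the tests verify this identity and
the equivalence of the whole merge sequence with an exhaustive
minimal-ESS-increase oracle on small instances. Partitions are taken **by
cluster count k** (defaults k = 2 and k = 5), not by cut height: heights
depend on the data and on linkage-height conventions, counts are
reproducible. Cluster labels are renumbered 1..k by first occurrence in
input order. Degenerate trees with tied merge heights where exactly k
clusters cannot be formed raise an error rather than silently returning a
different k.

Group summaries report per-cluster member counts (species/cultivar split),
quantitative trait mean ± sd (singleton clusters report sd = 0 with a
flag), and qualitative modal levels. Species proportions (percent species
within a cluster) and species shares (how the species distribute across
clusters) are rounded to one decimal, half-up, the convention used when
such percentages are reported.

## Ancestor-inclined statistics

The probability counts each pedigreed cultivar once, however many of its
1–2 known parents co-cluster with it; parents absent from the partition
drop from that cultivar's check, and a cultivar with no parent in the
partition leaves the denominator (logged). A cultivar with one known
parent is a full unit in the denominator — full and partial pedigrees are
counted together. Breeding frequency assigns every cultivar two parental
slots; known parents fill one slot each, and the unfilled remainder is
reported as explicit unknown mass so frequencies stay comparable across
partial pedigrees (parts sum to 100%).

The section/cluster ordinal correlation builds one (section code, cluster
code) pair per species appearing in both code maps and reports Pearson r,
r², the two-sided p from the exact t transform t = r√((n−2)/(1−r²)), and
n, so the pairing is auditable. No multiple-testing correction is applied
(a single planned test). The construction of the analogous published
statistic is underdetermined (per-species pairs vs. aggregated
proportions), which is why this operation documents its pairing and
exposes n rather than targeting any particular published value.

## Synthetic populations

The generator emulates the structure that makes this workflow function:

- **Latent groups.** Species are assigned to groups round-robin (every
  group populated); each group has its own level-probability vector per
  qualitative trait and mean per quantitative trait.
- **Trait families.** Real leaf panels contain correlated families
  (allometric size measures, pigmentation, venation). Family mates share a
  per-germplasm standard-normal latent through a Gaussian copula: each
  trait's draw uses z = a·u_family + √(1−a²)·ε and is mapped through the
  trait's own marginal (inverse-CDF for categorical levels, mean + sd·z
  for quantitative). Marginals are therefore exactly as configured while
  within-family correlation ≈ a₁a₂. This gives the PCA stage peaked,
  Table-style loadings and the pruning stage genuine r > 0.8 pairs.
- **Pedigrees.** Each cultivar draws 1–2 parent species; one *inheritance
  parent* is chosen uniformly, and every trait is copied from it with
  probability `inheritance_fidelity`, otherwise drawn from the group-pooled
  distribution. At fidelity 1 a cultivar's trait vector equals one
  parent's; at fidelity 0 it is independent of its parents.
- **Replicate noise.** Quantitative replicates are v·(1 + (CV/100)·z) —
  multiplicative Gaussian, so the within-germplasm CV is scale-free and
  equals the configured target in expectation; draws pushed ≤ 0 are
  clipped to a small positive floor (10⁻⁸) and logged. Qualitative
  replicates flip to a uniformly chosen other level with probability
  `flip_prob` (default 0.02).

One `numpy.random.Generator` seeded by the single config seed drives all
sampling; identical configs give byte-identical outputs.

`default_config` mirrors a realistic study: 34 species + 39 cultivars in 5
groups, 39 qualitative + 11 quantitative candidates, 30 replicates,
fidelity 0.9. Thirteen qualitative traits are near-monomorphic (0.92 mass
on one level — screened out for low diversity), 26 are polymorphic (0.75
peak mass, group-dependent peaks) in 11 families; 8 quantitative traits
combine 6% within-CV with 80% relative among-group spread (≈ 20% among-CV)
in 3 families, 2 carry 16% replicate noise (fail CV̄ ≤ 10%), and 1 is flat
across groups (fails CV ≥ 15%). Family copula loadings are drawn once in
[0.80, 0.95). These constants were fixed at design time as a realistic
emulation; the layout rng is decoupled from the data rng so the same panel
design is used across seeds.

**What passing tests do and do not show.** The generator produces
conditionally independent traits given group and family latents, exact
marginals, and noiseless registry data. Real data add measurement error in
scoring ordinal levels, environmental plasticity correlated across traits,
phylogenetic non-independence among species, and pedigree errors. Recovery
results (ARI = 1 under high separation, ancestor-inclined 100% at fidelity
1) therefore validate the *machinery*, not the field performance of the
method on any particular collection.

## Problem sizes and numerics

Tests and the acceptance script run the study-scale default (73 accessions
× 50 traits × 30 replicates, ≈ 110k observation rows, ≈ 1 s per full
pipeline run), exhaustive oracle checks at small n (all 4094 level-count
vectors with n ≤ 12 for Simpson's D; 100 random instances with n ≤ 8 for
Ward.D2), and 200-replication Monte-Carlo for the fidelity-0 chance-level
check with a compact 23-accession configuration. Eigenvalues are clipped
at zero with a −1e−10 PSD tolerance; the loading threshold uses 1e−9; the
reconstruction invariant uses 1e−8.

## Known limitations

- Cut heights are not comparable to published dendrogram heights obtained
  under other linkage-height conventions; use cluster counts.
- The pruning heuristic is greedy; it is optimal on the published example
  and on small instances we enumerate, but global minimality is not
  guaranteed for arbitrary conflict graphs.
- Ordinal coding imposes equal spacing between adjacent qualitative
  levels; the Gower option relaxes scale but not order.
- The ordinal evolutionary-order correlation treats ranks as interval
  data, as in the reference workflow; a rank-based coefficient would be a
  defensible alternative.
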