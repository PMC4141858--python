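# Methods

## The problem and the model

Anholocyclic aphids reproduce by apomictic parthenogenesis: offspring are
genetic copies of their mother apart from mutation. A worldwide
microsatellite survey of such a species therefore does not sample a
panmictic gene pool but a small number of clones, each smeared into a
cloud of near-identical multilocus genotypes (MLGs) by stepwise
microsatellite mutation and fragment-scoring error. The analysis task is
to recover those clones — multilocus lineages (MLLs) — from the genotype
table, to quantify how confident one can be that repeated genotypes are
truly clonal, and to describe the residual population structure with
estimators that are aware of clonality.

## Allelic distance

The distance between two diploid genotypes is the number of allelic
differences: per locus `2 − |multiset intersection|` of the two allele
pairs, summed over loci. A heterozygote 206/210 against 204/206 counts
one difference (the shared 206 is matched), not two; this keeps the
distance consistent with single stepwise mutations, which change exactly
one allele call. The distance is a metric (identity, symmetry, triangle
inequality), verified by brute force in the tests. Loci with missing
calls in either genotype are skipped and the sum rescaled by `L/(L−m)`
(rounded to nearest integer); this is configurable and irrelevant for the
shipped reference data, which are complete.

## Threshold detection and MLL assignment

For clonal data, the histogram of pairwise MLG distances is multimodal:
a low mode of within-clone differences (mutation/scoring noise), a gap,
then between-clone modes. The threshold is the first interior local
minimum — the smallest `d ≥ 2` with `count(d) < count(d−1)` and
`count(d) ≤ count(d+1)`, scanning the zero-filled support and breaking
ties toward smaller `d`. Monotone histograms have no detectable
threshold; the caller must then supply one (the CLI's `--threshold INT`).
MLLs are the connected components of the graph joining MLGs at distance
strictly below the threshold (single linkage), so "grouped at threshold 5"
means "differing by one to four alleles". Lineage labels are renumbered
deterministically by first member in MLG-id order, and MLG ids themselves
are lexicographic in the genotype, so the whole partition is reproducible
bit-for-bit regardless of input row order. On the shipped reference panel
the detected threshold is 5 and the five resulting lineages match the
published assignment exactly.

`LineageDelimiter` wraps distance computation, threshold detection and
assignment as a scikit-learn clusterer (`fit`, `labels_`, `threshold_`,
`metric="allele"|"precomputed"`); the module-level functions are the
primitives it composes and remain the natural interface inside the
pipeline.

## p_gen and p_sex

Whether the members of an MLL could instead be products of distinct sexual
events is assessed on the MLL's *identical loci* — those at which every
member MLG carries the same allele pair. The lineage is treated as one
repeated genotype with `n_copies` equal to its total MLG observations and
`N` the dataset's total observations.

The genotype probability under random mating uses inbreeding-corrected
genotype frequencies per locus:

- homozygote: `f_i² + f_i(1 − f_i) F_IS`
- heterozygote: `2 f_i f_j (1 − F_IS)`

multiplied over the loci used; with `F_IS = 0` this is the Hardy–Weinberg
product. Since clonal data have strongly negative F_IS, the correction
*increases* heterozygote probabilities — the conservative direction for
this test. Allele frequencies default to the round-robin estimator:
frequencies at locus *l* are counted over the unique genotypes obtained
when locus *l* is excluded from the collapse, so a large clone inflates
its alleles only once per distinct background; alleles lost by that
collapse retain one pseudo-copy so the probability stays defined. A plain
counting estimator is available (`frequency_method="simple"`), as is a
user-supplied F_IS; by default F_IS is the multilocus Weir–Cockerham
estimate on the MLG representatives.

Then `p_sex = P(X ≥ n_copies)` with `X ~ Binomial(N, p_gen)`; values
below 0.01 are taken to support clonal identity. p_sex is monotone in
both `p_gen` and `N`, which the tests check on a grid.

## Clonal richness

`R = (G − 1)/(N − 1)` with G the number of genotypes (MLGs or MLLs) and N
the number of retained analysis units; 0 means monoclonal, 1 all
distinct. The reference survey retains 98 representatives (one per MLG
per field sample), giving `R_MLG = 35/97 ≈ 0.361` and
`R_MLL = 4/97 ≈ 0.041`; reports round to three decimals.

## Minimum spanning network

Kruskal's algorithm with explicit tie handling: edges are processed in
non-decreasing weight; within a weight class, any edge joining two
components that were still separate when the class began belongs to *some*
MST — the first such edge (id order) per merge becomes a tree edge, the
rest are flagged `alternative`. The tree-edge weight sum is the (unique)
MST weight, and the union of tree and alternative edges equals the union
of all MSTs, which the tests verify against exhaustive spanning-tree
enumeration for n ≤ 7 and a standard MST oracle up to n = 36.
`expand_step_nodes` replaces a length-k edge by k unit edges through
k − 1 inferred nodes so plots can show one mutational step per edge.
Layout/rendering is out of scope; GraphML/DOT/edge-list exports carry the
lineage and host annotations.

## Population genetics

Estimators follow Weir & Cockerham (1984), multi-allelic, combined over
alleles and loci as ratios of summed variance components:

- within-population f (F_IS): `f = 1 − Σc / Σ(b + c)` with, per allele,
  `b = n/(n−1) (p(1−p) − (2n−1)/(4n) h)` and `c = h/2`;
- pairwise θ (F_ST): the full a/b/c components for r = 2 populations,
  `θ = Σa / Σ(a+b+c)`.

A population of fixed heterozygotes at equal allele frequencies gives
f = −1 exactly; fully fixed differences give θ = 1; both endpoints are
tested, along with a frozen hand-computed worked example (θ = 7/76) and
simulation checks near zero under panmixia.

Exact tests use seeded Monte-Carlo permutation with the
`(1 + k)/(1 + n_perm)` estimator rather than a Markov chain: alleles are
randomly re-paired within population and locus, the statistic being the
conditional probability of the genotype table (two-sided) or observed
heterozygosity (one-sided excess/deficit). A vectorised multilocus
variant (`hwe_test_global`) sums observed heterozygotes over polymorphic
loci and permutes each locus independently. Differentiation uses the
genic G-test (allele × population table per locus, `G = 2Σ o ln(o/e)`,
summed over loci) with p by permutation of individuals among populations.
Null calibration (uniform p-values) is asserted by KS tests over 200
seeded replicates. Analyses run on the one-representative-per-sample
reduction; running on a raw clonal panel is possible but mixes in clonal
pseudo-replication.

Per-locus Hardy–Weinberg p-values are reported raw; apply your preferred
multiplicity correction downstream (the pipeline writes per-locus tables).

## COI barcodes

Divergence is the uncorrected p-distance — differing sites over sites
unambiguous (A/C/G/T) in both sequences, N and gaps excluded pairwise,
standard barcoding practice. Model-corrected distances and tree building
are out of scope. Haplotypes are exact-match collapses; the haplotype
network reuses the MSN builder on integer substitution counts. Mean
divergence is reported both weighted by individual (all sequence pairs,
within-haplotype pairs contributing zero) and by distinct haplotype pair.

## The synthetic generator

`simulate_clonal_dataset` emulates the worldwide survey the analysis
assumes: `n_lineages` founder genotypes drawn on a dinucleotide allele
grid (180–260 bp, 2 bp motif), rejected until pairwise allelic distance
≥ `founder_min_distance` (default 8) and forced to carry both
heterozygous and homozygous loci (heterozygous with probability 0.5), so
each lineage shows the frozen-heterozygosity clonal signature. Samples
(default 57, over 42 localities and 2 hosts, 1333 individuals — the
survey's scale) are assigned one lineage each in blocks weighted
(12, 7, 25, 12, 1), mirroring the strong geographic structuring of the
reference survey. Each individual copies its founder and receives
`Binomial(2L·generations, μ)` stepwise ±1-motif mutations (defaults
`generations = 60`, `μ = 2 × 10⁻⁴`, capped at 2 per individual), which
yields within-lineage MLGs 1–4 steps apart — the separable regime the
threshold detector assumes, with founders ≥ 8 steps apart. An optional
scoring-error operator shifts allele calls ±1 motif at a given rate.
`simulate_coi` gives each lineage a founder haplotype at configured
substitution counts from a root sequence (default (0, 1, 1, 1, 2) at
distinct sites over 658 bp, i.e. five haplotypes and five substitutions),
inherited clonally with optional per-individual noise.

What the generator does *not* emulate: null alleles and allele dropout,
homoplasic back-mutation across lineages, sexual admixture (a switch
exists only implicitly via high mutation settings), linkage, uneven
within-sample clone competition, and COI heteroplasmy. Passing recovery
tests therefore show the pipeline is correct *in the separable clonal
regime it was designed for*, not that every field dataset will have a
detectable histogram minimum — real data with overlapping distance
supports will (correctly) raise "no threshold detectable".

True mutation and scoring-error rates for these loci are unknown; the
defaults are stylised values chosen once to reproduce the 1–4-step
within-lineage structure of the reference panel.

## Numerical and design conventions

- Missing alleles: integer sentinel 0, rendered `0/0`; all-missing
  individuals are dropped from collapse with a warning.
- Richness N: the retained-representative count (the published values
  follow this convention), not the field-sample count.
- Permutation p-values are never 0 (`(1+k)/(1+n_perm)`) and are
  reproducible given `(seed, n_perm)`.
- The heterozygote-excess acceptance check uses balanced lineage weights
  (12, 11, 12, 11, 11) so every lineage population is large enough for
  the permutation test's 0.01 resolution; the recovery check keeps the
  survey's own skewed weights.
- Test and acceptance problem sizes (20 recovery seeds at 1333
  individuals; 200 replicates for null-calibration KS checks; 100 random
  MSN matrices, exhaustive enumeration up to n = 7) were chosen as the
  smallest sets that exercise each property convincingly.
- Ties everywhere are broken deterministically (lexicographic MLG ids,
  id-ordered Kruskal, first-seen representatives), so identical inputs
  give byte-identical outputs.

## Known limitations

- `detect_threshold` implements a simple first-minimum rule; heavily
  sampled datasets with noisy histograms may warrant kernel smoothing
  before thresholding.
- p_sex is computed for a lineage as a single repeated genotype on its
  identical loci; per-MLG p_sex within a lineage is available through
  `p_gen`/`p_sex` directly but not reported by the pipeline.
- θ p-values (permutation) are not implemented; the G-test covers
  differentiation significance.
- No null-allele screening, linkage-disequilibrium, bottleneck or
  assignment tests, and no ordination or tree inference.
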