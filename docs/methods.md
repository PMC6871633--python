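# Methods

`popkit` analyzes reference panels of ancestry-informative SNPs (AISNPs):
di-allelic autosomal markers whose allele frequencies differ strongly among
biogeographic populations. The package covers the full analysis arc such
panels go through — data QC, forensic match statistics, ancestry-likelihood
ranking, PCA, and drift-scale tree building — plus a generative model for
validating every stage against known truth.

## Data model

A panel is an ordered list of loci with positive-strand reference/alternate
alleles. Because every locus is di-allelic, a single frequency per locus (the
reference allele's) fully describes a population, and genotypes reduce to
reference-allele dosages in {0, 1, 2}. All file formats are tab-separated
text with `.` for missing. Loci are identified by name only; no genomic
coordinates are stored (nothing in the pipeline uses them).

Raw genotype calls may arrive as base pairs reported on either strand.
`normalize_strand` reconciles each call against the locus' allele pair or its
reverse complement and codes dosage on the positive strand. A/T and C/G loci
are their own reverse complement, so strand cannot be inferred from the
bases; the default is to reject such loci (`ambiguous_strand="reject"`)
unless the caller vouches for the source's strand convention (`"trust"`).
The packaged `default_panel()` is a deterministic *synthetic* 55-locus
stand-in (real panels' allele/strand metadata is assay-specific and not
bundled); it deliberately contains no strand-ambiguous pairs.

## Hardy–Weinberg QC

Each locus × population sample with at least `min_n` (default 5) typed
individuals is tested two ways:

* a 1-df chi-square goodness-of-fit test against the HWE proportions implied
  by the sample allele frequency, and
* a conditional exact test: given the observed allele counts, the probability
  of each possible heterozygote count h is proportional to
  `multinomial(n; a, h, b) · 2^h`; the two-sided p sums configurations no
  more probable than the observed one.

The exact test drives significance decisions — several reference samples are
small (single digits of individuals), where the chi-square's asymptotics are
unreliable — and the chi-square is reported per row. Monomorphic samples fit
HWE trivially and report p = 1 rather than being dropped. The scan summary
gives both the observed-vs-expected significant count (the "deviations beyond
chance" framing) and Bonferroni flags; no FDR is applied by default.

## Match statistics

With reference-allele frequency p at a locus, HWE genotype frequencies are
(p², 2pq, q²). Per population:

* expected random match probability `RMP = Π_l (p⁴ + 4p²q² + q⁴)` — the
  probability two random members share the full multi-locus genotype, an
  inverse measure of the panel's heterozygosity in that population (the
  per-locus term is minimized at 0.375 for p = 0.5 and equals 1 at a fixed
  locus);
* most-common-genotype frequency `MCG = Π_l max(p², 2pq, q²)`, an upper
  envelope: MCG ≥ RMP always.

Monomorphic loci legitimately contribute 1 — no flooring here, and no
correction for within-population structure. An individual's own match
probability is the product of their genotype's HWE frequencies over typed
loci; missing loci are skipped (standard forensic practice).

## Likelihood ranking

For a query profile, each reference population's likelihood is the product of
its HWE genotype frequencies at the query's typed loci; populations are
ranked by log10 likelihood. A zero frequency would send the product to zero,
so frequencies are floored before use; the default floor is `1/(2N + 2)` —
one pseudo-observation of the unseen allele given the population's sampled
chromosome count — applied symmetrically (clip into `[f, 1−f]`). The floor
is configurable (`none`, `pseudo`, `fixed:<value>`).

Because reference samples are finite, small likelihood ratios are not
meaningful: entries within one order of magnitude of the best are flagged as
not significantly different candidate origins (inclusive at the −1.0
boundary, so populations "less than an order of magnitude apart" are banded
together), with a second flag at two orders. Ties are broken by population id
(presentation only). The rank-1 log-likelihood is identically the query's
individual match probability in that population — the two modules share the
genotype-frequency core, and a test enforces the identity. When a query is a
member of the reference sample being ranked, the self-inclusion bias is
negligible at realistic sample sizes and is not corrected by default; a
leave-one-out helper (`loo_frequencies`) recomputes the source population's
frequencies without the query when genotypes are available.

## PCA

PCA runs on the population × locus frequency matrix, column-centered and by
default unscaled (covariance convention — the natural reading of "PCA of the
SNP frequencies"); `scale=True` selects the correlation convention. One
column per locus: the alternate allele's column would be exactly collinear.
Signs follow a deterministic convention (largest-magnitude loading positive);
scores are invariant, up to reflection, under locus reordering and under
tabulating 1−p instead of p.

## Drift distances and trees

The pairwise drift-scale distance is the mean over loci of
`(p_i − p_j)² / (p̄(1−p̄))` with `p̄ = (p_i + p_j)/2`. Under pure drift the
numerator's expectation grows like the accumulated drift variance and the
normalization makes the quantity approximately additive along the tree in
units of drift. Loci fixed identically in both populations carry no
information and are skipped; loci fixed in only one are kept. The distance
function is pluggable — any alternative additive distance can be dropped into
`tau_matrix`.

Tree construction proceeds in three stages:

1. **Neighbor joining** (Saitou–Nei) gives an approximately additive starting
   topology; its own branch-length estimates are kept and may be negative.
   Q-matrix ties break toward the lowest index pair, making runs reproducible.
2. **Exact least squares**: for a fixed topology, leaf-pair path lengths are
   linear in the edge lengths (`A x = d`, `A[pair, edge] = 1` iff the edge
   lies on the pair's path — equivalently, iff the edge's bipartition
   separates the pair). Ordinary least squares over all n(n−1)/2 pairs gives
   the exact minimum-ssq lengths. The fit is deliberately *unconstrained*:
   negative drift cannot exist, so negative fitted segments are the model
   diagnostic this pipeline is built to surface, and they are counted
   (internal vs terminal, below −10⁻⁹ to ignore float dust) rather than
   clipped. An NNLS mode exists for users who want constrained lengths.
3. **Topology search**: hill-climbing over nearest-neighbor-interchange
   moves. The climb descends on the least-squares ssq — the smooth objective
   NNI moves improve — with a depth-two lookahead through the one-move
   neighborhood when stuck, which escapes the shallow local optima plain
   greedy NNI falls into (observed on 6-taxon additive matrices). The
   *returned* structures are ranked by the preference order that encodes the
   scientific goal: fewest negative internal segments, then fewest negative
   terminal segments, then smallest total length, then smallest ssq.
   Everything is deterministic given the start set and cap
   (`max_structures`, default 1000). A search that ends on trees full of
   negative segments is a finding, not a failure: it says no additive drift
   tree describes the populations.

Newick output (negative lengths allowed) round-trips through a standard
reader; trees with negative segments are flagged as not drawable as additive.

## Synthetic worlds

`simulate_frequencies` draws ancestral frequencies uniform on [0.1, 0.9]
(AISNP panels are ascertained for common, informative variants) and drifts
them along a user-specified tree: a branch with drift τ maps p to a
Beta draw with mean p and variance τ·p(1−p) (Balding–Nichols
parameterization), which keeps frequencies inside (0,1) for moderate τ
without truncation; a (10⁻¹², 1−10⁻¹²) clamp guards numeric edge cases only.
Defaults state the world the pipeline targets: 55 unlinked loci and 2N = 200
chromosomes per population (~100 individuals, a typical reference sample).
`sample_genotypes` draws dosages Binomial(2, p) — exact HWE, unlinked loci.

Gene flow is a one-shot mix of each leaf toward the global mean,
`p ← (1−m)p + m·p̄`. A subtlety discovered during validation: a single
shared rate m rescales every population's deviation from the mean by the
same factor, so it shrinks all distances near-uniformly and *preserves*
additivity — it cannot create negative segments. The negative-segment
diagnostic requires *unequal* admixture (per-population rates, supported via
a dict), which distorts the distance geometry instead of rescaling it; the
test suite uses unequal rates ≥ 0.2 against a matched pure-drift world.

What the generator does not emulate: linkage between loci, ascertainment
bias of real panel selection, genotyping error, migration as a continuous
process, and population growth/bottlenecks. A green synthetic test therefore
establishes correctness of the computation under the stated model, not
robustness to those real-data features.

## Numerical choices

* Negative-segment threshold −10⁻⁹ (below float noise of exact fits, far
  above any scientifically meaningful drift).
* Exact-test tie comparison uses a 10⁻⁹ relative log-probability slack so
  float ties collapse the way integer enumeration says they should.
* Likelihood floor default `1/(2N+2)`; RMP/MCG never floored.
* Frequency TSVs round-trip at a configurable decimal precision (default 6).

## Known limitations

* The published 76-population reference frequency table is not
  redistributable with the package; the checks that reproduce its printed
  results (PCA variance percentages, the NJ tree's 25 negative segments,
  per-population RMP magnitudes) run only when a user supplies that table at
  the documented path, and the packaged default panel is a synthetic
  stand-in.
* The exact published form of the drift-scale distance is not pinned down;
  the implemented normalized squared difference is additive under drift in
  expectation, but distance-sensitive results can shift under a different
  definition (hence the pluggable distance hook).
* The NNI search is local; with the structure cap it is not guaranteed to
  find the global optimum on large, strongly non-additive matrices — which
  is also true of the exploratory search the ranking criteria mimic.
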