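# Methods

## The analysis

`haplopop` treats a phased diploid cohort as a collection of 2N haplotype
copies over an ordered panel of L biallelic SNPs, each SNP oriented as
risk / low-risk. All computation happens on the binary risk encoding; the
nucleotide strings shown in reports are a rendering of that encoding through
the panel letters, so the same haplotype always prints the same way
regardless of VCF REF/ALT conventions.

### Frequency tables and compression

Haplotype frequencies are copy counts divided by the number of complete
copies in the unit (population or supergroup); copies with missing entries
are excluded from counting and their number logged. Tables carry a SUM
column — the unweighted sum of unit frequencies — and the standard reporting
filter keeps haplotypes with SUM strictly greater than 0.1. Unit columns are
deliberately not renormalized after filtering: the retained mass per unit
(column sum, typically 0.8–0.99) is itself informative. A copy-weighted
pooled frequency is available separately.

Compression projects haplotype strings onto a subset of panel positions and
sums the frequencies (and counts) of strings that become identical. Counts
are summed exactly, so per-unit mass is conserved and projection is
idempotent and order-independent (drop sets always refer to the original
panel indices).

### Corrected pairwise differences

For units X and Y, P(X,Y) is the mean Hamming distance over all N_X·N_Y
cross pairs of copies and P(X) the mean over unordered within-unit pairs;
the differentiation statistic is P′(X,Y) = P(X,Y) − (P(X)+P(Y))/2, which may
legitimately be negative. All three means are computed from per-locus allele
counts (the number of differing pairs at a locus is (n² − Σ_a c_a²)/2
within and n_x n_y − Σ_a c_aˣ c_aʸ between), which makes 10⁵ label
permutations affordable: the permutation engine samples random
size-preserving relabelings of the pooled copies in vectorized chunks and
uses the add-one estimator p = (b+1)/(n_perm+1) with inclusive tie handling
(conservative, never exactly zero). The default n_perm is 100,000,
overridable everywhere. In the pairwise matrix, per-pair seeds derive from
the master seed and the canonical sorted-label pair order, so results do not
depend on input order.

Copies containing missing entries are excluded from these statistics (this
removes exactly the pairs any of whose members is incomplete); the intended
inputs are complete phased panels.

### AMOVA and position filtering

The three-level design (copies within populations within groups) follows
the classical sum-of-squares decomposition over squared pairwise distances:

    SSD_total = (1/2N) Σᵢⱼ d²ᵢⱼ,   SSD_WP = Σ_p (1/2N_p) Σ_{i,j∈p} d²ᵢⱼ,

SSD_APWG = SSD_WG − SSD_WP and SSD_AG = SSD_total − SSD_WG, with degrees of
freedom G−1, P−G, N−P and variance components obtained from the
expected-mean-square coefficients n, n′, n″ for unbalanced designs. The
single-locus distance is 0/1 identity; the haplotypic distance is the
Hamming count, squared inside the SSDs. Copies are collapsed to unique
haplotypes with multiplicities before the quadratic form, so cohorts of
thousands of copies cost only a small matrix product. Negative variance
components are reported as computed and flagged; by default they are
truncated at zero for the percent-variation column only (configurable), and
an all-zero-distance input returns a flagged degenerate result rather than
NaNs.

Position filtering drops panel positions whose among-group percent
variation falls strictly below a threshold. The default threshold is 8%,
which on the published per-locus profile removes positions 2, 5 and 7–9;
the alternative published phrasing ("< 7.1%") is available by simply
passing that threshold. On simulated cohorts the borderline positions
(around 6–9% among-group variation) can fall on either side of the
threshold from draw to draw — the filter result is data, not a constant —
so pipelines that require the published core definition can fix the drop
set explicitly via `PipelineConfig.drop_positions`.

### Ordination

MDS is classical (Torgerson) scaling: negative P′ entries are clamped to
zero and treated as distances (squared inside the double-centering step);
coordinates come from the top-k non-negative eigenpairs and negative
eigenvalues are reported but contribute no axis. The choice to clamp-then-
square is a documented convention — the source analysis does not state how
its MDS treated negative or squared values. PCA of frequency tables takes
haplotypes as observations and unit frequencies as variables, centers
columns (unit-variance scaling off by default, available via `scale=True`),
and fixes signs so each component's largest-magnitude loading is positive.

### Phylogeny

Haplotype trees are built over the distinct (usually core) haplotype
strings. Neighbor joining is exact on additive matrices; a negative pendant
estimate is clamped to zero with the deficit moved to its sibling so the
pair's summed length is preserved. Likelihoods use the Jukes–Cantor model
(equal base frequencies, P_same(t) = 1/4 + 3/4·e^(−4t/3)) via Felsenstein's
pruning recursion, which for these binary-state haplotypes is insensitive
to the finer substitution-model details; branch lengths are bounded in
[1e-9, 20] and optimized coordinate-wise by bounded scalar search to a
log-likelihood tolerance of 1e-6. Up to 7 taxa every unrooted topology is
scored; beyond that an NJ start is improved by NNI hill climbing.
Likelihood ties break to the lexicographically smallest topology-only
Newick string, making the search deterministic.

Ancestral annotation roots the tree in the middle of the pendant branch of
the haplotype most frequent in the designated ancestral unit (ties to the
lexicographically smallest haplotype) — there is no outgroup sequence, so
outgroup rooting is not an option. Internal states come from Fitch
parsimony with ties resolved toward the parent state (at the root, toward
the ancestral leaf); each branch is annotated with the positions whose
state changes, and each leaf with its per-unit frequencies and risk load.

### Risk modelling

Risk load is the count of risk alleles a haplotype carries over the panel
subset; load 0 / load ℓ / anything else classify as lowest, highest and
intermediate risk. The Yin-Yang detector returns the highest-total pair of
haplotypes complementary at every position. Hardy–Weinberg diplotype
inference takes the two Yin-Yang haplotype frequencies (H = low-risk,
R = risk) and reports HH/HR/RR proportions either *raw* (an `other`
category absorbs the mass not covered by the two haplotypes) or
*renormalized* (the two frequencies rescaled to sum to one). Both modes are
first-class because published analyses mix them; the mode is recorded in
the output. Counts use largest-remainder rounding so they sum exactly to N.
Sex-stratified frequencies report an empty stratum as undefined, never as
zero.

## The simulator

The generator's job is to realize the study conditions: K populations
nested in G groups, each population drawing its haplotype frequency vector
from Dirichlet(c · group base) and each individual being two independent
pool draws (HWE random mating, no inbreeding). It emits a phased VCF
(REF = non-risk, ALT = risk; the extraction step does not rely on this), a
1000G-style sample panel TSV and a truth manifest holding the drawn and the
exactly-recounted realized frequencies; `recount_truth` closes the loop and
fails loudly on any mismatch.

The default scenario mirrors the published cohort: 18 populations in 4
supergroups (AFR 5, EAS 5, EUR 4, SAS 4) totalling 2000 individuals, group
pools holding the six published major 15-letter haplotypes at their
published supergroup frequencies. The residual mass per group — the rare
tail, 10–29% — is modelled in two parts chosen to reproduce the published
relationship between the full-length and core tables: a *core tail* of
sub-threshold haplotypes that project into the published 10-letter cores
(sized to the printed core-minus-constituent gaps, which also realizes the
African-specific sixth core near its printed, threshold-straddling 0.101),
and *generic* off-core fillers built as two-position variants of each
group's own majors, each split into a pair differing across the five
low-variance positions. The split mimics the real tail's polymorphism at
those positions, giving the default scenario a per-locus among-group
variance profile with the published shape.

Defaults and why: Dirichlet concentration c = 100, putting
within-continental-group differentiation at the few-percent level typical
of human continental groups; sex ratio 0.5 with sex-independent haplotype
assignment (the null against which sex effects can be tested); population
sizes as published (504/504/503/489 per group).

What the simulator does **not** emulate: recombination and mutation (the
pool is fixed; genealogy is out of scope), linkage decay across the region,
genotyping error or missingness, admixed individuals, and any true
sex-linked effect. Tests passing on simulated data therefore demonstrate
the correctness and calibration of the estimators under the stated
frequency model, not robustness to those real-data complications.

## Problem sizes

The test suite and the acceptance script scale their computations to desk
size as the package's own choice of experiment design: permutation
calibration uses 500 replicates of two 50-copy samples at 199 permutations;
oracle-equivalence checks use cohorts of at most 16 copies against explicit
pair enumeration; parameter recovery uses four units of 500 individuals;
the full default scenario (2000 individuals) is simulated once per run with
999 permutations for the 18×18 differentiation matrix. The library defaults
(100,000 permutations) remain those of the published analysis.

## Known limitations

- The AMOVA is exactly three-level; deeper hierarchies are out of scope.
- No analytical p-values for P′ (permutation only) and no permutation tests
  for AMOVA components.
- No haploblock detection or LD computation; haploblock labels are carried
  as panel annotations only.
- `ml_tree` is limited to 12 taxa; the pipeline keeps the 12 most frequent
  cores when a noisy cohort yields more.
- GWAS p-values on the panel are annotations and are never recomputed.
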