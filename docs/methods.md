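# Methods

This note records the statistical machinery implemented in `herdchar`, the
assumptions behind it, the defaults and why they were chosen, and the places
where the underlying literature leaves a genuine design choice.

## Data model

The universal container is a samples × SNPs matrix of minor-allele dosages
in {0, 1, 2} with −1 as the missing sentinel, plus an ordered SNP map
(autosome, 1-based bp position, alleles) and per-sample population labels.
The minor allele is oriented once at load time from the pooled frequency over
all samples (ties resolve to the A1/first-seen allele, which is
dialect-specific for PLINK text files); per-population frequencies downstream
are computed in this pooled orientation. All estimators handle missingness
complete-case per locus (or per locus pair); nothing imputes except PCA.
Bin edges everywhere are half-open `[lo, hi)`.

Non-autosomal markers are skipped at load with a warning: the estimators
assume autosomal diploid Hardy–Weinberg-style sampling and would be biased by
X/Y/MT copy-number differences.

## QC and pruning

SNP call-rate filtering runs before sample call-rate filtering (the order is
not canonical in the field; SNP-first matches common practice and makes the
report deterministic). Both thresholds default to 0.95.

LD pruning is the greedy windowed scheme: within each window of
`window_snps` markers (per chromosome), while any retained pair has
r² above the threshold, the lower-MAF member is removed (tie → later map
position); the window then slides by `step_snps`. r² here is the squared
Pearson correlation of dosages (the genotype-correlation definition used by
the standard tooling for pruning decisions). The default threshold is 0.2
with a 50-SNP window and 5-SNP step; a literal threshold of 2 is rejected as
impossible for a squared correlation. VIF-based pruning is not implemented.

## Within-population diversity

Per population and SNP: H_O is the heterozygote fraction among non-missing
calls; H_E uses the unbiased small-sample form (2n/(2n−1))·2p̂(1−p̂) —
chosen because breed panels often include populations of 10–25 animals,
where the plain 2pq form is noticeably biased; the plain form is available
via `unbiased_he=False`. MAF is min(p̂, 1−p̂). Means and SDs are across SNPs
(not across individuals). Loci monomorphic within a population contribute
H_O = H_E = 0 to the means (genome-wide-mean semantics); loci with zero
calls are excluded.

F_IS is the Weir–Cockerham within-population f = 1 − Σc/Σ(b+c), the
estimator the standard diversity packages report; unlike 1 − H̄_O/H̄_E it
weights loci by information content and can legitimately be negative under
heterozygote excess. The simple ratio form is exposed alongside for
comparison, and the two agree on large panmictic simulations.

## Weir–Cockerham F-statistics

Per-locus variance components follow the 1984 ANOVA estimators computed
from per-population sample sizes, allele frequencies and heterozygote
frequencies; populations with zero calls at a locus are excluded from that
locus. Multi-locus statistics combine components by ratio-of-sums (not
mean-of-ratios), the stable choice for low-information loci; the Wright
identity then holds exactly by construction. Negative sums are reported
as computed.

Inference: bootstrap resamples loci with replacement (95% percentile
intervals); the F_ST p-value permutes individuals' population labels; the
F_IS p-value re-pairs allele copies within populations (breaking
within-individual correlation while preserving allele counts). Permutation
p-values use the (hits+1)/(n+1) convention.

`pairwise_fst` runs the same machinery on each population pair alone, so the
matrix is symmetric with a zero diagonal and each entry is definitionally the
two-population global estimate. Populations with fewer than two samples are
excluded.

## AMOVA

Each diploid individual contributes two allele copies per locus (gametic
coding; phase-free, since the within-individual level depends only on
heterozygosity). With the 0/1 mismatch distance the three-level analysis is
an ANOVA on allele indicators; sums of squares and degrees of freedom are
accumulated over loci (the locus-summed variant; a locus-by-locus or
distance-matrix AMOVA would be an alternative), and the standard mean-square
equations yield σ²_a, σ²_b, σ²_c with the usual unequal-size coefficient
n_c on copy counts. Negative intermediate components are reported as
computed. Percent components are each divided by the same total, so they sum
to exactly 100. Permutations: whole individuals across populations for the
among-population level; allele copies re-paired within populations for the
within-individual level. The among-population percentage and the
multi-locus F_ST estimate the same quantity and agree to Monte-Carlo
tolerance on island-model simulations.

## Nei D_A and neighbor joining

D_A = 1 − (1/r) Σ_j Σ_i √(x_ij·y_ij) over r loci (a biallelic locus
contributes √(p_x p_y) + √(q_x q_y)); loci undefined in either population
are dropped from r. The square root is essential: without it the
"distance" of a population to itself is nonzero. D_A lies in [0,1], is
symmetric, and is zero exactly for identical frequency profiles. No
small-sample bias correction is applied by default.

Neighbor joining is the Saitou–Nei agglomeration with the Q-criterion.
Ties in Q are broken by the lexicographically smallest pair of clade names
(a clade is named after its smallest leaf label), making the output a pure
function of the input matrix. NJ is consistent: on an additive matrix it
returns the generating tree with exact branch lengths, which the suite
checks on random trees to 1e-9. Negative branch lengths can arise on
non-additive inputs (D_A is not additive); they are retained in the data
structure and only clamped to zero on request when writing Newick.

Bootstrap supports resample loci with replacement, rebuild the D_A matrix
and tree, and report for each internal edge of the point-estimate tree the
percentage of replicates containing the same bipartition.

## PCA

Columns are mean-centered and divided by √(p̂(1−p̂)) (Patterson scaling);
missing entries are imputed to the column mean — the standard choice for
array PCA, harmless at low missingness but worth remembering at high rates.
Monomorphic columns are skipped. Scores come from the eigendecomposition of
the sample-by-sample covariance; explained fractions are eigenvalues over
the trace. A breed-level mode runs the same decomposition on the
populations × SNPs frequency matrix, which is the natural object when only a
handful of principal components are expected to carry essentially all the
between-group variance.

## Admixture model and cross-validation

The likelihood is the binomial admixture model: dosage g_ij ~
Binomial(2, Σ_k q_ik f_kj) with Q rows on the simplex and F in [0,1].
Optimization is plain EM (multiplicative count updates) from a seeded
Dirichlet/uniform start — slower per step than quasi-Newton acceleration but
with the clean guarantee that the log-likelihood never decreases, which the
test suite asserts at every iteration. Defaults: tol 1e-6 on the
log-likelihood gain, max_iter 2000; F is clipped to [1e-6, 1−1e-6] and Q
renormalized each step. Missing entries are simply dropped from the
likelihood. K=1 is closed-form (pooled frequencies). Label switching is
resolved where needed (tests, recovery experiments) by Hungarian matching of
cluster columns.

Cross-validation masks random genotype *entries* (not whole individuals),
refits on the unmasked entries and scores masked dosages by root mean
squared deviation from the fitted expectation 2·Σ_k q_ik f_kj. CV fits use
looser tolerances (tol 1e-4, max_iter 500 by default) since ranking across
K — not the exact optimum — is what matters.

## LD and historical N_e

r² between two loci uses haplotype frequencies from the standard EM over
the double-heterozygote phase ambiguity, initialized deterministically at
linkage equilibrium; all other genotype configurations contribute
phase-known haplotype counts. A composite genotype-correlation estimator is
available via `method="composite"`. The decay summary averages r² over all
intra-chromosomal pairs in 20 fixed half-open bins: [0,1) kb, 10-kb steps to
100 kb, 100-kb steps to 1 Mb.

N_e estimation converts each bin's representative distance (the mean pair
distance in the bin) to a recombination fraction linearly at a configurable
cM/Mb (default 1, a sensible genome-wide average for cattle-like genomes),
assigns the bin to t = 1/(2c) generations ago, adjusts the mean r² for
sample size by subtracting 1/(2n) (n diploids; appropriate for the
EM/haplotype-based estimator), and applies

    N_T(t) = (4 f(c))⁻¹ (1/r²_adj − α),  f(c) = c(1−c/2)/(1−c)².

α defaults to 2.2 (mutation correction); 1 and 2 are selectable — α = 2 is
the natural choice for mutation-free simulated data. Bins whose adjusted r²
would imply a non-positive N_e are dropped with a warning. For N_e the
default binning is 20 log-spaced bins from 10 kb to 4 Mb, so both recent
(large-c) and ancient (small-c) generations are represented; this is a
declared interpretation, distinct from the fixed decay bins, and
configurable.

## Synthetic generators

*Balding–Nichols*: per locus an ancestral frequency uniform on
[0.05, 0.5]; population k draws its frequency from
Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) and individuals draw binomial dosages.
Chosen because F is exactly the model's F_ST, giving a closed-form recovery
target. Defaults used in the recovery suites (4 populations × 50 diploids,
5,000 loci, F = 0.2) give the multi-locus θ a standard error small enough
that a ±0.02 band is a real test.

*Forward Wright–Fisher*: non-overlapping generations of 2N haplotypes,
random mating, recombination as Bernoulli crossovers between adjacent loci
at the Haldane inter-locus fraction (cumulative-XOR strand choice), optional
symmetric mutation (default 0), and an arbitrary step trajectory of N_e —
forward rather than coalescent simulation precisely so a step trajectory can
be imposed directly. Loci start in linkage equilibrium at uniform
intermediate frequencies, so the early generations double as burn-in toward
drift–recombination equilibrium; loci monomorphic in the final sample are
dropped. The constant-N_e recovery experiment uses N_e = 100, 250
generations (≥ 2N, ample for the short-range LD that informs recent
generations), 1,500 loci on a 50-Mb chromosome at 1 cM/Mb, sampling 60
diploids, and evaluates bins mapping to t ≤ 60; estimates at ancient t are
not expected to be calibrated under this design because distant-past LD at
small c has not equilibrated from the linkage-equilibrium start.

*Admixture mixing* draws each allele copy's source population from the
individual's Q row and the allele from that source's frequency — exactly the
model the EM inverts, so recovery failures isolate estimator bugs rather
than model mismatch.

*Inbreeding injection* replaces each genotype, with probability f, by a
homozygote drawn at the population allele frequency (an
identical-by-descent allele pair), producing an expected heterozygote
deficit — hence F_IS — of f.

All generators are bit-reproducible under a fixed seed. What they do *not*
emulate about real SNP-array data: ascertainment bias of array panels,
genotyping error, linkage in the Balding–Nichols and admixture generators
(loci are exchangeable there), mutation–drift equilibrium in the
Wright–Fisher start, selection, and migration. Passing recovery tests
therefore demonstrates estimator correctness under the stated models, not
robustness to array artifacts.

## Numerical and scale choices

Simulation sizes in the test suite (thousands of loci, tens to hundreds of
individuals, 10-seed replications for stochastic claims) were chosen so each
recovery experiment has comfortable Monte-Carlo margins while the whole
suite stays quick on a single core. Permutation p-values are reported with
the add-one convention and cannot be zero. The haplotype EM iterates to an
absolute tolerance of 1e-12 with a 1000-iteration cap and flags
non-convergence. EM log-likelihood monotonicity is asserted with a 1e-8
slack to absorb the F-clipping at the box boundary.

## Known limitations

* Unphased-data AMOVA and F-statistics assume biallelic autosomal markers;
  multi-allelic loci are rejected at load.
* The admixture CV error is a generic masked-prediction score; its absolute
  values are not comparable to other software's CV numbers, only its ranking
  across K is meaningful.
* LD-based N_e inherits the usual caveats: the t = 1/(2c) mapping is a
  rough correspondence, linear physical→genetic mapping ignores local
  recombination-rate variation, and estimates at ancient generations are
  sensitive to the low-c tail of the r² distribution.
* The pipeline treats the first population as the LD/N_e target by default;
  loop over populations explicitly for per-breed trajectories.
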