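# Methods

`pilepop` estimates population-genetic quantities from samtools mpileup
data in regimes where genotypes cannot be called confidently: low or
variable coverage, pooled libraries without individual barcodes, and
genomes of unknown or mixed ploidy. This note documents the models, the
main tunable parameters, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Error model and likelihoods

Every base call `b` with Phred quality `q` is treated as wrong with
probability `eps = 10^(-q/10)`, the error being uniform over the three
other nucleotides:

    P(b | a) = 1 - eps        if b == a
             = eps / 3        otherwise

For a sample of ploidy `Y` carrying `g` copies of the minor (derived)
allele, a read is an equal-weight draw from the sample's chromosomes, so

    log P(O | G = g, Y) = sum_reads log[ (g/Y) P(b|minor) + (1 - g/Y) P(b|major) ]

All accumulation is in natural logs; mixtures of logged terms are combined
with max-shifted exponentials (log-sum-exp). Identical (base, quality)
read classes are collapsed to weighted classes, which is what makes dense
frequency grids affordable on pools with thousands of reads per site.

The major/minor/third alleles at a site are the nucleotides ranked by the
haploid (`Y = 1`) log-likelihood of all reads pooled across samples, with
ties broken in the fixed order A < C < G < T. Downstream models are
biallelic in (major, minor). A site's evidence for being bi- rather than
mono-allelic, and tri- rather than bi-allelic, is measured by nested LRTs
in which the k-allelic model takes each read as an equal-weight mixture
over the top k alleles; the equal weights are a deliberate choice (no
weight MLE) for determinism and symmetry. Negative LRTs are floored at 0;
significance is judged against a chi-square with 1 df.

## Pooled allele frequencies and SNP calling

The minor-allele frequency likelihood of a pool is the per-read mixture

    ll(f) = sum_reads log[ f P(b|minor) + (1 - f) P(b|major) ]

which is concave on [0, 1]. Three estimators are reported per site:

* **population MLE** — continuous maximiser of `ll` (no sample-size
  assumption), found by bounded golden-section/parabolic search
  (tolerance 1e-6) with explicit boundary checks;
* **sample MLE** — maximiser over the discrete grid `j/N` for
  `N = M * Y` pooled chromosomes (ties to the smaller count);
* **posterior mean** — mean of `j/N` under the uniform-prior posterior
  over the sample-allele-frequency (SAF) log-likelihood vector.

SAF vectors are stored max-shifted (maximum entry 0) rather than
normalised so likelihood-ratio semantics are preserved across sites;
posteriors are formed on the fly. SNP calling is the 1-df LRT of `f = 0`
against the MLE; the conventional cutoff 6.64 corresponds to p = 0.01.

## Site frequency spectrum and the 1/f^K fit

Under the standard neutral coalescent the probability that a variable
site has derived-allele count `f` of `N` chromosomes is proportional to
`1/f`. The package fits the one-parameter generalisation `1/f^K`
(`K = 1` constant size; `K > 1` shrinking; `K < 1` growing population)
by minimising the Kullback-Leibler divergence `D(observed || expected)`
over `K` in [0.01, 10] (golden-section, tolerance 1e-4). The divergence
is taken observed-first so empty observed classes are harmless; fixed
classes (`f = 0, N`) are excluded from the support.

The observed spectrum comes either from counting per-site sample-MLE
frequencies (`count`) or from summing per-site uniform-prior posteriors
over the SAF vectors (`afl`), which propagates low-coverage uncertainty.
An optional per-site truncation threshold zeroes posterior entries below
a given probability (renormalising per site) to damp noise; the default
is 0 (no truncation).

Because SAF vectors are indexed by the data-chosen minor allele, observed
spectra built from them carry no ancestral polarisation and are folded by
construction; the reproduction pipeline therefore fits the folded model
(classes `f` and `N - f` merged). Known behaviour at scale: with Q20
errors and modest depth, sites that are variable in the population but
monomorphic in the sample contribute spurious posterior singleton mass,
which steepens the observed spectrum and biases `K` upward by roughly
0.2 at depth 5 with 100 diploids; with near-error-free data (Q40, depth
20) the fit recovers the generating `K` to within 0.02. The truncation
threshold mitigates this at the cost of discarding genuine uncertainty.

## Case/control association

For two pools with SAF vectors `L_j` (cases) and `M_j` (controls), the
group log-likelihood of a population proportion `p` marginalises the
unknown sample count binomially:

    ll_group(p) = log sum_j exp(L_j) Binom(j; N_group, p)

The null maximises `ll_cases(p) + ll_controls(p)` over a single shared
`p`; the alternative maximises each group separately. Because the groups
may differ in chromosome count, the shared parameter is the continuous
proportion, scanned on a grid of step 1e-3 (the binomial log-pmf matrix
is cached per `N`). The LRT has 1 df. No counts or per-site frequencies
are ever assigned, so the test remains valid at low coverage.

## Ploidy inference

For sample `m` and candidate ploidy `y`, sites contribute

    log sum_{a in {major, minor}} P(R = a) sum_i P(O | G = i, y) Binom(i; y, f_a)

where `R` is the ancestral state, `i` counts derived-allele copies (the
genotype-likelihood vector for `a = minor` is the reversal of the vector
for `a = major`), and `f_a` is the derived-allele frequency the genotype
prior conditions on under assignment `a`. With a population-spectrum
prior that frequency is `E[F|K]` whichever physical allele is derived,
so the polarisation mixture is informative; with a per-site estimated
frequency the two assignments use complementary frequencies (`f`,
`1 - f`), which makes the two terms coincide algebraically — the reason
the per-site mode simply fixes `P(R=major) = 1`. Genotype probabilities
are binomial (Hardy-Weinberg) in `f_a`; inbreeding is not modelled. Four
prior configurations:

* `uniform` — flat genotype probabilities, no frequency or polarisation
  information;
* `sample` — `f` is the per-site pooled MLE, major allele taken as
  ancestral (`P(R=major) = 1`); unreliable for very small cohorts, where
  the pooled frequency is dominated by the sample being tested;
* `ancestral` — `f = E[F|K]`, the mean of the `1/f^K` population
  spectrum on `2 Ne` chromosomes, with `P(R=major)` equal to the
  spectrum's CDF at `N/2` (or a user-set probability);
* `folded` — `f = E[F|K]` with `P(R=a) = 0.5` (unknown polarisation).

The population chromosome count is `2 Ne` (diploid-population
convention), with `Ne` defaulting to 10,000. The per-sample MLE ploidies
form the inferred vector; confidence is reported as (i) an LRT against
the second most likely vector, which differs in exactly one sample
(twice the smallest per-sample margin), and (ii) a multiploidy LRT of the
free vector against the best equal-ploidy vector, chi-square with `M - 1`
df. The summed likelihood is composite (sites are linked, samples share
history), so a block bootstrap over contiguous site blocks is provided;
the per-sample frequency of each inferred ploidy across replicates is the
recommended confidence measure. Ploidy 1 cannot be assessed on SNP-called
data (conditioning on variability contradicts the haploid model), so the
tested range defaults to 2-8 when a SNP filter is active and 1-8
otherwise.

## Synthetic data generator

Per site: a population derived-allele frequency is drawn from the
`1/f^K` spectrum on `2 Ne` chromosomes (or held fixed); genotypes are
binomial in that frequency; read counts are Poisson with a per-sample
mean (optionally scaled by ploidy, "haploid depth"); each read carries
the derived allele with probability `g/Y`; errors occur at the Phred
rate and substitute a uniformly chosen other base; the ancestral allele
is the mpileup reference. Pooled mode concatenates samples into one
column. Base quality is constant per run; strand is uniform.

Not emulated: mapping error and mapping-quality variation, indels,
duplicated or overlapping reads, base-quality miscalibration and context
dependence, strand bias, linkage between sites (sites are independent),
and reference bias. Passing benchmarks therefore demonstrate statistical
correctness of the estimators under the stated error model, not
robustness to alignment artefacts in real data.

Reference designs (used by the tests and `scripts/acceptance.py`), at the
problem sizes the package adopts for routine validation:

* association power: 150 + 150 diploids, 200 causal SNPs (population
  frequencies 0.09 vs 0.04) and 200 null SNPs (0.10 both), mean depth
  20, Q20; power read at the empirical 90th percentile of null LRTs.
  Note the design's nominal power is approximately 0.81 (noncentrality
  about 6.3 at these frequencies), so single-replicate estimates
  fluctuate around 0.80 by a few points.
* SNP-calling F1: 20 diploids, 5000 sites at F = 0.05 plus 5000
  monomorphic, per-sample depth 2, Q20, threshold 6.64. At this depth
  roughly 13% of SNP sites are monomorphic in the sample and a single
  supporting read yields an LRT of only ~2.3, so recall — and hence F1
  (~0.68) — is information-limited rather than estimator-limited.
* K recovery: 100 diploids, 20,000 sites from the neutral spectrum
  (K = 1, Ne = 10,000), depth 5, Q20, folded Fit_afl fit (see the bias
  note above).
* ploidy recovery: one diploid, eight triploids, one tetraploid, 1000
  sites at 10x haploid depth, priors `sample`, `folded`, `ancestral`.

## Degenerate inputs and tie-breaks

Empty read sets yield flagged missing genotype vectors and flat SAF
vectors; sites with no retained reads are skipped (tracked per sample in
ploidy inference). Allele-ranking ties use the fixed nucleotide order;
discrete-argmax ties resolve to the smaller count. Reference base `N`
keeps the site, with alleles chosen purely from the data. All filters
apply to post-quality-filter read counts. Single-class observed spectra
push the K fit to a boundary and emit a warning.

## Limitations

The biallelic assumption is enforced, with triallelic sites flagged for
exclusion rather than modelled. The `1/f^K` family is a one-parameter
caricature of demography; it cannot represent bottleneck-then-growth
shapes. The association test assumes Hardy-Weinberg within each pool and
a shared error model between groups. Ploidy inference assumes a constant
ploidy along the analysed region per sample; within-genome aneuploidy
requires running regions separately.
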