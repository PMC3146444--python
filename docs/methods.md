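# Methods

This note documents the models implemented in `introgress`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions a user relying on the outputs
should know.

## The admixture model

The sampler targets the classic admixture model for diploid codominant
data. Latent variables and updates per sweep:

* **z** (origin of each gene copy): categorical,
  P(z = k) ∝ q_ik · p_kla, sampled independently per copy given the
  current Q and P. Missing genotypes are skipped everywhere.
* **P** (cluster allele frequencies): Dirichlet-conjugate update from the
  copy counts assigned to each cluster. Under the *independent* model the
  prior is Dirichlet(λ) per locus; under the *correlated* model (default)
  it is Dirichlet(p_anc,l · (1−F_k)/F_k), tying clusters to a shared
  ancestral frequency vector.
* **Q** (individual ancestries): Dirichlet(α + m_i1, …, α + m_iK) where
  m_ik counts copies of individual i assigned to cluster k. Individuals
  flagged as references with a cluster label are *clamped* to that
  cluster's unit vector and never updated.
* **α**: Gaussian Metropolis random walk (sd 0.025) on (0, 10], uniform
  prior, one shared α across clusters.
* **F_k** (correlated model): Gaussian Metropolis walk (sd 0.05) on
  (0, 1); gamma prior with mean 0.01 and sd 0.05.
* **p_anc** (correlated model): per locus, a mass-transfer Metropolis move
  between two randomly chosen alleles (sd 0.05), with Dirichlet(λ) prior.

λ is fixed at 1. Defaults are desk-scale — burn-in 5 000, sampling 20 000
sweeps, thinning 10 — chosen so that the full synthetic recovery
experiment runs in tens of seconds; the field-survey scale
(20 000 / 100 000) is available through `AdmixtureConfig`. The likelihood
trace is recorded at thinning points only, and
ln P(D) = mean(lnL) − var(lnL)/2 uses the sample variance of that trace.

**Supervision.** "Prior population information" is implemented as hard
clamping of reference ancestries. This is deliberately simpler than the
full migration-prior machinery of STRUCTURE's USEPOPINFO model: the
references here exist to anchor the two clusters and contribute allele
counts, which is all the supervised two-cluster analysis requires. For
supervised K = 2 runs the convention is cluster 0 = *graellsii*,
cluster 1 = *elegans*, derived from the species labels of reference
samples.

**Credible intervals** are empirical central 90% intervals of the thinned
post-burn-in Q samples. The bounds are widened, if necessary, to bracket
the posterior mean (an empirical percentile interval can exclude the mean
under extreme skew); classification always uses the posterior mean.

**Label symmetry.** Relabelling the clusters (swapping which pool anchors
which cluster) permutes the posterior Q columns, but only statistically,
not bit-for-bit: the categorical draws consume shared uniforms through an
inverse-CDF walk, so permuting cluster order changes the sample path.
The test suite verifies the permutation property within Monte-Carlo
tolerance with α frozen; α is frozen there because with very few free
individuals its posterior is broad and its slow random walk dominates
run-to-run noise.

**Combining replicate runs.** When several independent runs of the same
configuration are made, downstream analyses use the run with the highest
ln P(D); greedy column matching (`align_columns`) is provided for
consistent plotting only. CLUMPP-style averaging is out of scope.

**Mixing caveat.** A flat α trace triggers a warning, not an error. With
few unclamped individuals α is weakly identified and wanders slowly; fix
α (`alpha_proposal_sd = 0`) when it is a nuisance parameter.

## Hybrid cross simulation

`frequency_draw` mode (default) draws each offspring allele from the
parental pool's allele-frequency distribution, independently across loci —
pools are treated as being in Hardy–Weinberg and linkage equilibrium.
`pedigree` mode draws a parent individual uniformly and segregates one of
its two alleles per locus, preserving within-parent associations; use it
when F2 dose spectra (¼/½/¼) or realistic backcross variance matter. In
both modes successive crosses use the previously simulated panel as a
parental pool (re-tallied as frequencies in `frequency_draw`). Each cross
draws from its own RNG substream, so panels are stable under addition or
removal of crosses. No mutation, genotyping error or missing data are
generated.

## Ancestry bins

The published assignment groups are integer-percent intervals with gaps
(≥90 / 89–68 / 67–21 / 20–11 / ≤10). To make classification a total
function the cut points sit at the gap midpoints — 0.105, 0.205, 0.675,
0.90 — forming a partition of [0, 1] with the pure-*elegans* bin closed on
the left at 0.90 (a q of exactly 0.90 is "pure"). All cut points are
configurable; how boundary values were binned originally is not stated.

## Diversity and differentiation statistics

* Expected heterozygosity is Nei's unbiased gene diversity,
  (2n/(2n−1))(1 − Σp²), with n the non-missing diploid count.
* Group-level Ho/He/richness are unweighted means across loci; loci with
  no data in a group are excluded, never counted as zero.
* Allelic richness is rarefied to g gene copies; g defaults to the
  smallest non-missing gene count over all (group, locus) cells, so
  values are comparable across the compared groups. Binomial ratios are
  evaluated on the log-gamma scale.
* The Weir–Cockerham θ is the ratio of summed variance components over
  alleles and loci (ratio of sums, not mean of ratios). Loci monomorphic
  over all groups contribute nothing. The permutation test permutes whole
  multilocus genotypes among groups, preserving within-individual
  associations; p = (1 + #{θ* ≥ θ̂})/(n_perm + 1), so p-values lie on the
  grid (1+k)/(n_perm+1) and the type-I error is calibrated (verified by
  simulation in the test suite).
* Morph percentages are 100·count/N rounded to one decimal; rows with
  N = 0 are flagged and carry no percentages.

## Population PCA

PCA operates on populations, not individuals: rows are per-population
allele-frequency vectors over all (locus, allele) columns, weighted by
gene counts, and the weighted covariance is eigendecomposed exactly
(dense symmetric solver). Per-axis FST is *apportioned* as global θ times
the axis's inertia fraction — a reporting convention that sums to θ by
construction, not an estimator with independent sampling properties. Axis
signs are fixed by making the largest-magnitude loading positive, so
scores are reproducible bit-for-bit. The randomization test permutes
individuals among populations (sizes preserved) and compares leading
eigenvalues; this reconstruction of the original tool's randomization
scheme is a stated convention, since the scheme itself is not documented.

## Mitochondrial statistics

Sites containing gaps or ambiguous bases are removed alignment-wide
before collapsing (complete-sites policy, DnaSP-like); a pairwise-deletion
policy is available. Haplotype diversity and its sd follow Nei's h and
V(h); π is mean pairwise differences per site, computed from the
haplotype spectrum (the frequency-weighted and direct pairwise forms
agree exactly and both are tested). π is conventionally reported to five
decimals.

Two published π values are not recoverable from the printed alignment
lengths and haplotype configurations: the COII configuration ({9, 3}, one
polymorphic site, 673 bp) forces π = 0.00061, half the published 0.00122
(which would correspond to ≈335 analysed sites), and the CYTB value
depends on whether its two singleton haplotypes differ from the common
type at one or both polymorphic sites, which is unstated. The test suite
asserts the internally consistent values and documents the discrepancy;
the remaining H, sd(H) and π values are reproduced exactly.

## Synthetic data: what it does and does not emulate

Differentiation uses the Balding–Nichols model: population frequencies
are Dirichlet draws with concentration p_anc(1−θ)/θ, giving a tunable
expected FST with minimal parameters. The full scenario mirrors the
survey's shape — 442 individuals in 26 populations (220 + 166 + 56) at 6
loci, references outside Spain, Spanish individuals drawn with a known
ancestry mixture (27% pure, 58% backcross-like q ≈ 0.78, 14% F1/F2-like
q ≈ 0.45, plus a single *graellsii*-like individual) so report shapes
resemble the field tables qualitatively. The parental taxa get asymmetric
allele counts (6 vs 10 per locus) to echo the observed allelic imbalance
between the species.

The parameter-recovery scenario (two taxa at θ = 0.2, 6 loci × 10
alleles) uses *equifrequent* ancestral alleles. This matches the high
rarefied richness of the real loci (≈6–6.5 alleles retained under
rarefaction), and it matters: with strongly skewed ancestral frequencies
the Bayes-optimal estimator itself cannot recover uniform ancestries to
RMSE < 0.15 from 12 informative gene copies per individual — the recovery
bound is a property of the marker information, not of the sampler. The
recovery test's RMSE threshold sits essentially at that information
limit, which is why the ordering of simulated cross panels is asserted on
means averaged over three replicate experiments: the EB3/EB4 ancestry gap
(0.031) is comparable to the sampling error of a single 50-per-cross
panel.

What the generators do **not** emulate: mutation, null alleles and
genotyping error, linkage, within-population substructure beyond a single
Balding–Nichols layer, isolation-by-distance, and mtDNA sequence realism
beyond the haplotype configuration (backbones are random). Tests passing
on synthetic data therefore certify the statistical machinery and its
calibration, not robustness to these real-data complications.

## Degenerate inputs and tie-breaks

Half-missing genotypes are rejected at parse time, not coerced. A locus
with all data missing in a group yields an absent (NaN) statistic. K = 1
returns unit ancestries exactly. PCA of identical populations reports
zero axes; eigenvalues below 10⁻¹² of total inertia are dropped. ΔK is
undefined (NaN) where the sd of L(K) over replicate runs is zero, and
replicate runs are paired by index, truncating to the smallest replicate
count.

## Known limitations

Six microsatellite loci bound individual-level ancestry precision;
credible intervals are honest about this (see the worked example). The
sampler is single-chain; convergence is the user's responsibility for
K > 2 unsupervised runs (use replicate seeds and ln P(D)). The PCA
per-axis FST is a descriptive apportionment. The package deliberately
omits HW/linkage pre-checks, null-allele detection, alignment
construction and haplotype networks.
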