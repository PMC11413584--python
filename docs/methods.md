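# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the known limitations of
`seaselect`.

## Data model

Genotypes are biallelic SNP calls coded 0/1/2 (alternate-allele count)
with a reserved missing sentinel that never enters arithmetic; every
statistic pairwise-deletes missing calls per locus. Coordinates are
1-based in VCF on disk and 0-based half-open everywhere internally; the
conversion happens only in the I/O layer. Multiallelic and indel
records are dropped at read time with a logged count — every downstream
method assumes biallelic SNPs. Samples map to localities and localities
to coastal regions (NE/SE/S three-level hierarchy); environmental
predictors are locality-level, and individuals inherit their locality's
values wherever a per-individual design matrix is needed.

## Filters

Two threshold sets mirror common practice for reduced-representation
and transcriptome variant calls:

* GBS-style: drop loci with missing-genotype fraction > 0.20, then
  MAF < 0.01 (MAF computed on non-missing calls).
* RNA-Seq-style: variant base quality ≥ 30, summed alternate-strand
  coverage (DP4) ≥ 10, minor allele count ≥ 4 over gene copies
  (vcftools `--mac` semantics), call rate ≥ 0.98 (vcftools
  `--max-missing` semantics — the *retained* fraction, not the missing
  one), MAF ≥ 0.01. Rules apply in that fixed order; each removed locus
  is attributed to the first rule it fails, and loci failing several
  rules are listed separately so the totals are auditable.

## Diversity and structure

Unbiased expected heterozygosity uses the finite-copy correction
H_E = k/(k−1)·(1 − p² − q²) with k the non-missing gene copies. Per
locus this is algebraically identical to nucleotide diversity
π = 2x(k−x)/(k(k−1)); θ_π is reported as the *sum* of π over SNP loci
(mean pairwise multilocus difference), which is why it exceeds 1 for
multi-SNP panels; a per-site normalization is a trivial division the
caller can apply. F_IS is the multilocus ratio-of-sums 1 − ΣH_O/ΣH_E
over loci polymorphic within the population (mean-of-ratios is more
variance-sensitive at low-information loci); its permutation null
reshuffles gene copies among individuals within the population.

F_ST uses the Weir & Cockerham (1984) moment estimator: per-locus
among-population (a), among-individual (b) and within-individual (c)
components from the weighted allele frequencies, heterozygote
frequencies and the n_c sample-size correction, combined across loci as
θ = Σa/Σ(a+b+c). Monomorphic loci contribute zero to every component
and stay in the sums. Global and pairwise significance come from
permuting individuals across populations (add-one p-values, so
p ∈ [1/(n+1), 1]).

AMOVA operates on squared Euclidean distances between individual
allele-count vectors, with missing loci pairwise-deleted and each
pairwise distance rescaled by L/L_shared. Variance components follow
the standard moment equations for the two- or three-level design with
unequal sample sizes; negative components are reported as estimated and
flagged rather than truncated. Permutation strategies differ by level:
Φ_ST permutes individuals freely, Φ_SC within regions, Φ_CT permutes
whole localities among regions. Singleton localities are excluded with
a warning.

## Detection channels

**RDA.** The centered, mean-imputed genotype matrix is regressed on the
standardized predictor matrix; the constrained ordination is the SVD of
the fitted values. Full-model significance uses the pseudo-F
(constrained variance per constrained axis over residual variance per
residual df) under row permutations of the predictor matrix; per-axis p
compares each constrained eigenvalue to its own permutation
distribution. This per-axis test is the simple eigenvalue comparison,
not the sequential marginal test some ordination packages use — the
difference only matters for correlated axes beyond the first. SNPs are
flagged on axes with p ≤ 0.01 when their loading deviates more than
3 SD from the axis mean (the cutoff and the 1,000-permutation default
follow standard genotype–environment RDA practice; tests use fewer
permutations purely for speed, stated per call).

**Latent-factor scan.** The MCMC machinery of LFMM is replaced by a
direct estimator: latent factors are the top-K left singular vectors of
the genotype matrix after one round of predictor residualization
(so the factors do not absorb the tested signal), and each SNP is fit
by OLS on [1, predictor, factors]. The genomic-inflation adjustment is
kept exactly: λ = median(z²)/0.454936 (the χ²₁ median), adjusted
p = P(χ²₁ ≥ z²/λ), significance at α = 0.01. With K = 0 the scan
reduces to per-SNP simple regression (asserted in tests). K is chosen
by masked-entry cross-validation of the truncated SVD (10% of entries
masked, reconstruction error at the mask), replacing the cross-entropy
criterion of the original software with an equivalent held-out
reconstruction argument.

**F_ST-outlier scan.** A permutation scan stands in for the Bayesian
genome scan of the original workflow: per-locus WC θ against a pooled
null built from whole-matrix permutations of individuals (the null is
shared across loci; the `n_perm` parameter is the target pooled-null
size, so the number of matrix permutations is ⌈n_perm/L⌉), add-one
empirical p-values, Benjamini–Hochberg at FDR 5%. Because the null is
"no differentiation", any real background F inflates the discovery
count — the scan is calibrated under panmixia (asserted) and is used
here strictly as the third consensus channel, mirroring the original
design where only loci confirmed by ≥ 2 channels become candidates.

**Consensus.** Candidate = flagged by at least two channels (the
`min_methods` parameter), union = at least one, neutral = none; the
full Venn decomposition is reported.

## Effect classification

ORF prediction scans the forward strand (transcripts are single-stranded
as assembled) for ATG→stop spans of ≥ 100 codons (the common
coding-region-predictor default). One ORF is reported per (frame, stop):
the span from the 5′-most ATG — nested in-frame start codons are not
counted as separate ORFs, otherwise nearly every transcript would fail
the single-ORF filter that guards against ambiguous annotation.
Transcripts with zero or multiple predicted ORFs are excluded from the
classification universe (their SNP counts are logged).

Classification substitutes the alternate allele into the containing
codon under the standard genetic code: same amino acid → synonymous
(stop→stop included), sense↔stop → nonsense, different sense amino
acids → non-synonymous. Nonsense variants are *excluded* from kN and
tallied separately, reading "non-synonymous except for loss of sense"
as excluding premature-stop variants. kN/kS is a count ratio — no
site-frequency normalization — and is compared between candidate and
neutral sets by Pearson chi-square without continuity correction
(configurable); a zero margin raises an error pointing at exact tests.

## Ordinations and the enrichment test

The locality × SNP alternate-allele frequency matrix is ordinated by
covariance PCA (unscaled by default; the frequencies share a scale).
The contribution of SNP j to axis k is 100·v²_jk with v the unit
eigenvector, so contributions sum to 100 per axis. DAPC reduces the
individual genotype matrix to n_pca PC scores and applies LDA to them;
the discriminant eigenvalue is the between/within variance ratio, and
SNP contributions are the squared discriminant axis mapped back through
the PCA loadings, renormalized to 100. n_pca is chosen by a-score
(observed reassignment proportion minus its mean under label
permutations, plain argmax over the evaluated grid — no spline
smoothing); cluster number by k-means BIC(k) = n·ln(W_k/n) + k·ln(n).
This BIC under-penalizes when few PCs are retained (splitting
low-dimensional noise removes a large fraction of W), so cluster-number
recovery is only reliable with a generous PC count; tests exercise it
in that regime and treat k̂ qualitatively.

SNPs are ranked by descending contribution (ties broken
lexicographically by locus id for determinism). The enrichment series
runs a one-tailed Wilcoxon rank-sum test ("kN ranks are smaller") on
within-window ranks for every window top-m, m = 10…200. The exact null
distribution is used when both groups have ≤ 25 members (no ties are
possible on distinct ranks); otherwise the normal approximation with
continuity correction. Windows with an empty group give p = NA. No
correction is applied across iterations — the series mirrors the
iterative procedure it reproduces, and the report exposes every
per-iteration p rather than any single summary, because the minimum
over the series is not uniform under the null.

## Synthetic data

The generator emulates the sampling design the pipeline targets.
Population allele frequencies follow the Balding–Nichols model:
p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral
p ~ U(0.05, 0.95), giving an analytic F_ST target for estimator
recovery. Environment-linked loci add a logit-scale cline *on top of*
the drift draw — logit(p_k) = logit(p_k^BN) + β·z_k with z the
standardized predictor — so that β = 0 reduces exactly to neutrality.
Frequencies are clamped to [0.001, 0.999]. Genotypes are
Binomial(2, p_k) (Hardy–Weinberg within populations); missingness is
uniform (MCAR). Defaults: 11 localities × 8 diploids, 2,000 loci,
F = 0.05, 20 adaptive loci at β = 1, 5% missingness — a desk-scale
rendering of a ~10-locality, ~10³–10⁴-SNP rocky-shore study.

Transcripts are 5′UTR + ATG + sense codons + stop + 3′UTR
(150 codons, 60-nt UTRs by default), rejection-sampled until ORF
prediction finds exactly the planted frame. Planted SNPs are chosen to
*guarantee* their class (e.g. synonymous at positions whose codon
family is degenerate for that substitution), so classifier recovery is
exact by construction.

What the generator does not model: linkage disequilibrium, coalescent
demography, population-biased missingness, multi-predictor genetic
architectures, and sequencing error. Passing tests therefore show the
estimators and tests behave correctly under idealized HWE/BN sampling,
not that the pipeline is robust to those real-data complications.

## Numerical choices and edge cases

* Missing genotypes are mean-imputed only inside ordinations (RDA,
  PCA, DAPC, latent factors) — never in allele-frequency statistics.
* Loci with < 2 gene copies in a population are skipped for that
  population; all-missing loci are removed by the missingness filter
  before any division can occur.
* Degenerate (≈ 0) constrained eigenvalues are excluded from the RDA
  axis set via a relative singular-value threshold.
* Within-class scatter in DAPC gets a ridge proportional to its trace
  when singular (logged).
* Permutation p-values always use the add-one estimator, so they are
  bounded in [1/(n_perm+1), 1] and never zero.
* All stochastic stages take explicit seeds; the pipeline derives
  per-stage child seeds from one root seed, and reruns are
  byte-identical.

## Problem sizes

The bundled study conditions are scaled to desk hardware: simulations
use 10²–10³ individuals and 10²–2·10³ loci, permutation counts of
49–5,000 depending on the statistic, and the acceptance script's power
runs use 8 populations × 30 individuals with 1,000–2,000 loci. These
are package defaults chosen to make the estimator-recovery and
calibration properties measurable with comfortable margins.

## Known limitations

* The F_ST-outlier channel is not a reimplementation of the Bayesian
  genome scan it replaces; under strong background differentiation it
  over-flags relative to a hierarchical-prior model, which is why it is
  only ever used inside the ≥ 2-channel consensus.
* The latent-factor scan fixes one K per dataset (chosen by
  cross-validation) instead of merging hits across a K sweep; with a
  well-chosen K the flagged sets largely coincide, but borderline hits
  near α can differ.
* AMOVA negative variance components are reported as estimated;
  downstream Φ statistics can fall outside [0, 1] in near-panmictic
  data.
* kN/kS is a count ratio and must not be read as a site-normalized
  dN/dS rate; with few CDS SNPs it is dominated by sampling noise.
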