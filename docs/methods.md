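# Methods

`beanpanel` implements the analysis workflow used for SNP-array diversity
panels of common bean (*Phaseolus vulgaris*): quality control of a
HapMap/VCF genotype matrix, gene-pool structure estimation, discovery of
diagnostic (ancestry-informative) SNPs by genotype contrast, scanning for
Andean allelic introgression in a Mesoamerican background, group diversity
statistics and diversity-gain estimates, linkage-disequilibrium decay
modelling, hierarchical AMOVA, and the threshold machinery of an RCBD-based
association scan. Because public diversity panels of this kind are rarely
deposited with genotypes, the package ships a synthetic panel generator that
reproduces the statistical structure the analysis assumes, with full ground
truth for recovery testing.

## Genotype representation and quality control

Genotypes are alternative-allele dosages (0/1/2, NaN for missing). The
HapMap dialect used by bean SNP-array pipelines (single letters A =
reference homozygote, G = alternative homozygote, R = heterozygote, N =
missing) and biallelic VCF are both supported and round-trip losslessly.

QC removes SNPs in a fixed attribution order — unplaced (no chromosome
position) → missing fraction > 10% → heterozygous-call fraction > 5% → minor
allele frequency < 3% — so that the per-filter counts are reproducible; a
SNP failing several filters is counted once, at the first. MAF is computed
on non-missing raw calls; filters run before imputation. Missing calls are
then imputed with the per-SNP modal dosage (ties broken toward the lower
dosage). For a panel that is ≥ 95% homozygous with ≤ 10% missingness per
retained SNP, modal imputation is essentially a majority vote within a
nearly fixed column; an LD-aware imputer can be substituted behind the same
function if panels with higher heterozygosity are analysed.

## Admixture model

Population structure is estimated with the standard admixture likelihood:
genotype g_il ~ Binomial(2, Σ_k q_ik p_kl), maximised by alternating EM
updates of the membership coefficients Q and cluster allele frequencies P
(the FRAPPE/ADMIXTURE estimator). This targets the same Q and P as Bayesian
MCMC clustering but is deterministic given a seed and orders of magnitude
faster. Defaults: 5 random restarts (best log-likelihood kept), frequencies
clamped to [1e−6, 1−1e−6], convergence when the log-likelihood gain drops
below 1e−3, cap of 500 iterations. The log-likelihood is asserted
non-decreasing at every iteration. A supervised mode pins the Q rows of
reference accessions; per-chromosome runs are label-aligned to the
genome-wide solution by correlating cluster frequencies, which removes label
switching without any external alignment tool.

Model selection across K uses Evanno's ΔK = mean |L(K+1) − 2L(K) + L(K−1)| /
sd(L(K)) over replicate runs, flagged undefined where the run standard
deviation is zero.

### Purity screening and its noise floor

"Pure" recipient-pool accessions are those with membership q ≥ `pure_tol`
for the recipient cluster on *every* chromosome, estimated per chromosome.
Two properties of the ML estimator matter here:

* **Noise floor.** A per-chromosome q is estimated from L ≈ 250 SNPs; the
  ML point estimate of a boundary parameter has error of order 1/L, so a
  literal q ≥ 0.999 cut is below the estimator's resolution. The function
  default keeps the conventional 0.999 (appropriate when q is read from a
  rounded report), but the pipeline and acceptance workflow operate at
  `pure_tol = 0.99`, one order above the noise floor and still far from the
  smallest planted-introgression signal (~3%).
* **Common-introgression blind spot.** A donor segment carried by a large
  fraction of recipients is indistinguishable, to any admixture likelihood,
  from ordinary within-cluster polymorphism: its allele frequency is
  absorbed into P for the recipient cluster and q stays at 1. Only rare
  donor tracts move q. The synthetic panel therefore gives every
  introgressed accession at least one rare private tract (see below), which
  is also what breeding pedigrees produce; detection of the *shared*
  high-frequency segment is the job of the diagnostic-SNP frequency scan,
  not of q.

## Diagnostic SNPs and introgression scanning

Diagnostic SNPs are found by genotype contrast between the pure recipient
panel and the donor reference panel: a SNP qualifies iff every call in one
panel is one homozygote and every call in the other panel the opposite
homozygote; a heterozygote anywhere disqualifies, and missing calls are
tolerated only up to a per-panel fraction (default 0). The two orientation
sets (alternative allele fixed in the donor vs in the recipient pool) are
kept separate and are disjoint by construction.

The introgression scan then computes, at each diagnostic SNP, the
donor-allele frequency over **all** recipient-pool accessions (not only the
pure ones), counting heterozygotes as one donor copy:
freq = (2·donor-homozygotes + heterozygotes) / (2·non-missing). Frequencies
are binned [0, 0.10], (0.10, 0.15], (0.15, 0.20), [0.20, 1]; the published
round-number bin labels leave gaps, so the half-open intervals above are the
documented semantics, with 20% assigned to the top bin.

Segments are called greedily along the map: diagnostic SNPs with frequency
≥ 0.20 join the open segment while their r² with every current member stays
≥ 0.8 and the span stays within 5 Mb (singletons allowed). Genes near a SNP
are looked up in a GFF3 within a 2 Mb window centred on the SNP; distances
are signed (0 inside a gene, positive downstream, negative upstream).

## Diversity statistics

Per biallelic locus with alternative-allele frequency p (q = 1 − p):
Ho = heterozygote fraction; He = 2pq; uHe = He·2N/(2N−1); Shannon
I = −p ln p − q ln q (natural log, 0 at fixation); PIC = 1 − (p² + q²) −
2p²q². Group values are plain means over loci (averaging order documented
here because published tables are ambiguous at the third decimal). Private
alleles count allele/locus combinations present in one group and absent in
all others. Rarefied allelic richness is the exact hypergeometric
expectation Rs = Σ_a [1 − C(2N−n_a, g)/C(2N, g)] per locus, averaged over
loci; g defaults to twice the smallest group size. The diversity change
between an old and a modern group is Δ = 1 − v_modern/v_old, so a *gain* in
diversity is a *negative* Δ.

Genetic distances are Nei's (1972) standard distance with J terms summed
over all loci and alleles; unit pairs sharing no allele are flagged +inf
rather than silently propagated. UPGMA uses average linkage on the distance
matrix and returns an ultrametric `skbio.TreeNode` (newick-serialisable).

## Linkage disequilibrium

r² is the squared Pearson correlation of dosage vectors per
intrachromosomal pair. On fully homozygous data this equals the textbook
haplotype-count r² exactly (verified in tests); in a panel with ~2%
heterozygotes the two coincide to well within the decay-fit noise, which is
the documented approximation. Structure correction projects each dosage
vector off the covariate column space (e.g. admixture Q columns) before
correlating; kinship correction whitens the centred dosage matrix by
K^(−1/2) (eigendecomposition with a configurable ridge). Kinship itself is
the VanRaden genomic relationship matrix ZZ'/Σ2p(1−p).

Decay is fitted by nonlinear least squares of the Hill–Weir
drift-recombination expectation

    E(r²) = [(10+C)/((2+C)(11+C))]·[1 + ((3+C)(12+12C+C²))/(n(2+C)(11+C))],

with C = ρ·distance and n the number of accessions behind the pairs; the
fit is over raw pairs (distance-binning optional upstream), ρ ≥ 0 enforced
by optimising log ρ from three starting points. Note the curve's
large-distance limit is the sampling floor ≈ 1/n, not zero. The decay
distance at a threshold (conventionally r² = 0.2) is found by monotone root
bracketing and is "never" (None) when the curve starts at or below the
threshold. The minimum marker count for genome coverage is
round(genome size / decay distance), banker's rounding.

## AMOVA

The two-level hierarchy is commercial classes / cultivars within classes /
allele copies within cultivars: each accession contributes two 0/1 allele
copies per locus (heterozygotes split one copy each way), so the
within-cultivar stratum is the heterozygosity level and df total 2N−1. Sums
of squares use the Euclidean identity between pairwise squared allele
differences and deviations from group centroids; variance components solve
the nested expected-mean-square equations with unequal-size coefficients;
Phi_CT = σ²_a/σ²_tot, Phi_SC = σ²_b/(σ²_b+σ²_c), Phi_ST =
(σ²_a+σ²_b)/σ²_tot. Negative components are reported and flagged, not
truncated (a `truncate_negative` switch reproduces the truncating
behaviour of some packages). Permutation nulls: whole accessions among
classes (Phi_CT), allele copies among accessions within class (Phi_SC),
allele copies among all accessions (Phi_ST); p = (#null ≥ observed + 1)/
(n_perm + 1), default 9999 permutations (tests use a few hundred to stay
fast).

## Phenotypes and association thresholds

RCBD phenotype analysis fits value ~ mean + cultivar + block by least
squares (type-II decomposition; identical to the classical balanced ANOVA
when the design is complete, flagged when not). Broad-sense line-mean
heritability is h² = (MS_cultivar − MS_residual)/MS_cultivar, clamped at 0
and flagged when MS_cultivar < MS_residual; CV = 100·√MS_residual / grand
mean; Shapiro–Wilk runs on model residuals (the residual, not raw-trait,
placement is the documented choice). Least-squares means are model
predictions averaged over block levels. Growth habit, an ordinal 1–4 score,
is analysed with the same linear machinery — a documented simplification,
matching how such scores are routinely passed to association models.

The association scan is a PC-adjusted single-marker linear model (y ~
intercept + leading PC scores + dosage), vectorised across SNPs and, for
permutations, across phenotype columns. The number of PCs is chosen by BIC
in the higher-is-better convention loglik − (k/2)·ln n over 0..5 leading
PCs. Two scan-wide thresholds are provided: the Bonferroni bound α/m
(default α = 0.01), and an empirical threshold from the minimum-p
distribution over phenotype permutations (default 300). The quantile
convention is genuinely ambiguous in the literature this follows: the
default takes the 5% quantile of the min-p distribution, which controls the
family-wise error rate near 5% (verified by calibration tests); the
permissive literal "95% quantile" reading is available via
`quantile_level=0.95`. A multi-locus scan engine (FarmCPU-style iterative
fixed/random modelling) is deliberately out of scope; the threshold
machinery is engine-agnostic and the GLM scan is the pluggable default.

## The synthetic panel

The generator's defaults are the headline study conditions: 175
Mesoamerican + 10 Andean accessions, 11 chromosomes × 257 SNPs (2827),
37.5% of loci diagnostic (1060, split 552/508 by orientation), ~2% residual
heterozygosity, commercial classes Carioca/Black/Special in 131/29/25
proportions with the Carioca class split into old/modern/lines era groups,
22 introgression-free Mesoamerican accessions, a 2.6 Mb shared Andean
segment on Pv05 carried by ~29% of the Mesoamerican accessions plus one
accession with ~99% of that chromosome introgressed, and one rare private
donor tract (3 consecutive diagnostic SNPs) in every non-pure accession.

Non-diagnostic allele frequencies use a shared-ancestry construction: an
ancestral frequency p₀ ~ Beta(0.5, 0.5) per locus, and pool frequencies
drawn Balding–Nichols style around p₀ with pool-specific drift (F = 0.9
Mesoamerican, 0.7 Andean). Loci are then ascertained the way array content
is: panel-level MAF ≥ 0.04, per-pool MAF either 0 or ≥ 0.05 (arrays
under-represent rare variants), and no accidental fixed contrast between
the planted-pure and Andean panels (the planted diagnostic set is the
complete contrast set by construction). Shared ancestry plus the
rare-variant rule eliminates loci that are rare in one pool but common in
the other — exactly the loci that would otherwise give truly-pure
accessions a spurious admixture signal. Accessions are built by copying
founder haplotypes in 1 Mb blocks (8 founders per class, 6 Andean), which
induces block-scale LD and class differentiation; residual heterozygotes
are injected at non-diagnostic loci at a rate scaled so genome-wide Ho
matches `residual_het_rate`. Diagnostic loci are kept heterozygote-free:
within-pool monomorphism at those loci is their defining, selected-for
property. Phenotypes follow plot = trait mean + Σ QTL effects (centred
dosage) + polygenic value + block effect + residual, with the polygenic
variance set to hit target line-mean h² (0.78 DTF, 0.83 DTM/HAB); DTF and
DTM share a QTL, making their genetic correlation positive; growth habit is
discretised from a latent scale into classes 1–3 (elite panels carry no
climbing type). Genotype and phenotype streams are seeded separately so
phenotype replicates can be regenerated on a fixed panel.

What the generator does **not** emulate: coalescent genealogies and
realistic recombination maps (LD decays on the block scale, not from a
genetic map), mutation, selection, pedigree structure within classes,
genotyping error beyond residual heterozygosity and optional missingness,
and the third-decimal values of published group-diversity tables (the
ordering and magnitudes are reproduced; exact values depend on the real
panel's ascertainment history, which is not recoverable). Passing recovery
tests therefore demonstrates the *procedures* are correct and calibrated on
data with the assumed structure — not that any particular real panel would
yield the same numbers.

## Problem sizes

Unit and property tests run on panels of 25–95 accessions and a few hundred
SNPs with 2–4 chromosomes; permutation and calibration suites use 79–999
permutations and 120–400 replicates. The acceptance workflow runs the
full default panel (185 × 2827, 11 chromosomes) end to end with 3 EM
restarts, which completes in well under a minute on one CPU.
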