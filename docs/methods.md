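# Methods

`varpart` partitions the additive genetic variance of quantitative traits
across genomic annotation classes, chromosomes and allele-frequency bins,
and localizes individual signals with a mixed-model scan and a Bayesian
mixture over SNP effects. This note records the models, the numerical
choices, and what the synthetic cohort does and does not emulate.

## Variance-component model

For a phenotype vector *y* on *n* individuals the model is

    y = Xβ + Σ_G g_G + e,   g_G ~ N(0, A_G σ²_G),   e ~ N(0, I σ²_e)

where each A_G is the genomic relationship matrix (GRM) of one SNP subset,

    A_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with p_i the in-sample alt-allele frequency (computed within the analysis
sample per subset) and missing dosages mean-imputed to 2p_i before
centering. The per-component heritability is h²_G = σ²_G / σ²_P with
σ²_P = Σ σ²_G + σ²_e. "Separate" analysis fits one GRM at a time (and
absorbs any variance its SNPs tag through LD with other classes); "joint"
analysis fits all partition GRMs simultaneously, which is what makes the
class attribution interpretable. Fixed effects are year and season one-hot
factors plus a linear age covariate.

### AI-REML

The restricted likelihood is maximized by average-information (AI) Newton
steps. The first two iterations are EM-REML updates (slow but globally
stable); afterwards each AI proposal is accepted only if it does not
decrease the restricted log-likelihood, with step-halving and an EM
fallback otherwise, so the likelihood trace is monotone. Convergence
requires |Δ logL| < 1e-6 and a maximum relative parameter change < 1e-5,
within 100 iterations (non-convergence flags the result rather than
raising). Variance components are floored at 1e-8 × var(y); a component
pinned at the floor reads as "~0", mirroring boundary estimates such as
0.0001 in published joint fits. Standard errors come from the inverse AI
matrix at convergence; heritability-ratio SEs use the delta method. An AI
matrix with condition number above 1e10 flags the fit non-identifiable
(e.g. a GRM proportional to the identity confounded with the residual).

The single-GRM case is rotated into the GRM's eigenbasis once, making every
iteration O(n); the multi-GRM case uses dense Cholesky solves, which is
comfortable to n of a few thousand and ~30 components.

## Mixed-model association scan

Phenotypes are first adjusted by OLS for year, season and age; the adjusted
trait is tested SNP by SNP under y = a + b·x + g + e with g ~ N(0, A σ²_g).
Variance components are estimated once under the null and held fixed for
every test (the P3D/EMMAX shortcut), and one eigendecomposition of the GRM
turns each per-SNP GLS into a weighted 2×2 solve. The Wald statistic b/SE
is referred to the standard normal (large-n convention of the tool family).
The tested SNP stays inside the GRM — no leave-one-chromosome-out — so a
small proximal contamination (deflation at truly causal sites) is accepted;
null calibration is unaffected, as the calibration tests verify. Bonferroni
thresholds are 1/n (suggestive) and 0.05/n (significant) for n tests.

## Four-component mixture over SNP effects

Each SNP effect has prior β_j ~ Σ_c π_c N(0, m_c σ²_A) with multipliers
m = (0, 1e-4, 1e-3, 1e-2) and σ²_A the trait's additive variance. A
single-site Gibbs sampler draws, per sweep: the component indicator of each
SNP from π times the marginal likelihood of its residual score; the effect
from its conditional normal; π from Dirichlet(α + counts) with α = 1; and
σ²_e from its scaled inverse-χ² conditional. Defaults follow the published
setting: 50,000 sweeps, 20,000 burn-in; thinning (10) is this package's
choice. σ²_A is fixed from a prior single-GRM REML fit by default, may be
given explicitly, or sampled. Genotypes are centered but not standardized,
so a SNP's variance contribution is 2p(1−p)β², matching
%V_g = 100 · 2pqβ²/σ²_A, and the per-class display statistic is
VarPerSNP = (h²/n_class) × 100 / 1e-4.

Numerics: the kernel keeps SNP-major float32 genotypes and float32
residuals (SIMD-friendly) and refreshes the residual vector from exact
float64 state every 100 sweeps; chains are deterministic given the seed.

A caveat the tests quantify: when per-SNP identification is weak (the
likelihood tilt between the zero and 1e-4 components scales with
(n·2pq·1e-4·σ²_A/σ²_e)²), the mixture proportions are informed mostly by
the prior and drift. At cohort scale (n ≈ 2,000) a pure-noise run settles
at ≈93% zero-component occupancy, not higher; generative recovery of
(0.95, 0.04, 0.009, 0.001) to ±0.02 per component requires the sampler to
be given the generative σ²_A scale, which is how the recovery experiments
are run (the standard way to validate a Gibbs sampler against its own
generative model).

## Consequence annotation

A minimal annotator assigns one class per SNP with severity precedence
stop_gained > stop_lost > start_lost > missense > synonymous > utr5 > utr3
> intron > upstream > downstream > intergenic. Coding calls translate the
reference and alternate codons of the longest transcript's spliced CDS
(standard code, strand-aware complement). Regulatory flanks are ±5 kb from
the gene span; intergenic means beyond every flank. The six-class scheme is
{synonymous, missense, UTR, intron, regulatory, intergenic}; the three-class
scheme merges coding+UTR into "exon" and regulatory into "intergenic";
stop/start classes are dropped from class GRMs but stay in the all-SNP set.
SNPs in exons of non-coding transcripts fall back to "intron". QC keeps
SNPs with MAF ≥ 0.01, Wigginton-style two-sided HWE exact p ≥ 1e-4 and
imputation R² > 0.60 (boundary rules follow the quoted inequalities).

## Synthetic cohort

The generator emulates a progeny-test beef cattle cohort: 251 sires × 8
progeny (~2,000 steers) from unrelated dams. Haplotypes come from a
Gaussian-copula first-order Markov chain: a latent AR(1) with adjacent-
locus correlation ρ (default 0.9, reset at chromosome boundaries)
thresholded at each locus's target frequency, so marginal frequencies are
exact and LD decays geometrically in marker index. Each progeny inherits
one whole sire haplotype per chromosome plus an independent maternal
haplotype, giving half-sib GRM entries near 0.25. Target frequencies are
Beta(0.5, 0.5) truncated to [0.01, 0.99], populating all six MAF bins.

Genomes default to 29 autosomes with a linear 3→1 Mb length gradient (a
deliberate desk-scale reduction; real cattle autosomes are 40–160 Mb), 20
genes per chromosome with Poisson exon counts and exponential introns, CDS
built from random sense codons (ATG start, single stop). Genes are placed
with a minimum gap of twice the regulatory flank so class intervals never
overlap, which makes closed-form class-share expectations exact. The
resulting class spectrum is ordered as in real sequence data
(intergenic ≫ intron ≫ regulatory ≫ exon), though the absolute exon share
is a few-fold higher than the ~0.9% of an 11M-SNP cohort — a consequence
of desk-scale chromosome lengths, not of the placement logic.

Phenotypes are y = year + season + age·slope + Σ βx + e with either
class-enriched causal draws or the four-component mixture as the effect
distribution. By default the genetic score and an orthogonalized residual
are rescaled so realized h² equals the target exactly (±0.01 guaranteed);
generative-exact mode (`sigma2_residual` set) skips all rescaling. The
recorded truth includes per-class realized variances, the
linkage-equilibrium expectation Σ 2pqβ², and the mixture component of
every SNP.

What passing tests therefore show: the estimators recover the parameters of
a cohort with this LD, family and class structure at n ≈ 2,000. What they
do not show: behavior under multi-generation pedigrees, recombination
within chromosomes, selection, imputation error beyond an R² label, or
11M-SNP scale.

## Problem sizes used in the shipped experiments

Recovery and calibration experiments run at n ≈ 2,000 individuals and
5,000–10,000 SNPs: 30 phenotype replicates (over 3 genotype draws) for the
h² = 0.5 recovery; a 10,000-SNP gene-dense genome for the joint 3-class
attribution; 1,000 tested SNPs for null calibration; five seeds of
5,000-sweep chains for mixture recovery. These sizes were chosen so the
whole battery runs on a single CPU in minutes while keeping every
qualitative contrast (separate-vs-joint inflation, class attribution,
calibration) at full strength.

## Known limitations

- One fine class per SNP (disjoint partitions by construction); annotators
  that report per-transcript multi-consequences will count overlap classes
  differently, so fine-class totals need not match overlap-semantics tables.
- No dominance/epistatic GRMs, no GREML-LDMS stratification, no COJO.
- The Markov-LD model has a single parameter; it does not reproduce
  block-wise LD or frequency-dependent LD decay.
- Proportion SEs use the delta method on the AI covariance; likelihood-ratio
  intervals are not provided.
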