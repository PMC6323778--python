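# Methods

`aimkit` implements a complete pipeline for designing and validating small
panels of ancestry-informative markers (AIMs) in two-way admixed
populations, modelled on the Mexican-mestizo setting: individuals whose
genomes are a mixture of mainly European and Native American ancestry, with
disease prevalence that varies with ancestry and therefore confounds
case-control association studies.

## The selection model

Genotypes are counted-allele dosages g ∈ {0, 1, 2}. After quality control
(samples then variants with ≥ 2% missing calls removed, then variants with
minor allele frequency < 1%), each variant column is standardized the
EIGENSTRAT way,

    x_ij = (g_ij − μ_j) / sqrt(p_j (1 − p_j)),   p_j = μ_j / 2,

with missing entries mean-imputed to zero after centering. PCA of X gives
sample scores (U s) and per-variant SNP weights

    w_jk = (x_·j · score_·k) / (n · sqrt(λ_k)),   λ_k = s_k² / m.

In a two-way admixed cohort PC1 is essentially the ancestry axis, so PC1
SNP weights rank variants by ancestry informativeness. Selection then:

1. keeps the two 1% tails of the PC1 weight distribution (quantiles by
   linear interpolation; the tail fraction is configurable),
2. ranks candidates per chromosome by |weight| and keeps the top 20,
3. allocates panel slots in two phases — first the best candidate of each
   chromosome (genome-wide coverage, chromosomes taken strongest-first so
   panels smaller than 22 markers still cover the most informative ones),
   then greedy fill by global |weight| under per-chromosome quotas derived
   from the Denver size classification (A–G) of the autosomes — skipping
   any candidate whose pairwise genotype r² with an accepted member reaches
   the LD threshold (default 0.05),
4. builds nested panels (16/32/48/64 by default) by allocating the largest
   first and re-allocating each smaller panel from within its parent's
   members, which guarantees the nested chain by construction.

Quotas default to {A:5, B:4, C:3, D:3, E:2, F:2, G:2} per chromosome at the
largest panel size — large chromosomes receive more markers than small
ones, and the quotas jointly supply 67 ≥ 64 slots over the 22 autosomes; a
smaller panel's quotas are ceiling-scaled (minimum 1), since floor-scaling
leaves fewer slots than the panel needs once every chromosome must be
covered. Ties anywhere break by (chromosome, position), making selection a
deterministic function of cohort and configuration. On ≤ 12-candidate toys
the two-phase greedy provably matches (and is tested against) exhaustive
search over all quota-, coverage- and LD-feasible subsets maximizing the
weight sum; with LD conflicts between near-equal candidates greedy is a
heuristic, as for any forward selection.

The weight *scale* is irrelevant to selection (only ranks and quantiles are
used), so no attempt is made to match any particular implementation's
internal scaling; the Bayesian posterior-frequency variance option exists
but defaults off for the same reason.

## Association testing and genomic control

Per-variant models are additive in dosage: logistic regression (Newton
iterations with step halving, gradient tolerance 1e-8) for binary traits,
OLS for quantitative traits, with covariates plus optionally the top two
PCs — either genome-wide ("gold standard") or recomputed from a candidate
panel — as stratification adjustments. Tests are Wald, χ² = (β/se)²
against χ²₁. Quasi-separation (|β| > 20) returns a flagged result with an
infinite-SE sentinel rather than an exception. Missing genotypes are
handled complete-case per variant; a missing covariate drops the sample
from the whole scan. The fits are a vectorized in-package IRLS/OLS because
a genome scan makes tens of thousands of small fits; statsmodels serves as
the independent oracle in the test suite.

The genomic inflation factor is λ = median(χ²)/0.4549364231. QQ data uses
plotting positions (i − 0.5)/n and P values unadjusted for λ. Panel quality
is judged by (1) squared Pearson correlation between gold PC1 and panel
PC1 (sign-aligned; PCs are recomputed inside every subsample or region,
mimicking an analyst who only has that sample) and (2) squared correlation
of −log10 P between gold-PC-corrected and panel-PC-corrected scans —the
−log10 scale is used because panel evaluation cares about tail behaviour,
with a raw-scale option.

## Supervised ancestry estimation

Given parental allele frequencies estimated from labelled reference
samples (add-one pseudocount (1 + Σg)/(2 + 2n) by default, keeping
frequencies off the 0/1 boundary), each individual's ancestry vector q
maximizes the binomial likelihood with π_j = Σ_k q_k p_kj over the simplex
via the supervised EM update

    q_k ← q_k · (1/2J) Σ_j [ g_j p_kj/π_j + (2 − g_j)(1 − p_kj)/(1 − π_j) ].

Parental frequencies stay fixed (supervised): the target use case always
anchors on genotyped reference panels, and the per-individual problem is
then concave for K = 2, so uniform initialization suffices. Convergence is
a per-individual log-likelihood gain below 1e-7 (default); non-convergence
is reported, not raised. EM monotonicity and agreement with a 0.001-step
grid search are asserted in tests.

## The simulator

The generator emulates the statistical structure the method assumes rather
than any particular dataset:

- **Drift**: per locus an ancestral frequency uniform on (0.05, 0.95);
  each parental population draws Beta(p(1−F)/F, (1−p)(1−F)/F)
  (Balding–Nichols), F = 0.15 per side by default — strong two-way
  divergence of the European/Native American order.
- **Admixture**: q ~ Dirichlet with mean (0.43, 0.57) for K = 2 or
  (0.42, 0.55, 0.03) for K = 3 (the small third component mirroring the
  minor African contribution), total concentration 6 — individual ancestry
  SD ≈ 0.19, the wide spread seen in Mexican cohorts.
- **Genotypes**: independent Binomial(2, q·p) per locus; variants assigned
  round-robin to chromosomes 1–22 so chromosome-aware selection is
  exercised. Loci are **unlinked** by design (the LD rule demands
  uncorrelated AIMs); an optional duplicate-locus mode copies columns with
  2% noise to give the LD pruner real conflicts.
- **Phenotypes**: binary via logit P(case) = baseline + 2.0·q_EUR by
  default — a strong ancestry effect chosen because the motivating
  case-control setting shows massive uncorrected inflation — with baseline
  set for ~50% prevalence; quantitative analogously with Gaussian noise.
  Age/sex/BMI covariates are drawn independently of genotype.
- **Regions**: optionally individuals are split across named regions with
  specified mean Native-like ancestry (0.50/0.63/0.60/0.65 for the four
  Mexican regions in the validation battery).
- **Validation sample**: `simulate_validation_cohort` mirrors the
  composition real AIM validations use — admixed individuals analysed
  alongside parental reference individuals (95 European-like + 38
  Native-like by default, each ~98% pure) — because ancestry-recovery r²
  depends strongly on the ancestry variance of the evaluated sample, and
  published concordance figures are computed on reference-inclusive runs.
- **Designed panels**: `plant_aim_panel` appends loci with parental deltas
  drawn from (0.78, 0.92), the informativeness a validated panel reports
  (every delta > 0.77), with genotypes consistent with each individual's
  simulated ancestry.

What passing tests on this simulator do **not** show: behaviour under real
LD (where AIMs share information with genome-wide structure), genotyping
artefacts, related individuals, or more than trivial third-ancestry
contamination.

## Known limitations and honest failure modes

With 32 *unlinked* loci the per-individual ancestry information is bounded
(roughly 2δ²/π(1−π) per locus), capping panel-vs-gold PC1 r² near 0.89 at
deltas ~0.85 and near 0.91 even at deltas ~0.95 for a cohort with ancestry
SD 0.19. Real 32-AIM panels report higher concordance on real cohorts;
the gap is attributable to admixture LD (each real AIM tags surrounding
haplotype information) and cohort heterogeneity, neither of which an
unlinked-locus simulator reproduces. Consequently the robustness battery's
within-region concordances land around 0.86–0.90 here; this ceiling is a
property of the simulation model, deliberately retained rather than tuned
away.

## Problem sizes and numerics

The stratification battery runs at 2,000 individuals × 20,000 loci (QC'd),
a size at which every qualitative phenomenon of interest — uncorrected
λ well above 1.5, panel-corrected λ ≈ 1, P-value concordance > 0.9,
monotone panel-size concordance — is stable; the ancestry battery at
n = 500 with 32 loci; regional robustness at 2,000 × 8,000. PCA uses exact
SVD for small matrices and the algebraically identical n×n Gram-matrix
eigendecomposition for tall-skinny ones (many more variants than samples),
with the dense-covariance oracle checking both routes in tests. Component
signs are fixed so each score vector's largest-magnitude entry is
positive. Monomorphic variants are an error in core normalization but are
dropped (with weight rows zeroed) when PCA is recomputed inside subsamples,
where a variant can lose its variation by chance. All simulator randomness
flows from a single seed; selection and estimation are deterministic given
their inputs.
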