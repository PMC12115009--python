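# Methods

## The statistical problem

A partially inbred breeding population is generated by self-pollinating a
small set of elite clones. Because pollen contamination is common, the
realized pedigree must first be corrected by parentage testing; the
corrected population (phenotyped field trees plus genotyped-only orchard
trees) then trains genomic prediction models whose job is to rank the
orchard trees by additive merit. This package implements that full chain
and validates it on simulated data, since populations of this kind are
proprietary and rarely shareable.

## Mixed models

All frequentist models are linear mixed models

y = Xβ + Zu + ε,  u ~ N(0, K σ²ᵤ),  ε ~ N(0, I σ²ₑ),

with β the fixed effects (general mean and block; the trial is an RCBD
with one tree per plot, so no plot term exists) and K one of:

* **A** — numerator relationships from the pedigree by the tabular method:
  a₍ᵢᵢ₎ = 1 + ½·a₍sire,dam₎, a₍ᵢⱼ₎ = ½(a₍ⱼ,sire₎ + a₍ⱼ,dam₎); one selfing
  generation of a non-inbred parent gives F = 0.5, two give 0.75.
* **G** — VanRaden method 1: Z = M − 2p column-centred dosages,
  G = ZZ'/(2Σpⱼqⱼ), allele frequencies from the analysed sample.
* **D** (additive+dominance model) — classical dominance coding
  w = (−2p², 2pq, −2q²) for dosages (0, 1, 2), D = WW'/Σ(2pⱼqⱼ)².
  Mean-imputed fractional dosages code to 0, their HWE expectation.
* **H** — single-step blend: G* = (1−b)G + b·A22 with b = 0.05 by default,
  H22 = G*, H12 = A12 A22⁻¹ G*, H11 = A11 + A12 A22⁻¹ (G* − A22) A22⁻¹ A21.
  τ/ω scaling of G*⁻¹ and A22⁻¹ is available through the inverse form.

### REML

Variance components come from REML through two interchangeable routes:

* **Eigen route** (default for one random term): rotate the phenotyped
  block of K to its eigenbasis and profile the restricted likelihood over
  λ = σ²ᵤ/σ²ₑ with bounded 1-D optimization (log-λ ∈ [−18, 18], xatol
  1e−9). Exact and fast; this is what 10-fold CV uses.
* **EM route** (any number of random terms): classical EM-REML on
  Henderson's mixed-model equations — σ²ₖ ← (ûₖ'Kₖ⁻¹ûₖ + σ²ₑ tr(Kₖ⁻¹Cᵏᵏ))/q,
  σ²ₑ ← y'ê/(n−p) — with Aitken extrapolation every 5 iterations (kept
  only when it stays positive and does not lower the likelihood),
  convergence at 1e−6 relative change, max 500 iterations, variance floor
  1e−8. The restricted likelihood is non-decreasing across plain EM steps
  and this is asserted in tests. The two routes agree to ~1e−3 in GEBVs on
  shared fixtures, which is itself a test.

Unphenotyped individuals are predicted by carrying them in K with empty
rows in Z — equivalently û_all = σ²ᵤ K[:, obs] V⁻¹(y − Xβ̂). A duplicate
kinship row therefore receives an identical GEBV, which is tested.

Kinship matrices are inverted with a 1e−6 diagonal jitter, but only when
the condition number exceeds 1e10; well-conditioned identity cases (e.g.
H with G = A22) then hold to machine precision.

## Bayesian whole-genome regression

The five samplers share y = Xβ + ε with X the centred dosage matrix and
differ in the prior on βⱼ: common normal variance (BRR), per-marker
scaled-inv-χ² variances (BayesA), spike-and-slab with per-marker slab
variances (BayesB, π fixed at 0.99 by default), spike-and-slab with one
slab variance and π estimated under Beta(1, 9) (BayesC), and the
normal–exponential (Laplace) hierarchy (BL). Residual variance has a
scaled-inv-χ² prior throughout. Updates are single-site Gibbs; the
spike-and-slab indicator uses the marginal Bayes factor with the slab
integrated out; BL's 1/τ²ⱼ is inverse-Gaussian and its λ² is Gamma — the
hierarchy is parameterized on λ² because that is the conjugate Gibbs form
of the Laplace scale (the scale itself is often written with a Gamma
prior; the difference is a reparameterization choice recorded here).

Defaults: 20,000 iterations, 2,000 burn-in, thinning 5; ν_β = ν_e = 5;
prior scales solved from an R² = 0.5 heuristic on var(y) (BGLR-style);
λ² prior shape 1.1 with rate matched to the heuristic. Fixed effects are
removed by OLS (intercept + block) before marker regression so the
sampled design is exactly the marker matrix; an optional intercept can be
sampled jointly. Chains are seeded and bit-reproducible; a fixed-variance
BRR mode exists whose posterior mean has the ridge closed form
(X'X + (σ²ₑ/σ²_β)I)⁻¹X'y, used as an exact correctness check with
batch-means Monte-Carlo SEs.

Effective sample sizes for the variance chains use an
initial-positive-sequence autocorrelation estimator.

## Cross-validation protocol

The lower 5% of the phenotype is winsorized once on the full response
(values below the 5th percentile are set to it; the upper tail is never
touched). The quantile uses linear interpolation between order statistics
— the scientific-stack default. Note a subtlety: under that convention
re-winsorizing can move the threshold slightly upward, so exact operator
idempotence holds only at a fixed threshold value; the tests assert the
fixed-threshold form plus one-sidedness.

Ids are shuffled by the seed and dealt round-robin into k = 10 folds
(sizes differ by at most one). Relationship matrices are built once on
all individuals and only phenotypes are masked per fold — the same
mechanism that predicts the orchard cohort. Bayesian models are refit per
fold with training-set centring. Metrics per fold: PC = Pearson
correlation of prediction and observation (n−1 convention), MSE, and
R² = 1 − SSres/SStot about the held-out mean (negative when worse than
the mean). Fold metrics are averaged and their SD reported; models are
ranked by mean PC, ties broken alphabetically. All nine models are
evaluated on one common phenotype scale.

## Parentage assignment

Markers are ranked by expected heterozygosity 2pq (ties: MAF, then id)
and the top 723 used by default. For each offspring with a known seed
parent, every candidate father c gets a natural-log LOD
Σⱼ log P(g_o | g_m, g_c) / P(g_o | g_m, random father from allele
frequencies). Genotyping error ε mixes each transition probability toward
its HWE genotype distribution with weight 1 − (1−ε)³ (trio term) or
1 − (1−ε)² (mother-offspring term) — an error-smoothed simplification of
the full per-genotype error integration; with ε = 0 impossible
transitions give −∞ (hard exclusion). Δ = best LOD − runner-up LOD. The
critical Δ is calibrated by simulating offspring of random candidate
pairs (with error) and taking the smallest Δ at which at least 80%
(relaxed; optionally 95% strict) of assignments exceeding it name the
true father; 10,000 replicates by default. An offspring is *selfed* when
its best candidate is its own seed parent with at least relaxed
confidence, *crossed* when another candidate wins confidently, else
*unassigned*.

## Linkage disequilibrium

r² is the squared Pearson correlation of unphased dosage vectors
(composite LD) over same-chromosome pairs within a distance cap; gametic
D is available via a two-locus EM that splits double heterozygotes
between coupling and repulsion. Decay curves are distance-binned means.
Because sample r² is inflated by roughly 1/n, contrasts between cohorts
of different size (20 founders vs. hundreds of selfed progeny) are made
at matched sample size by subsampling the larger cohort.

## The simulator: what it does and does not emulate

Founder haplotypes threshold a stationary AR(1) Gaussian latent process
(per-chromosome correlation `adjacent_ld_rho`, default 0.9) at
marker-specific quantiles, giving LD that decays geometrically along the
marker grid; realized MAFs are forced to the floor (0.05) by flipping
majority alleles. Meiosis is Haldane (no interference), one Morgan per
chromosome mapped linearly onto `chrom_length_bp`. Each offspring is
selfed with probability `selfing_rate` (default 0.62), otherwise sired by
a uniform other parent. The trait is y = mean + block + BV + dominance +
residual with BV = Σ xⱼaⱼ over (optionally sparse) causal markers, scaled
so the additive share of the non-block phenotypic variance equals
`h2_additive` (default 0.4, inside the 0.3–0.7 range typical for growth
traits) and the dominance share `d2_dominance` (default 0.1); defaults
give a 12.25 ± 4.18 cm DBH-like trait on 30 blocks (block SD 1.5 cm).
Outliers (rate 0.02) replace records with values below mean − 5 SD,
exercising winsorization. Genotyping error re-draws a call from HWE
(rate 0.005); missingness is 0.01. All stages derive their RNG streams
from one seed and are byte-reproducible.

Not emulated: selection across generations, epistasis, multi-environment
structure, realistic genome coordinates, linkage between the trait and
population structure beyond what one selfing generation induces. Passing
tests therefore demonstrate correctness of the machinery under the
assumed generative model, not performance guarantees on any real
population.

## Validation-study problem sizes

The self-contained studies in `selfpred.experiments` (run by the test
suite and `scripts/acceptance.py`) use: 20 random mixed-model fixtures
with n ≤ 30 for the MME/GLS equivalence; a 20-individual selfing pedigree
with 100,000 gene drops (Monte-Carlo SE ≈ 0.003 per entry); BRR vs. ridge
at n = 50, m = 20 with 50,000 iterations; heritability recovery and the
GBLUP/ABLUP ordering on 20 replicates of 600 offspring × 2,000 markers
(recovery uses a purely additive, outlier-free configuration so the
estimand is clean); the LD contrast on 10 replicates of 28 founders ×
560 fully selfed progeny subsampled to 28; and paternity accuracy on
1,000 offspring of 20 candidates at 500 markers with 5% error. These
sizes were chosen once as the smallest that leave Monte-Carlo noise well
below the effects being measured.

## Known limitations

* EM-REML near a variance boundary (e.g. the dominance component on a
  purely additive trait) converges slowly and may stop at the iteration
  cap with a warning; the returned fit is still usable.
* The Cervus-style parentage simulation assumes all candidates genotyped
  at all subset loci (matching this design); partial candidate sampling
  and unknown mothers are out of scope.
* The H-matrix τ/ω path inverts dense matrices and is not meant for
  pedigrees beyond a few thousand individuals.
* Composite r² is used for LD throughout; haplotype-phase r² is not
  implemented (EM D is provided for the gametic covariance only).
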