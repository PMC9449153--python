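# Methods

`hatchtraj` implements genetic evaluation of longitudinal poultry hatchery
traits — fertility of set (FERT), hatch of fertile (HOF) and hatch of set
(HOS), recorded biweekly as percentages over a hen's lay from 38 to 62
weeks — with cumulative and random-regression animal models under pedigree
BLUP and single-step genomic BLUP. Because production data of this kind are
proprietary, the package ships a synthetic breeding-program generator with
exactly the statistical structure the models assume, so every downstream
component is testable end to end.

## Models

**Cumulative (CUM) model.** One whole-lay record per hen,

y_ij = mu + hw_i + a_j + e_ij,

with hatch week `hw` fixed, animal effect `a ~ N(0, A sigma2_a)` (or
`H sigma2_a` in single-step form) and homogeneous residual. The cumulative
record is the mean of a hen's biweekly percentages.

**Random-regression (RR) model.** Biweekly records

y = mu + hw + ehw + sum_l b_l phi_l(x) + z_F(x)' aF + z_F(x)' peF
      + z_M(x)' aM + z_M(x)' peM + e,

where `x` is hen age mapped affinely onto [-1, 1] and `phi_l` are
orthonormal Legendre polynomials, `sqrt((2l+1)/2) P_l(x)`. The fixed age
trend is cubic (`l = 1..3`; the intercept is carried by the factor part).
Default random-regression orders are hen additive 3, tom additive 1, hen
permanent environment 3, tom permanent environment 2 — the most
parsimonious model retained by likelihood-ratio/AIC comparison against the
full model. Additive coefficient vectors are `N(0, A (x) K)` (Kronecker
with the numerator relationship matrix, or `H` for single-step);
permanent-environment coefficients are i.i.d. across subjects. Residual
variance is heterogeneous with one class per biweekly age (13 classes).

The hen permanent-environment term is indexed by hen (each hen is mated to
a single tom for her whole lay in the default design, so hen and
hen-by-tom indexing coincide; the generator makes the mate assignment
configurable).

**Relationships.** `A` and its sparse inverse follow the tabular method and
Henderson's rules with inbreeding from the Meuwissen–Luo recursion. `G` is
VanRaden's first method, `Z Z' / (2 sum p(1-p))`, with allele frequencies
observed in the genotyped set (base-population frequencies are unknown for
these data; the choice is exposed in code). The single-step inverse is

H^-1 = A^-1 + [0 0; 0 (0.95 G + 0.05 A22)^-1 - A22^-1],

with the 0.95/0.05 blend as the default weight. Marker quality control
removes non-autosomal markers, markers with minor-allele frequency
strictly below 0.05, and markers failing a 1-df chi-square Hardy–Weinberg
test at P < 1e-8 (no continuity correction or exact test; with such an
extreme threshold the chi-square approximation is the operative choice).

**Breeding values.** Per-age EBVs are `z(t)' alpha_hat` for the hen
additive coefficients (toms analogously); for the cumulative model the
single animal solution is the EBV.

## Variance-component estimation

Restricted maximum likelihood, with the restricted log-likelihood computed
through the mixed-model equations:

-2 logL = log|R| + log|G| + log|C| + y'Py + (n - p) log 2 pi.

* Models with one scalar random term and homogeneous residual (the CUM
  model) are estimated by an exact one-dimensional profile likelihood in
  the variance ratio `lambda = sigma2_e / sigma2_a`, maximized by bounded
  Brent search (`log lambda` in [log 1e-4, log 1e6], xatol 1e-8).
* Everything else uses average-information (AI) REML on a log-Cholesky
  parameterization of each K plus log residual variances, so iterates can
  never leave the feasible region. Steps are Levenberg–Marquardt damped
  and accepted only if the exact restricted log-likelihood does not
  decrease; on failure the damping grows tenfold (this replaces the
  classical EM fallback, which exists to restore feasibility that the
  parameterization already guarantees). Convergence: |dlogL| < 1e-8 and
  relative parameter change < 1e-6, plus a plateau rule (three consecutive
  gains below 1e-4, typical of boundary drift along near-singular K
  directions, e.g. a vanishing tom additive variance). Starting values
  put half the phenotypic variance on the residual and split the rest
  equally across terms with diagonal K.
* Score traces use the mixed-model identities
  `tr(P Z (Rel (x) dK) Z') = nlev tr(K^-1 dK) - tr(C^uu (Rel^-1 (x) K^-1 dK K^-1))`
  and `tr(P dV_c) = n_c - tr(C^-1 W_c' W_c)/sigma2_c`; the average
  information matrix is `1/2 F' P F` with `F_i = dV_i P y`.

For small systems the coefficient matrix is handled densely. At scale the
trace terms need selected entries of `C^-1`, which a general sparse LU
cannot provide (numerically zero entries are pruned from its factors), so
the package carries its own factorization: a blocked left-looking LDL'
driven by the block elimination tree, with one dense block per animal
(all of its regression coefficients) and one for the fixed effects, a
minimum-degree ordering of the collapsed animal graph, cached symbolic
analysis, BLAS panel updates, and a frontal Takahashi recurrence for the
selected inverse. All of it is validated against dense inversion in the
test suite.

Large random-regression fits are warm-started from a REML fit to the
earliest generations' records (a data-driven staging that typically leaves
only a handful of full-data AI iterations); problem sizes used in the
tests and the acceptance script are stated below.

## Model comparison and validation

AIC is `-2 logL + 2p` where `p` counts free (co)variance parameters —
`sum q(q+1)/2` per term plus residual classes **plus one** — the
convention that reproduces published model-comparison tables for this
model family exactly; the extra count is configurable. Likelihood-ratio
tests compare nested candidates against the full model on `df = delta p`.

Predictive ability follows forward validation: phenotypes adjusted for all
fixed effects of the full-data pedigree-BLUP fit; the youngest cohorts
(pedigree generation refined by hatch week) totalling ~10% of hens form
the validation set; breeding values are re-estimated without their
records; the summary is the Pearson correlation between reduced-data
(G)EBV and full-data adjusted phenotypes over validation animals — per
biweekly age for RR, with the unweighted mean as the single value (the
aggregation behind published single-value RR predictivities is not
standardized; the per-age series is always reported alongside).

## Synthetic data

The generator emulates a pedigreed turkey maternal line: discrete
generations, ~5:1 hen:tom matings (one tom per hen for her whole lay),
gene-dropped unlinked SNPs (founder frequencies U(0.1, 0.9); the last
chromosome labeled non-autosomal to exercise QC), selective genotyping of
the youngest fraction of animals, and biweekly records built from the RR
model above. Additive coefficients support two architectures:

* **markers** (default): coefficients are sums of per-marker effect
  vectors on the gene-dropped genotypes, `a_i = sum_j (x_ij - 2p_j) b_j`
  with `b_j ~ N(0, K / (2 sum p(1-p)))`. Relatives then covary through
  their *realized* genomic relationship (expectation: the pedigree A), so
  genomic relationship matrices genuinely carry information about
  breeding values — without this, single-step evaluation could never beat
  pedigree BLUP on simulated data.
* **pedigree**: coefficients are gene-dropped with the exact pedigree
  covariance — founders `N(0, K)`, offspring = parent average + Mendelian
  deviation with covariance `d_i K`, `d_i = 1/2 - (F_s + F_d)/4` — giving
  `N(0, A (x) K)` exactly. This is the model-matched setting used for
  parameter-recovery tests (markers are uninformative about breeding
  values under it).

Records stay Gaussian (no truncation to [0, 100]) to keep
REML recovery unbiased; a clamp flag exists. A per-age dropout probability
(default 0.1) reproduces unbalanced counts across ages.

Default generating values mimic a hatch-of-fertile-like trait: hen
additive coefficient covariance `diag(200, 8, 3, 1.5)` (per-age additive
variance ~100-125 %^2), tom additive `diag(10, 2)`, hen permanent
environment `diag(220, 30, 10, 5)`, tom permanent environment
`diag(40, 6, 3)`, residual variance rising linearly from 350 to 560 %^2
over 38-62 weeks, overall mean 81.1%, small fixed hatch-week and
egg-hatch-week effects, and a declining cubic age trend. That puts per-age
heritability near 0.12-0.16 and repeatability near 0.3.

What the generator does **not** emulate: linkage/LD between markers,
selection or non-random mating, overlapping generations, genotyping
error/imputation, and the bounded, overdispersed nature of real percentage
records. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

## Problem sizes and numerical choices

* Test suite: CUM heritability recovery uses 20 replicates of 2,000
  recorded hens at h2 = 0.30; RR recovery uses one 3,000-hen, 6-generation
  program (4,320 animals, ~35,000 records, ~26,500 mixed-model equations);
  the ssGBLUP-vs-BLUP comparison uses 10 replicates of 1,600 hens with the
  youngest half genotyped at 600 markers.
* Acceptance script: one 750-hen program, 1,200 markers, youngest 35%
  genotyped; both model families fitted under both relationship matrices.
* Residual variances are floored at 1e-8 times the phenotypic variance;
  fixed-factor rank deficiency is resolved by an intercept plus
  first-level-zeroed dummies (equivalent to absorbing the mean into the
  first factor); MME solves use the blocked LDL' (dense Cholesky below
  ~1,200 equations); ages must lie on the biweekly grid.

## Known limitations

* Single-trait analyses only; no dominance, genetic groups, or
  metafounders; no genotype imputation.
* The AI-REML plateau rule reports `flat` status when a variance component
  sits on the boundary; the affected component is effectively zero and its
  standard errors are not meaningful.
* `build_A` materializes the full dense A (and A22) — adequate to ~10k
  animals, not for national-scale pedigrees.
* The single-value RR summaries (means over ages) are conventions;
  alternative weightings are easy to compute from the per-age tables.
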