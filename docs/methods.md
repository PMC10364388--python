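# Methods

`igeblup` implements the quantitative-genetic analysis of a binary,
group-recorded trait — combined skin damage (CSD) scored once per gilt
at the end of the finishing phase — under models that do or do not
account for social (indirect) genetic effects, together with the
simulation machinery needed to exercise every stage without access to
commercial breeding data.

## Models

The phenotype is the binary score (1 = skin damage prevented sale,
2 = sold) multiplied by 100 and treated as a linear trait. Two animal
models are fitted:

* classical (Model 1):
  `y = Xb + Z_D u_D + Z_1 gr + Z_2 cl + Z_3 cg + e`
* social interaction (Model 2):
  `y = Xb + Z_D u_D + Z_S u_S + Z_1 gr + Z_2 cl + Z_3 cg + e`

with fixed effects of line, scorer and age at scoring (linear
covariate, centred at its mean), and random pen group (`gr`), common
litter (`cl`), contemporary group (`cg` = farm x year-month of birth)
and residual. `Z_S` links each record to the social effect of every
pen mate, so its row sums equal pen size minus one. The genetic
(co)variance is

    var([u_D; u_S]) = [[s2_uD, s_uDS], [s_uDS, s2_uS]] (x) A,

with `A` the pedigree numerator relationship matrix; `gr`, `cl`, `cg`
and `e` are iid. Treating a binary score linearly is a deliberate
modelling simplification (the threshold/probit route is a non-goal);
all variance components are therefore on the observed 100-point scale.

Single-step genomic evaluation replaces `A^-1` in the mixed-model
equations by

    H^-1 = A^-1 + [0 0; 0 G_blend^-1 - A22^-1],

where `G = MM' / (2 sum p_j (1-p_j))` from dosages centred by twice
the allele frequency observed in the genotyped set, blended with 5% of
`A22` before inversion. Variance components are estimated without
genomic information by default; `H^-1`-REML is available by passing
`H^-1` and its log-determinant.

## Derived parameters

With `Nbar` the mean pen-group size (so `Nbar - 1` social
contributors per record) and `r` the mean additive relationship
between pen mates (computed exactly over all pen-mate pairs):

    h2        = s2_uD / (s2_uD + s2_gr + s2_cl + s2_cg + s2_e)
    s2_TBV    = s2_uD + 2 (Nbar-1) s_uDS + (Nbar-1)^2 s2_uS
    s2_P_DS   = s2_uD + (Nbar-1) r [2 s_uDS + (Nbar-2) s2_uS]
                + (Nbar-1) s2_uS + s2_gr + s2_cl + s2_cg + s2_e
    T2        = s2_TBV / s2_P_DS
    r_uDS     = s_uDS / sqrt(s2_uD s2_uS)

Total breeding values are `TBV = u_D + (N - 1) u_S` with the animal's
own pen size `N`; animals without a pen (sires, other ancestors) use
the population mean (default 10.7).

## REML

EM-REML on Henderson's mixed-model equations is the reference
algorithm: each round solves the equations at the current components
and updates every variance from the solution cross-products plus trace
corrections taken from the coefficient-matrix inverse; the 2x2 genetic
block is updated as a matrix (with an eigenvalue floor should rounding
leave the PD cone). The residual update is
`(y'y - sol' T'y) / (n - rank X)`. Convergence uses the squared
relative change `sum(dtheta^2)/sum(theta^2) < tol` (default 1e-9,
maxiter 500).

Plain EM is monotone but crawls on this model class: the likelihood
has long, curved, nearly flat valleys in which the direct variance
trades off against the direct-social covariance, and optima frequently
sit on or near the boundaries `s2_uS = 0` / `|r_uDS| = 1`. Three
acceleration devices are layered on top, all guarded so that no
accepted step loses restricted likelihood (the trajectory stays
monotone and the fixed points are exactly the EM fixed points):

* average-information (AI) Newton steps taken on an unconstrained
  parameterisation (log variances, atanh correlation), with a
  Levenberg-Marquardt ladder and per-element step clipping, accepted
  through a step-halving ladder only if they improve the likelihood;
* periodic geometric extrapolation along the stride-2 parameter path
  (Aitken-style), for valleys in which both EM and AI creep;
* during deep crawls the AI attempt (whose quadratic model is
  unreliable there) is skipped in favour of EM plus extrapolation.

The restricted log-likelihood is evaluated through the mixed-model
identity `-2logL = (n-p) log 2pi + log|R| + log|G| + log|C| + y'Py`;
`log|A|` comes from the Mendelian-sampling variances, `log|H|` from
`log|A| + log|G_blend| - log|A22|`, and `log|C|` from the dense
Cholesky factor. Trace terms use the inverse Cholesky factor: only
the diagonal of `C^-1` and its entries on the sparsity pattern of the
relationship inverse are formed (a CHOLMOD-style sparse selected
inverse is not available in this stack; the dense route bounds the
practical problem size at roughly 8,000 equations, which the study
designs respect). AIC is `-2logL + 2k` with `k` the number of
estimated (co)variance parameters only (5 classical, 7 social) —
fixed effects are profiled out by REML and the source publications do
not define `k`, so the standard REML-AIC convention is adopted.

Starting values default to an equal split of the phenotypic variance
(the social variance scaled by `1/(Nbar-1)` so its phenotypic
contribution matches the other shares; the covariance starts at 0).
The replicate studies pass explicit informed starts instead — a
low-heritability split, and for the social model a warm start at the
classical fit — because starting values do not move the guarded
optimum (equal-split, truth-started and warm-started runs agree to
four or more digits) but cut the iteration count several-fold.

## Synthetic data

The generator emulates a multiplier-farm F1-gilt population: purebred
founder pools per line, within-line ancestor generations, breeding
sires (two sire lines) and dams (three dam lines) producing crossbred
litters on five farms; a configurable fraction of sires serves several
farms, and sires enter service in a staggered fashion so that young
sires with progeny only late in the recording window exist (the
forward-validation design needs them). Litters average about five
scored gilts; pens are filled within farm with randomly ordered gilts,
sizes drawn around 10.7 +/- 0.7 (floored at 2; the emulated population
grouped by body weight, which is not modelled); contemporary group is
farm x birth month. Breeding values flow through the pedigree by the
standard recursion — founders draw `(u_D, u_S)` from the 2x2 genetic
covariance, offspring are the parent average plus a Mendelian-sampling
deviation with variance `(0.5 - 0.25(F_s + F_d))` times the 2x2 matrix
— and SNP genotypes by gene dropping from per-line founder
frequencies (uniform on [0.05, 0.5] plus line jitter), exported only
for the purebred ancestors flagged as genotyped.

Phenotypes arise on the liability scale:
`liability = line + scorer + slope*(age - mean) + u_D + sum of pen
mates' u_S + gr + cl + cg + e`, thresholded at the
`1 - target_incidence` quantile calibrated on the realised mean and
standard deviation of the liabilities (default incidence 4.3%).
Moment calibration rather than the exact empirical quantile keeps the
realised incidence an honest random quantity around its target.

Two recording modes matter for interpretation:

* binary (default): the analysed 100/200 score is a thresholded
  version of the liability, so fitted observed-scale components are
  *not* the generating liability-scale components (dichotomising at
  4.3% incidence shrinks heritable variance by roughly a factor of
  five);
* liability recording (`record_liability=True`): the continuous
  liability itself is recorded, the linear mixed models are exactly
  correctly specified, and the generating components live on the
  observed scale. All parameter-recovery experiments use this mode,
  which is what "generating components are interpreted on the observed
  scale" means throughout this package.

Default generating components are the social-model benchmark values
(direct 14.21, social 0.29, correlation -0.05, pen 68.84, litter 8.60,
contemporary group 15.79) with residual 284.3, chosen so that the
analytic T2 at `Nbar = 10.7`, `r = 0.03` equals 0.10; the classical
benchmark uses 14.08 / 72.28 / 8.91 / 16.60 with residual 357.41,
completing a phenotypic variance of 469.3 so the generating
heritability is 0.030. Fixed-effect magnitudes (line sd 2, scorer sd
4, age slope 0.1 per day on the 100-point scale) are small but nonzero
so estimability is exercised.

What the generator does not emulate: body-weight-based pen formation
(pen composition is random within farm), mortality, culling or
regrouping, male or mixed-sex pens, linkage disequilibrium beyond
family cosegregation, and selection in the ancestor generations.
Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the stated generating model, not robustness
to those real-data features.

## Replicate studies and problem sizes

The recovery studies run 10 replicates per model of ~2,033 gilts
(5 farms x 38 pens x 10.7) from 60 sires and 250 litters of ~8 gilts
over a base of 40 founders per line, liability-recorded, fitted with
`tol = 1e-7`, `maxiter = 30`; replicates that reach the iteration
ceiling are flagged and retained (guarded monotone updates leave such
estimates between start and optimum). Each social replicate reports
T2 computed from its own fitted components, mean pen size and exact
pen-mate relationship. Study-level results are means with Monte-Carlo
standard errors across replicates; at these data sizes the social
components are weakly identified, for two structural reasons. First,
the direct variance and the direct-social covariance trade off along
a curved likelihood valley. Second, the pen-mate social sum is close
to a pen-level effect (members of a pen differ only by excluding
their own contribution), so `(Nbar-1) s2_uS` and `s2_gr` are nearly
confounded and are separated only by the covariances of relatives
housed in different pens. Per-replicate optima can therefore sit at
`s2_uS = 0`, at `|r_uDS| = 1`, or — in occasional replicates — at a
point where pen variance has been traded for a much larger social
variance at equal likelihood support. Per-replicate estimates of T2
consequently scatter widely (a heavy right tail), and the boundary
pileups skew the replicate mean of the direct variance upward — a
small-sample property of constrained REML under these conditions, not
of the implementation (the same machinery recovers every classical
component without bias, and truth-started refits reach the same
optima with better likelihood than the generating point). Only
replicate means with their Monte-Carlo standard errors are meaningful
at this scale; the emulated study's ~23x larger data set is what
makes single-fit estimates interpretable.

The GWAS null-calibration study uses 100 replicates of 100 genotyped
animals x 300 SNPs with a purely polygenic phenotype (no causal
variant): backsolved p-values should be uniform and the mean count of
Bonferroni-significant SNPs at alpha = 0.05 stays below alpha.

## Validation and GWAS choices

The LR method estimates breeding values from the complete data and
from a partial data set (records up to a cutoff, default the end of
October 2019; the cutoff day itself is included). Accuracy is
`sqrt(cov(EBV_p, EBV_c) / ((1 - Fbar) s2_u))` with `s2_u` the genetic
variance matching the EBV kind (direct, social, or `s2_TBV`), bias the
difference of means (partial minus complete), dispersion
`cov(EBV_c, EBV_p)/var(EBV_p)`; all covariances use the n-1
denominator, and `Fbar` is the mean pedigree inbreeding of the
validation animals at the complete-data pedigree. Standard errors
bootstrap the validation animals (the validation units) with
replacement; degenerate resamples are skipped and counted.

SNP effects are backsolved as `a = (s2_a/s2_u) M' G_blend^-1 u` with
`s2_a` defaulting to `s2_u / (2 sum p_j(1-p_j))`, so the leading ratio
is the VanRaden scaling constant. Standard errors propagate
`Var(u) = G_blend s2_u - PEV` (PEV from the MME coefficient-matrix
inverse) through the same linear map; a naive variant ignoring PEV is
available for sensitivity analysis and for problem sizes where the
dense inverse is impractical. Windows of 20 adjacent SNPs slide one
SNP at a time within a chromosome (truncated end windows dropped; a
disjoint mode exists for additivity checks); the window share is the
variance of `M_w a_w` over genotyped animals divided by the fitted
genetic variance of the matching component. Significance is
Bonferroni-corrected, `0.05/m`.

## Genotype quality control

SNPs are removed iff minor allele frequency < 0.05 (strict, so a SNP
at exactly 0.05 is kept), call rate < 0.95, the 1-df Hardy-Weinberg
chi-square p-value < 1e-7 (pooled across lines; per-line testing is a
flag away), or the SNP lies on a designated sex chromosome; all
criteria are evaluated jointly on the raw matrix and animals are never
removed. Missing dosages are imputed deterministically by twice the
within-line allele frequency (pooled frequency as fallback for a line
with no observed call), preserving per-line mean dosages exactly.

## Known limitations

* The dense linear-algebra path bounds REML at roughly 8,000
  equations; BLUP-only solves scale further via sparse solvers.
* Estimates on binary-recorded data are observed-scale quantities of a
  linear model applied to a 4.3%-incidence score; no liability-scale
  transformation is provided.
* On flat likelihood regions the reported REML estimate is the guarded
  fixed point the trajectory reaches; different (equally likely)
  plateau points can differ materially in derived quantities such as
  T2 — replicate means, not single fits, are the supported summary at
  desk scale.
* Unknown-parent groups and metafounders are not modelled; unknown
  parents are unrelated founders.
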