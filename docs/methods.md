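# Methods

This note documents the statistical models, the synthetic data generator,
the numerical choices, and the design decisions behind `gpcomp`.

## The synthetic population

The simulator stands in for a commercial crossbred pig cohort: real data of
this kind are proprietary, so every analysis in the package runs on
populations generated by `gpcomp.simulate`.

**Pedigree.** Generation 0 holds `n_founders` unrelated, non-inbred
founders. Each subsequent generation randomly pairs the previous generation
into disjoint matings (no selfing), each producing `offspring_per_mating`
offspring. The default configuration (450 founders, 3 generations, 3
offspring per mating) yields a final cohort of ~1,500 individuals, the size
of the genotyped cohort this pipeline is designed around; the real
population is a terminal three-way cross, but breed structure is not used
by any estimator here, so a single admixed pedigree is sufficient.

**Genotypes.** Biallelic markers are laid uniformly on `n_chromosomes`
(default 18, the pig autosome count) of `morgans_per_chromosome` genetic
length (default 1 Morgan). Founder haplotype alleles are Bernoulli draws at
per-marker frequencies from `founder_maf_law` (uniform on [0.05, 0.5] by
default). Descendants are produced by gene dropping: each gamete receives a
Poisson(L) number of crossovers at uniform genetic positions (Haldane map,
no interference — the simplest standard choice; LD decay is qualitatively
adequate but not calibrated to any real population, for which no LD or MAF
summaries are available). A fraction `indel_fraction` of markers is
labelled INDEL; the label is a pure class annotation — no mechanistic
difference between SNPs and INDELs is modelled, matching how the analysis
treats them (panel comparisons only).

**Traits.** Three architectures: `polygenic` (every marker gets a normal
effect), `sparse` (`n_qtl` markers get normal effects), and `mixture`
(`n_qtl` markers assigned to a four-component scheme with relative
variances 0 / 1e-4 / 1e-3 / 1e-2 and proportions 0.05 / 0.50 / 0.30 / 0.15
— most causal effects small, a few moderate). Effects are rescaled so the
realized additive variance equals `target_h2`, and the residual is drawn,
orthogonalized against g in-sample and rescaled so that realized
heritability equals the target *exactly* (phenotypic variance 1 before
fixed effects). This calibration to the realized rather than expected
genetic variance makes parameter-recovery tests sharp: an estimator's error
is its own, not the simulator's sampling noise.

**Fixed effects.** Each entry of `fixed_effect_spec` (name, level count,
effect SD) assigns individuals to levels uniformly and adds level values
drawn N(0, sd^2). Defaults emulate sex (2 levels, sd 0.5), farm (3, 0.3),
birth year-month (12, 0.3) and slaughter lot (20, 0.3) on a unit-variance
trait — strong enough that skipping the correction visibly hurts
downstream accuracy.

**What the generator does not emulate:** genotyping or imputation error,
selection, mutation, non-additive gene action, population-specific LD, and
trait-specific phenotype distributions. Passing tests therefore demonstrate
correctness of the estimators under an idealized additive world, not
expected accuracies on real pig data.

## Phenotype correction

`correct_phenotypes` fits trait ~ intercept + categorical fixed effects by
OLS (reference-level dummies) and returns `y_c` = residual + grand mean.
Retaining the grand mean keeps `y_c` on the raw trait scale so the overall
mean in downstream mixed models stays meaningful; using the grand mean
rather than the reference-level intercept makes the correction invariant to
level relabelling. Rank-deficient (confounded) designs are rejected with
the aliased columns named, via pivoted QR. The correction is fitted once on
the full dataset by default — matching the two-stage practice where
corrected phenotypes precede cross-validation — which leaks a small amount
of validation information through the fixed-effect estimates; a
`fit_index` argument supports leakage-free within-training-fold correction,
and raises if held-out records carry factor levels unseen in training.

## Relationship matrices

* **G** (VanRaden): `G = MM'/(2 sum p_i(1-p_i))`, `M` the dosage matrix
  centred at `2 p_i`. `p_i` is the *counted-allele* frequency by default:
  centring at the literal minor allele frequency would break `E[M] = 0`,
  and the "minor" wording in common descriptions is treated as a slip; the
  literal variant remains available (`freq_convention="minor"`) for
  sensitivity checks. Frequencies come from the observed data unless
  explicit (e.g. base-population) frequencies are supplied. Monomorphic
  markers are excluded from numerator and denominator.
* **A / A22**: tabular-method numerator relationships, founders unrelated;
  A22 is the genotyped sub-block.
* **A^-1**: Henderson's rules with inbreeding; inbreeding coefficients are
  taken from the tabular A diagonal, so the result is exact for any
  parents-first pedigree (verified against dense inversion).
* **Blending**: with observed-frequency centring the columns of M sum to
  zero, so G is always singular (G·1 = 0). Where an inverse is required
  (the MME, H^-1), `G* = (1-eps) G + eps A22` (or identity), eps = 0.05
  default. REML does not need the inverse — the likelihood is evaluated
  through the eigendecomposition — so heritability estimation uses the raw
  G; blending there would bias h2 upward by roughly eps.
* **H^-1** = A^-1 plus `(G^-1 - A22^-1)` added to the genotyped block. No
  tau/omega scaling weights and no G-to-A22 mean tuning: the plain
  single-step combination.

## REML

Single-kinship model `y = Xb + g + e`, `g ~ N(0, K sigma_g2)`. K is
eigendecomposed once; every likelihood, gradient and average-information
evaluation is then O(n). Updates are AI-REML steps, replaced by an EM-REML
step (guaranteed ascent) whenever the AI step would leave the parameter
space or lose likelihood; convergence is relative log-likelihood change
below `tol` (1e-8). The fixed design inside REML is intercept-only, since
fixed effects are removed in the correction stage. Standard errors come
from the inverse AI matrix, with the delta method for h2. Boundary
estimates (sigma_g2 at the floor of 1e-8 var(y)) are reported as h2 = 0;
non-convergence is flagged, never silent.

## BLUP solvers

GBLUP and ssGBLUP solve the mixed model equations directly (dense
factorization — adequate at the few-thousand-individual scale this package
targets; the contract is the relative residual of the solved system,
checked at 1e-6, not the factorization). The variance ratio
`k = sigma_e2/sigma_g2` is re-estimated by REML on each training fold by
default (no leakage); a global-estimate mode exists for speed and for
mirroring estimate-once workflows. SNP-BLUP (ridge regression on centred
dosages, `k_marker = k * 2 sum p(1-p)`) is implemented as an independent
oracle: its GEBVs equal GBLUP's exactly when both use the same centring
frequencies and G is full rank, which the equivalence benchmark exercises
with external generating frequencies (observed-frequency centring makes G
singular by construction, see above).

## Bayesian samplers

One numba-compiled single-site Gibbs engine covers all five priors; the
chain is bit-reproducible under a seed. Residuals are maintained
incrementally on every update. Default chain length follows common
practice: 12,000 iterations, 2,000 burn-in (the benchmark studies use
shorter, documented chains). Genotypes are centred by column mean before
sampling; the constant shift is absorbed by mu and GEBVs are reported on
the centred scale, which is irrelevant to correlation and slope metrics.

Full conditionals follow the standard formulations; hyperparameters use
the usual weakly-informative defaults, solved from an assumed genetic
variance share R2 = 0.5 of var(y) with MSx = sum of marker variances:

* Effect variances (BayesA/B per marker, BayesC slab): scaled-inverse-chi2
  with df 5 and scale `S0 = var(y) R2 (df+2) / (df MSx share)`, where
  `share` = 1 - Pi for the spike-and-slab models.
* Residual: scaled-inverse-chi2, df 5, scale matched to `(1-R2) var(y)`.
* BayesB: fixed spike probability Pi (default 0.95, configurable); the
  marker indicator is sampled from the marginal likelihood ratio with the
  effect integrated out. Pi = 0 runs through the same spike-and-slab code
  path with inclusion probability 1, and is checked against BayesA.
* BayesC: common slab variance; Pi ~ Uniform(0,1) updated as
  Beta(m - k + 1, k + 1) (k = included markers); `fix_pi` freezes it.
* Bayesian LASSO: normal-exponential mixture `g_j ~ N(0, tau_j^2 sigma_e2)`,
  `1/tau_j^2` inverse-Gaussian, lambda^2 ~ Gamma(1.1, rate) with the rate
  set so the prior mode sits at the standard guess
  `2 (1-R2) MSx / R2`.
* BayesR: four components with relative variances (0, 1e-4, 1e-3, 1e-2) of
  a *sampled* total marker variance sigma_g2 (scaled-inverse-chi2 update
  from the non-null effects — the mixture description fixes only the
  ratios, so the total is treated as a parameter, the standard choice);
  mixture proportions Dirichlet(1,1,1,1).

Monte Carlo standard errors are reported by batch means on the sigma_e2
trace. A chain whose posterior residual variance collapses below
1e-8 var(y) is flagged as diverged.

## Evaluation

`make_folds` partitions individuals into n equal folds (sizes differ by at
most one), re-randomized every round; each fold validates once per round.
The default plan is 5 folds x 5 rounds = 25 validation fits. Accuracy is
the Pearson correlation between GEBV and corrected phenotype in the
validation set — deliberately *not* divided by sqrt(h2). Bias is the OLS
slope of `y_c` on GEBV. Undefined metrics (constant vectors) are flagged
NaN with a warning and excluded from aggregation. The experiment grid
derives per-cell seeds from the master seed via `SeedSequence`, records
failed cells and continues.

## Benchmark studies (`gpcomp.experiments`)

Problem sizes are chosen so each study has adequate statistical power and
the whole set runs in about a minute on one core:

* REML recovery: n = 1000 unrelated individuals genotyped at the m = 200
  causal loci. The GREML sampling SE is roughly sqrt(2m)/n ~ 0.02, so a
  +-0.05 recovery window tests the estimator, not panel noise.
* Fold-count comparison: one dataset (n = 1000, m = 3000, h2 = 0.5),
  40 paired rounds of 2- vs 3-fold CV, sign test across rounds.
* Density profile: 20 replicate pedigree populations (LD from gene
  dropping), panels of 100 / 1000 / 5000 markers thinned from the
  polygenic panel, 5-fold CV; sign test on low-to-mid gain plus a plateau
  check (mid-to-high gain below low-to-mid gain and not negative beyond
  noise).
* Single-step advantage: 20 replicates, ~340-animal phenotyped cohorts
  with 30% ungenotyped, both models evaluated on identical folds of the
  genotyped subset (pairing removes fold noise from the comparison).
* QTL detection: one planted QTL among 500 markers, n = 500, ten
  replicates per sampler.
* Bias calibration: 10 replicates of n = 1000, 5-fold GBLUP with per-fold
  REML k.

## Known limitations

* Dense linear algebra throughout: fine to a few thousand individuals and
  ~50K markers, not engineered for national-evaluation scale.
* Single-trait, additive-only models; no dominance/epistasis, no
  multi-trait REML, no GxE, no repeated records.
* The Bayesian samplers run a single chain; convergence diagnostics are
  limited to batch-means MCSE.
* Marker thinning is uniform random; no map-aware or LD-aware selection.
* Synthetic LD is not calibrated to any real population, so absolute
  accuracies here do not forecast accuracies on real data — only the
  orderings and identities the studies assert.
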