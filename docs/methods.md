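# Methods

## Model

Phenotypes of T traits for individual i are modelled as

    y_i = X_i b + sum_l gamma_l u_il g_l + e_i,        e_i ~ N(0, Sigma_e)

where u_il in {-1, 0, 1} codes the genotype at SNP l (homozygous reference,
heterozygous, homozygous alternate), g_l is the T-vector of that SNP's
effects on all traits, and gamma_l in {0, 1} switches the SNP in or out of
the model with prior P(gamma_l = 0) = pi.  Given inclusion, g_l ~ N(0,
Sigma_gl) with a SNP-specific T x T covariance; Sigma_gl ~ IW(nu, S) with S
= diag(s_k) inferred from the data (uniform priors on s_k > 0, on b, and on
Sigma_e over positive-definite matrices).  Crucially, Sigma_gl keeps its
inverse-Wishart prior regardless of gamma_l; this is what makes every full
conditional a standard distribution so the MCMC needs only Gibbs steps.
Setting pi = 0 recovers multi-trait Bayesian shrinkage regression (every
SNP in the model); pi may also be fixed in (0,1) or given a uniform prior
and inferred (Beta posterior).

The genomic breeding value of an individual is the genetic part of the
regression: GBV_i = sum_l u_il * E(gamma_l g_l).  Intercepts are excluded
from GBV; the evaluation metrics (correlation, regression slope) are
location-invariant, so this only affects the reported GBV scale.

## MCMC engine (Gibbs sampling)

One cycle updates, in fixed order: sampled residuals for missing phenotype
cells; b from its multivariate-normal conditional; for each SNP the pair
(gamma_l, g_l); each Sigma_gl; the scale parameters s_k; Sigma_e; and pi.
Non-obvious derivations:

- **Collapsed inclusion step.**  gamma_l is drawn from its conditional with
  g_l integrated out analytically given Sigma_gl and Sigma_e: the odds of
  inclusion are (1-pi)/pi * |V_l|^(1/2) |Sigma_gl^-1|^(1/2) *
  exp(m_l' V_l^-1 m_l / 2), where V_l = (Sigma_gl^-1 + (sum_i u_il^2)
  Sigma_e^-1)^-1 and m_l is the conditional mean of g_l.  Then g_l | gamma_l
  = 1 ~ N(m_l, V_l), else g_l = 0.  A naive componentwise step conditioning
  on g_l = 0 could never re-enter the model; the collapsed step is what
  makes pure Gibbs sampling of the spike-and-slab work.
- **Sigma_gl** | rest ~ IW(nu + gamma_l, S + gamma_l g_l g_l') — excluded
  SNPs refresh their covariance from the prior.
- **s_k** | rest ~ Gamma(shape N*nu/2 + 1, rate (1/2) sum_l
  (Sigma_gl^-1)_kk), from the |S|^(nu/2) exp(-tr(S Sigma_gl^-1)/2) factors
  under the uniform prior.
- **Sigma_e** | rest ~ IW(n - T - 1, sum_i y_i* y_i*') in the
  degrees-of-freedom convention where IW(nu, S) has density proportional to
  |Sigma|^-(nu+T+1)/2; this is the exact conjugate update for the
  |Sigma_e|^(-n/2) likelihood under the flat prior and matches the
  variational engine's (n - T - 1)-scaling.
- **pi** | rest ~ Beta(N - sum gamma + 1, sum gamma + 1).

Missing residuals are drawn per individual from the partitioned normal
e_m ~ N(S_mo S_oo^-1 e_o, S_mm - S_mo S_oo^-1 S_om); individuals with no
observed trait draw from the marginal N(0, Sigma_e).

Point estimates are posterior means over retained samples.  The SNP effect
used for prediction is the mean of the product gamma_l g_l, not the product
of means.  Default chain: 11000 cycles, 1000 burn-in, every 10th retained.

The per-SNP loop is compiled (numba) with the residual matrix held
trait-major so the length-n inner loops vectorise; the residual cache is
updated incrementally per SNP (O(nT)), keeping a full sweep at O(N n T +
N T^3).  A pure-numpy `gibbs_sweep` with identical update structure serves
small problems and verification.

## Variational engine (coordinate ascent)

The joint posterior is approximated by the fully factorized q(b) q(Sigma_e)
prod_l q(gamma_l, g_l) q(Sigma_gl) q(S) (and q(pi) when inferred), each
factor the standard distribution induced by the conjugate structure: normal
for b and for g_l given inclusion, Bernoulli for gamma_l, inverse-Wishart
for Sigma_e (df n - T - 1) and Sigma_gl (df nu + E(gamma_l)), Wishart for S
(df N*nu + T + 1), Beta for pi.  The updates pass expectations rather than
draws; the inclusion probability uses the same determinant-and-quadratic-
form odds as the collapsed Gibbs step, computed in log space with a guarded
logistic transform.  E(gamma_l g_l) = E(gamma_l) g_hat_l and E(gamma_l g_l
g_l') = E(gamma_l)(g_hat_l g_hat_l' + V_gl) hold exactly by construction at
every iteration.  Missing-cell residuals are replaced by their conditional
expectations E(Sigma_mo) E(Sigma_oo)^-1 e_o*; the inverse-Wishart scaling
constant cancels in that ratio, so it is formed directly from the blocks of
the scale matrix S_e.

Sweep order: fixed effects -> residual covariance -> per-SNP inclusion/
effect then SNP covariance (in index order) -> scale matrix -> pi ->
missing-data expectations.  The model only fixes the stationary conditions,
not an order; this order feeds every update the freshest dependencies.

Initialization: effects at zero (the first sweep is then a battery of
single-SNP regressions), E(b) from the GLS solve of the raw phenotypes,
E(Sigma_e^-1) at the inverse phenotypic covariance, E(gamma_l) at the prior
mean 1 - pi, E(S) at identity.  Convergence is declared when the relative
squared change |theta* - theta|^2 / |theta*|^2 of the monitored expectation
vector (E(b), all E(gamma_l g_l), vec(S_e), vec(E(S)), E(pi)) drops below
1e-8; per-SNP covariances are excluded from the vector to keep the
criterion O(NT).  Hitting the iteration cap (default 10000) is reported in
the diagnostics, not raised.  The engine is deterministic: repeated runs
are bit-identical.

Although the prior restricts S to diagonal, the variational posterior of S
is a full Wishart; E(S) is used as computed.  `PriorConfig(s_diagonal=True)`
forces diag(E(S)) for users preferring prior fidelity.

## Hyperparameters

- nu (inverse-Wishart df of Sigma_gl): default 5.0 when pi = 0 and 3.2 when
  pi is inferred; must exceed T - 1.  Prediction accuracy is insensitive
  over roughly 3 < nu < 6.
- pi: 0 (all SNPs retained, shrinkage only), a fixed value, or inferred.
- Chain length / tolerance as above.

Single-trait mode fits T independent T = 1 models with the identical code
path and merges them (diagonal covariance estimates).  Individuals missing
a trait's phenotype are dropped from that trait's single-trait fit — with
one trait there is nothing to condition the imputation on, and dropping is
the exact marginal likelihood.

## Synthetic-data generator

The generator emulates a livestock/crop-style genomic-selection benchmark:

- **Population history.**  Ne = 100 monoecious diploids, random mating with
  recombination and mutation for 1000 generations to reach mutation-drift
  balance and build linkage disequilibrium; the next two generations are
  expanded to 1000 individuals each and serve as training (genotypes +
  phenotypes) and test (genotypes + true breeding values only) cohorts.
  Founders are monomorphic; all diversity is mutational.
- **Genome.**  10 chromosomes of 100 cM; 101 markers/chromosome at 1 cM
  spacing (1010 SNPs; the dense scenario uses 1010/chromosome for 10100)
  and 100 QTL/chromosome, each QTL at the midpoint of a marker interval.
  Recombination is Haldane (no interference), implemented exactly as a
  two-state Markov chain along each chromosome with switch probability
  (1 - exp(-2d))/2 per adjacent-locus gap d (Morgans).
- **Mutation.**  Infinite-alleles bookkeeping at rate 2.5e-3 per marker
  locus per meiosis and 5.0e-5 per QTL; at sampling time each locus is
  collapsed to two alleles by declaring the surviving mutation with the
  highest minor allele frequency (in the training cohort) visible and
  collapsing everything else to the ancestral allele; ties break toward the
  earliest mutation.  Loci with no surviving mutation are constant columns
  and are retained (never filtered); the engines handle them through the
  prior.
- **Traits.**  QTLs polymorphic in the training cohort are assigned to four
  groups with probabilities (0.4, 0.1, 0.1, 0.4): pleiotropic for traits A
  and B, A only, B only, C only — so 80% of trait-A QTLs are shared with B
  on average and C is genetically independent.  Effect magnitudes are
  Gamma(shape 0.4, scale 1.66); the pleiotropic pair (x, y) is built from
  three independent gammas with shapes (0.36, 0.04, 0.04) at the common
  scale as x = x1 + x2, y = x1 + x3, giving corr(x, y) = 0.36/0.40 = 0.9
  with the stated marginals.  One random sign per QTL is shared across the
  pair; independent signs would destroy the positive genetic correlation
  between A and B (about 0.72 on average at these settings).
- **Phenotypes.**  TBV = sum of mutant-allele dosage times effect over
  polymorphic QTLs; environmental effects are trivariate normal with
  correlations (0.1, 0.2, 0.3) and variances sigma_E,t^2 = (1/h_t^2 - 1) *
  Var(TBV_t) computed from the realized training-cohort TBV variances
  (heritabilities 0.8, 0.1, 0.1).  A replicate in which no polymorphic QTL
  affects some trait is a hard error.
- **Missing-data scenario.**  From the complete dense-marker data, trait A
  is deleted for individuals 801-1000, B for 1-500, C for 201-700 (1-based),
  leaving 800/500/500 records and exactly 100 fully recorded individuals.
  For cohort sizes other than 1000 the windows scale proportionally
  (strict mode errors instead).

What the generator does *not* emulate: genotyping error, missing genotypes,
non-additive gene action, selection during the history, population
structure or admixture, and sequencing-style ascertainment. Passing tests
on these data show the estimators recover the generating model's signal;
they do not certify performance on real data violating those assumptions.

`fast_config()` provides a miniature configuration (2 chromosomes, 52
markers, Ne 40, 250 generations, cohorts of 150) with mutation rates raised
to keep locus diversity (theta = 4 Ne mu) at the full-scale value; unit
tests and CLI smoke runs use it.

## Numerical choices

- Small-matrix algebra (T <= 3 in practice) inside the compiled sweeps is
  hand-coded Cholesky-based: factor, triangular solves, log-determinants
  from the factor diagonal.  Non-SPD intermediates raise immediately.
- Inverse-Wishart draws go through the Bartlett decomposition of the
  precision (any factor F with FF' = scale^-1 is valid, so the transposed
  inverse Cholesky factor is used directly).
- Inclusion odds are formed in log space and clipped at |35| before the
  logistic transform.
- The MCMC engine mixes two seeded streams: numpy Generator for the
  Python-level draws (b, Sigma_e, s, pi, missing residuals) and the
  compiled kernel's own state for per-SNP draws, both derived from the
  chain seed; runs are exactly reproducible.
- MAF ties at biallelic collapse break deterministically (lowest allele
  label = earliest mutation event).
- Degenerate inputs: zero-variance predicted GBVs make correlation and
  slope NaN (reported, not raised); an all-zero residual scatter raises as
  a degenerate fit; n <= T + 1 individuals cannot update the residual
  covariance.

## Desk-scale defaults

The replicate-experiment driver defaults to 10 replicates for the
1010-SNP scenarios and 3 for the 10100-SNP scenario. The test suite and
the acceptance script reproduce the study's headline numbers at desk
scale: 10 simulated replicates for simulator statistics, 5 variational
fits, 4 MCMC fits with shortened chains (2500 cycles, 500 burn-in, thin
4 — verified to track the 11000-cycle chains' accuracies to within ~0.01
on the same replicate), 5 cross-validation replicates (10 folds each,
1200-cycle chains) and 3 missing-data replicates.  Reference comparisons
use the study's between-replicate standard deviations as bands.

## Known limitations

- The variational approximation understates posterior uncertainty (it is a
  point-estimation tool here); its prediction accuracy runs a few percent
  below the MCMC engine, with larger slope (bias) deviations for
  low-heritability traits, as in the original study.
- With pi inferred, uncorrelated low-heritability traits can lose accuracy
  relative to single-trait analysis; pi = 0 is the safer default for mixed
  trait panels.
- The polygenic extension (a pedigree/genomic relationship random effect on
  top of the SNP regression) is out of scope.
- No convergence diagnostics beyond the parameter-change metric and trace
  exports; R-hat and effective sample size are left to the user.
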