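# Methods

## The model

`hollimap` maps quantitative trait loci (QTLs) that govern interactions
between two co-cultured species.  The phenotype is not a scalar but a
pair of abundance trajectories, and the genotype-specific mean curves
are solutions of a coupled ordinary differential equation system that
combines logistic self-limited growth with a Holling type II
(saturating) cross-species term:

    dE/dt = r_e E (1 - E/K_e) + r_e E (alpha_es / (1 + E)) S
    dS/dt = r_s S (1 - S/K_s) + r_s S (alpha_se / (1 + S)) E

E and S are the abundances of species A and B; r_e, r_s are Malthusian
growth rates (per hour); K_e, K_s carrying capacities (abundance units);
alpha_es and alpha_se are signed interaction scalars — positive values
mean the focal species benefits from its partner, negative values that
it is harmed, zero that it is unaffected.  The saturating form
alpha/(1+E) makes the per-capita interaction effect approach its ceiling
gradually with density, the empirically dominant shape for
consumer-mediated interactions.

The first summand is the **independent** growth component — what the
species would do in monoculture — and the second the **dependent**
component contributed by the partner.  `decompose_trajectory` computes
the independent component by solving the interaction-free logistic
system standalone from the same initial state (it has an exact closed
form) and defines dependent = net − independent, so the decomposition
identity is exact at every time point.  An alternative convention would
integrate the interaction term along the coupled trajectory; we use the
standalone-monoculture definition because it matches the experimental
contrast (the same strain grown alone) that the method is built around.

## Likelihood

Each individual is an interspecific strain pair observed at T times in
co-culture (or a single strain in monoculture).  Its stacked vector
(E(1..T); S(1..T)) is modelled as multivariate normal.  At a marker pair
(one marker per genome, haploid biallelic coding) the four genotype
combinations AB, Ab, aB, ab each get their own ODE parameter set
theta_j = (r_e, K_e, alpha_es, r_s, K_s, alpha_se); the 2T x 2T
covariance is shared across combinations and structured as a bivariate
first-order structured antedependence model, SAD(1):

    e_k(t) = phi_k e_k(t-1) + eps_k(t),    k in {E, S},

with innovation SDs nu_e, nu_s and a contemporaneous cross-species
innovation correlation rho.  This five-parameter family is the minimal
bivariate SAD(1): it produces nonstationary within-species serial
covariance (variances grow along the trajectory, as growth data do) and
a cross-species covariance band, i.e. all four blocks of the
longitudinal covariance.  Initial abundances are not free parameters:
by default all combinations share one initial state fixed at the global
mean first-time abundance, reflecting a common inoculum (per-combination
and freely fitted variants are available via `FitConfig.init_mode`;
fixing a shared init also keeps nested fits strictly comparable).

Maximisation uses a hybrid of Nelder-Mead simplex search and
fourth-order Runge-Kutta integration.  Parameters are transformed so the
search is unconstrained (log for rates, capacities and innovation SDs;
scaled atanh mapping phi into (-3, 3); atanh for rho; identity for
alpha).  Because the likelihood separates over combinations once the
covariance is fixed, the fitter cycles block-coordinate simplex updates
— one 6-parameter search per combination, then one 5-parameter SAD
search — until the joint log-likelihood gains less than `tol` (default
1e-3) or the cycle budget is exhausted.  Sufficient statistics
(per-combination means, pooled within-scatter) make each likelihood
evaluation O(T^3) regardless of sample size.  Starting values come from
per-species logistic least squares on combination means, alpha = 0, and
moment estimates of the SAD parameters; optional restarts jitter the
transformed starting point.  Proposals outside a generous plausibility
box (r <= 20/h, K within 20x the observed abundance scale, |alpha| <= 5)
are rejected: the likelihood has a ridge along which K and alpha trade
off while the fitted curve barely changes, and without the box the
simplex occasionally escapes to absurd joint values on noisy data.

## Hypothesis tests and scans

The scan statistic is LR = 2(log L1 − log L0), comparing the
genotype-specific fit (H1) against a single shared curve (H0).  The H0
fit does not depend on the marker and is computed once per scan; every
H1 fit warm-starts from it, which both accelerates the scan and makes
LR >= 0 structural (simplex refinement from the null solution can only
improve).  One-genome scans use two genotype classes (6 extra free
parameters in co-culture, 2 in monoculture, where the interaction-free
logistic is the mean model); the two-genome pairwise scan uses the four
combinations (18 extra parameters).  Follow-up subset tests refit with
either the independent-growth block (r_e, K_e, r_s, K_s) or the
interaction block (r_e, alpha_es, r_s, alpha_se) constrained equal
across combinations, localising a significant signal to intrinsic
growth or to the interspecific interaction.

Thresholds: one-genome scans default to a permutation threshold — whole
trajectories are permuted against genotypes (preserving the longitudinal
covariance and pair structure) and the (1 − alpha) order statistic of
per-permutation maximum LRs is used.  Two-genome scans default to a
Bonferroni-corrected chi-square quantile (the per-test level 1e-6 with
df = 18 reproduces the convention used for dense pairwise scans).

## Synthetic data and its calibration

The generator (`hollimap.simulate`) emulates a 45-pair bacterial
co-culture mapping experiment: n interspecific pairs, independent
biallelic markers at frequency 0.5 per genome, 16 observation times over
36 h, genotype effects at one causal marker pair, and bivariate SAD(1)
residuals.  Defaults live in `src/hollimap/data/default_simulation.yaml`:

- backbone parameters r_e = 0.25/h, K_e = 23.94, r_s = 0.22/h,
  K_s = 21.56, mutually antagonistic interaction scalars
  alpha_es = −0.08, alpha_se = −0.12, inoculum (0.8, 0.8) at t = 0.
  Capacities and the rate scale follow the logistic fits to the
  co-culture mean curves of the emulated experiment; the antagonism
  signs and asymmetry (species B harmed more) follow its reported
  interaction structure.
- genotype effects are multiplicative: the focal allele of each genome
  scales its own species' (r, K) by +-8%, and the allele-sign product
  scales both interaction scalars by +-25% (a cross-genome epistatic
  component).  Monoculture trajectories carry the own-genome effect only.
- residual structure phi_e = phi_s = 0.77, rho = 0.3.

Heritability is the noise dial: `calibrate_noise_from_h2` sets the
innovation SDs so that, at the reference time (the time of maximum
genetic variance, separately per species), the frequency-weighted
variance of combination mean curves is a fraction H^2 of total variance.
A consequence worth stating explicitly: after calibration, detection
power is invariant to the overall effect magnitude — only H^2, the
sample size, and the effect/covariance *shapes* matter.  The shape
parameters (phi and the effect mix) were therefore fixed once by a
noncentrality design calculation: the exact asymptotic noncentrality of
the four-combination LR test under the generator,
lambda = sum_j n f_j delta_j' Sigma^{-1} delta_j (available as
`implied_noncentrality`), was set to ~9.3 at n = 45, H^2 = 0.05 — the
operating point at which a chi-square(18) test at point-wise alpha =
0.05 reproduces the published power table of the study this design
emulates.  These are study-design constants, not tuning knobs, and the
power study (`power_fpr_study`) tests the causal pair against exactly
that chi-square threshold.

What the generator does *not* emulate: linkage disequilibrium between
markers (markers are independent), multi-locus architectures (one causal
pair), non-Gaussian measurement error, and abundance truncation at zero
(residuals are exactly Gaussian, so low-abundance observations can be
slightly negative).  Passing tests therefore demonstrate the method's
statistical behaviour under its own assumptions, not robustness to real
sequencing-derived abundance data.

## Numerical choices

- ODE integration: fixed-step classical RK4; partial steps land exactly
  on observation times, so sampled values retain full accuracy on
  non-integer grids.  Default step 0.01 h for standalone trajectory
  work; 0.05 h inside general fitting and 0.1 h in the replicate
  studies (at rates ~0.3/h the local truncation error at 0.1 h is
  ~1e-6 relative, far below measurement noise).  States beyond 1e12
  raise a divergence error naming the time rather than propagating NaN.
- Covariance factorisations use Cholesky decomposition; the SAD block
  objective evaluates n log|Sigma| + tr(Sigma^{-1} M) with M the pooled
  scatter around the current means.
- Ties between optimizer restarts resolve to the earliest restart
  (strict improvement is required to replace the incumbent).
- Degenerate inputs: all-zero abundance matrices, combination cells with
  fewer than two members, and monomorphic markers are rejected or
  skipped with named reasons rather than fitted.

## Problem sizes of the shipped studies

The replicate studies are sized for a single CPU: the power/FPR study
runs 200 replicates per (n, H^2) cell in the acceptance script and 100
per cell in the test suite; parameter recovery uses 100 replicates at
n = 45 and n = 200; permutation calibration uses a 5-marker panel, a
200-permutation threshold and 200 independent null genomes.  Binomial
confidence intervals are reported alongside every empirical rate so that
reduced replicate counts remain interpretable.

## Known limitations

- The interaction scalars alpha are weakly identified from
  plateau-dominated trajectories at low heritability: the data constrain
  a (K, alpha) combination (the joint curve through the plateau) much
  more sharply than either parameter alone.  Fitted *curves* and LR
  tests are unaffected (the likelihood is flat along the ridge), but
  individual alpha estimates at H^2 <= 0.10 carry large variance, and
  mean-bias summaries of alpha should be read with that in mind.
  Designs with richer transient dynamics (earlier sampling, stronger
  coupling) identify alpha much better.
- The model covers exactly two species; no Holling type I/III variants,
  no adaptive or stiff solvers, no interval mapping between markers, and
  no FDR control beyond Bonferroni/permutation.
- Monoculture and co-culture data are analysed separately; a joint
  likelihood across culture conditions would share information but is
  not implemented.
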