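# Methods

## The estimation problem

Routine electronic medical records (EMRs) follow patients who were actually
offered a treatment, but contain no concurrent untreated control group;
randomized trials provide unbiased comparisons, but only for the subset of
routine patients who would have satisfied trial entry criteria. `emrsynth`
estimates the average effect of a treatment offer on a continuous outcome
(an MMSE-style 0–30 cognition score in the motivating application, where
acetylcholinesterase inhibitors are offered to dementia patients) at a fixed
time `alpha` after the offer, by combining both sources so that the
characteristic bias of each can be identified and removed.

Two named biases organise everything:

* **Projection bias** `phi_alpha`: a treated-only cohort supports a
  counterfactual only through the assumption that, absent treatment, each
  patient would have continued on their pre-offer trajectory. If the
  untreated post-offer slope `gamma2` actually differs from the pre-offer
  slope `gamma1`, the extrapolation estimator is off by
  `phi_alpha = (gamma2 - gamma1) * alpha`.
* **Generalizability bias** `zeta = ARE1 - ARE`: trials estimate the effect
  `ARE1` in the trial-eligible stratum, not the population effect `ARE`.

## Trajectory model

Outcomes for subject `i` at time `t` (years relative to the treatment
offer) are modelled as piecewise linear with change points at `t = 0` and at
an unknown `delta` in (0, 3): pre-offer slope `beta1`, initial post-offer
slope `beta2`, late slope `beta3` after `delta`, residual SD `sigma`. Under
the pre-offer-continuation assumption, the treatment effect at `alpha` is

    theta_alpha = (beta2 - beta1) * alpha                             alpha <  delta
                = (beta2 - beta3) * delta + (beta3 - beta1) * alpha   alpha >= delta

and the likelihood is written with `theta_alpha` itself as a coefficient on
an indicator basis (with `beta2` implied), so the quantity of interest has a
direct prior and posterior. Because `delta` is a parameter, the basis —
including which branch of the `alpha`/`delta` comparison applies — is
rebuilt at every posterior draw. Subject random effects can be placed on any
subset of {intercept, pre-slope, treatment effect, late slope}.

The combined model stratifies every fixed effect on the observed trial
eligibility flag `S_i` and splits the treatment coefficient into
`ARE1*1{S=1} + ARE2*1{S=0} + phi_alpha`, with one projection-bias term
shared by both strata (the working assumption is that extrapolation errs
equally in both). The trial meta-analysis enters as a normal prior on
`ARE1` (mean = pooled estimate, SD = pooled standard error); `phi_alpha`
gets N(0, 100^2); the eligible proportion `pi` gets U(0, 1); the population
effect is the per-draw mixture `ARE = pi*ARE1 + (1-pi)*ARE2`. Without the
trial prior only the sums `ARE1 + phi_alpha` and `ARE2 + phi_alpha` are
identified; the informative prior anchors `ARE1`, which is what lets the
model separate both biases even when they act in the same direction.

## Priors

* Fixed coefficients: independent N(0, 100^2) (score units; effectively
  flat over the plausible range of a 0–30 outcome), configurable.
* `sigma ~ U(0, 100)`; `delta ~ U(0, 3)` (the second change point must fall
  after the offer and within the observation window).
* Random effects: one effect — SD ~ U(0, 100); two effects — SDs
  U(0, 100) and correlation U(-1, 1); three or more — separation strategy,
  i.e. per-effect SDs U(0, 100) scaling a correlation matrix whose Cholesky
  factor is parametrized by hyperspherical angles with uniform priors on
  (0, pi). The angle parametrization is an equivalent positive-definite
  construction standing in for a scaled inverse-Wishart; restricted to two
  effects it is checked in the test suite against the direct
  SD/correlation recipe and agrees within Monte-Carlo error.

## Computation

Given `(delta, sigma, RE covariance)` the model is linear-Gaussian, so both
the subject random effects and the fixed coefficients are integrated out in
closed form using Woodbury / matrix-determinant-lemma identities on the
low-rank structure (per-subject q x q and global p x p solves only; no
dense N x N algebra). The remaining 5–12-dimensional block is sampled with
the emcee affine-invariant ensemble using differential-evolution moves,
which mix far better than the stretch move on this correlated posterior.
Fixed coefficients are then re-drawn exactly from their conditional
multivariate normal for each retained ensemble draw. Because `S_i` is fully
observed, `pi`'s posterior is exactly Beta(s+1, n-s+1) independent of the
trajectory block and is drawn directly from that conjugate form — the
mixture identity for `ARE` therefore holds exactly per draw.

Defaults: walkers = max(2*ndim + 2, 12); 1200 steps per walker, first half
discarded, thinned by 2. Walkers are treated as chains for split-R-hat and
effective sample size (arviz); a fit is flagged non-converged when any
R-hat exceeds 1.05. Divergence counts are reported as zero for interface
stability — the concept belongs to Hamiltonian samplers and does not arise
here. Marginal-likelihood evaluations are validated in the test suite
against a brute-force dense multivariate-normal oracle, and conditional
coefficient draws against the dense GLS posterior.

Numerical guard rails: `delta` is kept 1e-6 inside its bounds; proposals
with non-positive-definite precision terms get log-probability -inf; walker
initialization is data-driven (within-subject residual spread for `sigma`,
between-subject spread for the intercept-RE SD) with small jitter.

## Generative model (simulator)

The simulator draws the target population hierarchically: eligibility
`Z ~ Bernoulli(pi)`; individual effects `Delta_i` normal around the stratum
mean (`ARE1` or `ARE2 = (ARE - pi*ARE1)/(1-pi)`) with total within-stratum
variance `nu^2`, of which `tau1^2` sits between trial subsets; outcome
levels at the offer normal around `Gamma01`/`Gamma02`. Untreated
trajectories are two-slope lines (`gamma1` then `gamma2`); treated
trajectories add an offset that is 0 at the offer, equals `Delta_i` exactly
at `alpha`, and kinks once at `delta` with slope gap `gamma3 - gamma2`.
Trials randomize 50:50 and are summarized as differences in mean change
score from offer to `alpha`; the cohort offers treatment to everyone and
records 1–8 scores per subject at uniform times in [-1, 3] years,
emulating the irregular visit pattern of the EMR application (which
averaged ~4.3 scores per patient).

Stock parameter values: `ARE = 1`, `alpha = 0.25`, `Gamma0 = Gamma01 =
Gamma02 = 20`, `gamma1 = -2`, `gamma3 = -1.9`, `delta = 0.3`, `sigma = 2`,
`sigma0 = 4`, `nu^2 = 1`, `tau1^2 = 0.25`, `n1 = 1000` across `k = 4`
trials. Where a grid of study conditions exists the default is the middle
setting (`pi = 0.7`, `gamma2 = -2`, `ARE1 = 1`). Quantities the scenario
table leaves implicit are fixed once as: `Gamma01 = Gamma0`,
`tau0^2 = 0.25` (mirroring `tau1^2`), within-subset variances
`omega^2 = nu^2 - tau1^2` and `omega0^2 = sigma0^2 - tau0^2` (reading the
stated totals as marginal variances). Cohort members are drawn
independently of the trial replicates, so their latent effects use the
marginal stratum distributions with the trial-subset level integrated out.

What the simulator does **not** emulate: informative dropout or
visit-timing linked to disease state, ceiling/floor effects (simulated
scores may exceed 30), non-normal residuals, covariate shift between the
trial-eligible cohort stratum and actual trial samples, and partial
adherence. Passing recovery tests therefore demonstrates internal validity
of the estimators under this generative structure, not robustness to those
real-data features.

## Estimator comparison harness

`run_study` replicates scenarios end to end and reports, per scenario and
estimator, the absolute bias, empirical SE and MSE of (i) the pooled
trials-only estimate (inverse-variance, DerSimonian–Laird by default since
the generative model injects between-trial heterogeneity), (ii) the
cohort-only posterior mean of `theta_alpha`, and (iii) the combined
posterior mean of `ARE`. Per-replicate seeds derive deterministically from
the master seed; non-converged MCMC replicates are excluded and counted
rather than imputed. Scenario grids are given as explicit lists (no
fractional-design machinery); averages across scenarios are plain means.

## Problem sizes

The package's reference study conditions use cohorts of 1500–6000 and 500
replicates. The bundled tests and the acceptance script run a scaled-down
profile chosen as this package's own verification budget: cohort size 400,
20 replicates for each MCMC-based estimator, 200 replicates for the
(cheap) trials-only average, ensemble chains of 1200 steps, and the
two-random-effect structure {intercept, pre-slope}. At this scale the
Monte-Carlo SE of a 20-replicate mean is roughly 0.1 score points for the
cohort-only estimator and 0.15 for the combined one; recovery checks use
3 Monte-Carlo SEs.

## Known limitations and open choices

* The window bounds of the inclusion filter are treated as closed on both
  ends, and the operational "baseline score" is the adjusted score nearest
  the offer (ties to the earlier record); subjects with a missing baseline
  field are conservatively flagged ineligible.
* `delta` is shared across subjects and strata, and a single residual SD is
  used throughout; the random effect on the treatment coefficient is shared
  across strata.
* With diffuse data near the change point, the U(0, 3) prior on `delta`
  leaves posterior mass at larger change points, which mildly shrinks the
  posterior mean of `theta_alpha` toward zero at small cohort sizes; the
  effect fades as the cohort grows.
* The posterior SD is reported as the estimator's SE.
* The trials-only pooling method is selectable (fixed-effect or
  DerSimonian–Laird) but no meta-regression, risk-of-bias weighting or
  power-prior discounting is provided.
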