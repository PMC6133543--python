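# Methods

This note documents the models implemented in `linkage_evo`, the choices
made where conventions were genuinely open, and what the synthetic-data
validation does and does not establish.

## Four-bar kinematics

A planar four-bar linkage is modelled as a frame (fixed link) joining
two ground pivots, with the input and output links rotating about them
and the coupler closing the chain.  The input angle is the interior
angle between the input link and the frame at their shared pivot; the
output angle is measured from the frame direction at the other pivot, so
a parallelogram satisfies `theta_out = theta_in` identically.  Closure
is solved with the law-of-cosines diagonal decomposition: the diagonal
from the input-link tip to the output pivot satisfies
`d^2 = a^2 + f^2 - 2af cos(theta_in)` and the chain assembles iff
`|c - o| <= d <= c + o` (lengths `f, a, o, c` for fixed, input, output,
coupler).  Because `d` is monotone in the input angle, the assembly
range is a single interval, computed analytically.

Only the open (non-crossed) assembly branch is solved; the biological
systems this package models (fish oral and opercular jaws, mantis-shrimp
raptorial appendages) all operate as open chains.  Kinematic
transmission is `KT = |d theta_out / d theta_in|`, evaluated by central
finite differences at 0.1 degrees by default, with one-sided fallback at
range boundaries, and one step trimmed from the assembly-range endpoints
in full-rotation scans because the derivative diverges where coupler and
output become collinear.  Crank geometries can pass through an interior
*dead point* where the output momentarily stalls; minimum-KT scans
legitimately approach zero there, and the grid minimum converges to zero
at the rate of the step size rather than to a fixed positive value.

Three measurement protocols are exposed, matching how KT is measured in
practice: `static` (instantaneous KT with the input link at a start
angle, 30 degrees by default — the biologically relevant jaw posture in
the oral four-bar literature), `min` (minimum instantaneous KT over the
full assembly range, the dynamic protocol used for raptorial and
opercular systems), and windowed `mean`/`min-range` statistics over a
specified input rotation (9 degrees for raptorial-appendage
conversions, 5 degrees for opercular ones).  The absolute reference
posture for the static protocol is not standardised across datasets, so
the start angle is a parameter.  Both the averaged and the minimum
statistic over a conversion window are computed; which one feeds a
downstream analysis is the caller's choice.

## Phylogenetic machinery

Trees are rooted, time-calibrated Newick phylogenies (dendropy-backed).
Under Brownian motion the tip covariance is `C_ij = depth(MRCA(i, j))`;
Pagel's lambda multiplies the off-diagonal entries.  Ultrametricity is
checked with relative tolerance 1e-6 and produces a warning rather than
an error, since empirical calibrated trees are numerically
non-ultrametric; all likelihoods use exact per-tip depths, so mild
deviation is handled without adjustment.  All trait transforms use the
natural logarithm.  Branches are identified by stable preorder indices
(parents before children), with per-branch start/end times and
descendant-tip masks precomputed for the OU machinery.

## Mechanical sensitivity (PGLS)

Mechanical sensitivity is the strength of the relationship between KT
and a link's size-corrected length, measured by generalized least
squares with residual covariance `sigma^2 C(lambda)`.  lambda is
estimated by maximising the profile log-likelihood over [0, 1]
(bounded scalar optimisation, cross-checked against the interval
endpoints); REML is not used.  Predictors are mobile-link lengths
divided by the fixed link and log-transformed; the response (KT) is
log-transformed by default.  Each mobile link is fitted as the sole
predictor, one regression per link, and links are ranked by r^2; a
joint multiple regression is available but is not the default.

Conventions that the PGLS literature leaves open were resolved as
follows: r^2 is `1 - RSS/TSS` in the lambda-whitened space against the
GLS intercept-only model; coefficient standard errors use the unbiased
residual variance `RSS/(n - p)`; p-values are two-sided t tests on
`n - p` degrees of freedom with no multiple-testing correction; AIC is
`2k - 2 logL` with `k = p + 2`, counting the residual variance and the
estimated lambda.

## Evolutionary tempo (Brownian rates)

Each log-trait is an independent Brownian motion with its own rate
`sigma^2_k` around a GLS-estimated phylogenetic mean; within-species
measurement error, when supplied, adds a diagonal to the trait's
covariance.  Traits are deliberately modelled without an evolutionary
correlation parameter: the question is whether *rates* differ, and the
equal-rate constraint ties `sigma^2` across otherwise independent
blocks.  The equal-rate and free-rate models are compared by a
likelihood-ratio test against chi-squared with `k - 1` degrees of
freedom, and every pairwise combination of traits is also tested at
1 df (the joint and pairwise views answer slightly different questions,
so both are reported).

Without measurement error the per-trait ML rate has the closed form
`sigma2_hat = r' C^{-1} r / n`; optimisation is performed on the
log-sigma^2 scale initialised at that value, which matters only when
measurement error makes the optimum non-analytic.  Standard errors come
from the observed information (central finite differences of the
log-likelihood on log-sigma^2, delta-method back-transform), and 95%
intervals are symmetric normal on the sigma^2 scale, truncated below at
zero for reporting.  On a star tree this SE reduces to the iid-normal
result `sigma2_hat * sqrt(2/n)`, which the tests verify.

## Evolutionary mode (OU shifts by reversible jump)

Shifts in the Ornstein-Uhlenbeck optimum `theta` are sampled by
reversible-jump MCMC.  The tip distribution under a multi-regime OU
process with attraction `alpha` and diffusion `sigma^2` is multivariate
normal with

    V_ij   = sigma^2/(2 alpha) exp(-alpha d_ij) (1 - exp(-2 alpha t_ij))
    E[y_i] = theta_base + sum_s (theta_s - theta_before(s))
                          (1 - exp(-alpha (T_i - t_s)))

summing over shifts on tip `i`'s root path.  The root state equals the
ancestral regime's optimum — the simplest identifiable treatment, since
a separate root parameter is weakly identified on ultrametric trees.
The same mean/covariance functions back both the sampler's likelihood
and the OU simulator, so simulation and inference are consistent by
construction (verified by round-trip likelihood tests).

Priors: the shift count is Poisson with mean 1, truncated at the number
of branches; at most one shift per branch with equal probability among
branches and uniform position along the branch; each optimum is normal
with mean equal to the trait mean and SD twice the trait SD; `alpha`
and `sigma^2` are half-Cauchy with scales `2/T` and `var(y)/T` for tree
depth `T`.  Proposed shift optima are drawn from their prior, which
reduces the birth/death acceptance ratios to `mu/(K+1)` and `K/mu`
times the likelihood ratio.  The move mixture is 0.2 birth / 0.2 death /
0.2 relocate / 0.4 parameter updates; random-walk step sizes adapt
toward a 0.3 acceptance rate during burn-in only, keeping the
post-burn-in kernel fixed.  A run with the likelihood disabled
reproduces the prior (uniform branch probabilities, truncated-Poisson
shift counts), which validates detailed balance of the jump moves.

Detectability.  A shift's posterior probability at a particular branch
must overcome prior odds of roughly `E[K]/B` (about 1/200 on a 101-tip
tree), plus the Occam factor from integrating the shift optimum over
its prior.  A deep shift of three stationary SDs typically yields a
maximum-likelihood advantage of only `exp(3)`–`exp(10)` over the best
no-shift OU fit — partly because a free `alpha` can absorb a clade-level
offset as drift — so such shifts sit near the detection threshold:
roughly half of replicate simulations produce `pp > 0.5` at the true
branch, and the rest concentrate their (smaller) posterior mass on the
correct branch without crossing the threshold.  This is a property of
the model and priors, not of the sampler: a deterministic oracle that
marginalises the optima analytically and integrates `alpha`, `sigma^2`
and the shift position by quadrature (truncated at one shift)
reproduces the sampler's per-branch probabilities, and a `max_shifts`
cap lets the sampler be compared to that oracle on an identical model
space.  Larger shifts, shallower shifts (whose tips retain more of the
displacement), or stronger attraction all raise the probability
sharply.

Likelihood evaluations are cached by factoring the covariance as
`sigma^2 W(alpha)`: only `alpha` updates refactorise; mean-only moves
cost one triangular solve; `sigma^2` updates are O(1).  Per-branch
posterior probabilities are the fraction of post-burn-in samples (both
chains pooled) in which the branch carries a shift; branches above 0.5
are reported as strongly supported with posterior-mean optima before
and after the shift.  Convergence is assessed with the Gelman-Rubin
statistic across replicate chains on `alpha`, `sigma^2`, the ancestral
optimum, and the log-likelihood.  Inference is warned against (not
refused) below 50 tips, where shift placement is known to be unstable.
Default run length is 200k generations; production-scale runs (millions
of generations, as used for empirical datasets) are a parameter.

## Synthetic data

The generators produce the structures the analysis assumes: pure-birth
(Yule) trees rescaled to unit depth (19–101 tips in the validation
suite, matching the range of real four-bar datasets); Brownian
log-link-length evolution with trait-specific rates, the fast link an
order of magnitude faster than the rest (`sigma^2` 0.1 vs 0.01 per unit
depth); optional per-species measurement error; and multi-regime OU
draws from the exact sampler likelihood.

The default linkage geometry (fixed 0.9, input 1.0, output 0.25,
coupler 0.5 — a high-transmission system whose output link is
several-fold shorter than the rest, as in raptorial and opercular
four-bars) was chosen so that (a) the 30-degree static posture remains
closable under Brownian spread, because the frame is near
`input * cos(30 deg)`, making the frame diagonal insensitive to drift,
and (b) KT responds smoothly and monotonically to the output link over
the simulated range, clear of dead-point geometries.  Datasets
containing any non-closable species are rejected and redrawn whole
(preserving the exact Brownian generative model among accepted
datasets), with the rejection count reported; the rejection rate under
the defaults is well below the 50% failure threshold.

What passing tests show — and do not.  The simulators match the
analysis models exactly, so the validation demonstrates correctness of
the implementations and calibration of the tests under their own
assumptions.  Real datasets differ in ways the generators do not
emulate: non-ultrametric calibrated trees, correlated evolution among
links, measurement protocols mixing static and dynamic KT, non-Brownian
tail behaviour, and body-size allometry beyond the fixed-link
correction.  Agreement on synthetic data therefore validates the
machinery, not the biological conclusions drawn from any particular
empirical dataset.

## Validation problem sizes

The test suite and the acceptance script use Monte-Carlo sizes chosen
as a compromise between statistical resolution and a desk-scale run:
four-bar oracle sweeps of 200–1000 random linkage/angle pairs at 1e-9
agreement; 100 datasets for the lambda grid cross-check; 200–500
replicates (n = 100–200 tips) for CI coverage, LRT calibration and
rate-recovery checks; and 60k–300k-generation MCMC runs (101 tips) for
the shift analyses, with ten replicate simulations for the
shift-recovery and false-positive rates.  Production analyses of
empirical data should use the full chain lengths (millions of
generations) the `ngen` parameter exposes.

## Known limitations

* Only planar four-bar mechanics are modelled; non-planar linkage
  systems require 3D treatment out of scope here.
* The crossed assembly branch is not solved; systems operating through
  a branch change (dead-point crossing) are not representable.
* Shifts are in `theta` only; `alpha` and `sigma^2` are global, and
  multi-trait joint OU models are not implemented.
* The rjMCMC explores positions within a branch uniformly; posterior
  position within a branch is weakly identified and is reported only
  through the branch-level probability.
* Pairwise rate tests are not corrected for multiplicity, matching
  standard practice in the comparative-rates literature.
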