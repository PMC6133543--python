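# linkage-evo

Four-bar linkage mechanics meets phylogenetic comparative methods:
`linkage_evo` measures how the geometry of biological four-bar linkages
(fish oral and opercular jaws, mantis-shrimp raptorial appendages)
shapes the **tempo** and **mode** of morphological evolution.

A four-bar linkage is a closed chain of four rigid links — fixed
(frame), input, output, and coupler — whose mechanical output is
summarised by kinematic transmission, `KT = |dθ_out/dθ_in|`: high KT
amplifies displacement, low KT amplifies force.  *Mechanical
sensitivity* is the disproportionate dependence of KT on particular
links.  The package asks, for a clade with measured link lengths on a
time-calibrated phylogeny:

1. **Which links drive KT?**  Phylogenetic generalized least squares
   (PGLS) of KT on each size-corrected, log-transformed link, with
   Pagel's λ estimated by maximum likelihood in the residual covariance
   `σ²C(λ)`.
2. **Do those links evolve faster?**  Per-link Brownian-motion rates
   σ² (variance of proportional change per unit time) with 95% CIs from
   the inverse Hessian, compared by likelihood-ratio tests between an
   equal-rate and a free-rate model (joint and all pairwise).
3. **Where do trait optima shift?**  Reversible-jump MCMC over
   multi-optimum Ornstein–Uhlenbeck models
   `dy = α(θ − y)dt + σ dW`, sampling the number, locations and
   magnitudes of shifts in θ across branches, with per-branch posterior
   shift probabilities (pp > 0.5 = strong support) and Gelman–Rubin
   convergence checks.

A four-bar solver computes KT from link lengths under the field's
measurement protocols (static KT at a 30° input posture; minimum KT
over the full rotation; windowed minimum/mean), and a synthetic-data
module generates Yule trees, multi-rate Brownian link evolution with
geometry-derived KT, and multi-regime OU data for end-to-end
validation.  See `docs/methods.md` for models, conventions, priors,
and known limitations.

## Worked example

Simulate a 101-species clade whose output link evolves an order of
magnitude faster than the other links, with KT computed from the
simulated geometry by the four-bar solver, then run the sensitivity and
tempo analyses:

```python
from linkage_evo import (simulate_tree, sensitivity_scan, rank_links,
                         compare_rates)
from linkage_evo.simulate import simulate_linkage_dataset

tree = simulate_tree(101, seed=1)
table, meta = simulate_linkage_dataset(tree, seed=2)

fits = sensitivity_scan(table, tree)           # one PGLS per mobile link
res = compare_rates(table.log_transformed(["input", "output", "coupler"]),
                    tree, columns=["input", "output", "coupler"])
```

Formatting the fits and rate comparison prints:

```
    link   slope     SE       t         p     r2 lambda
   input   0.094  0.279    0.34  7.37e-01  0.001  1.000
  output  -0.922  0.034  -26.98  1.97e-47  0.880  0.995
 coupler  -0.113  0.286   -0.40  6.93e-01  0.002  1.000
most sensitive link: output
sigma2[input]   = 0.0091  (95% CI 0.0066-0.0116)
sigma2[output]  = 0.1263  (95% CI 0.0915-0.1612)
sigma2[coupler] = 0.0098  (95% CI 0.0071-0.0124)
equal-vs-free LRT = 233.74 (df=2), p = 1.75e-51
```

Reading it: log KT falls 0.92% per 1% increase in the relative output
link (r² = 0.88) while the other links carry no signal — the system is
mechanically sensitive to its shortest link — and that same link's
evolutionary rate is ~13× the others, a difference the likelihood-ratio
test finds overwhelming.  Fast evolution concentrates in the link that
controls the mechanics.

Shift detection on one trait (here on the log KT column, warning below
50 tips, as inference is unstable on small trees):

```python
import numpy as np
from linkage_evo import rjmcmc_shifts, summarize_shifts
y = np.log(table.values(["kt"]).ravel())
post = rjmcmc_shifts(y, tree, n_generations=200_000, chains=2, seed=3)
print(summarize_shifts(post, pp_threshold=0.5))   # branch, pp, θ before/after
print(post.gelman_r)                              # R ≈ 1 on converged runs
```

## Command line

Each stage is also a subcommand (thin wrappers over the functions
above): `linkage-evo simulate | kt | sensitivity | rates | shifts |
validate | run`, where `run --config run.yaml` executes the whole
pipeline (KT → sensitivity → rates → optional shifts) into a run
directory with `kt.csv`, `sensitivity.csv`, `rates.json`, `shifts/`,
and a `run.log` that records the seed and config hash.  Rerunning the
same config and seed reproduces the outputs byte for byte.

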