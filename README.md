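# ssdopt

Surrogate-assisted global optimisation for **simulation-based clinical-trial
sample size determination**.

Trials with multilevel structure — cluster randomisation, therapists nested
in one arm, doctors shared across arms, multiple correlated endpoints —
rarely admit closed-form power formulas, so their operating characteristics
(power, type I error rate) must be estimated by Monte Carlo.  At the same
time there is usually more than one quantity worth minimising (total
participants, number of clusters, number of care providers), so "the"
optimal design is really a Pareto set of trade-offs.  Plain multi-objective
search is hopeless when every candidate evaluation costs thousands of
simulated trials; `ssdopt` makes it practical for statisticians designing
such trials.

## Method

A design is a point x in a bounded box X (integer dimensions allowed).  The
problem is

    min  f_1(x), ..., f_B(x)        (cheap, deterministic objectives)
    s.t. g_j(x) = OC_j(x) - c_j <= 0   j = 1..C

where each operating characteristic OC_j is estimated by N Monte Carlo
replicates of a user-written trial simulator, giving an unbiased estimate
with standard error omega = sqrt(p(1-p)/N).  The solver is efficient global
optimisation (EGO):

1. Evaluate a Sobol space-filling initial design.
2. Fit one Gaussian-process regression per constraint (squared-exponential
   kernel, the known MC variances as a fixed heteroscedastic noise
   diagonal, hyperparameters by multi-start marginal-likelihood
   maximisation).
3. A design is *deemed feasible* when the upper p-quantile of each
   constraint's predictive distribution, q = m + Phi^-1(p) s, is <= 0.
   Candidates are scored by expected improvement: their dominated-
   hypervolume gain over the current approximation set times the
   probability Phi(-m+/s+) of being deemed feasible after the planned
   evaluation, per constraint.
4. Maximise this acquisition by particle swarm, round integer dimensions,
   evaluate, and repeat until the budget of (E + iterations) x N x C
   simulations is spent.

The result is an approximation set: mutually nondominated, currently-deemed-
feasible designs, scored by the exact dominated hypervolume against a
reference point.  A fixed space-filling comparator (one Sobol batch,
confidence-interval filter, nondominated survivors) is included, as are two
built-in problems: an analytic two-arm cluster RCT whose closed-form
noncentral-t power yields the true Pareto set, and a two-endpoint
multilevel pilot trial (partially nested therapists, crossed doctors,
correlated endpoints, one-sided likelihood-ratio tests from in-package ML
mixed-model fits).

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Design a cluster randomised trial: k clusters and n participants per arm
(k in [10, 100], n in [100, 500]), minimise total participants 2n and total
clusters 2k, subject to type II error at most 0.1 for a standardised effect
of 0.3 at one-sided alpha 0.025 (within/between variances 0.95/0.05).

```python
import numpy as np
from ssdopt import (EGOConfig, run_ego, extract_approximation_set,
                    approximation_set_table, dominated_hypervolume)
from ssdopt.problems import ClusterTrialParams, make_cluster_problem

problem, sim = make_cluster_problem(ClusterTrialParams())
config = EGOConfig(iterations=30, initial_design_size=20, n_per_eval=100,
                   root_seed=1)
state = run_ego(problem, sim, config)
aset = extract_approximation_set(state)
print(approximation_set_table(state, aset).to_string(index=False))
print("hypervolume:", dominated_hypervolume(aset, problem.reference_point()))
print("simulations:", state.total_simulations)
```

Output:

```
   k     n  total_participants  total_clusters  type2_error_estimate  type2_error_se  type2_error_n
59.0 295.0               590.0           118.0                  0.06        0.023749            100
58.0 297.0               594.0           116.0                  0.09        0.020236            200
53.0 304.0               608.0           106.0                  0.06        0.023749            100
51.0 310.0               620.0           102.0                  0.10        0.030000            100
45.0 315.0               630.0            90.0                  0.12        0.032496            100
41.0 335.0               670.0            82.0                  0.13        0.033630            100
38.0 354.0               708.0            76.0                  0.09        0.028618            100
37.0 356.0               712.0            74.0                  0.10        0.030000            100
35.0 380.0               760.0            70.0                  0.08        0.027129            100
33.0 400.0               800.0            66.0                  0.11        0.031289            100
32.0 429.0               858.0            64.0                  0.07        0.025515            100
31.0 432.0               864.0            62.0                  0.08        0.027129            100
hypervolume: 75596.00000000001
simulations: 5000
```

Each row is one nondominated design the optimiser currently deems
adequately powered, with its pooled Monte Carlo estimate of the type II
error (the 58-cluster design was proposed twice, so its 2 x 100 replicates
pooled).  Reading down the table: spending more clusters buys a smaller
trial — from 864 participants in 62 clusters to 590 in 118.  The
hypervolume (against the default reference point (1100, 220)) summarises
the whole set; the exhaustive-search true Pareto front of this analytic
problem scores 88288, so 50 evaluations of 100 replicates recover about
86% of the attainable hypervolume, using 5000 simulated trials in total.

## Command line

```sh
ssd-opt run --config config.yaml        # full optimisation run
ssd-opt resume --config config.yaml --checkpoint out/checkpoint.json -k 20
ssd-opt fixed --config config.yaml --points 50
ssd-opt benchmark --config config.yaml --repeats 20 --fixed-sizes 50,200
ssd-opt report --config config.yaml --checkpoint out/checkpoint.json
```

A minimal config:

```yaml
problem:
  name: cluster          # or "pace" (two-endpoint multilevel trial)
  params: {effect: 0.3}
ego:
  iterations: 30
  initial_design_size: 20
  n_per_eval: 100
  quantile_level: 0.9
  seed: 1
output_dir: out
```

Runs write an evaluation-log CSV, the approximation-set CSV, surrogate
diagnostics JSON and a checkpoint; every report is recomputable from the
evaluation log.  Unknown config keys are rejected.  Custom problems are
built in Python by implementing the simulator contract
(`simulate_once(x, hypothesis, rng) -> 0 or 1`) and a `ProblemSpec`; a
factory returning the pair can be named in the config instead of a
built-in problem (`problem: {module: "my_trial:make_problem"}`).

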