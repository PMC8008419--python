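# Methods

## The problem

Choosing the sample size of a clinical trial with several design
parameters — numbers of participants, clusters, therapists, doctors, an
allocation ratio, a nominal test level — is a constrained multi-objective
optimisation problem: minimise several conflicting cost-like criteria
subject to constraints on operating characteristics (power, type I error
rate).  When the analysis is complex the operating characteristics have no
closed form and must be estimated by Monte Carlo simulation, which makes
each candidate design expensive to evaluate.  `ssdopt` solves such
problems with surrogate-assisted efficient global optimisation (EGO):
Gaussian-process regression models of the simulated operating
characteristics guide the choice of which design to simulate next.

## Monte Carlo error model

A user-supplied simulator returns a binary reject indicator per replicate.
The mean of N independent indicators is an unbiased estimate of the
operating characteristic p, treated for modelling purposes as the truth
plus Gaussian noise with variance omega^2 = p(1-p)/N.  Before computing
omega the estimate is clipped to [0.5/N, 1-0.5/N]: an estimate of exactly
0 or 1 at finite N does not mean certainty, and a zero noise entry would
corrupt the GP fit.  Every evaluation draws from an independent substream
keyed by (root seed, evaluation index, constraint index), so an
interrupted run can be resumed and reproduces the evaluations the
uninterrupted run would have made.

## Gaussian-process surrogates

One GP per constraint models its operating characteristic over the design
box, with the squared-exponential kernel

    k(x, x') = sigma * exp(-sum_j (x_j - x'_j)^2 / lambda_j^2)

on inputs affinely mapped to the unit box (design parameters differ in
scale by orders of magnitude; length-scales are then comparable across
dimensions).  Observation noise is the fixed diagonal of MC variances —
it is known from the error model, not an estimated nugget.  Targets are
centred by their empirical mean (stored and added back at prediction
time); the zero-mean formulas apply to the residuals.  This constant-mean
treatment matters because raw operating characteristics live near their
thresholds, far from zero.

Hyperparameters (sigma, lambda_1..lambda_D) maximise the log marginal
likelihood over log sigma in [log 1e-6, 0] and log lambda_j in
[log 0.01, log 10] (unit-box scale), from 10 quasi-random starts plus a
data-driven heuristic start; the best local optimum wins.  If every start
fails, median-heuristic length-scales are used with a logged warning.
Factorisations add jitter 1e-8 (growing tenfold to at most 1e-4) when a
covariance matrix is numerically indefinite.

## Feasibility and acquisition

A design is *deemed feasible* when, for every constraint j, the upper
100p% quantile of the GP predictive distribution of g_j = OC_j - threshold_j
is at or below zero: q = m + Phi^-1(p) s <= 0.  The quantile level
defaults to p = 0.9 — conservative enough that designs are only declared
feasible with reasonable evidence, not so extreme that noisy early
estimates lock the feasible region — and is configurable and logged.
p = 0.5 is accepted as the non-conservative edge (q collapses to the
mean).

Before evaluating a candidate with planned MC error omega, the
post-evaluation quantile is itself normal:

    m+ = m + Phi^-1(p) sqrt(omega^2 s^2 / (omega^2 + s^2))
    s+^2 = s^4 / (omega^2 + s^2)

This is the one-step noisy-Kriging update; it satisfies both sanity
limits (omega -> 0 gives (m, s); omega -> infinity gives (q, 0)), which
ship as tests at 1e-10.  The planned omega uses the GP predictive mean of
the operating characteristic clipped to [0.001, 0.999].

The acquisition value of a candidate is its hypervolume improvement over
the current approximation set multiplied by the product over constraints
of Phi(-m+/s+), the probability of being deemed feasible after the
evaluation.  Note the feasibility-confirmation probability is *not*
monotone in the planned sample size when the current quantile is already
feasible: an uninformative evaluation freezes a feasible quantile, so the
probability starts at 1 and decreases toward Phi(-m/s).  Monotonicity
holds in the regime that matters for search — mean feasible, quantile not
yet (m < 0 < q).

The acquisition is maximised by particle swarm over the continuous box
(swarm 40, 200 iterations, constriction coefficients w = 0.7298,
c1 = c2 = 1.49618, clamp-and-reflect bounds; all configurable).  If the
entire swarm history has zero acquisition — nothing can improve the front
— the point with the highest feasibility product is returned as an
exploration fallback and logged.

## Pareto tools

All objectives are minimised; dominance is the usual componentwise
relation.  Dominated hypervolume is computed exactly: in 2-D by the
sorted staircase sum, in 3-D by sweeping slices of the third objective
(each slice a 2-D staircase); four or more objectives are unsupported.
Members at or beyond the reference point contribute zero with a logged
warning.  Objective-space duplicates collapse to the first-evaluated
design, and a candidate equal to a member in every objective counts as
dominated, keeping sets minimal.  The default reference point is the
per-objective worst box-corner value scaled by 1.1; its exact position is
immaterial as long as it is worse than anything the search can return,
but it is fixed per problem so hypervolumes are comparable across methods
and repeats.  The inner PSO loop uses a vectorised lower-envelope form of
the 2-D hypervolume improvement that is tested against the
union-minus-base definition.

## The loop

The initial design is a Sobol sequence scaled to the box (E = 10 points
per dimension by default, capped so the initial phase uses at most half
the evaluation budget; collisions after integer rounding are replaced by
subsequent sequence elements).  Each loop iteration refits the GPs to all
data, maximises the acquisition, rounds integer dimensions half-up, and
evaluates the proposal with N replicates per constraint.  A proposal that
rounds onto an already-evaluated design pools its replicates with the
earlier ones — successes and sample sizes add, the noise entry shrinks —
so no budget is wasted.  Total simulator calls are exactly
(E + iterations) x N x #constraints.  The loop terminates on its
iteration count alone; a checkpoint written after every evaluation
(evaluation log, iteration counter, GP state) makes a run resumable
bit-for-bit, because all randomness is keyed by evaluation/iteration
indices rather than a mutable generator state.

Surrogate health is monitored by standardised prediction errors
z = (observed - m) / sqrt(s^2 + omega^2) at each proposed point; |z| > 3
flags a surprising evaluation.

The fixed space-filling comparator evaluates a single Sobol batch,
discards every design whose MC confidence interval (95% two-sided by
default) is not entirely below each nominal threshold, and returns the
nondominated survivors.

## Built-in problems

**Cluster RCT (analytic truth).**  Two-arm cluster randomised trial,
outcome y_ij = b0 + b1 t_i + u_j + e_i with u_j ~ N(0, sigma_B^2),
e_i ~ N(0, sigma_W^2); analysis is a one-sided two-sample t-test on the k
cluster means per arm.  Defaults: sigma_W^2 = 0.95, sigma_B^2 = 0.05
(unit total variance, ICC 0.05), alpha = 0.025 one-sided, nominal type II
error 0.1, design box k in [10, 100], n in [100, 500] per arm, objectives
(2n, 2k).  Because the test depends on the data only through cluster
means, power is a noncentral-t tail probability (df 2k-2, noncentrality
delta / sqrt(2 (sigma_B^2 + sigma_W^2/m) / k), m = n/k), giving a truth
oracle and, by exhaustive integer search, the true Pareto set.  The
standardised effect defaults to delta = 0.3, a conventional
small-to-moderate effect on this unit-variance scale; it is configurable
everywhere.  The simulator draws cluster means directly from their exact
aggregated distribution N(mu_arm, sigma_B^2 + sigma_W^2/m_j) with
balanced integer cluster sizes — identical in law to drawing every
individual outcome, and fast enough for 1e4-replicate calibration.

**Two-endpoint multilevel trial.**  Pilot trial with two correlated
continuous endpoints, therapists partially nested in the intervention arm
(k groups, random effect switched on by treatment), doctors crossed over
both arms (j groups), and patients cross-classified.  Bivariate normal
therapist effects, doctor effects and residuals carry the cross-endpoint
correlations (defaults all 0.9) with marginal variances 0.19 / 0.37 /
3.29, giving a control-arm doctor VPC of 0.1 and a therapist VPC of 0.05.
The treatment effect defaults to 1.10 on both endpoints (standardised
0.56 against the intervention-arm SD).  Intervention patients are
allocated round-robin to therapists and, independently, to doctors;
control patients round-robin to doctors; n0 = round(r n1) half-up.
Cluster sizes are therefore as balanced as possible, the efficient choice
when allocation is controllable.

Each endpoint is analysed with its own univariate Gaussian mixed model —
deliberately ignoring the cross-endpoint correlation, as the separate-
models analysis it emulates would — fitted by maximum likelihood (ML, not
REML: the likelihood ratio test needs comparable maximised likelihoods).
The marginal covariance V = sigma_T^2 Z_T Z_T' + sigma_D^2 Z_D Z_D' +
sigma_W^2 I is assembled from explicit therapist/doctor index columns.
Fixed effects and sigma_W^2 are profiled out by GLS; the profile
likelihood over (log phi_T, log phi_D) (variance ratios, bounds
[-12, 4]) is maximised by L-BFGS-B with an analytic envelope-theorem
gradient from three starts.  All W-weighted quantities reduce through the
Woodbury identity to a (k + j)-dimensional capacitance matrix, so a fit
costs O(n (k+j)^2) rather than O(n^3).  The one-sided p-value is
1 - Phi(sign(b1_hat) sqrt(2 (l1 - l0))) via the chi^2_1/normal
equivalence; a replicate whose fits fail is recorded as a non-rejection
(conservative) with a logged flag.  The trial is positive when either
endpoint is significant at the design's nominal level a (a "both" rule is
available as a configuration switch), inflating the familywise type I
error toward 1 - (1-a)^2 under independence and down to a under perfect
correlation — which is why a is itself a design parameter, constrained at
0.2, alongside power at 90% under effects of 1.10 on both endpoints.

## What the generators do and do not emulate

The built-in simulators generate exactly the Gaussian hierarchical
structures above: known nuisance parameters, balanced allocation, no
missingness, no dropout, no non-normality, and working models that are
correctly specified apart from the deliberate neglect of cross-endpoint
correlation.  Passing tests therefore demonstrate that the optimiser,
surrogates and fitters behave correctly under these conditions; they say
nothing about robustness to model misspecification beyond that one
mechanism, which is the user's responsibility when writing a simulator
for a real trial.

## Numerical choices and problem sizes

Tests and the acceptance script keep the default run practical on one
core by scaling repeat counts, not tolerances: the optimiser-vs-comparator
comparison uses 20 seeds at the full evaluation budget (20 initial + 30
iterations, N = 100) in the test suite and 10 in the reporting script;
hypervolume oracle checks use 1e6 rejection samples per set; cluster
calibration uses 1e4 replicates; multilevel familywise calibration uses
2000 (independent-endpoint check) and 1000 (correlation band) replicates
at a reduced design (n1 = n0 = 40, k = 4, j = 5).  Mixed-model recovery
uses n1 = n0 = 800, k = 40, j = 30 with 150 replicates: ML variance
components carry a known O(1/#groups) downward bias (about -18% for
sigma_T^2 at k = 10, within a 15% band by k = 40), so consistency is
checked where the asymptotics apply, while exactness of the likelihood
itself is checked against a dense multivariate-normal density at 1e-8.

## Known limitations

- Hypervolume (and therefore the acquisition) supports 2 or 3 objectives
  only.
- Objectives must be cheap and deterministic; only constraints may be
  simulation-estimated.
- One evaluation per iteration (no batch acquisition, no look-ahead).
- The GP kernel is fixed squared-exponential; no monotonicity or
  boundedness priors, although power surfaces are often monotone.
- Constraint modelling assumes the binomial error model; variance
  reduction schemes (common random numbers, antithetics) are out of scope.
- ML variance components are biased low with few clusters; this affects
  interpretation of fitted components, not the LRT-based decisions the
  operating characteristics are built from.
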