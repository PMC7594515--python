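# Methods

## Model

`pminr` tests whether a biological network — a known topology of p nodes
(genes, proteins, methylation levels) and a set of undirected edges — is
associated with a binary case-control outcome, and which of its nodes and
edges carry that association, while adjusting for covariates.

The per-individual connection strength of an edge (i, j) is measured by
pointwise mutual information,

    PMI(x, y) = log p(x, y) − log p(x) − log p(y),

evaluated at the individual's own pair of node values. PMI is zero
everywhere exactly when the two variables are independent and deviates from
zero under linear *or* nonlinear dependence, which is what lets the method
detect edge effects that a correlation-based feature misses. The joint
density is estimated by bivariate kernel density estimation with a normal
kernel,

    f̂_H(z) = (1/n) Σ_i (2π)^−1 |H|^−1/2 exp(−½ (z − Z_i)ᵀ H^−1 (z − Z_i)),

and the marginals by the univariate analogue. The resulting per-individual
edge features E_ij enter a logistic network regression,

    logit P(Y = 1) = β₀ + Σ_s α_s Z_s + Σ_i β_i x_i + Σ_{i<j} I_ij γ_ij E_ij,

where I_ij restricts edge terms to pairs actually connected in the topology.
Per-term Wald tests (z = estimate/SE against the standard normal) identify
contributing nodes and edges; a likelihood-ratio test of the full model
against the intercept+covariates model, on p + |edges| degrees of freedom,
tests the network as a whole. The comparator PMNR replaces E_ij with the
standardized cross-product (x_il − x̄_i)(x_jl − x̄_j)/(s_i s_j), the
per-individual summand of the Pearson correlation, and is exact for linear
dependence but blind to nonlinear dependence that leaves the correlation
near zero (e.g. x_j = x_i² + ε).

## Density estimation choices

* **Bandwidths.** Diagonal Scott-rule matrices: H_kk = (sd_k · n^(−1/6))²
  for the joint, h = sd · n^(−1/5) for marginals. Scale-equivariant, smooth,
  and standard; both are plug-in defaults, not optimized per dataset. A
  degenerate (zero-variance) node is a hard error naming the node.
* **Evaluation paths.** The reference path sums kernels exactly at every
  data point (O(n²) per edge). The default fast path evaluates the joint on
  an 80×80 grid spanning the data range ± 3 bandwidths — the diagonal
  bandwidth factorizes the grid evaluation into two (grid × n) kernel
  matrices and a matrix product — and interpolates with a bicubic spline at
  the data points; marginals use a 400-point grid and a cubic spline. The
  two paths agree to ~2×10⁻⁴ on the PMI scale (tested bound 10⁻³).
* **Floor.** Densities are floored at 10⁻¹² before logs so deep-tail points
  give large negative but finite PMI; floor hits are counted and logged.
* **Pooling.** Densities are estimated from all N individuals pooled across
  outcome groups, since one E_ij per individual enters a single regression.
* **Known bias.** KDE smoothing biases PMI toward zero; at the origin of a
  ρ = 0.6 bivariate normal with N = 2000 the bias is ≈ −0.07 against the
  closed form −½·log(1 − ρ²) ≈ 0.223. The bias shrinks with N (tested as
  decreasing MSE from N = 500 to N = 2000) and affects power, not validity:
  under the null PMI features are exchangeable noise and Wald type-I error
  stays nominal.

## Fitting and inference

The logistic model is fitted by iteratively reweighted least squares with
convergence when max |score| < 10⁻⁸ or the relative log-likelihood change
drops below 10⁻¹⁰, capped at 100 iterations; the coefficient covariance is
the inverse observed information (equal to expected information for the
logistic link). Collinear designs raise an error naming the dependent
terms (QR diagnostic). Complete or quasi-separation — non-convergence or any
standardized-scale coefficient beyond 15 — flags the fit and its p-values
rather than silently penalizing; an optional ridge (e.g. 10⁻⁴) is available
to stabilize such fits while keeping plain MLE the default. Edge features
enter raw by default (a standardization switch exists). Raw p-values are the
primary output; a Bonferroni column over the p + |edges| network terms is
optional, since the node and edge tests are highly correlated and Bonferroni
is conservative here.

## Simulation design

The generator emulates a case-control co-expression study on the packaged
26-node / 37-edge pathway topology (a connected stand-in with generic labels;
conclusions are averaged over random effect placement precisely so that the
particular wiring does not drive them):

* **Covariance.** Unit variances; each edge's correlation drawn uniformly
  from {0.10, 0.15, …, 0.55}; the matrix is redrawn until its smallest
  eigenvalue is positive (per replicate by default; a fixed-covariance mode
  draws once per configuration).
* **Scenarios.** `linear` draws N_p(0, Σ). The nonlinear scenarios then
  overwrite the designated edge's second node: x_j = α·g(x_i) + ε with
  ε ~ N(0, 1) and g = square (`quadratic`), sine (`sine`) or squared sine
  (`sine_squared`). The nonlinear strength defaults to α = 1, giving
  detectable but non-saturating dependence at the sample sizes studied.
* **Response.** Zero-intercept logistic generator
  logit P(Y=1) = Σ β_i x_i + Σ γ_ij e_ij with generator-side edge term
  e_ij = x_i·x_j (linear) or α·g(x_i)·x_j (nonlinear scenarios), so cases
  and controls are balanced in expectation under the null. Effect sizes
  default to β = 0.3 and γ = 0.2 (linear/quadratic) or γ = 0.6 (sine-type).
* **Situations.** Per replicate the effect targets are redrawn at random:
  one node, one edge, or a node-edge pair with the node either an endpoint
  of the edge ("hanging on" it) or disjoint from it; under the null nothing
  carries an effect and a randomly chosen no-effect node and edge are the
  tested targets, so the recorded rejection rate is a type-I error. A
  fixed-target mode pins the targets instead.
* **Harness.** Each replicate draws Σ, targets, X and Y, fits both PMINR and
  PMNR, and records whether the tested node's Wald p, the tested edge's Wald
  p, and the global LRT p fall below 0.05. Per-replicate RNG streams are
  spawned from the master seed (reproducible and order-independent). Failed
  replicates are excluded and tallied, with a warning above 5%. Rejection
  proportions are reported with binomial Monte-Carlo SE √(p̂(1−p̂)/R).

### What the generator does and does not emulate

It reproduces the correlation-structured Gaussian node model, balanced
outcomes, and sparse single-target effects typical of pathway analyses. It
does not emulate heavy-tailed or count-valued expression, measurement batch
effects, covariate confounding (no Z in simulation), mis-specified
topologies, or more than one effecting node/edge at a time — so passing
operating characteristics here demonstrate calibration and relative power
under the stated model, not performance on any particular real assay.

### Problem sizes

Default test-suite runs use reduced replicate counts chosen to keep
Monte-Carlo error small relative to the effects being asserted: R = 200 at
n = 500 for the null calibration check, R = 300 at n = 600 for the power
orderings, R = 200 per sample size for the power-vs-n monotonicity. The
acceptance script runs the null study at R = 500, n = 1000. Orderings are
asserted with 2·SE margins rather than absolute power values.

## Numerical notes and degenerate inputs

* LRT statistics are clamped at zero (they are nonnegative in exact
  arithmetic for nested MLEs).
* Wald p-values for zero-SE terms are NaN rather than invented.
* An empty edge set is legal everywhere: the design reduces to
  intercept + covariates + nodes and the edge-feature matrix has zero
  columns; an edgeless topology yields the identity covariance in
  simulation.
* Grid interpolation never extrapolates: the grid covers the data range
  ± 3 bandwidths and is only queried at data points.
* All stochastic routines take explicit seeds or `numpy` Generators;
  identical seeds reproduce outputs byte-identically (tested).

## Limitations

* The plug-in use of estimated PMI features ignores their estimation
  uncertainty; at small n this biases coefficients and costs power, and the
  global LRT can run anti-conservative at n near the parameter count.
* Only binary outcomes are supported; extensions to other GLM families are
  out of scope.
* Multiple-testing control beyond the optional Bonferroni column is left to
  the user; the node and edge tests are mutually correlated.
* Edge effects estimated from the regression are associational; mediation
  within the network is not modeled.
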