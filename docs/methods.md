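# Methods

## Model

`stickdpm` fits the full stick-breaking Dirichlet process mixture model
(DPMM) for *profile regression*: subjects carry a profile of J locally
independent categorical covariates X_i (K_j categories each), an optional
binary response Y_i, and optional real fixed effects W_i that act on the
response globally rather than per cluster.  The likelihood of subject i in
cluster c is

    f(D_i | Θ_c, β) = [ ∏_j φ_{c,j,X_ij} ] · Bernoulli(Y_i; expit(θ_c + βᵀW_i)),

with cluster parameters Θ_c = (Φ_c, θ_c).  Cluster weights follow the
stick-breaking construction ψ_c = V_c ∏_{l<c}(1 − V_l), V_c ~ Beta(1, α);
the model is sampled *without* integrating out the weights, so the
concentration parameter α has the conjugate conditional
Gamma(shape + C, rate − Σ_c log(1 − V_c)) over the represented sticks.

Priors: Φ_{c,j} ~ Dirichlet(a_j) with a_j = (1,…,1) by default;
θ_c, β_l ~ t₇(0, 2.5) — heavy-tailed enough to let cluster response rates
approach 0 or 1; α either fixed or Gamma(shape, rate).  All defaults are
exposed on `PriorSpec`.

A key property of the stick-breaking prior is its weak ordering of the
weights: E[ψ_c] > E[ψ_{c+1}] and P(ψ_c > ψ_{c+1}) > 1/2 for every c
(`mc_order_probability` estimates the latter).  The likelihood, by
contrast, is label-invariant.  A sampler that never revisits label
orderings therefore under-explores the prior's ordering dimension, which
matters whenever α is inferred: α couples to the weights through every
stick, so frozen orderings distort its posterior.

## Sampling engine

Each sweep is a fixed sequence of blocked updates:

1. **Slice variables and allocations** (Walker-type): u_i ~ U(0, ψ_{Z_i});
   new components (stick from Beta(1, α), parameters from the priors) are
   appended until the undistributed mass ∏(1 − V) falls below min_i u_i;
   each Z_i is then redrawn from P(Z_i = c) ∝ 1{ψ_c > u_i} f(D_i | Θ_c, β)
   by Gumbel-max over the represented components, and the representation
   is trimmed to max_i Z_i + 1 components.  Components beyond the highest
   occupied label are exchangeable prior draws, so dropping them is exact
   marginalisation.
2. **Sticks**: V_c ~ Beta(1 + n_c, α + Σ_{l>c} n_l); slice variables are
   refreshed so u_i < ψ_{Z_i} always holds.
3. **Φ**: conjugate Dirichlet updates (batched gamma draws when all K_j
   are equal); empty represented clusters are refreshed from the prior so
   they remain viable split targets.
4. **θ, β**: random-walk Metropolis (β as one block).  Proposal scales
   adapt by Robbins–Monro toward acceptance 0.44 (scalars) and 0.23 (the
   β block) during burn-in only, so the kept sample targets the exact
   posterior.
5. **α**: the Gamma conditional above (no-op when fixed).
6. **Label-switching moves 1–3**, each attempted once per sweep.

All randomness flows through a single seeded `numpy` Generator in fixed
order; identical configurations give bit-identical chains.

The exact blocking of published slice-sampler implementations is not
specified in enough detail to clone, so this engine is validated
behaviourally instead: on a six-subject covariate-only fixture the sampled
partition distribution is compared with the exactly enumerated posterior
over all 203 set partitions (total variation < 0.05 at 5·10⁴ sweeps), a
test that exercises every Gibbs block jointly; prior-reproduction runs
(no data) check the α and stick conditionals against their marginals.

## Label-switching moves

Move 1 exchanges the allocations and parameters of two labels drawn from
{1..Z\*} (Z\* = highest occupied label), leaving the weights in place.
Move 2 exchanges two neighbouring labels *and* their sticks V_c, V_{c+1},
which preserves all downstream weights.  Move 3 exchanges neighbouring
labels and simultaneously proposes new weights for the pair, sized by the
conditional stick-posterior means under the proposed allocations and
rescaled so ψ_c + ψ_{c+1} is conserved; the pair's sticks are back-solved
from the new weights.  Its closed-form acceptance ratio
R = (ψ⁺/(ψ_{c+1}R₁ + ψ_c R₂))^{n_c+n_{c+1}} R₁^{n_{c+1}} R₂^{n_c} is
implemented in log space (`move3_acceptance_ratio`) and cross-checked in
the tests against an oracle that builds ψ′ from the expected-weight
definition directly.

Three exactness refinements were required by this engine's trimmed
representation, each diagnosed by one-step stationarity tests from exact
prior draws and by prior-only chain enumeration:

- **Boundary auto-rejection (moves 1 and 3).**  A proposal that empties
  the top occupied label lowers Z\* and shrinks the represented stick
  set; the reverse proposal can then never be generated, so accepting
  such swaps creates a one-way flow that deflates the posterior number
  of clusters.  These proposals are rejected outright.
- **One-beyond pairing with a Hastings factor (move 2).**  Move 2's pool
  is {1..Z\*}, with the pair (Z\*, Z\*+1) materialising a fresh stick
  from Beta(1, α); the materialised stick's prior density cancels against
  the proposal, and the pool-size asymmetry contributes a factor
  Z\*/Z\*′ to the acceptance ratio.  The move also runs at Z\* = 1 —
  that case is the reverse of swaps that empty label 2, and skipping it
  unbalances the kernel.  This keeps the always-accept behaviour for
  swaps into an empty lower slot, which drives the early re-ordering of
  clusters.
- **Change-of-variables factor (move 3).**  The weight-matched proposal
  is a deterministic map of (V_c, V_{c+1}); exact detailed balance for a
  deterministic proposal multiplies the density ratio by the map's
  Jacobian, |J| = R₁R₂ (ψ⁺/Ψ′)² (P − ψ_c)/(P − ψ′_c) with P the stick
  mass remaining before the pair.  The sampler's acceptance uses R·|J|;
  measured Jacobians range over roughly 0.2–0.95, and omitting the factor
  inflates the posterior cluster count measurably on enumerable fixtures.
  The public `move3_acceptance_ratio` keeps the plain R, which equals the
  allocation-density ratio exactly.

Moves 1–2 compute their ratios by differencing the joint log density
rather than closed forms; terms that are invariant under any swap
(component-parameter priors, the data likelihood — the parameter multiset
travels with the labels) can be dropped from the difference via
`joint_log_density(..., include_invariant=False)`.  The closed forms are
asserted as cross-checks in the tests, never used as the implementation.

## Marginal partition posterior

`log_marginal_partition_posterior` scores an allocation vector by
p(Z | D) at fixed α (unnormalised over partitions): the DP partition
prior (EPPF) K log α + Σ_c lgamma(n_c) + lgamma(α) − lgamma(α + n), plus
per-cluster Dirichlet-multinomial covariate marginals in closed form,
plus the response block integrated over all cluster intercepts and β
jointly by Laplace approximation.  α is conditioned on (default 1,
configurable) rather than integrated; choose the conditioning value from
exploratory runs with α free.

The Laplace mode is found by damped Newton with step halving; the t₇
prior is not log-concave in its tails, so non-ascent Newton directions
fall back to gradient ascent.  The Gaussian approximation is sharpened
by the standard fourth-order O(1/n) correction assembled from the
analytic third/fourth derivatives of the logistic likelihood and t
prior (contractions F/8 + B/8 + A/12 through Σ = (−H)⁻¹).  Against
independent quadrature the corrected value is accurate to ~1e-5 (one
cluster, n = 50) and ~6e-4 (two clusters plus a fixed effect); the
plain second-order value (`order=2`) errs at the few-times-1e-3 level.
The Laplace is joint over (θ₁..θ_K, β) because β couples clusters; with
no fixed effects the problem factorises per cluster automatically.

`compare_runs` summarises per-run traces of log p(Z | D) and flags a run
whose upper quartile sits below another run's lower quartile — the
signature of a chain stuck in a lower-posterior region, typically caused
by initialising with too few clusters.  Pairwise mean differences carry
batch-means standard errors (20 batches) to acknowledge autocorrelation.

## Post-processing

The posterior similarity matrix S_ij (fraction of kept sweeps with
Z_i = Z_j) is label-invariant by construction.  The representative
partition maximises the Binder-type score Σ_{i<j, co-clustered}
(S_ij − 1/2) over k-medoids candidates on dissimilarity 1 − S for
k = 1..k_max (default: largest observed cluster count + 2, allowing
out-of-sample optima).  The k-medoids is the alternating
(assign/recenter) variant with squared-distance seeding, deterministic
given a seed.  Predictions for new profiles are Rao-Blackwellised:
per sweep, membership weights w_c ∝ ψ_c f_X(x\*|Φ_c) over represented
components (renormalised; the residual stick mass is ignored by
default), prediction Σ_c w_c expit(θ_c + βᵀw\*), averaged over sweeps —
this requires chains run with `store_params=True`.

## Synthetic designs

**Design 1** (strong signal): n = 1000 subjects in five balanced random
groups; group g puts probability `separation` on category ((g+j) mod K)+1
of covariate j (remainder uniform), K = 5, J = 10; response Bernoulli
with per-group logits (−2, −1, 0, 1, 2); no fixed effects.  The default
separation is 0.9: at 0.8 the exact marginal partition posterior puts
non-trivial mass on splitting off individual outlier subjects (singleton
splits costing < 2 log units), so the posterior mode of the cluster count
legitimately exceeds the number of generating groups and the data are not
"well separated" in the model's own terms; at 0.9 every singleton split
loses posterior mass (checked across dataset seeds with the closed-form
covariate marginal before any sampler tuning).

**Design 2** (ordering stress test): α ~ Gamma(9, 0.5) — read as
shape/rate, mean 18; a flag switches to the scale convention — sticks
broken until 99.99% of the mass is placed, Φ_c flat-Dirichlet, θ_c and
the 10 fixed-effect coefficients t₇(0, 2.5), W standard normal,
allocations by the weights, J = 10 covariates with 5 categories.
Datasets from this design have dozens of clusters of stochastically
decaying size, the regime where ordering mixing limits α recovery.

**Tiny fixture**: n ≤ 8, binary covariates with a planted two-block
lean, used for exhaustive-partition oracles (Bell(6) = 203).

What the generators do *not* emulate: covariate dependence within
clusters, missing data, rare categories, or the confounding structure of
real case-control data; passing the recovery tests shows sampler
correctness and mixing on clean signals, not robustness to real-data
pathologies.

## Test problem sizes

The heavier end-to-end checks run at desk scale: cluster-number recovery
uses the full design-1 dataset (n = 1000) with 10 initial clusters and
2000 + 2000 sweeps; the enumeration oracle uses 5·10⁴ kept sweeps per
move configuration; the α-recovery comparison uses design-2 datasets at
n = 250 with ten dataset seeds, 100 initial clusters and a deliberately
tight 200 + 800 sweep budget per run (the mixing handicap of the
two-swap sampler shows as intermittently slow convergence, so the
comparison pools many short runs rather than a few long ones); the
initialisation-robustness check uses design 1 at n = 300 with starts at
1/5/10/30/50 clusters and 800 + 500 sweeps with the partition posterior
evaluated every kept sweep.  These sizes keep each property comfortably
reproducible in minutes; the qualitative claims they check (mode of the
cluster count, posterior invariance, move-3's mixing benefit for α,
initialisation insensitivity under strong signal) are scale-free.

## Numerical choices

- All density computations in log space; −∞ propagates (a zero
  probability on an observed category flags an impossible allocation
  rather than erroring).
- Sticks are clipped to [1e−12, 1 − 1e−12] after Beta draws so log1p
  terms stay finite.
- Categorical sampling uses Gumbel-max, which also breaks ties
  continuously.
- Degenerate inputs: J = 0 with a response gives a pure response
  mixture; Y absent switches to the covariate-only model; n = 0 chains
  reproduce the prior (used by the prior-reproduction tests).
- Slice coverage is capped at 10⁴ extensions per sweep; exceeding it
  raises with the current α, since it indicates α has drifted to an
  extreme value.

## Limitations

- Bernoulli response and categorical covariates only; no variable
  selection; no split-merge moves; single-chain execution (multi-run
  comparison is by separate seeded runs).
- The Walker slice representation regenerates many short-lived
  components per sweep when α is large (order α log n), which dominates
  runtime in the design-2 regime.
- The marginal partition posterior is unnormalised over partitions:
  valid for comparisons at the same α on the same data, not as model
  evidence.
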