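# stickdpm

Bayesian profile regression with a full stick-breaking Dirichlet process
mixture sampler.

`stickdpm` is for epidemiologists and applied statisticians who want to
cluster subjects jointly by a profile of categorical covariates and a
binary outcome — letting the data decide the number of clusters — while
doing honest inference on the Dirichlet process concentration parameter
α.  It implements the pieces that make that inference trustworthy in
practice: deliberate label-switching Metropolis moves that keep the
chain mixing over the weakly identified cluster ordering, and a
marginal-partition-posterior diagnostic that exposes non-convergence
that parameter traces hide.

## Model

Subjects i = 1..n carry J categorical covariates X_i, an optional binary
response Y_i and optional fixed effects W_i.  An infinite mixture

    P(Z_i = c) = ψ_c,   ψ_c = V_c ∏_{l<c} (1 − V_l),   V_c ~ Beta(1, α),

assigns subjects to clusters; cluster c has categorical probabilities
Φ_{c,j} ~ Dirichlet(a_j) and response intercept θ_c ~ t₇(0, 2.5), with
logit P(Y_i = 1) = θ_{Z_i} + βᵀW_i and β_l ~ t₇(0, 2.5) global.  The
weights are sampled explicitly (slice sampling), so α gets a conjugate
Gamma update from the sticks.  Because the stick-breaking prior orders
the weights (P(ψ_c > ψ_{c+1}) > ½ for every c) while the likelihood
ignores labels, three label-switching moves are run every sweep — two
classic label/stick swaps and a weight-matched swap that proposes new
weights near their conditional posterior means — without which the
posterior of α is unreliable.

Convergence is monitored with the marginal partition posterior p(Z | D)
at fixed α: Dirichlet-multinomial covariate marginals in closed form
plus a fourth-order Laplace integral over the response parameters.
Chains started from too few clusters sit visibly lower on this statistic
than chains started generously, which individual parameter traces fail
to show.  Post-processing gives the posterior similarity matrix, a
Binder-optimal partition via k-medoids, and Rao-Blackwellised
predictions for new profiles.

See `docs/methods.md` for the algorithms, defaults and design decisions.

## Worked example

Recover five well-separated groups from the package's first simulation
design (1000 subjects, 10 five-category covariates, binary outcome):

```python
import numpy as np
from stickdpm import PriorSpec, SamplerConfig, run_chain
from stickdpm.synthetic_data import SimSpec, gen_dataset1
from stickdpm.postprocess import similarity_matrix, optimal_partition

data, truth = gen_dataset1(SimSpec(seed=42))
cfg = SamplerConfig(n_init_clusters=10, n_burn=2000, n_keep=2000, seed=3)
chain = run_chain(data, PriorSpec(), cfg)       # alpha ~ Gamma(2, 1)

vals, counts = np.unique(chain.K_occ, return_counts=True)
print(dict(zip(vals.tolist(), (counts / counts.sum()).round(3).tolist())))
print("posterior mean alpha:", chain.alpha.mean().round(2))

from stickdpm.model_core import canonical_labels
S = similarity_matrix(chain.Z[::5])
part = optimal_partition(S, k_max=int(chain.K_occ.max()) + 2)
print("optimal partition:", part.K_occ, "clusters; matches truth:",
      np.array_equal(part.Z, canonical_labels(truth)))
```

Output (about 40 s on one core):

```
{5: 0.972, 6: 0.028}
posterior mean alpha: 0.81
optimal partition: 5 clusters; matches truth: True
```

The posterior of the number of non-empty clusters puts 97% of its mass
on the generating value 5, and the similarity-based point estimate
reproduces the generating partition exactly.

The same pipeline is available from the shell:

```sh
stickdpm simulate --design dataset1 --seed 42 --out sim1.csv
stickdpm run --data sim1.csv --config config.yaml --out chain1/
stickdpm diagnose chain1/ chain2/ --out diag/
stickdpm summarise chain1/ --out summary/
stickdpm predict chain1/ --profiles new_profiles.csv --out predictions.csv
```

where `config.yaml` holds `priors:` and `sampler:` sections (see
`stickdpm.io.read_config`).

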