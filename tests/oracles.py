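"""Independent brute-force oracles used by the test suite.

Everything here is deliberately simple and kept apart from the package's
own code paths: exhaustive set-partition enumeration, Monte-Carlo stick
posteriors, and a weight-matched swap ratio built from the expected-weight
definition rather than the closed form.
"""

import numpy as np

from stickdpm.diagnostics import log_marginal_partition_posterior
from stickdpm.model_core import canonical_labels


def all_partitions(n):
    """All set partitions of {0..n-1} as restricted-growth label vectors."""

    def rec(prefix, m):
        if len(prefix) == n:
            yield np.array(prefix, dtype=np.int64)
            return
        for z in range(m + 1):
            yield from rec(prefix + [z], max(m, z + 1))

    yield from rec([0], 1)


def exact_partition_posterior(data, alpha, priors=None):
    """Exact posterior over all set partitions via the marginal partition
    posterior (covariate-only: closed form, no approximation)."""
    parts = list(all_partitions(data.n))
    logp = np.array([log_marginal_partition_posterior(Z, data, alpha, priors)
                     for Z in parts])
    post = np.exp(logp - logp.max())
    post /= post.sum()
    index = {tuple(Z): k for k, Z in enumerate(parts)}
    return parts, post, index


def empirical_partition_freqs(alloc_samples, index):
    freq = np.zeros(len(index))
    for Z in alloc_samples:
        freq[index[tuple(canonical_labels(Z))]] += 1
    return freq / freq.sum()


def total_variation(p, q):
    return 0.5 * float(np.abs(np.asarray(p) - np.asarray(q)).sum())


def mc_expected_weight(c, counts, alpha, reps, rng):
    """Monte-Carlo E[psi_c | Z, alpha] from the conditional stick posteriors."""
    counts = np.asarray(counts, dtype=float)
    tails = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    V = rng.beta(1.0 + counts, alpha + tails, size=(reps, len(counts)))
    psi = V * np.concatenate([np.ones((reps, 1)),
                              np.cumprod(1.0 - V, axis=1)[:, :-1]], axis=1)
    return psi[:, c].mean(), psi[:, c].std(ddof=1) / np.sqrt(reps)


def move3_ratio_oracle(n_c, n_c1, tail, alpha, psi_c, psi_c1):
    """Weight-matched swap ratio built directly from the Eq.-6 proposal:
    construct psi' from expected-weight ratios and form the allocation
    density ratio, never touching the closed-form R1/R2 expressions."""
    from stickdpm.model_core import expected_weight_given_Z

    counts = np.array([n_c, n_c1, tail], dtype=float)
    counts_prop = np.array([n_c1, n_c, tail], dtype=float)
    e1 = (expected_weight_given_Z(0, counts_prop, alpha)
          / expected_weight_given_Z(1, counts, alpha))
    e2 = (expected_weight_given_Z(1, counts_prop, alpha)
          / expected_weight_given_Z(0, counts, alpha))
    psi_plus = psi_c + psi_c1
    norm = psi_c1 * e1 + psi_c * e2
    psi_c_new = psi_c1 * psi_plus * e1 / norm
    psi_c1_new = psi_c * psi_plus * e2 / norm
    log_ratio = (n_c1 * np.log(psi_c_new) + n_c * np.log(psi_c1_new)
                 - n_c * np.log(psi_c) - n_c1 * np.log(psi_c1))
    return float(np.exp(log_ratio))
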