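"""Synthetic profile-regression data in two simulation designs.

Design 1 is a strong-signal benchmark: a fixed number of balanced,
well-separated groups, each with its own dominant category per covariate
and its own response intercept.  A sampler should recover the generating
number of clusters and partition essentially exactly.

Design 2 is the hard case for label-ordering mixing: the number and
sizes of clusters themselves follow the stick-breaking prior with
concentration alpha drawn from its Gamma hyperprior, component
parameters drawn from their priors, plus fixed effects.  Recovering the
generating distribution of alpha across replicate datasets exercises the
sampler's mixing over cluster orderings.

A tiny covariate-only fixture with a planted two-block structure
supports exhaustive-enumeration oracles (all set partitions of up to 8
subjects).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import Dataset
from scipy.special import expit

__all__ = ["SimSpec", "gen_dataset1", "gen_dataset2", "gen_tiny_fixture"]

_STICK_CAP = 10_000


@dataclass
class SimSpec:
    """Parameters of a simulated profile-regression dataset.

    ``separation`` is the probability mass on a group's dominant category
    (the remainder is spread uniformly), so it must exceed ``1/K``;
    ``theta_values`` are the per-group response intercepts on the logit
    scale.  ``alpha_gamma`` is the (shape, rate) of the concentration
    hyperprior used by design 2; ``gamma_is_rate=False`` reads the second
    entry as a scale instead.
    """

    design: str = "dataset1"
    n: int = 1000
    J: int = 10
    K: int = 5
    L: int = 0
    n_groups: int = 5
    separation: float = 0.9
    theta_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0)
    alpha_gamma: tuple[float, float] = (9.0, 0.5)
    gamma_is_rate: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1.0 / self.K) < self.separation <= 1.0:
            raise ValueError("separation must lie in (1/K, 1]")

    @classmethod
    def dataset2(cls, n: int = 1000, seed: int = 0, **kw) -> "SimSpec":
        """Design-2 defaults: 10 five-category covariates, 10 fixed effects."""
        return cls(design="dataset2", n=n, J=10, K=5, L=10, seed=seed, **kw)


def _group_phi(spec: SimSpec) -> np.ndarray:
    """(G, J, K) category probabilities: group g puts `separation` on
    category (g + j) mod K, remainder uniform."""
    G, J, K = spec.n_groups, spec.J, spec.K
    phi = np.full((G, J, K), (1.0 - spec.separation) / (K - 1))
    for g in range(G):
        for j in range(J):
            phi[g, j, (g + j) % K] = spec.separation
    return phi


def _sample_categorical_rows(phi_rows: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of an (n, K) probability matrix."""
    u = rng.uniform(size=phi_rows.shape[0])
    return (phi_rows.cumsum(axis=1) < u[:, None]).sum(axis=1)


def gen_dataset1(spec: SimSpec | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Dataset, np.ndarray]:
    """Well-separated balanced-group data with a binary response.

    Subjects are split into ``n_groups`` balanced groups at random (sizes
    differing by at most one when n is not divisible); covariates follow
    the group's dominant-category profile and the response is Bernoulli
    with logit equal to the group's intercept.  Returns the dataset and
    the generating labels.
    """
    spec = spec or SimSpec()
    rng = rng or np.random.default_rng(spec.seed)
    n, G = spec.n, spec.n_groups
    if len(spec.theta_values) != G:
        raise ValueError("need one intercept per group")
    labels = np.empty(n, dtype=np.int64)
    labels[rng.permutation(n)] = np.arange(n) % G
    phi = _group_phi(spec)
    X = np.empty((n, spec.J), dtype=np.int64)
    for j in range(spec.J):
        X[:, j] = _sample_categorical_rows(phi[labels, j], rng)
    theta = np.asarray(spec.theta_values)
    Y = (rng.uniform(size=n) < expit(theta[labels])).astype(np.int64)
    K = np.full(spec.J, spec.K, dtype=np.int64)
    return Dataset(X=X, Y=Y, K=K), labels


def gen_dataset2(spec: SimSpec | None = None,
                 rng: np.random.Generator | None = None
                 ) -> tuple[Dataset, float, np.ndarray]:
    """Stick-breaking mixture data with alpha drawn from its Gamma prior.

    Draws ``alpha ~ Gamma(shape, rate)`` (mean shape/rate = 18 at the
    default (9, 0.5)), breaks sticks until the cumulative weight exceeds
    0.9999, draws flat-Dirichlet category probabilities, t-distributed
    intercepts and fixed-effect coefficients, standard-normal fixed
    effects, and emits covariates and a Bernoulli response.  Returns the
    dataset, the generating alpha, and the generating labels.
    """
    spec = spec or SimSpec.dataset2()
    rng = rng or np.random.default_rng(spec.seed)
    shape, second = spec.alpha_gamma
    scale = 1.0 / second if spec.gamma_is_rate else second
    alpha = float(rng.gamma(shape, scale))

    V, log_rem = [], 0.0
    while log_rem > np.log(1e-4):
        if len(V) >= _STICK_CAP:
            raise RuntimeError(f"stick cap {_STICK_CAP} exceeded (alpha={alpha:.3g})")
        v = float(rng.beta(1.0, alpha))
        V.append(v)
        log_rem += np.log1p(-v)
    V = np.asarray(V)
    psi = V * np.concatenate([[1.0], np.cumprod(1.0 - V)[:-1]])
    psi = psi / psi.sum()
    C = len(psi)

    labels = rng.choice(C, size=spec.n, p=psi)
    phi = rng.dirichlet(np.ones(spec.K), size=(C, spec.J))
    theta = 2.5 * rng.standard_t(7.0, size=C)
    beta = 2.5 * rng.standard_t(7.0, size=spec.L)
    W = rng.standard_normal((spec.n, spec.L)) if spec.L else None
    X = np.empty((spec.n, spec.J), dtype=np.int64)
    for j in range(spec.J):
        X[:, j] = _sample_categorical_rows(phi[labels, j], rng)
    eta = theta[labels] + (W @ beta if spec.L else 0.0)
    Y = (rng.uniform(size=spec.n) < expit(eta)).astype(np.int64)
    K = np.full(spec.J, spec.K, dtype=np.int64)
    return Dataset(X=X, Y=Y, W=W, K=K), alpha, labels


def gen_tiny_fixture(n: int, J: int, rng: np.random.Generator | None = None,
                     separation: float = 0.9) -> Dataset:
    """Tiny covariate-only binary dataset with a planted two-block split.

    The first half of the subjects lean to category 0, the second half to
    category 1, with probability ``separation``.  Restricted to n <= 8 so
    that the full set-partition lattice stays enumerable (Bell(8) = 4140).
    """
    if n > 8:
        raise ValueError("tiny fixture capped at n = 8 for exhaustive enumeration")
    rng = rng or np.random.default_rng(0)
    block = (np.arange(n) >= (n + 1) // 2).astype(np.int64)
    p1 = np.where(block == 0, 1.0 - separation, separation)
    X = (rng.uniform(size=(n, J)) < p1[:, None]).astype(np.int64)
    return Dataset(X=X, K=np.full(J, 2, dtype=np.int64))
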