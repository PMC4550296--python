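"""Core types and mathematics of the full stick-breaking DPMM.

Houses the data container, prior specification, sampler state, the
stick-breaking construction, the profile-regression likelihood (locally
independent categorical covariates, logistic binary response with global
fixed effects), the Dirichlet-process partition prior (EPPF), and the
stick-weight order properties that motivate the label-switching moves.

Conventions
-----------
Category labels and cluster labels are 0-based everywhere inside the
package; 1-based labels appear only in files read or written by
:mod:`stickdpm.io`.  All probability computations are in log space and
``-inf`` propagates rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, log_expit

__all__ = [
    "Dataset",
    "PriorSpec",
    "ComponentParams",
    "MixtureState",
    "Partition",
    "stick_weights",
    "log_f_X",
    "log_f_Y",
    "log_eppf",
    "expected_weight_given_Z",
    "mc_order_probability",
    "t_logpdf",
    "joint_log_density",
    "log_likelihood_matrix",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Dataset:
    """Subject-level profile-regression data.

    Parameters
    ----------
    X
        ``(n, J)`` integer matrix of categorical covariates; entry ``X[i, j]``
        is a 0-based category in ``{0, ..., K[j]-1}``.
    Y
        Optional length-``n`` binary response (0/1).  ``None`` selects the
        covariate-only mixture model.
    W
        Optional ``(n, L)`` real matrix of fixed effects entering the
        response model globally (non-cluster-specific).
    K
        Length-``J`` vector of category counts.  Inferred from ``X`` as
        ``X.max(axis=0) + 1`` when omitted.
    """

    X: np.ndarray
    Y: np.ndarray | None = None
    W: np.ndarray | None = None
    K: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D integer matrix")
        n, J = self.X.shape
        if self.K is None:
            self.K = self.X.max(axis=0) + 1 if n and J else np.zeros(J, dtype=np.int64)
        self.K = np.asarray(self.K, dtype=np.int64)
        if self.K.shape != (J,):
            raise ValueError("K must have one entry per covariate column")
        if J and n:
            if self.X.min() < 0 or np.any(self.X >= self.K):
                raise ValueError("categorical entries must lie in {0..K_j-1}")
        if self.Y is not None:
            self.Y = np.asarray(self.Y, dtype=np.int64)
            if self.Y.shape != (n,):
                raise ValueError("Y length must match X rows")
            if not np.isin(self.Y, (0, 1)).all():
                raise ValueError("Y must be binary (0/1)")
        if self.W is not None:
            self.W = np.asarray(self.W, dtype=np.float64)
            if self.W.ndim != 2 or self.W.shape[0] != n:
                raise ValueError("W row count must match X rows")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def J(self) -> int:
        return self.X.shape[1]

    @property
    def L(self) -> int:
        return 0 if self.W is None else self.W.shape[1]

    @property
    def has_response(self) -> bool:
        return self.Y is not None


@dataclass
class PriorSpec:
    """Hyperparameters of the profile-regression DPMM.

    ``a`` are the per-covariate Dirichlet parameters for the category
    probabilities (default all-ones); cluster intercepts ``theta_c`` and
    fixed-effect coefficients ``beta_l`` carry heavy-tailed Student-t
    priors, ``t_7(0, 2.5)``; the concentration parameter alpha is either
    fixed or given a ``Gamma(shape, rate)`` hyperprior.
    """

    a: list[np.ndarray] | None = None
    theta_df: float = 7.0
    theta_loc: float = 0.0
    theta_scale: float = 2.5
    beta_df: float = 7.0
    beta_loc: float = 0.0
    beta_scale: float = 2.5
    alpha_fixed: float | None = None
    alpha_shape: float = 2.0
    alpha_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.a is not None:
            self.a = [np.asarray(aj, dtype=np.float64) for aj in self.a]
            for aj in self.a:
                if np.any(aj <= 0):
                    raise ValueError("Dirichlet parameters must be positive")
        for v in (self.theta_df, self.theta_scale, self.beta_df, self.beta_scale,
                  self.alpha_shape, self.alpha_rate):
            if v <= 0:
                raise ValueError("prior hyperparameters must be strictly positive")
        if self.alpha_fixed is not None and self.alpha_fixed <= 0:
            raise ValueError("fixed alpha must be strictly positive")

    def dirichlet_a(self, data: Dataset) -> list[np.ndarray]:
        """Dirichlet parameter vectors, defaulting to all-ones of length K_j."""
        if self.a is None:
            return [np.ones(int(k)) for k in data.K]
        if len(self.a) != data.J:
            raise ValueError("need one Dirichlet vector per covariate")
        for aj, k in zip(self.a, data.K):
            if len(aj) != int(k):
                raise ValueError("Dirichlet vector length must equal K_j")
        return self.a

    @property
    def alpha_is_fixed(self) -> bool:
        return self.alpha_fixed is not None


@dataclass
class ComponentParams:
    """Cluster-specific parameters Theta_c = (Phi_c, theta_c)."""

    phi: list[np.ndarray]
    theta: float = 0.0

    def __post_init__(self) -> None:
        self.phi = [np.asarray(p, dtype=np.float64) for p in self.phi]
        for p in self.phi:
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-10:
                raise ValueError("each Phi_cj must be a probability vector")


@dataclass
class MixtureState:
    """Complete state of the full stick-breaking sampler.

    ``C`` represented components with sticks ``V``, weights ``psi``
    (``psi[c] = V[c] * prod_{l<c} (1 - V[l])``), component parameters,
    global fixed-effect coefficients ``beta``, allocations ``Z`` (0-based,
    ``< C``), slice variables ``u`` (``u[i] < psi[Z[i]]``) and the
    concentration parameter ``alpha``.
    """

    V: np.ndarray
    psi: np.ndarray
    components: list[ComponentParams]
    beta: np.ndarray
    Z: np.ndarray
    u: np.ndarray
    alpha: float

    @property
    def C(self) -> int:
        return len(self.V)

    @property
    def z_star(self) -> int:
        """Highest occupied label + 1 (Z* in the usual stick-breaking notation)."""
        return int(self.Z.max()) + 1 if len(self.Z) else 0

    def counts(self, upto: int | None = None) -> np.ndarray:
        """Cluster occupancy counts over labels ``0..upto-1`` (default C)."""
        m = self.C if upto is None else upto
        return np.bincount(self.Z, minlength=m)[:m]

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if np.any(self.V <= 0) or np.any(self.V > 1):
            raise ValueError("sticks must lie in (0, 1]")
        if not np.allclose(self.psi, stick_weights(self.V), atol=1e-10):
            raise ValueError("psi inconsistent with sticks")
        if len(self.Z) and (self.Z.min() < 0 or self.Z.max() >= self.C):
            raise ValueError("allocation outside represented components")
        if len(self.Z) and np.any(self.u >= self.psi[self.Z]):
            raise ValueError("slice variable not below its component weight")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class Partition:
    """A set partition of ``{0..n-1}`` in first-appearance canonical form."""

    Z: np.ndarray
    counts: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.Z = canonical_labels(np.asarray(self.Z, dtype=np.int64))
        self.counts = np.bincount(self.Z)
        if len(self.Z) and self.counts.min() < 1:
            raise ValueError("canonical partition has no empty clusters")

    @property
    def n(self) -> int:
        return len(self.Z)

    @property
    def K_occ(self) -> int:
        return len(self.counts)

    def members(self, c: int) -> np.ndarray:
        return np.flatnonzero(self.Z == c)


def canonical_labels(Z: np.ndarray) -> np.ndarray:
    """Relabel clusters by order of first appearance (idempotent)."""
    _, canon = np.unique(Z, return_inverse=True)
    # np.unique sorts by label value; remap so first appearance gets 0
    order = {}
    out = np.empty_like(Z)
    nxt = 0
    for i, z in enumerate(Z):
        if z not in order:
            order[z] = nxt
            nxt += 1
        out[i] = order[z]
    return out


# ---------------------------------------------------------------------------
# stick-breaking construction
# ---------------------------------------------------------------------------


def stick_weights(V: np.ndarray) -> np.ndarray:
    """Map stick proportions V to mixture weights psi.

    ``psi_1 = V_1`` and ``psi_c = V_c * prod_{l<c} (1 - V_l)``; the
    remaining mass after C sticks is ``prod_{c<=C} (1 - V_c)`` so partial
    sums never exceed 1.
    """
    V = np.asarray(V, dtype=np.float64)
    if V.size and (V.min() <= 0 or V.max() > 1):
        raise ValueError("stick proportions must lie in (0, 1]")
    if V.size == 0:
        return np.zeros(0)
    remaining = np.concatenate([[1.0], np.cumprod(1.0 - V)[:-1]])
    return V * remaining


def remaining_mass(V: np.ndarray) -> float:
    """Undistributed stick mass prod_c (1 - V_c) after the represented sticks."""
    return float(np.prod(1.0 - np.asarray(V, dtype=np.float64)))


# ---------------------------------------------------------------------------
# likelihood terms
# ---------------------------------------------------------------------------


def log_f_X(x_row: np.ndarray, comp: ComponentParams) -> float:
    """Log covariate likelihood sum_j log phi_{c,j,x_j} for one subject.

    A zero probability on an observed category yields ``-inf``.
    """
    total = 0.0
    for j, xj in enumerate(np.asarray(x_row, dtype=np.int64)):
        p = comp.phi[j][xj]
        if p <= 0.0:
            return -np.inf
        total += np.log(p)
    return total


def log_f_Y(y: int, theta: float, beta: np.ndarray, w: np.ndarray) -> float:
    """Log Bernoulli likelihood under logit(P(Y=1)) = theta + beta'w.

    Computed as ``y*eta - log(1 + exp(eta))`` via ``log_expit`` for
    overflow safety.
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=np.float64))
    w = np.atleast_1d(np.asarray(w, dtype=np.float64))
    if beta.shape != w.shape:
        raise ValueError("beta and w must have matching length")
    eta = theta + float(beta @ w)
    return float(log_expit(eta) if y == 1 else log_expit(-eta))


def log_likelihood_matrix(data: Dataset, components: list[ComponentParams],
                          beta: np.ndarray) -> np.ndarray:
    """``(n, C)`` matrix of log f(D_i | Theta_c, beta).

    Vectorised over subjects per component: the covariate term gathers
    ``log phi_{c,j,X_ij}`` and the response term is the Bernoulli log
    likelihood at ``eta = theta_c + W beta``.
    """
    n, J = data.X.shape
    C = len(components)
    out = np.zeros((n, C))
    if J and (data.K == data.K[0]).all():
        K = int(data.K[0])
        phi = np.empty((C, J, K))
        for c, comp in enumerate(components):
            for j in range(J):
                phi[c, j] = comp.phi[j]
        with np.errstate(divide="ignore"):
            logphi = np.log(phi)
        for j in range(J):
            out += logphi[:, j, data.X[:, j]].T
    elif J:
        for c, comp in enumerate(components):
            acc = np.zeros(n)
            with np.errstate(divide="ignore"):
                for j in range(J):
                    acc += np.log(comp.phi[j])[data.X[:, j]]
            out[:, c] = acc
    if data.has_response:
        offset = data.W @ beta if data.W is not None else np.zeros(n)
        theta = np.array([comp.theta for comp in components])
        eta = theta[None, :] + offset[:, None]
        out += np.where(data.Y[:, None] == 1, log_expit(eta), log_expit(-eta))
    return out


# ---------------------------------------------------------------------------
# partition prior (EPPF) and stick-order properties
# ---------------------------------------------------------------------------


def log_eppf(partition: Partition, alpha: float, n: int | None = None) -> float:
    """Log Dirichlet-process partition prior (EPPF).

    ``K log alpha + sum_c lgamma(n_c) + lgamma(alpha) - lgamma(alpha + n)``
    for a partition with K occupied clusters of sizes ``n_c``.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts = partition.counts
    if n is None:
        n = int(counts.sum())
    elif n != counts.sum():
        raise ValueError("partition counts must sum to n")
    return float(
        len(counts) * np.log(alpha)
        + gammaln(counts).sum()
        + gammaln(alpha)
        - gammaln(alpha + n)
    )


def expected_weight_given_Z(c: int, counts_by_label: np.ndarray, alpha: float) -> float:
    """Conditional posterior mean E[psi_c | Z, alpha] of a stick weight.

    Under the conjugate stick posteriors ``V_l | Z ~ Beta(1 + n_l,
    alpha + sum_{m>l} n_m)`` (labels 0-based, empty labels allowed),

        E[psi_c | Z, alpha] = prod_{l<c} E[1 - V_l] * E[V_c].
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    counts = np.asarray(counts_by_label, dtype=np.float64)
    if not 0 <= c < len(counts):
        raise ValueError("label outside the counts vector")
    tails = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
    val = (1.0 + counts[c]) / (1.0 + alpha + counts[c] + tails[c])
    for l in range(c):
        val *= (alpha + tails[l]) / (1.0 + alpha + counts[l] + tails[l])
    return float(val)


def mc_order_probability(alpha: float, c: int, reps: int = 100_000,
                         seed: int | np.random.Generator = 0) -> tuple[float, float]:
    """Monte-Carlo estimate of the prior order probability P(psi_c > psi_{c+1}).

    Draws ``reps`` i.i.d. stick sequences ``V ~ Beta(1, alpha)`` and
    returns the fraction of draws with ``psi_c > psi_{c+1}`` together with
    its binomial standard error.  The stick-breaking prior weakly orders
    the weights: this probability exceeds 1/2 for every ``c`` (0-based).
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    V = rng.beta(1.0, alpha, size=(reps, c + 2))
    # psi_c / psi_{c+1} = V_c / (V_{c+1} (1 - V_c)); shared prefix cancels
    hit = V[:, c] > V[:, c + 1] * (1.0 - V[:, c])
    p = float(hit.mean())
    se = float(np.sqrt(max(p * (1.0 - p), 1.0 / reps) / reps))
    return p, se


# ---------------------------------------------------------------------------
# priors and joint density
# ---------------------------------------------------------------------------


def t_logpdf(x: np.ndarray | float, df: float, loc: float, scale: float):
    """Student-t log density, the heavy-tailed prior for theta_c and beta_l.

    Written out with lgamma/log1p (identical to scipy.stats.t.logpdf but
    cheap enough for per-cluster calls inside the sweep loop).
    """
    z = (np.asarray(x, dtype=np.float64) - loc) / scale
    return (gammaln((df + 1.0) / 2.0) - gammaln(df / 2.0)
            - 0.5 * np.log(df * np.pi) - np.log(scale)
            - (df + 1.0) / 2.0 * np.log1p(z * z / df))


def joint_log_density(state: MixtureState, data: Dataset, priors: PriorSpec,
                      include_invariant: bool = True) -> float:
    """Log joint density of the represented state (slice variables integrated out).

    Sums the stick prior ``Beta(V_c; 1, alpha)``, the component-parameter
    priors (Dirichlet for Phi, t for theta), the prior on beta, the
    allocation probabilities ``log psi_{Z_i}`` and the data likelihood.
    The alpha hyperprior is omitted: every label-switching move leaves
    alpha unchanged, so it cancels from all Metropolis ratios computed by
    differencing this function.

    ``include_invariant=False`` drops the component-parameter priors, the
    beta prior and the data likelihood.  Label-switching moves carry the
    component parameters along with the labels, so those terms are
    invariant under every swap (an identity the test suite asserts) and
    differencing the remaining stick-prior and allocation terms gives the
    same Metropolis ratio at a fraction of the cost.
    """
    total = float(np.sum((state.alpha - 1.0) * np.log1p(-np.minimum(state.V, 1 - 1e-15)))
                  + state.C * np.log(state.alpha))
    with np.errstate(divide="ignore"):
        total += float(np.log(state.psi[state.Z]).sum())
    if not include_invariant:
        return total
    a = priors.dirichlet_a(data)
    for comp in state.components:
        for j in range(data.J):
            aj = a[j]
            lp = gammaln(aj.sum()) - gammaln(aj).sum()
            mask = aj != 1.0  # avoid 0 * log(0) at the flat-prior default
            if mask.any():
                with np.errstate(divide="ignore"):
                    lp += ((aj[mask] - 1.0) * np.log(comp.phi[j][mask])).sum()
            total += float(lp)
        if data.has_response:
            total += float(t_logpdf(comp.theta, priors.theta_df,
                                    priors.theta_loc, priors.theta_scale))
    if data.has_response and data.L:
        total += float(t_logpdf(state.beta, priors.beta_df,
                                priors.beta_loc, priors.beta_scale).sum())
    ll = log_likelihood_matrix(data, state.components, state.beta)
    total += float(ll[np.arange(data.n), state.Z].sum())
    return total
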