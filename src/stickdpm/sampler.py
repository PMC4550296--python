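"""Blocked Metropolis-within-Gibbs sampler for the full stick-breaking DPMM.

The engine is a Walker-style slice sampler: auxiliary variables
``u_i ~ U(0, psi_{Z_i})`` truncate the infinite mixture to the finitely
many components whose weight exceeds the smallest slice, after which all
blocks have standard conditionals.  Each sweep updates, in fixed order:
slice variables and allocations, sticks, category probabilities Phi,
cluster intercepts theta, fixed-effect coefficients beta, the
concentration parameter alpha, and finally the three label-switching
moves.  Random-walk proposal scales for theta and beta are adapted by
Robbins-Monro recursion during burn-in only, so the kept sample targets
the exact posterior.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass

import numpy as np

from . import label_switching as ls
from .model_core import (
    ComponentParams,
    Dataset,
    MixtureState,
    PriorSpec,
    log_likelihood_matrix,
    stick_weights,
    t_logpdf,
)

__all__ = [
    "SamplerConfig",
    "ChainOutput",
    "init_state",
    "update_slice_and_allocations",
    "update_sticks",
    "update_phi",
    "update_theta",
    "update_beta",
    "update_alpha",
    "run_chain",
]

_STICK_CLIP = 1e-12  # sticks kept inside (clip, 1-clip) for log safety


@dataclass
class SamplerConfig:
    """Run-length, initialisation and move settings for one MCMC chain.

    ``n_init_clusters`` should exceed the anticipated number of clusters:
    the sampler merges clusters far more readily than it splits them, so
    initialising with too few risks trapping the chain below the mode.
    """

    n_init_clusters: int = 10
    n_burn: int = 1000
    n_keep: int = 1000
    thin: int = 1
    seed: int = 0
    moves_enabled: tuple[bool, bool, bool] = (True, True, True)
    rw_scale_theta: float = 0.5
    rw_scale_beta: float = 0.2
    adapt_burnin_only: bool = True
    store_params: bool = False
    compute_mpp: bool = False
    mpp_alpha: float = 1.0
    mpp_thin: int = 1
    max_stick_extensions: int = 10_000
    progress: bool = False

    def __post_init__(self) -> None:
        if self.n_init_clusters < 1:
            raise ValueError("need at least one initial cluster")
        if self.n_burn < 0 or self.n_keep < 0:
            raise ValueError("sweep counts must be non-negative")
        if self.thin < 1 or self.mpp_thin < 1:
            raise ValueError("thinning interval must be >= 1")


@dataclass
class ChainOutput:
    """Per-kept-sweep records of one chain plus run metadata."""

    Z: np.ndarray                      # (S, n) allocations
    alpha: np.ndarray                  # (S,)
    K_occ: np.ndarray                  # (S,) non-empty clusters
    loglik: np.ndarray                 # (S,) data log likelihood
    log_mpp: np.ndarray | None         # (S,) marginal partition posterior
    accept: np.ndarray                 # (S, 3) move outcome, nan = not attempted
    config: SamplerConfig
    version: str = "stickdpm-0.1.0"
    params: list[dict] | None = None   # per-sweep psi/theta/phi/beta if stored

    @property
    def n_sweeps(self) -> int:
        return self.Z.shape[0]

    def acceptance_table(self, window: int = 500) -> np.ndarray:
        """Move acceptance rates over consecutive sweep windows.

        Returns an array with rows ``(window_start, move1, move2, move3)``;
        sweeps where a move was not attempted are excluded from its rate.
        """
        rows = []
        for start in range(0, self.n_sweeps, window):
            block = self.accept[start:start + window]
            rates = [float(np.nanmean(block[:, m])) if np.isfinite(block[:, m]).any()
                     else np.nan for m in range(3)]
            rows.append([start, *rates])
        return np.asarray(rows)


def _draw_component(data: Dataset, priors: PriorSpec,
                    rng: np.random.Generator) -> ComponentParams:
    """Draw Theta_c = (Phi_c, theta_c) from the prior."""
    a = priors.dirichlet_a(data)
    phi = [rng.dirichlet(a[j]) for j in range(data.J)]
    theta = 0.0
    if data.has_response:
        theta = float(priors.theta_loc + priors.theta_scale * rng.standard_t(priors.theta_df))
    return ComponentParams(phi=phi, theta=theta)


def _draw_components_batch(m: int, data: Dataset, priors: PriorSpec,
                           rng: np.random.Generator) -> list[ComponentParams]:
    """Draw m fresh components from the prior in one batched pass.

    Used by the slice-coverage extension, which can need dozens of new
    components per sweep when alpha is large; bypasses per-component
    validation since the draws are simplex points by construction.
    """
    a = priors.dirichlet_a(data)
    J = data.J
    thetas = np.zeros(m)
    if data.has_response:
        thetas = priors.theta_loc + priors.theta_scale * rng.standard_t(
            priors.theta_df, size=m)
    if J and (data.K == data.K[0]).all():
        g = rng.standard_gamma(np.broadcast_to(np.stack(a), (m, J, int(data.K[0])))
                               if J else np.zeros((m, 0, 0)))
        g = g / g.sum(axis=2, keepdims=True)
        out = []
        for i in range(m):
            comp = ComponentParams.__new__(ComponentParams)
            comp.phi = [g[i, j] for j in range(J)]
            comp.theta = float(thetas[i])
            out.append(comp)
        return out
    out = []
    for i in range(m):
        comp = ComponentParams.__new__(ComponentParams)
        comp.phi = [rng.dirichlet(a[j]) for j in range(J)]
        comp.theta = float(thetas[i])
        out.append(comp)
    return out


def init_state(data: Dataset, priors: PriorSpec, cfg: SamplerConfig,
               rng: np.random.Generator) -> MixtureState:
    """Initial state: balanced random allocations, prior-drawn parameters.

    Subjects are spread over ``n_init_clusters`` labels by shuffled
    round-robin (sizes differ by at most one); sticks and component
    parameters come from their priors, beta starts at zero and alpha at
    its fixed value or prior mean.
    """
    n = data.n
    if n and cfg.n_init_clusters > n:
        raise ValueError("more initial clusters than subjects")
    alpha = (priors.alpha_fixed if priors.alpha_is_fixed
             else priors.alpha_shape / priors.alpha_rate)
    C = cfg.n_init_clusters
    if n:
        Z = np.empty(n, dtype=np.int64)
        Z[rng.permutation(n)] = np.arange(n) % C
    else:
        Z = np.zeros(0, dtype=np.int64)
    V = np.clip(rng.beta(1.0, alpha, size=C), _STICK_CLIP, 1 - _STICK_CLIP)
    psi = stick_weights(V)
    components = [_draw_component(data, priors, rng) for _ in range(C)]
    beta = np.zeros(data.L)
    u = rng.uniform(0.0, psi[Z]) if n else np.zeros(0)
    return MixtureState(V=V, psi=psi, components=components, beta=beta,
                        Z=Z, u=u, alpha=alpha)


def update_slice_and_allocations(state: MixtureState, data: Dataset,
                                 priors: PriorSpec, rng: np.random.Generator,
                                 max_extensions: int = 10_000) -> MixtureState:
    """Redraw slice variables, extend the sticks to cover them, reallocate.

    After drawing ``u_i ~ U(0, psi_{Z_i})``, new components are generated
    from the prior until the undistributed stick mass falls below
    ``min_i u_i`` (so every component a subject could move to is
    represented); each ``Z_i`` is then redrawn from
    ``P(Z_i=c) ∝ 1{psi_c > u_i} f(D_i | Theta_c, beta)`` by Gumbel-max.
    The representation is finally trimmed to ``max_i Z_i + 1`` components.
    """
    n = data.n
    if n == 0:
        return state
    u = rng.uniform(0.0, state.psi[state.Z])
    u_min = float(u.min())
    V = list(state.V)
    log_rem = float(np.log1p(-np.asarray(V)).sum())
    extensions = 0
    while log_rem >= np.log(u_min):
        if extensions >= max_extensions:
            raise RuntimeError(
                f"slice not covered after {max_extensions} stick extensions "
                f"(alpha={state.alpha:.3g}); the concentration parameter may "
                "have drifted to an extreme value")
        v = float(np.clip(rng.beta(1.0, state.alpha),
                          _STICK_CLIP, 1 - _STICK_CLIP))
        V.append(v)
        log_rem += np.log1p(-v)
        extensions += 1
    components = list(state.components)
    if extensions:
        components.extend(_draw_components_batch(extensions, data, priors, rng))
    V = np.asarray(V)
    psi = stick_weights(V)
    logf = log_likelihood_matrix(data, components, state.beta)
    scores = np.where(psi[None, :] > u[:, None], logf, -np.inf)
    scores += rng.gumbel(size=scores.shape)
    Z = scores.argmax(axis=1)
    keep = int(Z.max()) + 1
    state.V = V[:keep]
    state.psi = psi[:keep]
    state.components = components[:keep]
    state.Z = Z
    state.u = u
    return state


def update_sticks(state: MixtureState, rng: np.random.Generator) -> MixtureState:
    """Conjugate stick update: V_c ~ Beta(1 + n_c, alpha + sum_{l>c} n_l).

    Slice variables are refreshed afterwards so that ``u_i < psi_{Z_i}``
    holds under the new weights (their conditional is uniform).
    """
    counts = state.counts()
    tails = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0]])
    V = rng.beta(1.0 + counts, state.alpha + tails)
    state.V = np.clip(V, _STICK_CLIP, 1 - _STICK_CLIP)
    state.psi = stick_weights(state.V)
    if len(state.Z):
        state.u = rng.uniform(0.0, state.psi[state.Z])
    return state


def update_phi(state: MixtureState, data: Dataset, priors: PriorSpec,
               rng: np.random.Generator) -> MixtureState:
    """Conjugate Dirichlet update of the category probabilities.

    Occupied clusters draw ``Phi_cj ~ Dirichlet(a_j + category counts)``;
    empty represented clusters are refreshed from the prior (same formula
    with zero counts), keeping them live split targets.
    """
    a = priors.dirichlet_a(data)
    C, J = state.C, data.J
    if J and data.n and (data.K == data.K[0]).all():
        # equal category counts: one batched gamma draw for all (c, j)
        K = int(data.K[0])
        counts = np.zeros((C, J, K))
        flat = (state.Z[:, None] * J + np.arange(J)[None, :]) * K + data.X
        np.add.at(counts.reshape(-1), flat.ravel(), 1.0)
        post = counts + np.stack(a)[None, :, :]
        g = rng.standard_gamma(post)
        g /= g.sum(axis=2, keepdims=True)
        for c in range(C):
            for j in range(J):
                state.components[c].phi[j] = g[c, j]
        return state
    for c in range(state.C):
        members = np.flatnonzero(state.Z == c)
        for j in range(J):
            post = a[j].copy()
            if len(members):
                post += np.bincount(data.X[members, j], minlength=int(data.K[j]))
            state.components[c].phi[j] = rng.dirichlet(post)
    return state


def _cluster_response_loglik(theta: float, y: np.ndarray, offset: np.ndarray) -> float:
    from scipy.special import log_expit
    eta = theta + offset
    return float(np.where(y == 1, log_expit(eta), log_expit(-eta)).sum())


def update_theta(state: MixtureState, data: Dataset, priors: PriorSpec,
                 rng: np.random.Generator, scale: float = 0.5) -> tuple[int, int]:
    """Random-walk Metropolis update of each cluster intercept theta_c.

    Empty clusters are redrawn from the t prior.  Returns (accepted,
    attempted) counts for proposal-scale adaptation; no-op without a
    response model.
    """
    if not data.has_response:
        return 0, 0
    offset = data.W @ state.beta if data.W is not None else np.zeros(data.n)
    acc = att = 0
    for c in range(state.C):
        members = np.flatnonzero(state.Z == c)
        comp = state.components[c]
        if len(members) == 0:
            comp.theta = float(priors.theta_loc
                               + priors.theta_scale * rng.standard_t(priors.theta_df))
            continue
        att += 1
        prop = comp.theta + scale * rng.standard_normal()
        y, off = data.Y[members], offset[members]
        delta = (_cluster_response_loglik(prop, y, off)
                 - _cluster_response_loglik(comp.theta, y, off)
                 + float(t_logpdf(prop, priors.theta_df, priors.theta_loc,
                                  priors.theta_scale))
                 - float(t_logpdf(comp.theta, priors.theta_df, priors.theta_loc,
                                  priors.theta_scale)))
        if np.log(rng.uniform()) < delta:
            comp.theta = prop
            acc += 1
    return acc, att


def update_beta(state: MixtureState, data: Dataset, priors: PriorSpec,
                rng: np.random.Generator, scale: float = 0.2) -> tuple[int, int]:
    """Joint random-walk Metropolis update of the fixed-effect block beta."""
    if not data.has_response or data.L == 0:
        return 0, 0
    theta_i = np.array([state.components[c].theta for c in state.Z])
    prop = state.beta + scale * rng.standard_normal(data.L)
    cur_ll = _cluster_response_loglik(0.0, data.Y, theta_i + data.W @ state.beta)
    new_ll = _cluster_response_loglik(0.0, data.Y, theta_i + data.W @ prop)
    delta = (new_ll - cur_ll
             + float(t_logpdf(prop, priors.beta_df, priors.beta_loc,
                              priors.beta_scale).sum())
             - float(t_logpdf(state.beta, priors.beta_df, priors.beta_loc,
                              priors.beta_scale).sum()))
    if np.log(rng.uniform()) < delta:
        state.beta = prop
        return 1, 1
    return 0, 1


def update_alpha(state: MixtureState, priors: PriorSpec,
                 rng: np.random.Generator) -> MixtureState:
    """Conjugate Gamma update of the concentration parameter.

    ``alpha | V ~ Gamma(shape + C_rep, rate - sum_c log(1 - V_c))`` over
    the represented sticks; no-op when alpha is fixed.
    """
    if priors.alpha_is_fixed:
        return state
    rate = priors.alpha_rate - float(np.log1p(-state.V).sum())
    if rate <= 0:
        raise RuntimeError("non-positive rate in alpha update (invalid sticks)")
    state.alpha = float(rng.gamma(priors.alpha_shape + state.C, 1.0 / rate))
    return state


def run_chain(data: Dataset, priors: PriorSpec, cfg: SamplerConfig) -> ChainOutput:
    """Run one chain and record the kept sweeps.

    Fully reproducible: all randomness flows from a single generator
    seeded with ``cfg.seed``, and blocks execute in fixed order.
    """
    from .diagnostics import log_marginal_partition_posterior

    rng = np.random.default_rng(cfg.seed)
    state = init_state(data, priors, cfg, rng)
    n_total = cfg.n_burn + cfg.n_keep
    move_fns = (ls.move1_swap_random_labels,
                ls.move2_swap_neighbour_sticks,
                ls.move3_weight_matched_swap)
    scales = [cfg.rw_scale_theta, cfg.rw_scale_beta]

    recs: dict[str, list] = {k: [] for k in
                             ("Z", "alpha", "K_occ", "loglik", "log_mpp", "accept")}
    params: list[dict] | None = [] if cfg.store_params else None
    kept = 0
    for sweep in range(n_total):
        state = update_slice_and_allocations(state, data, priors, rng,
                                             cfg.max_stick_extensions)
        state = update_sticks(state, rng)
        state = update_phi(state, data, priors, rng)
        acc_t = update_theta(state, data, priors, rng, scales[0])
        acc_b = update_beta(state, data, priors, rng, scales[1])
        state = update_alpha(state, priors, rng)
        accept_flags = [np.nan, np.nan, np.nan]
        for m, fn in enumerate(move_fns):
            if cfg.moves_enabled[m]:
                out = fn(state, data, priors, rng)
                if out is not None:
                    accept_flags[m] = float(out)
        if cfg.adapt_burnin_only and sweep < cfg.n_burn:
            step = (sweep + 1) ** -0.6
            for idx, (targ, (na, natt)) in enumerate(((0.44, acc_t), (0.23, acc_b))):
                if natt:
                    scales[idx] = float(np.exp(np.log(scales[idx])
                                               + step * (na / natt - targ)))
        if sweep >= cfg.n_burn and (sweep - cfg.n_burn) % cfg.thin == 0:
            recs["Z"].append(state.Z.copy())
            recs["alpha"].append(state.alpha)
            recs["K_occ"].append(len(np.unique(state.Z)) if data.n else 0)
            logf = log_likelihood_matrix(data, state.components, state.beta)
            recs["loglik"].append(float(logf[np.arange(data.n), state.Z].sum())
                                  if data.n else 0.0)
            if cfg.compute_mpp and kept % cfg.mpp_thin == 0:
                recs["log_mpp"].append(log_marginal_partition_posterior(
                    state.Z, data, cfg.mpp_alpha, priors))
            else:
                recs["log_mpp"].append(np.nan)
            recs["accept"].append(accept_flags)
            if params is not None:
                params.append({
                    "psi": state.psi.copy(),
                    "theta": np.array([c.theta for c in state.components]),
                    "phi": [[p.copy() for p in c.phi] for c in state.components],
                    "beta": state.beta.copy(),
                })
            kept += 1
        if cfg.progress and (sweep + 1) % 1000 == 0:
            print(f"sweep {sweep + 1}/{n_total}  K_occ="
                  f"{len(np.unique(state.Z)) if data.n else 0}  "
                  f"alpha={state.alpha:.3f}", file=sys.stderr)

    S = kept
    n = data.n
    log_mpp = np.asarray(recs["log_mpp"]) if cfg.compute_mpp else None
    return ChainOutput(
        Z=np.asarray(recs["Z"], dtype=np.int64).reshape(S, n),
        alpha=np.asarray(recs["alpha"]),
        K_occ=np.asarray(recs["K_occ"], dtype=np.int64),
        loglik=np.asarray(recs["loglik"]),
        log_mpp=log_mpp,
        accept=np.asarray(recs["accept"], dtype=np.float64).reshape(S, 3),
        config=cfg,
        params=params,
    )
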