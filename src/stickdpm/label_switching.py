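"""Label-switching Metropolis moves for the stick-breaking sampler.

The stick-breaking prior is not invariant to cluster relabelling: it
weakly orders the weights (``E[psi_c] > E[psi_{c+1}]``), so a correctly
mixing chain must visit label orderings according to their posterior
weight, which one-at-a-time allocation updates almost never do.  Three
Metropolis moves address this:

1. exchange the labels (allocations and parameters) of two randomly
   chosen clusters, leaving the weights in place;
2. exchange the labels of two neighbouring clusters together with their
   sticks ``V_c, V_{c+1}``;
3. a weight-matched neighbour swap: exchange labels and simultaneously
   propose new weights near their conditional expectation given the
   proposed allocations, redistributing ``psi_c + psi_{c+1}`` between the
   pair.

Moves 1-2 are accepted with the exact joint-density Metropolis ratio
computed by differencing :func:`stickdpm.model_core.joint_log_density`
(the known closed forms serve as cross-checks in the test suite, not as
the implementation).  Move 3 uses its closed-form ratio R, computed in
log space.
"""

from __future__ import annotations

import warnings

import numpy as np

from .model_core import (
    Dataset,
    MixtureState,
    PriorSpec,
    expected_weight_given_Z,
    joint_log_density,
    stick_weights,
)

__all__ = [
    "move1_swap_random_labels",
    "move2_swap_neighbour_sticks",
    "move3_acceptance_ratio",
    "move3_weight_matched_swap",
    "write_acceptance_csv",
]


def _swap_allocations(state: MixtureState, c1: int, c2: int) -> None:
    m1 = state.Z == c1
    state.Z[state.Z == c2] = c1
    state.Z[m1] = c2


def _refresh_slice(state: MixtureState, labels: tuple[int, ...],
                   rng: np.random.Generator) -> None:
    # Gibbs refresh of u_i for subjects whose component weight changed,
    # restoring u_i < psi_{Z_i} after an accepted move.
    affected = np.isin(state.Z, labels)
    if affected.any():
        state.u[affected] = rng.uniform(0.0, state.psi[state.Z[affected]])


def move1_swap_random_labels(state: MixtureState, data: Dataset, priors: PriorSpec,
                             rng: np.random.Generator,
                             occupied_only: bool = False) -> bool | None:
    """Exchange two random cluster labels, weights left in place.

    The pair is drawn uniformly from the labels up to the highest
    occupied one, ``Z* = max_i Z_i`` (``occupied_only=True`` restricts to
    non-empty clusters).  A swap of the occupied top label with an empty
    one would lower Z* and shrink the represented stick set, a proposal
    whose reverse cannot be generated; such proposals are rejected
    outright so the kernel stays reversible.  Returns the acceptance
    flag, or ``None`` when fewer than two labels exist.
    """
    z_star = state.z_star
    if z_star < 2:
        return None
    if occupied_only:
        pool = np.unique(state.Z)
        if len(pool) < 2:
            return None
        c1, c2 = rng.choice(pool, size=2, replace=False)
    else:
        c1, c2 = rng.choice(z_star, size=2, replace=False)
    c1, c2 = int(min(c1, c2)), int(max(c1, c2))
    counts = state.counts(z_star)
    if c2 == z_star - 1 and counts[c1] == 0:
        return False  # would lower Z*: irreversible, auto-reject

    log_cur = joint_log_density(state, data, priors, include_invariant=False)
    _swap_allocations(state, c1, c2)
    state.components[c1], state.components[c2] = \
        state.components[c2], state.components[c1]
    log_new = joint_log_density(state, data, priors, include_invariant=False)
    if np.log(rng.uniform()) < log_new - log_cur:
        _refresh_slice(state, (c1, c2), rng)
        return True
    state.components[c1], state.components[c2] = \
        state.components[c2], state.components[c1]
    _swap_allocations(state, c1, c2)
    return False


def move2_swap_neighbour_sticks(state: MixtureState, data: Dataset,
                                priors: PriorSpec,
                                rng: np.random.Generator) -> bool | None:
    """Exchange two neighbouring labels together with their sticks.

    ``c`` is drawn uniformly from the labels up to ``Z* = max_i Z_i``;
    when the top label is chosen its neighbour is the first component
    beyond the representation, materialised from the stick prior
    ``Beta(1, alpha)``.  Swapping ``V_c`` and ``V_{c+1}`` leaves
    ``(1-V_c)(1-V_{c+1})`` and hence all downstream weights unchanged.
    The swap can raise or lower Z* (a swap into an empty lower slot is
    always accepted), so the acceptance ratio carries the pool-size
    Hastings factor ``Z*/Z*'`` alongside the joint-density ratio; the
    materialised stick's prior density cancels against the proposal.
    """
    z_star = state.z_star
    if z_star < 1:
        return None
    # the pool must include Z* = 1 (single occupied label): the pair
    # (1, 2) with a materialised stick is the reverse of swaps that empty
    # label 2, and dropping it would unbalance the kernel
    c = int(rng.integers(z_star))
    created = False
    if c + 1 == state.C:  # pair reaches one beyond the represented sticks
        state.V = np.append(state.V, np.clip(rng.beta(1.0, state.alpha),
                                             1e-12, 1 - 1e-12))
        state.psi = stick_weights(state.V)
        from .sampler import _draw_component
        state.components.append(_draw_component(data, priors, rng))
        created = True

    def apply() -> None:
        _swap_allocations(state, c, c + 1)
        state.components[c], state.components[c + 1] = \
            state.components[c + 1], state.components[c]
        state.V[c], state.V[c + 1] = state.V[c + 1], state.V[c]
        state.psi = stick_weights(state.V)

    log_cur = joint_log_density(state, data, priors, include_invariant=False)
    apply()
    log_new = joint_log_density(state, data, priors, include_invariant=False)
    log_ratio = log_new - log_cur + np.log(z_star) - np.log(state.z_star)
    if np.log(rng.uniform()) < log_ratio:
        _refresh_slice(state, (c, c + 1), rng)
        return True
    apply()
    if created:
        state.V = state.V[:-1]
        state.psi = stick_weights(state.V)
        state.components.pop()
    return False


def _log_move3_ratio(n_c: float, n_c1: float, tail: float, alpha: float,
                     psi_c: float, psi_c1: float) -> float:
    if min(n_c, n_c1, tail) < 0:
        raise ValueError("cluster counts must be non-negative")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if psi_c <= 0 or psi_c1 <= 0:
        raise ValueError("weights must be strictly positive")
    log_r1 = np.log1p(1.0 / (alpha + n_c1 + tail))
    log_r2 = -np.log1p(1.0 / (alpha + n_c + tail))
    psi_plus = psi_c + psi_c1
    denom = psi_c1 * np.exp(log_r1) + psi_c * np.exp(log_r2)
    return float((n_c + n_c1) * (np.log(psi_plus) - np.log(denom))
                 + n_c1 * log_r1 + n_c * log_r2)


def move3_acceptance_ratio(n_c: float, n_c1: float, tail: float, alpha: float,
                           psi_c: float, psi_c1: float) -> float:
    """Closed-form acceptance ratio R of the weight-matched swap.

    With ``R1 = (1+alpha+n_{c+1}+T)/(alpha+n_{c+1}+T)`` and
    ``R2 = (alpha+n_c+T)/(1+alpha+n_c+T)`` where ``T`` is the total count
    beyond label c+1,

        R = (psi+ / (psi_{c+1} R1 + psi_c R2))^(n_c+n_{c+1})
            * R1^{n_{c+1}} * R2^{n_c},

    evaluated in log space.  Acceptance probability is ``min(1, R)``.
    """
    return float(np.exp(_log_move3_ratio(n_c, n_c1, tail, alpha, psi_c, psi_c1)))


def move3_weight_matched_swap(state: MixtureState, data: Dataset,
                              priors: PriorSpec,
                              rng: np.random.Generator) -> bool | None:
    """Neighbour label swap with weights moved toward their conditional mean.

    Picks ``c`` uniformly below the highest occupied label, proposes the
    allocation and parameter exchange of the neighbouring pair, and new
    weights ``psi'_c, psi'_{c+1}`` proportional to
    ``psi_{c+1} E[psi_c | Z', alpha]/E[psi_{c+1} | Z, alpha]`` (and
    symmetrically), rescaled so the pair's total weight is conserved; the
    sticks of the pair are back-solved from the new weights.  Accepted
    with probability ``min(1, R)``.
    """
    z_star = state.z_star
    if z_star < 2:
        return None
    c = int(rng.integers(z_star - 1))
    counts = state.counts().astype(np.float64)
    n_c, n_c1 = counts[c], counts[c + 1]
    if c + 1 == z_star - 1 and n_c == 0:
        return False  # would empty the top label and lower Z*: auto-reject
    tail = float(counts[c + 2:].sum())
    psi_c, psi_c1 = float(state.psi[c]), float(state.psi[c + 1])

    prefix = float(np.prod(1.0 - state.V[:c]))
    if prefix <= 0.0:
        warnings.warn("weight-matched swap rejected: no stick mass left "
                      "before the chosen pair")
        return False

    counts_prop = counts.copy()
    counts_prop[c], counts_prop[c + 1] = n_c1, n_c
    e1 = (expected_weight_given_Z(c, counts_prop, state.alpha)
          / expected_weight_given_Z(c + 1, counts, state.alpha))
    e2 = (expected_weight_given_Z(c + 1, counts_prop, state.alpha)
          / expected_weight_given_Z(c, counts, state.alpha))
    psi_plus = psi_c + psi_c1
    norm = psi_c1 * e1 + psi_c * e2
    psi_c_new = psi_c1 * psi_plus * e1 / norm
    psi_c1_new = psi_c * psi_plus * e2 / norm

    # The closed-form R is the density ratio of the allocation terms; the
    # weight proposal is a deterministic map of (V_c, V_{c+1}), so exact
    # detailed balance additionally needs its change-of-variables factor
    # |J| = e1 e2 (psi+/Psi')^2 (P - psi_c)/(P - psi'_c), with P the
    # stick mass remaining before the pair.
    log_R = _log_move3_ratio(n_c, n_c1, tail, state.alpha, psi_c, psi_c1)
    log_jac = (np.log(e1) + np.log(e2) + 2.0 * (np.log(psi_plus) - np.log(norm))
               + np.log(prefix - psi_c) - np.log(prefix - psi_c_new))
    if np.log(rng.uniform()) >= log_R + log_jac:
        return False

    _swap_allocations(state, c, c + 1)
    state.components[c], state.components[c + 1] = \
        state.components[c + 1], state.components[c]
    v_c = min(psi_c_new / prefix, 1.0 - 1e-12)
    v_c1 = min(psi_c1_new / ((1.0 - v_c) * prefix), 1.0 - 1e-12)
    state.V[c], state.V[c + 1] = v_c, v_c1
    state.psi = stick_weights(state.V)
    _refresh_slice(state, (c, c + 1), rng)
    return True


def write_acceptance_csv(chain, path, window: int = 500) -> None:
    """Write per-window move acceptance rates in long form.

    Columns: window start sweep, move id (1-3), acceptance rate over the
    window (empty when the move was never attempted).
    """
    import pandas as pd

    table = chain.acceptance_table(window)
    rows = [{"window_start": int(r[0]), "move": m + 1, "rate": r[1 + m]}
            for r in table for m in range(3)]
    pd.DataFrame(rows).to_csv(path, index=False)
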