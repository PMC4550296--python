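"""Post-processing of chain output into label-invariant summaries.

Everything here depends on the allocations only through which subjects
are co-clustered, so arbitrary relabelling of clusters between sweeps
(nuisance label-switching) cannot affect the results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .model_core import Partition

__all__ = [
    "SimilarityMatrix",
    "similarity_matrix",
    "binder_score",
    "optimal_partition",
    "predict_response",
]


@dataclass
class SimilarityMatrix:
    """n x n posterior co-clustering probabilities, diagonal exactly 1."""

    matrix: np.ndarray
    n_sweeps: int

    def __post_init__(self) -> None:
        M = np.asarray(self.matrix, dtype=np.float64)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValueError("similarity matrix must be square")
        if not np.allclose(M, M.T) or M.min() < 0 or M.max() > 1:
            raise ValueError("similarities must be symmetric probabilities")
        self.matrix = M

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def similarity_matrix(alloc_samples: np.ndarray, chunk: int = 64) -> SimilarityMatrix:
    """Empirical co-clustering probabilities S_ij across kept sweeps.

    ``S_ij`` is the fraction of sweeps with ``Z_i = Z_j``; computed in
    sweep chunks to bound memory at ``chunk * n^2``.
    """
    Z = np.asarray(alloc_samples, dtype=np.int64)
    if Z.ndim != 2 or Z.shape[0] < 1:
        raise ValueError("need a (sweeps, n) allocation array with >= 1 sweep")
    S, n = Z.shape
    acc = np.zeros((n, n))
    for start in range(0, S, chunk):
        blk = Z[start:start + chunk]
        acc += (blk[:, :, None] == blk[:, None, :]).sum(axis=0)
    M = acc / S
    np.fill_diagonal(M, 1.0)
    return SimilarityMatrix(matrix=M, n_sweeps=S)


def binder_score(S: SimilarityMatrix, Z: np.ndarray, threshold: float = 0.5) -> float:
    """Binder-type partition score sum_{i<j co-clustered} (S_ij - threshold).

    Maximising this trades off pairs that should be together
    (``S_ij > threshold``) against pairs forced together wrongly.
    """
    Z = np.asarray(Z)
    same = Z[:, None] == Z[None, :]
    iu = np.triu_indices(len(Z), k=1)
    return float(((S.matrix - threshold)[iu])[same[iu]].sum())


def _kmedoids(D: np.ndarray, k: int, rng: np.random.Generator,
              max_iter: int = 100) -> np.ndarray:
    """Alternating k-medoids on a dissimilarity matrix (seeded, deterministic)."""
    n = D.shape[0]
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d = D[:, medoids].min(axis=1) ** 2
        total = d.sum()
        if total <= 0:
            pool = np.setdiff1d(np.arange(n), medoids)
            medoids.append(int(rng.choice(pool)))
        else:
            medoids.append(int(rng.choice(n, p=d / total)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            idx = np.flatnonzero(assign == c)
            if len(idx):
                new[c] = idx[np.argmin(D[np.ix_(idx, idx)].sum(axis=0))]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    return np.argmin(D[:, medoids], axis=1)


def optimal_partition(S: SimilarityMatrix, k_max: int, seed: int = 0,
                      threshold: float = 0.5) -> Partition:
    """Best-scoring representative partition from the similarity matrix.

    Runs k-medoids on dissimilarity ``1 - S`` for each candidate number
    of clusters ``k = 1..k_max`` and returns the candidate maximising the
    Binder-type pairwise score.  The optimum need not equal any sampled
    partition.  A sensible ``k_max`` is the largest number of occupied
    clusters seen in the chain plus a small margin.
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    rng = np.random.default_rng(seed)
    D = 1.0 - S.matrix
    best: tuple[float, np.ndarray] | None = None
    for k in range(1, min(k_max, S.n) + 1):
        Z = np.zeros(S.n, dtype=np.int64) if k == 1 else _kmedoids(D, k, rng)
        score = binder_score(S, Z, threshold)
        if best is None or score > best[0]:
            best = (score, Z)
    return Partition(best[1])


def predict_response(new_X: np.ndarray, new_W: np.ndarray | None, chain) -> np.ndarray:
    """Rao-Blackwellised posterior predictive probabilities P(Y*=1 | x*, w*).

    Per kept sweep, a new profile's cluster membership is averaged
    probabilistically: ``w_c ∝ psi_c * f_X(x* | Phi_c)`` over the
    represented components (renormalised), and the prediction is
    ``sum_c w_c expit(theta_c + beta' w*)``; the final estimate averages
    over sweeps.  Requires a chain run with parameter storage enabled.
    """
    if chain.params is None:
        raise ValueError("chain has no stored parameters; rerun the sampler "
                         "with store_params=True to enable prediction")
    new_X = np.asarray(new_X, dtype=np.int64)
    m = new_X.shape[0]
    preds = np.zeros(m)
    for rec in chain.params:
        psi, theta, phi, beta = rec["psi"], rec["theta"], rec["phi"], rec["beta"]
        C = len(psi)
        logw = np.empty((m, C))
        for c in range(C):
            acc = np.log(psi[c])
            row = np.zeros(m)
            for j in range(new_X.shape[1]):
                with np.errstate(divide="ignore"):
                    row += np.log(phi[c][j])[new_X[:, j]]
            logw[:, c] = acc + row
        logw -= logw.max(axis=1, keepdims=True)
        w = np.exp(logw)
        w /= w.sum(axis=1, keepdims=True)
        offset = new_W @ beta if (new_W is not None and len(beta)) else 0.0
        preds += (w * expit(theta[None, :C] + np.atleast_1d(offset)[:, None])).sum(axis=1)
    return preds / len(chain.params)
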