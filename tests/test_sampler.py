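import numpy as np
import pytest
from scipy.stats import gamma as gamma_dist, kstest, t as t_dist

from stickdpm import Dataset, PriorSpec, SamplerConfig, init_state, run_chain
from stickdpm.sampler import (
    update_alpha,
    update_beta,
    update_phi,
    update_slice_and_allocations,
    update_sticks,
    update_theta,
)


def _empty_dataset(n=0):
    return Dataset(X=np.zeros((n, 0), dtype=int), K=np.zeros(0, dtype=int))


class TestInit:
    def test_single_cluster(self, tiny_data, flat_priors, rng):
        cfg = SamplerConfig(n_init_clusters=1)
        st = init_state(tiny_data, flat_priors, cfg, rng)
        assert np.all(st.Z == 0)
        st.validate()

    def test_balanced_round_robin(self, flat_priors, rng):
        data = Dataset(X=np.zeros((10, 1), dtype=int), K=np.array([1]))
        cfg = SamplerConfig(n_init_clusters=5)
        st = init_state(data, flat_priors, cfg, rng)
        assert np.array_equal(np.bincount(st.Z), np.full(5, 2))

    def test_deterministic(self, tiny_data, flat_priors):
        s1 = init_state(tiny_data, flat_priors,
                        SamplerConfig(n_init_clusters=3, seed=4),
                        np.random.default_rng(11))
        s2 = init_state(tiny_data, flat_priors,
                        SamplerConfig(n_init_clusters=3, seed=4),
                        np.random.default_rng(11))
        assert np.array_equal(s1.Z, s2.Z) and np.array_equal(s1.V, s2.V)

    def test_too_many_clusters(self, tiny_data, flat_priors, rng):
        with pytest.raises(ValueError):
            init_state(tiny_data, flat_priors, SamplerConfig(n_init_clusters=7), rng)


class TestBlocks:
    def test_allocation_conditional(self, flat_priors, rng):
        """A subject facing a 1e6 likelihood ratio essentially never lands in
        the wrong component."""
        data = Dataset(X=np.zeros((1, 1), dtype=int), K=np.array([2]))
        from stickdpm.model_core import ComponentParams, MixtureState, stick_weights
        wrong = 0
        for _ in range(400):
            V = np.array([0.5, 0.98])
            st = MixtureState(
                V=V, psi=stick_weights(V),
                components=[ComponentParams(phi=[np.array([1 - 1e-6, 1e-6])]),
                            ComponentParams(phi=[np.array([1e-6, 1 - 1e-6])])],
                beta=np.zeros(0), Z=np.array([0]), u=np.array([0.1]), alpha=1.0)
            st = update_slice_and_allocations(st, data, flat_priors, rng)
            wrong += int(st.Z[0] == 1)
        assert wrong <= 1

    def test_slice_marginalisation(self, flat_priors, rng):
        """Holding (psi, Theta) fixed, the stationary distribution of the
        repeated slice/allocation update is P(Z=c) ∝ psi_c f(D|Theta_c)."""
        data = Dataset(X=np.array([[0]]), K=np.array([2]))
        from stickdpm.model_core import ComponentParams, MixtureState, stick_weights
        V = np.array([0.4, 0.999])  # nearly the whole stick: extensions rare
        comps = [ComponentParams(phi=[np.array([0.7, 0.3])]),
                 ComponentParams(phi=[np.array([0.2, 0.8])])]
        psi = stick_weights(V)
        target = psi[:2] * np.array([0.7, 0.2])
        target /= target.sum()
        hits = np.zeros(2)
        n_rep = 20_000
        z = 0
        for _ in range(n_rep):
            st = MixtureState(V=V.copy(), psi=psi.copy(),
                              components=list(comps), beta=np.zeros(0),
                              Z=np.array([z]), u=np.array([0.05]), alpha=1.0)
            st = update_slice_and_allocations(st, data, flat_priors, rng)
            z = int(st.Z[0]) if st.Z[0] < 2 else 0
            hits[z] += 1
        freq = hits / hits.sum()
        se = np.sqrt(target * (1 - target) / n_rep)
        assert np.all(np.abs(freq - target) < 4 * se + 0.005)

    def test_stick_posterior_mean(self, flat_priors, rng):
        """counts=(5,0), alpha=1 gives E[V_1 | Z] = 6/7."""
        from stickdpm.model_core import ComponentParams, MixtureState, stick_weights
        V = np.array([0.5, 0.5])
        st = MixtureState(V=V, psi=stick_weights(V),
                          components=[ComponentParams(phi=[]) for _ in range(2)],
                          beta=np.zeros(0), Z=np.zeros(5, dtype=int),
                          u=np.full(5, 0.01), alpha=1.0)
        draws = []
        for _ in range(20_000):
            st = update_sticks(st, rng)
            draws.append(st.V[0])
        assert abs(np.mean(draws) - 6 / 7) < 0.005

    def test_phi_conjugate_update(self, flat_priors, rng):
        """Cluster category counts (3,0) with a flat prior give
        Dirichlet(4,1), mean (0.8, 0.2); empty clusters redraw the prior."""
        data = Dataset(X=np.zeros((3, 1), dtype=int), K=np.array([2]))
        from stickdpm.model_core import ComponentParams, MixtureState, stick_weights
        V = np.array([0.5, 0.5])
        st = MixtureState(V=V, psi=stick_weights(V),
                          components=[ComponentParams(phi=[np.ones(2) / 2])
                                      for _ in range(2)],
                          beta=np.zeros(0), Z=np.zeros(3, dtype=int),
                          u=np.full(3, 0.01), alpha=1.0)
        occ, emp = [], []
        for _ in range(20_000):
            st = update_phi(st, data, flat_priors, rng)
            occ.append(st.components[0].phi[0][0])
            emp.append(st.components[1].phi[0][0])
        assert abs(np.mean(occ) - 0.8) < 0.005
        assert abs(np.mean(emp) - 0.5) < 0.01

    def test_response_updates_noop_without_y(self, tiny_data, flat_priors, rng):
        st = init_state(tiny_data, flat_priors, SamplerConfig(n_init_clusters=2), rng)
        assert update_theta(st, tiny_data, flat_priors, rng) == (0, 0)
        assert update_beta(st, tiny_data, flat_priors, rng) == (0, 0)

    def test_alpha_fixed_unchanged(self, tiny_data, flat_priors, rng):
        st = init_state(tiny_data, flat_priors, SamplerConfig(n_init_clusters=2), rng)
        a0 = st.alpha
        for _ in range(10):
            update_alpha(st, flat_priors, rng)
        assert st.alpha == a0


class TestPriorReproduction:
    def test_alpha_and_stick_marginals(self):
        """With no data the Gibbs blocks must reproduce the prior: alpha
        marginally Gamma(9, 0.5) and V_1 marginally Beta(1, alpha)-mixed."""
        priors = PriorSpec(alpha_shape=9.0, alpha_rate=0.5)
        data = _empty_dataset(0)
        cfg = SamplerConfig(n_init_clusters=3, n_burn=200, n_keep=10_000,
                            seed=9, moves_enabled=(False, False, False))
        rng = np.random.default_rng(cfg.seed)
        st = init_state(data, priors, cfg, rng)
        alphas, v1 = [], []
        for _ in range(cfg.n_burn + cfg.n_keep):
            st = update_sticks(st, rng)
            st = update_alpha(st, priors, rng)
            alphas.append(st.alpha)
            v1.append(st.V[0])
        alphas = np.array(alphas[cfg.n_burn:])
        ks = kstest(alphas, gamma_dist(a=9.0, scale=2.0).cdf).statistic
        assert ks < 0.02

    def test_theta_prior_reproduction(self, rng):
        """Empty clusters refresh theta from t7(0, 2.5)."""
        data = Dataset(X=np.zeros((2, 1), dtype=int),
                       Y=np.array([0, 1]), K=np.array([1]))
        priors = PriorSpec(alpha_fixed=1.0)
        from stickdpm.model_core import ComponentParams, MixtureState, stick_weights
        V = np.array([0.5, 0.5])
        st = MixtureState(V=V, psi=stick_weights(V),
                          components=[ComponentParams(phi=[np.ones(1)], theta=0.0)
                                      for _ in range(2)],
                          beta=np.zeros(0), Z=np.zeros(2, dtype=int),
                          u=np.full(2, 0.01), alpha=1.0)
        draws = []
        for _ in range(8000):
            update_theta(st, data, priors, rng, scale=0.5)
            draws.append(st.components[1].theta)
        ks = kstest(np.array(draws), t_dist(df=7, scale=2.5).cdf).statistic
        assert ks < 0.02


class TestRunChain:
    def test_empty_keep(self, tiny_data, flat_priors):
        ch = run_chain(tiny_data, flat_priors, SamplerConfig(
            n_init_clusters=2, n_burn=5, n_keep=0, seed=1))
        assert ch.Z.shape == (0, tiny_data.n)

    def test_determinism(self, tiny_data, flat_priors):
        cfg = SamplerConfig(n_init_clusters=3, n_burn=20, n_keep=30, seed=123)
        c1 = run_chain(tiny_data, flat_priors, cfg)
        c2 = run_chain(tiny_data, flat_priors, cfg)
        assert np.array_equal(c1.Z, c2.Z)
        assert np.array_equal(c1.alpha, c2.alpha)
        assert np.array_equal(c1.loglik, c2.loglik)

    def test_state_invariants_every_sweep(self, response_data, rng):
        """All MixtureState invariants hold after each full sweep, with all
        moves enabled and alpha sampled."""
        priors = PriorSpec()
        cfg = SamplerConfig(n_init_clusters=4, seed=2)
        from stickdpm import label_switching as ls
        st = init_state(response_data, priors, cfg, rng)
        scales = [0.5, 0.2]
        for _ in range(60):
            st = update_slice_and_allocations(st, response_data, priors, rng)
            st = update_sticks(st, rng)
            st = update_phi(st, response_data, priors, rng)
            update_theta(st, response_data, priors, rng, scales[0])
            update_beta(st, response_data, priors, rng, scales[1])
            st = update_alpha(st, priors, rng)
            ls.move1_swap_random_labels(st, response_data, priors, rng)
            ls.move2_swap_neighbour_sticks(st, response_data, priors, rng)
            ls.move3_weight_matched_swap(st, response_data, priors, rng)
            st.validate()

    def test_adaptation_lands_in_band(self, response_data):
        """Post-burn-in random-walk acceptance rates sit in (0.2, 0.6)."""
        priors = PriorSpec()
        cfg = SamplerConfig(n_init_clusters=2, n_burn=800, n_keep=400, seed=5,
                            moves_enabled=(False, False, False))
        rng = np.random.default_rng(cfg.seed)
        st = init_state(response_data, priors, cfg, rng)
        scales = [0.5, 0.2]
        acc = np.zeros(2)
        att = np.zeros(2)
        for sweep in range(cfg.n_burn + cfg.n_keep):
            st = update_slice_and_allocations(st, response_data, priors, rng)
            st = update_sticks(st, rng)
            st = update_phi(st, response_data, priors, rng)
            at = update_theta(st, response_data, priors, rng, scales[0])
            ab = update_beta(st, response_data, priors, rng, scales[1])
            if sweep < cfg.n_burn:
                step = (sweep + 1) ** -0.6
                for k, (targ, (na, nat)) in enumerate(((0.44, at), (0.23, ab))):
                    if nat:
                        scales[k] = float(np.exp(np.log(scales[k])
                                                 + step * (na / nat - targ)))
            else:
                acc += [at[0], ab[0]]
                att += [at[1], ab[1]]
        rates = acc / att
        assert np.all(rates > 0.2) and np.all(rates < 0.6)
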