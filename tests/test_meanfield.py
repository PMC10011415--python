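import numpy as np
import pytest

import hypermass as hm
from hypermass.meanfield import integrate_steady


class TestPoissonBinomial:
    def test_certainty(self):
        pmf = hm.poisson_binomial_enum([1.0, 1.0])
        assert pmf[2] == pytest.approx(1.0)

    def test_hand_enumeration(self):
        pmf = hm.poisson_binomial_enum([0.2, 0.5, 0.7])
        assert pmf[0] == pytest.approx(0.8 * 0.5 * 0.3)
        assert pmf.sum() == pytest.approx(1.0)

    def test_empty_vector(self):
        assert hm.poisson_binomial_enum([])[0] == 1.0
        assert hm.poisson_binomial_dft([])[0] == 1.0

    def test_enum_refuses_long_vectors(self):
        with pytest.raises(ValueError):
            hm.poisson_binomial_enum(np.full(21, 0.5))

    def test_dft_symmetric_binomial(self):
        assert hm.poisson_binomial_dft([0.5, 0.5]) == pytest.approx([0.25, 0.5, 0.25])

    def test_dft_all_zero(self):
        pmf = hm.poisson_binomial_dft(np.zeros(7))
        assert pmf[0] == pytest.approx(1.0)

    def test_domain_check(self):
        with pytest.raises(ValueError):
            hm.poisson_binomial_dft([0.5, 1.2])


class TestOdeRhs:
    def test_absorbing_fixed_point(self, small_blob, default_params):
        y = np.zeros(20)
        assert np.all(hm.ode_rhs(y, small_blob, default_params) == 0.0)

    def test_all_active_pure_decay(self, small_blob, default_params):
        y = np.ones(20)
        assert hm.ode_rhs(y, small_blob, default_params) == pytest.approx(
            np.full(20, -default_params.delta)
        )

    def test_pairwise_reduces_to_quenched_sis(self):
        rng = np.random.default_rng(1)
        import networkx as nx

        G = nx.random_regular_graph(4, 16, seed=3)
        H = hm.Hypergraph(sorted(tuple(sorted(e)) for e in G.edges()), node_count=16)
        p = hm.DynamicsParameters(lam=0.3, delta=1.2, theta_star=0.5)
        y = rng.random(16)
        A = (hm.projected_adjacency(H) > 0).astype(float)
        expected = -1.2 * y + 0.3 * (1 - y) * (A @ y)
        assert hm.ode_rhs(y, H, p) == pytest.approx(expected)

    def test_dimension_mismatch(self, small_blob, default_params):
        with pytest.raises(ValueError):
            hm.ode_rhs(np.zeros(5), small_blob, default_params)

    def test_flow_stays_in_unit_box(self, small_blob, default_params):
        """rhs points inward on the boundary faces of [0,1]^N."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            y = rng.random(20)
            i = rng.integers(20)
            y0 = y.copy()
            y0[i] = 0.0
            assert hm.ode_rhs(y0, small_blob, default_params)[i] >= 0.0
            y1 = y.copy()
            y1[i] = 1.0
            assert hm.ode_rhs(y1, small_blob, default_params)[i] <= 0.0


class TestIntegrateSteady:
    def test_zero_converges_immediately(self, small_blob, default_params):
        st = integrate_steady(np.zeros(20), small_blob, default_params)
        assert st.converged and st.rho == 0.0

    def test_upper_steady_state_residual(self, small_blob):
        p = hm.DynamicsParameters(lam=0.5, delta=1.0, theta_star=0.2)
        st = integrate_steady(np.ones(20), small_blob, p)
        assert st.converged
        assert np.abs(hm.ode_rhs(st.y, small_blob, p)).max() < 1e-8
        assert st.rho > 0.5

    def test_reproducible_under_tighter_tolerance(self, small_blob):
        p = hm.DynamicsParameters(lam=0.5, delta=1.0, theta_star=0.2)
        a = integrate_steady(np.ones(20), small_blob, p, residual_tol=1e-8)
        b = integrate_steady(np.ones(20), small_blob, p, residual_tol=1e-9)
        assert np.abs(a.y - b.y).max() < 1e-7

    def test_ode_overestimates_exact_chain(self):
        """On the homogeneous hyperblob the mean-field steady state sits at
        or slightly above the exact QS expectation."""
        from hypermass.blobchain import BlobChainParams, chain_summary, stationary_pi

        N, lam_k, lam_star = 40, 1.8, 5.0
        H = hm.make_hyperblob(N, N - 1, seed=2)
        lam = lam_k / N
        p = hm.DynamicsParameters(
            lam=lam,
            delta=1.0,
            theta_star=0.2,
            modulation=lambda c: 1.0 if c == 2 else lam_star / lam,
        )
        st = integrate_steady(np.ones(N), H, p)
        exact = chain_summary(
            stationary_pi(BlobChainParams(N=N, lam_k=lam_k, lam_star=lam_star, theta_star=0.2))
        )
        assert st.converged
        assert st.rho >= exact["rho"] - 0.02


class TestBranchContinuation:
    def test_absorbing_seed_stays_absorbing(self, small_blob, default_params):
        traces = hm.branch_continuation(
            small_blob,
            default_params,
            [0.1, 0.2, 0.3],
            seed_state=np.zeros(20),
            directions=("up",),
        )
        assert traces[0].rhos == pytest.approx([0.0, 0.0])  # merges after repeat

    def test_distinct_seeds_give_distinct_traces(self, community_small):
        """Seeding from one active community vs all-active uncovers two
        separated branches over a shared lambda window."""
        N = community_small.node_count
        p = hm.DynamicsParameters(lam=0.1, delta=1.0, theta_star=0.5)
        grid = [0.1, 0.12, 0.14]
        c1 = np.zeros(N)
        c1[: N // 2] = 1.0
        t_all = hm.branch_continuation(
            community_small, p, grid, np.ones(N), directions=("up",), seed_lambda=0.1
        )[0]
        t_c1 = hm.branch_continuation(
            community_small, p, grid, c1, directions=("up",), seed_lambda=0.1
        )[0]
        shared = min(len(t_all.rhos), len(t_c1.rhos))
        assert shared >= 1
        gaps = [abs(a - b) for a, b in zip(t_all.rhos[:shared], t_c1.rhos[:shared])]
        assert max(gaps) > 5.0 / N


class TestProperties:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.0, 1.0), min_size=0, max_size=10))
    def test_dft_always_matches_enumeration(self, probs):
        a = hm.poisson_binomial_enum(probs)
        b = hm.poisson_binomial_dft(probs)
        assert np.abs(a - b).max() < 1e-10
        assert b.sum() == pytest.approx(1.0)
        assert np.all(b >= 0)
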