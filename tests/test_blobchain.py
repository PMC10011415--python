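import numpy as np
import pytest
import scipy.sparse as sp

import hypermass as hm
from hypermass.blobchain import BlobChainParams, fit_power_law


@pytest.fixture
def params60():
    return BlobChainParams(N=60, lam_k=1.5, lam_star=5.0, delta=1.0, theta_star=0.2)


class TestGenerator:
    def test_death_rate_entry(self, params60):
        Q = hm.build_generator(params60).toarray()
        assert Q[3, 2] == pytest.approx(3.0)

    def test_qs_constraint(self, params60):
        Q = hm.build_generator(params60).toarray()
        assert Q[1, 0] == 0.0
        Qfree = hm.build_generator(params60.replace(qs=False)).toarray()
        assert Qfree[1, 0] == pytest.approx(1.0)

    def test_rows_sum_to_zero(self, params60):
        Q = hm.build_generator(params60)
        assert np.abs(np.asarray(Q.sum(axis=1)).ravel()).max() < 1e-12

    def test_jump_adds_to_birth_at_penultimate_state(self, params60):
        N = params60.N
        Q = hm.build_generator(params60).toarray()
        beta = params60.birth_rates()
        assert Q[N - 1, N] == pytest.approx(beta[N - 1] + params60.lam_star)

    def test_theta_from_fraction(self):
        p = BlobChainParams(N=50, lam_k=1.0, lam_star=1.0, theta_star=0.2)
        assert p.theta == 10

    def test_qs_only_differs_through_state_one(self, params60):
        dq = hm.build_generator(params60).toarray()
        df = hm.build_generator(params60.replace(qs=False)).toarray()
        diff = np.argwhere(dq != df)
        assert set(map(tuple, diff)) <= {(1, 0), (1, 1)}


class TestEvolve:
    def test_conservation(self, params60):
        Q = hm.build_generator(params60)
        P0 = np.zeros(61)
        P0[5] = 1.0
        Pt = hm.evolve(Q, P0, [0.0, 1.0, 10.0])
        assert Pt.sum(axis=1) == pytest.approx(np.ones(3))

    def test_subcritical_absorbs_without_qs(self):
        p = BlobChainParams(N=40, lam_k=0.5, lam_star=0.0, theta_star=0.2, qs=False)
        Q = hm.build_generator(p)
        P0 = np.zeros(41)
        P0[4] = 1.0
        Pt = hm.evolve(Q, P0, [200.0])
        assert Pt[0, 0] > 0.999

    def test_qs_chain_converges_to_stationary(self, params60):
        Q = hm.build_generator(params60)
        P0 = np.zeros(61)
        P0[1] = 1.0
        Pt = hm.evolve(Q, P0, [1000.0])
        pi = hm.stationary_pi(params60).pi
        assert np.abs(Pt[0] - pi).max() < 1e-6

    def test_rejects_unnormalized(self, params60):
        Q = hm.build_generator(params60)
        with pytest.raises(ValueError):
            hm.evolve(Q, np.ones(61), [1.0])


class TestStationary:
    def test_pure_death_point_mass(self):
        p = BlobChainParams(N=30, lam_k=0.0, lam_star=0.0, theta_star=0.5)
        pi = hm.stationary_pi(p).pi
        expected = np.zeros(31)
        expected[1] = 1.0
        assert pi == pytest.approx(expected)

    @pytest.mark.parametrize("N", [20, 100, 500])
    def test_recursion_matches_nullspace(self, N):
        p = BlobChainParams(N=N, lam_k=1.2, lam_star=5.0, theta_star=0.2)
        d1 = hm.stationary_pi(p)
        d2 = hm.stationary_nullspace(hm.build_generator(p), theta=p.theta)
        assert np.abs(d1.pi - d2.pi).max() < 1e-8

    def test_sis_limit_birth_death_product(self):
        """lam_star = 0 reduces to the QS-SIS birth-death chain with the
        closed-form product stationary distribution."""
        p = BlobChainParams(N=120, lam_k=1.6, lam_star=0.0, theta_star=0.2)
        pi = hm.stationary_pi(p).pi
        beta = p.birth_rates()
        ref = np.zeros(121)
        ref[1] = 1.0
        for n in range(1, 120):
            ref[n + 1] = ref[n] * beta[n] / (p.delta * (n + 1))
        ref /= ref.sum()
        assert np.abs(pi - ref).max() < 1e-12

    def test_stationarity_residual(self, params60):
        pi = hm.stationary_pi(params60).pi
        Q = hm.build_generator(params60)
        assert np.abs(Q.T @ pi).max() < 1e-8

    def test_two_state_toy_nullspace(self):
        a, b = 0.7, 0.3
        Q = sp.csr_matrix(np.array([[-a, a], [b, -b]]))
        d = hm.stationary_nullspace(Q)
        assert d.pi == pytest.approx([b / (a + b), a / (a + b)])

    def test_all_zero_generator_degenerate(self):
        with pytest.raises(np.linalg.LinAlgError):
            hm.stationary_nullspace(sp.csr_matrix((3, 3)))


class TestChainSummary:
    def test_partition(self, params60):
        d = hm.stationary_pi(params60)
        s = hm.chain_summary(d, params60)
        assert s["p_lower"] + s["p_upper"] == pytest.approx(1.0)

    def test_hand_built_split(self):
        pi = np.zeros(5)
        pi[1] = pi[4] = 0.5
        d = hm.StationaryDistribution(pi=pi, theta=3)
        s = hm.chain_summary(d)
        assert s["p_lower"] == pytest.approx(0.5)
        assert s["p_upper"] == pytest.approx(0.5)
        assert s["rho"] == pytest.approx(2.5 / 4)

    def test_empty_region_is_nan(self):
        pi = np.zeros(5)
        pi[1] = 1.0
        d = hm.StationaryDistribution(pi=pi, theta=3)
        s = hm.chain_summary(d)
        assert s["p_upper"] == 0.0
        assert np.isnan(s["rho_upper"])


class TestScaling:
    def test_planted_power_law(self):
        Ns = np.array([100, 200, 400, 800, 1600, 3200])
        widths = 2.5 * Ns ** -0.5
        mu, se = fit_power_law(Ns, widths)
        assert mu == pytest.approx(0.5, abs=0.01)

    def test_lower_branch_susceptibility_peak_grows(self):
        """The lower (SIS-like) branch shows a susceptibility peak whose
        height grows with N: the second-order transition signature."""
        heights = []
        for N in (200, 400, 800):
            best = 0.0
            for lam in np.arange(0.85, 1.1, 0.01):
                p = BlobChainParams(N=N, lam_k=float(lam), lam_star=10.0, theta_star=0.2)
                s = hm.chain_summary(hm.stationary_pi(p), p)
                if s["p_lower"] > 0.5 and np.isfinite(s["chi_lower"]):
                    best = max(best, s["chi_lower"])
            heights.append(best)
        assert heights[0] < heights[1] < heights[2]
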