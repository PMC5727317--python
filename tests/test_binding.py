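import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import null_space

import kaisim as ks
from kaisim.binding import (
    binding_rhs,
    free_concentrations,
    rate_matrix,
    rates_from_structure,
)
from kaisim.params import BindingDistribution
from kaisim.states import IDX_CA, N_STATES, STATE_IJ, index_of


def product_form_stationary(rates, A, B):
    """Closed-form stationary law of the frozen-rate binding chain.

    Detailed balance on the (i, j) lattice gives
    pi(i, j) ~ C(6,i) r^i C(i,j) s^j with r = h_B*B/f_B, s = h_BA*A^2/f_BA,
    and pi(C6A2)/pi(0,0) = h_A*A^2/f_A.  Independent of the kinetics code.
    """
    r = rates.h_B * B / rates.f_B
    s = rates.h_BA * A * A / rates.f_BA
    pi = np.zeros(N_STATES)
    for (i, j) in STATE_IJ:
        pi[index_of(i, j)] = math.comb(6, i) * r**i * math.comb(i, j) * s**j
    pi[IDX_CA] = pi[index_of(0, 0)] * rates.h_A * A * A / rates.f_A
    return pi / pi.sum()


class TestRatesFromStructure:
    def test_ground_state_limit(self, defaults):
        r = rates_from_structure(1.0, defaults)
        assert (r.h_A, r.f_A, r.h_B, r.f_B) == (defaults.h_A0, 0.0, 0.0, defaults.f_B0)

    def test_competent_state_limit(self, defaults):
        r = rates_from_structure(0.0, defaults)
        assert (r.h_A, r.f_A, r.h_B, r.f_B) == (0.0, defaults.f_A0, defaults.h_B0, 0.0)

    def test_linearity_at_midpoint(self, defaults):
        r = rates_from_structure(0.5, defaults)
        assert r.h_A == pytest.approx(defaults.h_A0 / 2)
        assert r.f_A == pytest.approx(defaults.f_A0 / 2)
        assert r.h_B == pytest.approx(defaults.h_B0 / 2)
        assert r.f_B == pytest.approx(defaults.f_B0 / 2)
        # KaiA on KaiB does not see the KaiC structure
        assert (r.h_BA, r.f_BA) == (defaults.h_BA, defaults.f_BA)

    def test_rejects_out_of_range(self, defaults):
        with pytest.raises(ValueError):
            rates_from_structure(1.1, defaults)


class TestBindingRhs:
    def test_no_partners_no_flux(self, defaults):
        r = rates_from_structure(0.5, defaults)
        dp = binding_rhs(BindingDistribution.free().probs, 0.0, 0.0, r)
        assert np.all(dp == 0.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.99),
           st.floats(0, 3000), st.floats(0, 30000))
    def test_probability_conservation(self, seed, X, A, B):
        """The master equation moves mass around but never creates it."""
        p = np.random.default_rng(seed).dirichlet(np.ones(N_STATES))
        r = rates_from_structure(X, ks.default_params())
        assert abs(binding_rhs(p, A, B, r).sum()) < 1e-12

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.99))
    def test_nonnegativity_preserved_at_boundary(self, seed, X):
        """States with zero probability can only gain mass."""
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(N_STATES))
        zero = rng.integers(0, N_STATES, size=5)
        p[zero] = 0.0
        p /= p.sum()
        dp = binding_rhs(p, 500.0, 10000.0, rates_from_structure(X, ks.default_params()))
        assert np.all(dp[p == 0.0] >= 0.0)

    @pytest.mark.parametrize("X,A,B", [(0.3, 500.0, 10000.0),
                                       (0.8, 1200.0, 2000.0),
                                       (0.5, 50.0, 25000.0)])
    def test_stationary_distribution_three_routes(self, defaults, X, A, B):
        """Long-time integration = generator null space = product form."""
        rates = rates_from_structure(X, defaults)
        Q = rate_matrix(rates, A, B)
        # route 1: null space of the generator
        ns = null_space(Q)
        assert ns.shape[1] == 1
        pi_null = ns[:, 0] / ns[:, 0].sum()
        # route 2: closed-form detailed-balance solution
        pi_prod = product_form_stationary(rates, A, B)
        # route 3: integrate the kinetics to stationarity
        sol = solve_ivp(
            lambda t, p: binding_rhs(p, A, B, rates), (0.0, 2000.0),
            BindingDistribution.free().probs, method="BDF",
            jac=lambda t, p: Q, rtol=1e-10, atol=1e-14,
        )
        pi_int = sol.y[:, -1]
        assert np.abs(pi_null - pi_prod).max() < 1e-8
        assert np.abs(pi_int - pi_prod).max() < 1e-8

    def test_stationary_kaib_load_increases_with_B(self, defaults):
        rates = rates_from_structure(0.4, defaults)
        loads = []
        for B in (2000.0, 10000.0, 20000.0):
            pi = product_form_stationary(rates, 300.0, B)
            loads.append(sum(i * pi[index_of(i, j)] for (i, j) in STATE_IJ))
        assert loads[0] < loads[1] < loads[2]


class TestFreeConcentrations:
    def test_all_free(self, defaults):
        P = np.tile(BindingDistribution.free().probs, (10, 1))
        A, B = free_concentrations(P, ks.rescale_ensemble(defaults, 10))
        assert A == pytest.approx(defaults.A_T)
        assert B == pytest.approx(defaults.B_T)

    def test_all_sequestered_is_infeasible_at_defaults(self, defaults):
        # C6B6A12 on every hexamer would bind 12*N/V = 12000 KaiA monomers,
        # far beyond A_T = 2000: the totals forbid full occupancy
        p = ks.rescale_ensemble(defaults, 10)
        P = np.tile(BindingDistribution.point((6, 6)).probs, (10, 1))
        with pytest.raises(RuntimeError, match="deficit"):
            free_concentrations(P, p)

    def test_all_in_cii_complex_exhausts_kaia(self, defaults):
        # every hexamer in C6A2 holds one dimer: A = A_T - 2*N/V = 0
        p = ks.rescale_ensemble(defaults, 10)
        P = np.tile(BindingDistribution.point("CA").probs, (10, 1))
        A, B = free_concentrations(P, p)
        assert A == pytest.approx(0.0, abs=1e-9)
        assert B == pytest.approx(defaults.B_T)

    def test_partial_occupancy_arithmetic(self, defaults):
        p = ks.rescale_ensemble(defaults, 4)
        P = np.stack([
            BindingDistribution.point("CA").probs,
            BindingDistribution.point((3, 2)).probs,
            BindingDistribution.point((1, 0)).probs,
            BindingDistribution.free().probs,
        ])
        A, B = free_concentrations(P, p)
        per_hex = p.C6T / 4
        assert A == pytest.approx(p.A_T - 2 * (1 + 2) * per_hex)
        assert B == pytest.approx(p.B_T - (3 + 1) * per_hex)
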