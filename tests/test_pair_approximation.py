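"""Directed-graph pair approximation: identities, steady states, dynamics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st


from crossfeed.biophysics import GrowthModel, LocalRules
from crossfeed.pair_approximation import (
    CompositionProbabilities,
    PairState,
    collapse_interval,
    equilibrium,
    integrate,
    link_change_vectors,
    local_to_global_ratio,
    ode_rhs,
    probabilities_from_links,
    state_from_probabilities,
    steady_state_frequency,
    steady_state_general,
    transition_rates,
    well_mixed_frequency,
)

probs_floats = st.floats(0.0, 1.0)
interior = st.floats(0.05, 0.95)


def rules_of(r_A=3.0, r_B=3.0, mu_A=1.0, mu_B=1.0, model="frequency_linear"):
    return LocalRules(r_A=r_A, r_B=r_B, mu_hat_A=mu_A, mu_hat_B=mu_B,
                      growth_model=model)


def _interior_grid():
    """(rules) combinations with an interior equilibrium, spanning
    ratios 0.1-10 and neighborhood sizes 3-130."""
    out = []
    for ratio in np.logspace(-1, 1, 9):
        for r_a in (3.0, 5.0, 10.0):
            for r_b in (r_a, 30.0, 130.0):
                lo, hi = collapse_interval(r_a, r_b)
                if lo < ratio < hi:
                    out.append(rules_of(r_a, r_b, ratio, 1.0))
    return out


class TestProbabilities:
    def test_all_A_state(self):
        r = rules_of()
        st_ = PairState(N=10, N_AA=30, N_AB=0, N_BA=0, N_BB=0)
        p = probabilities_from_links(st_, r)
        assert (p.P_A, p.P_BgA, p.P_AgB) == (1.0, 0.0, 0.0)

    def test_two_cell_mutual_pair(self):
        r = LocalRules(r_A=1, r_B=1, mu_hat_A=1.0, mu_hat_B=1.0)
        st_ = PairState(N=2, N_AA=0, N_AB=1, N_BA=1, N_BB=0)
        p = probabilities_from_links(st_, r)
        assert (p.P_A, p.P_BgA, p.P_AgB) == (0.5, 1.0, 1.0)

    @given(x=interior, p=probs_floats, s=probs_floats)
    def test_round_trip(self, x, p, s):
        r = rules_of(4.0, 9.0, 0.5, 1.5)
        probs = CompositionProbabilities(x, p, s)
        back = probabilities_from_links(state_from_probabilities(probs, r, N=50), r)
        assert back.P_A == pytest.approx(x, abs=1e-12)
        assert back.P_BgA == pytest.approx(p, abs=1e-12)
        assert back.P_AgB == pytest.approx(s, abs=1e-12)

    def test_inconsistent_links_rejected(self):
        r = rules_of()
        bad = PairState(N=10, N_AA=30, N_AB=0, N_BA=5, N_BB=0)
        with pytest.raises(ValueError):
            probabilities_from_links(bad, r)


class TestTransitionRates:
    def test_absorbing_boundary(self):
        r = rules_of()
        t_plus, _ = transition_rates(CompositionProbabilities(0.7, 0.0, 0.3), r)
        assert t_plus == 0.0

    def test_symmetric_inputs_balance(self):
        # symmetric rules and a 50:50 state with the clustering-law local
        # structure: the two event rates must coincide
        r = rules_of(5.0, 5.0, 1.3, 1.3)
        q = local_to_global_ratio(5.0) * 0.5
        t_plus, t_minus = transition_rates(
            CompositionProbabilities(0.5, q, q), r
        )
        assert t_plus == pytest.approx(t_minus)


class TestLinkChanges:
    @given(x=interior, p=probs_floats, s=probs_floats)
    def test_degree_conservation(self, x, p, s):
        # one B->A conversion adds exactly r_A in-links to the A side and
        # removes exactly r_B from the B side; mirrored for the reverse
        r = rules_of(4.0, 9.0, 0.5, 1.5)
        dp, dm = link_change_vectors(CompositionProbabilities(x, p, s), r)
        assert dp[0] + dp[1] == pytest.approx(r.r_A)
        assert dp[2] + dp[3] == pytest.approx(-r.r_B)
        assert dm[0] + dm[1] == pytest.approx(-r.r_A)
        assert dm[2] + dm[3] == pytest.approx(r.r_B)

    def test_equal_degrees_conserve_total_links(self):
        r = rules_of(8.0, 8.0, 1.0, 2.0)
        dp, dm = link_change_vectors(CompositionProbabilities(0.4, 0.3, 0.5), r)
        assert dp.sum() == pytest.approx(0.0, abs=1e-12)
        assert dm.sum() == pytest.approx(0.0, abs=1e-12)

    def test_boundary_state_keeps_counts_feasible(self):
        # almost-all-B state: applying Delta+ must not drive counts negative
        r = rules_of(4.0, 4.0, 1.0, 1.0)
        n = 100.0
        probs = CompositionProbabilities(1.0 / n, 1.0, 1.0 / n)
        state = state_from_probabilities(probs, r, N=n)
        dp, _ = link_change_vectors(probs, r)
        new = np.array(
            [state.N_AA, state.N_AB, state.N_BA, state.N_BB]
        ) + dp
        assert (new >= -1e-9).all()


class TestOde:
    def test_zero_at_absorbing_states(self):
        r = rules_of(4.0, 9.0, 0.5, 1.5)
        for x in (0.0, 1.0):
            st_ = state_from_probabilities(
                CompositionProbabilities(x, 0.0, 0.0), r, N=20
            )
            assert np.all(ode_rhs(st_, r) == 0.0)

    def test_fixed_point_matches_closed_forms(self):
        # the ODE must vanish at the closed-form equilibrium across the
        # whole (ratio, r_A, r_B) grid
        for r in _interior_grid():
            eq = equilibrium(r)
            st_ = state_from_probabilities(
                CompositionProbabilities(eq.P_A, eq.P_BgA, eq.P_AgB), r
            )
            assert np.abs(ode_rhs(st_, r)).max() < 1e-9

    def test_symmetry_of_symmetric_systems(self):
        r = rules_of(6.0, 6.0, 1.0, 1.0)
        st_ = state_from_probabilities(
            CompositionProbabilities(0.5, 0.3, 0.3), r, N=10
        )
        d = ode_rhs(st_, r)
        assert d[0] == pytest.approx(d[3], abs=1e-12)  # dN_AA == dN_BB


class TestIntegrate:
    def test_constant_at_equilibrium(self, experimental_rules):
        eq = equilibrium(experimental_rules)
        st_ = state_from_probabilities(
            CompositionProbabilities(eq.P_A, eq.P_BgA, eq.P_AgB),
            experimental_rules,
        )
        traj = integrate(st_, experimental_rules, t_end=50.0)
        assert np.allclose(traj["P_A"], eq.P_A, atol=1e-7)

    def test_symmetric_rules_converge_to_half(self):
        r = rules_of(8.0, 8.0, 1.0, 1.0)
        st_ = state_from_probabilities(
            CompositionProbabilities(0.3, 0.7, 0.3), r
        )
        traj = integrate(st_, r, t_end=500.0)
        assert traj["P_A"].iloc[-1] == pytest.approx(0.5, abs=1e-6)

    def test_experimental_multistart_convergence(self, experimental_rules):
        target = steady_state_frequency(experimental_rules)
        for x0 in (0.1, 0.5, 0.9):
            st_ = state_from_probabilities(
                CompositionProbabilities(x0, 1.0 - x0, x0), experimental_rules
            )
            traj = integrate(st_, experimental_rules, t_end=2000.0)
            assert traj["P_A"].iloc[-1] == pytest.approx(target, abs=1e-4)


class TestClosedForms:
    def test_equilibrium_anchor_experimental(self, experimental_rules):
        assert round(steady_state_frequency(experimental_rules), 2) == 0.20

    def test_equilibrium_symmetry_and_boundary(self):
        assert steady_state_frequency(rules_of(3, 3, 1, 1)) == pytest.approx(0.5)
        assert steady_state_frequency(rules_of(7, 7, 2, 2)) == pytest.approx(0.5)
        # ratio 2 at r=3 sits exactly on the fixation boundary
        assert steady_state_frequency(rules_of(3, 3, 2, 1)) == pytest.approx(1.0)

    def test_requires_r_A_at_least_two(self):
        with pytest.raises(ValueError):
            steady_state_frequency(rules_of(1.5, 3.0, 1, 1))

    def test_well_mixed(self):
        assert well_mixed_frequency(rules_of(3, 3, 1, 3)) == pytest.approx(0.25)
        assert well_mixed_frequency(rules_of(3, 3, 0.22, 0.78)) == pytest.approx(0.22)
        assert well_mixed_frequency(rules_of(3, 3, 2, 2)) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            well_mixed_frequency(rules_of(3, 3, 0.0, 0.0))

    def test_local_to_global_ratio(self):
        assert local_to_global_ratio(3) == pytest.approx(0.5)
        assert round(local_to_global_ratio(130), 2) == 0.99
        assert local_to_global_ratio(1e9) == pytest.approx(1.0)
        assert 1.0 - local_to_global_ratio(101) <= 0.01 + 1e-12
        with pytest.raises(ValueError):
            local_to_global_ratio(1.5)

    def test_spatial_approaches_well_mixed_for_large_r(self):
        # < 1 percentage point gap once both types have 100 neighbors
        gaps = []
        for ratio in np.logspace(-1, 1, 21):
            r = rules_of(100.0, 100.0, ratio, 1.0)
            gaps.append(abs(steady_state_frequency(r) - well_mixed_frequency(r)))
        assert max(gaps) <= 0.01


class TestProductivity:
    def test_experimental_ratio(self, experimental_rules):
        assert round(equilibrium(experimental_rules).productivity_ratio, 2) == 0.92

    def test_symmetric_small_neighborhood_halves_productivity(self):
        eq = equilibrium(rules_of(3, 3, 1, 1))
        assert eq.productivity_ratio == pytest.approx(0.5)

    def test_well_mixed_limit(self):
        eq = equilibrium(rules_of(5000.0, 5000.0, 1.0, 2.0))
        assert eq.productivity_ratio == pytest.approx(1.0, abs=1e-3)

    def test_collapse_zeroes_productivity(self):
        eq = equilibrium(rules_of(3, 3, 5.0, 1.0))  # ratio 5 outside (1/2, 2)
        assert eq.collapsed == "A_fixed"
        assert eq.productivity_spatial == 0.0
        assert eq.productivity_ratio == 0.0

    def test_spatial_never_beats_well_mixed_for_cross_feeding(self):
        for r in _interior_grid():
            assert equilibrium(r).productivity_ratio <= 1.0 + 1e-12


class TestCollapseInterval:
    def test_symmetric_three_neighbors(self):
        lo, hi = collapse_interval(3, 3)
        assert (lo, hi) == pytest.approx((0.5, 2.0))

    def test_widens_to_all_ratios_for_large_r(self):
        lo, hi = collapse_interval(1e6, 1e6)
        assert lo < 1e-4 and hi > 1e4

    def test_endpoints_match_numeric_scan(self):
        # the unclamped equilibrium changes sign / crosses 1 exactly at
        # the interval endpoints
        for r_a, r_b in [(3, 3), (3, 30), (5, 130), (10, 10)]:
            lo, hi = collapse_interval(r_a, r_b)
            for edge, boundary in ((lo, 0.0), (hi, 1.0)):
                below = steady_state_frequency(
                    rules_of(r_a, r_b, edge * 0.999, 1.0)
                )
                above = steady_state_frequency(
                    rules_of(r_a, r_b, edge * 1.001, 1.0)
                )
                # clamped value sits on the boundary on the outer side
                outer = below if boundary == 0.0 else above
                inner = above if boundary == 0.0 else below
                assert outer == boundary
                assert 0.0 < inner < 1.0


class TestRelabelingSymmetry:
    @given(ratio=st.floats(0.6, 1.8), r=st.floats(3.0, 50.0))
    def test_swapping_types_mirrors_frequency(self, ratio, r):
        a = rules_of(r, r, ratio, 1.0)
        b = rules_of(r, r, 1.0, ratio)
        assert steady_state_frequency(a) == pytest.approx(
            1.0 - steady_state_frequency(b), abs=1e-12
        )
        assert well_mixed_frequency(a) == pytest.approx(
            1.0 - well_mixed_frequency(b), abs=1e-12
        )


class TestGeneralGrowthModels:
    def test_density_matched_products_give_even_split(self):
        # mu_A r_A == mu_B r_B (2*5 == 1*10) -> exact 50:50
        r = rules_of(5, 10, 2.0, 1.0, model="density_linear")
        assert steady_state_general(r).P_A == pytest.approx(0.5, abs=1e-9)

    def test_density_majority_follows_mu_r_product(self):
        r = rules_of(5, 10, 3.0, 1.0, model="density_linear")  # 15 > 10
        assert steady_state_general(r).P_A > 0.5
        r2 = rules_of(5, 10, 1.0, 1.0, model="density_linear")  # 5 < 10
        assert steady_state_general(r2).P_A < 0.5

    def test_inhibition_spatial_growth_exceeds_well_mixed(self):
        r = rules_of(3, 3, 1.0, 1.0, model="inhibition_linear")
        eq = steady_state_general(r)
        assert eq.productivity_spatial >= eq.productivity_wm
        assert eq.productivity_ratio >= 1.0

    def test_custom_linear_matches_closed_form(self):
        r = rules_of(4, 9, 0.5, 1.0, model="custom")
        eq = steady_state_general(
            r, lambda n, rr: 0.5 * n / rr, lambda n, rr: 1.0 * n / rr
        )
        closed = steady_state_frequency(rules_of(4, 9, 0.5, 1.0))
        assert eq.P_A == pytest.approx(closed, abs=1e-9)

    def test_frequency_model_consistency(self, experimental_rules):
        assert steady_state_general(experimental_rules).P_A == pytest.approx(
            steady_state_frequency(experimental_rules), abs=1e-9
        )
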