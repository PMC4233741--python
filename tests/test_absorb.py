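"""Absorbing-chain solve, closed-form oracles, start averaging, limits."""

from fractions import Fraction

import numpy as np
import pytest

from moranfix import (build_canonical_chain, closed_form_conditional_time,
                      closed_form_fixation_probability, full_state_space,
                      make_named_graph, reduced_space, solve, solve_graph,
                      start_averaged, strong_selection_limit)
from moranfix.graphs import NAMED_GRAPHS

R_GRID = [0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 10.0]


class TestSolveExact:
    def test_neutral_complete_graph_times(self, motifs):
        """From one mutant on K4 at r = 1: conditional fixation in 9 steps,
        split evenly (3, 3, 3) across the mutant-count states."""
        res = solve_graph(motifs["complete"], 1, exact=True)
        assert res.tau_cond[0] == 9
        assert list(res.T_cond[0]) == [3, 3, 3]
        assert res.Phi[0, 1] == Fraction(1, 4)

    def test_neutral_ring_sojourn_exceeds_complete_by_one(self, motifs):
        """The ring lingers one extra step (on average) in the two-mutant
        state; the one- and three-mutant sojourns match the complete graph."""
        ring = solve_graph(motifs["ring"], 1, exact=True)
        assert list(ring.T_cond[0]) == [3, 4, 3]
        assert ring.tau_cond[0] == 10

    def test_phi_rows_sum_to_one(self, motifs):
        for g in motifs.values():
            res = solve_graph(g, Fraction(3, 2), exact=True)
            assert all(sum(row) == 1 for row in res.Phi)

    def test_tau_unconditional_is_row_sum_of_F(self, diamond):
        res = solve_graph(diamond, Fraction(2), exact=True)
        for i in range(res.space.n_transient):
            assert res.tau_unc[i] == sum(res.F[i])

    def test_neutral_fixation_is_one_over_n_on_regular_graphs(self):
        for name, n in (("ring", 5), ("complete", 5), ("ring", 6)):
            res = solve_graph(make_named_graph(name, n), 1, exact=True)
            starts = res.space.single_mutant_indices()
            assert all(res.Phi[i, 1] == Fraction(1, n) for i in starts)

    def test_exact_inverse_matches_sympy(self, diamond):
        """The rational Gauss-Jordan fundamental matrix equals sympy's
        exact matrix inverse of (I - Q) entry for entry."""
        import sympy

        from moranfix import build_canonical_chain

        chain = build_canonical_chain(diamond, reduced_space(diamond),
                                      Fraction(3, 2))
        t = chain.n_transient
        M = sympy.eye(t) - sympy.Matrix(
            t, t, lambda i, j: sympy.Rational(chain.Q[i, j]))
        ref = M.inv()
        res = solve(chain)
        for i in range(t):
            for j in range(t):
                assert sympy.Rational(res.F[i, j]) == ref[i, j]

    def test_float_agrees_with_exact(self, diamond):
        exact = solve_graph(diamond, Fraction(3, 2), exact=True)
        flt = solve_graph(diamond, 1.5, exact=False)
        assert np.allclose(np.asarray(exact.tau_cond, dtype=float),
                           flt.tau_cond, rtol=1e-12)


class TestLumpability:
    @pytest.mark.parametrize("name", NAMED_GRAPHS)
    @pytest.mark.parametrize("r", [0.5, 1.0, 2.0])
    def test_full_chain_matches_reduced_chain(self, motifs, name, r):
        """Solving the raw 2^n chain and the orbit-lumped chain gives the
        same fixation probability and conditional time from every
        single-mutant configuration."""
        g = motifs[name]
        full = solve(build_canonical_chain(g, full_state_space(g), r,
                                           exact=False))
        red = solve_graph(g, r, exact=False)
        red_idx = red.space.index_of
        full_space = full.space
        for i in range(full_space.n_transient):
            config = full_space.representative(i)
            if full_space.mutant_count(i) != 1:
                continue
            j = red_idx[config]
            assert full.Phi[i, 1] == pytest.approx(red.Phi[j, 1], rel=1e-10)
            assert full.tau_cond[i] == pytest.approx(red.tau_cond[j],
                                                     rel=1e-10)


class TestClosedForms:
    def test_neutral_limit(self):
        assert closed_form_fixation_probability(4, 1, 1) == Fraction(1, 4)
        assert closed_form_fixation_probability(10, 1.0, 3) == pytest.approx(0.3)

    def test_known_value_r2(self):
        assert closed_form_fixation_probability(4, Fraction(2)) == \
            Fraction(8, 15)

    @pytest.mark.parametrize("N", [3, 4, 6])
    @pytest.mark.parametrize("r", R_GRID)
    def test_matches_matrix_solve_on_complete_graph(self, N, r):
        g = make_named_graph("complete", N)
        res = solve_graph(g, r, exact=False)
        assert float(res.Phi[0, 1]) == pytest.approx(
            closed_form_fixation_probability(N, r), abs=1e-9)
        assert float(res.tau_cond[0]) == pytest.approx(
            closed_form_conditional_time(N, r), abs=1e-9)

    def test_conditional_time_neutral_value(self):
        assert closed_form_conditional_time(4, 1) == 9

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            closed_form_fixation_probability(4, -1)
        with pytest.raises(ValueError):
            closed_form_fixation_probability(1, 2)


class TestStartAveraging:
    def test_diamond_weights_half_half(self, diamond):
        avg = start_averaged(solve_graph(diamond, Fraction(2), exact=True))
        assert sorted(avg.weights.values()) == [Fraction(1, 2), Fraction(1, 2)]

    def test_star_weights_quarter_three_quarters(self, motifs):
        avg = start_averaged(solve_graph(motifs["star"], Fraction(2),
                                         exact=True))
        assert sorted(avg.weights.values()) == [Fraction(1, 4), Fraction(3, 4)]

    def test_single_orbit_graphs_have_weight_one(self, motifs):
        for name in ("ring", "complete"):
            avg = start_averaged(solve_graph(motifs[name], 1, exact=True))
            assert list(avg.weights.values()) == [1]

    def test_average_is_mean_of_the_two_diamond_curves(self, diamond):
        """Uniform start averaging on the diamond is the plain mean of the
        hub-start and degree-2-start conditional times."""
        res = solve_graph(diamond, 3.0, exact=False)
        starts = res.space.single_mutant_indices()
        avg = start_averaged(res)
        mean = sum(res.tau_cond[i] for i in starts) / 2
        assert float(avg.tau_cond) == pytest.approx(mean)

    def test_fixation_weighting_differs_on_heterogeneous_graphs(self, diamond):
        res = solve_graph(diamond, 2.0, exact=False)
        uni = start_averaged(res, weighting="uniform")
        fix = start_averaged(res, weighting="fixation")
        assert float(uni.tau_cond) != pytest.approx(float(fix.tau_cond))
        assert sum(fix.weights.values()) == pytest.approx(1)


class TestStrongSelection:
    def test_complete_graph_limiting_sojourns(self, motifs):
        """As r -> inf the up-move probability at i mutants tends to
        (N-i)/(N-1); expected visits are the reciprocals (1, 3/2, 3)."""
        g = motifs["complete"]

        def sojourn(state):
            return lambda r: float(solve_graph(g, r, exact=False)
                                   .T_cond[0][state])

        for state, expected in [(0, 1.0), (1, 1.5), (2, 3.0)]:
            lim = strong_selection_limit(sojourn(state))
            assert lim.converged
            assert lim.value == pytest.approx(expected, abs=1e-4)

    def test_ring_one_and_three_mutant_sojourns_match_complete(self, motifs):
        ring = motifs["ring"]

        def sojourn(state):
            return lambda r: float(solve_graph(ring, r, exact=False)
                                   .T_cond[0][state])

        assert strong_selection_limit(sojourn(0)).value == \
            pytest.approx(1.0, abs=1e-4)
        assert strong_selection_limit(sojourn(2)).value == \
            pytest.approx(3.0, abs=1e-4)

    def test_diamond_three_mutant_sojourn_grows_under_strong_selection(
            self, diamond):
        """The shielded wild-type effect: the total three-mutant sojourn on
        the diamond is larger in the strong-selection limit than at
        neutrality."""
        space = reduced_space(diamond)
        three = [i for i in range(space.n_transient)
                 if space.mutant_count(i) == 3]

        def total(r):
            res = solve_graph(diamond, r, exact=False)
            avg = start_averaged(res)
            return float(sum(avg.sojourn_cond[i] for i in three))

        lim = strong_selection_limit(total)
        assert lim.converged
        assert lim.value > total(1.0)

    def test_nonconvergence_is_flagged_not_raised(self):
        lim = strong_selection_limit(lambda r: np.log(r), r_sequence=(10, 100))
        assert not lim.converged

    def test_rejects_decreasing_sequence(self):
        with pytest.raises(ValueError):
            strong_selection_limit(lambda r: 0.0, r_sequence=(10, 1))


@pytest.mark.parametrize("name", NAMED_GRAPHS)
def test_fixation_probability_increases_with_fitness(motifs, name):
    g = motifs[name]
    phis = [float(start_averaged(solve_graph(g, r, exact=False))
                  .fixation_probability) for r in R_GRID]
    assert all(b > a for a, b in zip(phis, phis[1:]))
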