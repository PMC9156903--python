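"""Survival probabilities: conditional, marginal (closed form vs
quadrature), decomposition, restriction, and the vulnerable-N finder."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescuedip import (
    ModelParams,
    establishment_prob,
    find_vulnerable_N,
    survival_components,
    survival_given_p,
    survival_probability,
    survival_probability_quadrature,
    survival_restricted,
)

# parameter sets spanning the survival-curve panels: benefit, mutation
# rate and cost each varied around the baseline
PANEL_PARAMS = [
    ModelParams(),
    ModelParams(s_b=0.011),
    ModelParams(s_b=0.5),
    ModelParams(mu=1e-6),
    ModelParams(mu=1e-4),
    ModelParams(s_d=1e-4),
]


class TestConditionalSurvival:
    def test_reduces_to_de_novo_at_p_zero(self, defaults):
        pi = establishment_prob(defaults.s_r)
        expected = 1.0 - math.exp(-1000 * pi * defaults.mu / defaults.delta)
        assert survival_given_p(0.0, 1000, defaults) == pytest.approx(
            expected, rel=1e-12
        )

    def test_zero_without_allele_or_mutation(self):
        params = ModelParams(mu=0.0)
        assert survival_given_p(0.0, 1000, params) == 0.0

    def test_fixed_small_benefit_population(self):
        # population of 500 fixed for an allele with net advantage 0.001
        # survives ~63% of the time (complement of the ~37% extinction)
        params = ModelParams(s_b=0.011, mu=0.0)
        assert survival_given_p(1.0, 500, params) == pytest.approx(0.63, abs=0.01)

    @given(
        p=st.tuples(
            st.floats(min_value=0.0, max_value=1.0),
            st.floats(min_value=0.0, max_value=1.0),
        ).filter(lambda t: t[0] < t[1])
    )
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_strictly_increasing_in_p(self, p, defaults):
        lo, hi = p
        assert survival_given_p(lo, 500, defaults) < survival_given_p(
            hi, 500, defaults
        )

    def test_rejects_bad_frequency(self, defaults):
        with pytest.raises(ValueError):
            survival_given_p(-0.1, 100, defaults)
        with pytest.raises(ValueError):
            survival_given_p(1.5, 100, defaults)


class TestMarginalSurvival:
    @pytest.mark.parametrize("params", PANEL_PARAMS)
    @pytest.mark.parametrize("N", [10, 30, 100, 300, 1000, 3000, 10_000])
    def test_closed_form_matches_quadrature(self, N, params):
        closed = survival_probability(N, params)
        direct = survival_probability_quadrature(N, params)
        assert abs(closed - direct) < 1e-6

    def test_vanishes_in_small_weak_limit(self):
        params = ModelParams(s_b=0.01 + 1e-9)
        assert survival_probability(1, params) < 1e-6

    def test_non_monotone_at_baseline(self, defaults):
        Ns = np.geomspace(1e3, 1e4, 40)
        P = [survival_probability(N, defaults) for N in Ns]
        drops = [(Ns[i], Ns[j]) for i in range(len(Ns)) for j in (i + 1,)
                 if j < len(Ns) and P[i] > P[j]]
        assert drops, "expected a decreasing stretch between 1e3 and 1e4"

    def test_nondecreasing_in_benefit_and_mutation_rate(self, defaults):
        for N in (100, 2000):
            p_here = survival_probability(N, defaults)
            assert survival_probability(N, ModelParams(s_b=0.1)) >= p_here - 1e-12
            assert survival_probability(N, ModelParams(mu=1e-4)) >= p_here - 1e-12


class TestDecomposition:
    @given(logN=st.floats(min_value=1.0, max_value=6.0))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_composition_identity(self, logN, defaults):
        dec = survival_components(10.0 ** logN, defaults)
        recomposed = dec.p_stand + (1.0 - dec.p_stand) * dec.p_de_novo
        assert dec.p_total == recomposed  # exact by construction
        assert dec.p_total >= max(dec.p_stand, dec.p_de_novo)
        for v in (dec.p_stand, dec.p_de_novo, dec.p_total, dec.p_closed_form):
            assert 0.0 <= v <= 1.0

    def test_de_novo_is_conditional_at_zero(self, defaults):
        dec = survival_components(500, defaults)
        assert dec.p_de_novo == pytest.approx(
            survival_given_p(0.0, 500, defaults), rel=1e-12
        )

    def test_baseline_sweep_structure(self, defaults):
        Ns = np.geomspace(10, 1e6, 25)
        decs = [survival_components(N, defaults) for N in Ns]
        # standing variation dominates at small N ...
        assert decs[0].p_stand > 10 * decs[0].p_de_novo
        # ... de novo takes over approaching N_mut = 1/mu
        near_mut = survival_components(defaults.N_mut, defaults)
        assert near_mut.p_de_novo > 0.99
        # composed and closed-form marginals stay close (mu/delta = 1e-3)
        assert all(abs(d.p_total - d.p_closed_form) <= 0.01 for d in decs)


class TestRestrictedSurvival:
    def test_no_restriction_recovers_marginal(self, defaults):
        full = survival_restricted(1000, defaults, 1.0)
        assert full == pytest.approx(
            survival_probability_quadrature(1000, defaults), abs=1e-12
        )

    def test_rescue_only_curve_is_monotone(self, defaults):
        p_max = defaults.delta / defaults.s_b  # mean fitness below one
        Ns = np.geomspace(10, 1e4, 15)
        vals = [survival_restricted(N, defaults, p_max) for N in Ns]
        assert all(b >= a - 1e-10 for a, b in zip(vals, vals[1:]))

    def test_conditioning_removes_high_frequency_mass(self):
        params = ModelParams(s_d=0.0)
        restricted = survival_restricted(500, params, 0.5)
        full = survival_probability_quadrature(500, params)
        assert restricted <= full

    def test_monotone_in_p_max(self, defaults):
        vals = [survival_restricted(800, defaults, pm) for pm in (0.1, 0.3, 0.6, 1.0)]
        assert all(b >= a - 1e-10 for a, b in zip(vals, vals[1:]))

    def test_degenerate_p_max_rejected(self, defaults):
        with pytest.raises(ValueError):
            survival_restricted(100, defaults, 0.0)


class TestVulnerableN:
    def test_baseline_minimum_exists_in_expected_range(self, defaults):
        rep = find_vulnerable_N(defaults, 10, 1e6)
        assert rep.exists
        assert 10 < rep.n_star < 1e6
        # refined point is no higher than its neighbourhood
        for fac in (0.9, 1.1):
            assert rep.p_at_min <= survival_probability(rep.n_star * fac, defaults)

    def test_near_neutral_cost_has_no_minimum(self):
        rep = find_vulnerable_N(ModelParams(s_d=1e-4), 10, 1e4)
        assert not rep.exists
        assert rep.n_star is None and rep.p_at_min is None

    def test_large_benefit_has_no_minimum(self):
        rep = find_vulnerable_N(ModelParams(s_b=2.0), 10, 1e6)
        assert not rep.exists

    def test_flat_saturated_tail_not_reported(self):
        # high mutation supply: survival ~1 over most of the range; the
        # saturated plateau must not produce a spurious minimum
        rep = find_vulnerable_N(ModelParams(mu=1e-3), 10, 1e6)
        assert not rep.exists

    def test_invalid_range_rejected(self, defaults):
        with pytest.raises(ValueError):
            find_vulnerable_N(defaults, 100, 100)
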