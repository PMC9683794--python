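import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from polyshift.alleles import (
    AlleleContext,
    estimate_amplification_A,
    fixation_excess_table,
    freq_change_moments,
    longterm_contribution_lande,
    longterm_contribution_nonlande,
    rapid_phase_contribution,
    rapid_phase_pair_difference,
    wright_fixation_prob,
)
from polyshift.config import EffectSizeDistribution, ModelParams
from polyshift.equilibrium import (
    amplification_factor,
    equilibrium_variance,
    marginal_variance_density,
    variance_density,
)
from polyshift.phenotype import lande_distance, rapid_phase_end


def pi_by_quadrature(a: float, x: float) -> float:
    """Fixation probability straight from the diffusion integrals."""
    num, _ = integrate.quad(lambda y: math.exp(a * a * y * (1 - y)), 0.0, x,
                            epsabs=0.0, epsrel=1e-12)
    den, _ = integrate.quad(lambda y: math.exp(a * a * y * (1 - y)), 0.0, 1.0,
                            epsabs=0.0, epsrel=1e-12)
    return num / den


class TestFreqChangeMoments:
    def test_boundaries_are_absorbing(self):
        for x in (0.0, 1.0):
            mean, var = freq_change_moments(AlleleContext(a=4.0, x=x, D=10.0, VS=2e4), N=1000)
            assert mean == 0.0 and var == 0.0

    def test_balanced_at_half_frequency_without_directional_selection(self):
        mean, _ = freq_change_moments(AlleleContext(a=4.0, x=0.5, D=0.0, VS=2e4), N=1000)
        assert mean == 0.0

    def test_stationary_stabilizing_example(self):
        ctx = AlleleContext(a=4.0, x=0.1, D=0.0, VS=2e4)
        mean, var = freq_change_moments(ctx, N=10_000)
        assert mean == pytest.approx(-16.0 / 2e4 * 0.09 * 0.4, rel=1e-12)  # -2.88e-5
        assert var == pytest.approx(0.09 / 2e4, rel=1e-12)                  # 4.5e-6

    def test_directional_term_favors_aligned_alleles(self):
        up, _ = freq_change_moments(AlleleContext(a=2.0, x=0.5, D=50.0, VS=2e4), N=100)
        down, _ = freq_change_moments(AlleleContext(a=-2.0, x=0.5, D=50.0, VS=2e4), N=100)
        assert up > 0 > down and up == pytest.approx(-down)

    def test_strong_directional_selection_warns(self):
        with pytest.warns(UserWarning, match="s_d"):
            AlleleContext(a=10.0, x=0.1, D=2000.0, VS=2e4)


class TestWrightFixationProb:
    def test_neutral_allele_fixes_at_initial_frequency(self):
        assert wright_fixation_prob(0.0, 0.3) == 0.3
        assert wright_fixation_prob(1e-6, 0.3) == pytest.approx(0.3, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(st.floats(0.0, 10.0), st.floats(0.0, 1.0))
    def test_complementary_frequencies_sum_to_one(self, a, x):
        assert wright_fixation_prob(a, x) + wright_fixation_prob(a, 1.0 - x) == \
            pytest.approx(1.0, abs=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(0.1, 8.0))
    def test_monotone_in_frequency(self, a):
        x = np.linspace(0.0, 1.0, 101)
        pi = wright_fixation_prob(a, x)
        assert np.all(np.diff(pi) > 0)
        assert pi[0] == 0.0 and pi[-1] == 1.0

    @pytest.mark.parametrize("a,x", [(4.0, 0.1), (2.0, 0.25), (1.0, 0.05), (6.0, 0.5)])
    def test_matches_direct_quadrature(self, a, x):
        assert wright_fixation_prob(a, x) == pytest.approx(pi_by_quadrature(a, x),
                                                           rel=1e-10)

    def test_underdominant_suppression_of_rare_alleles(self):
        # stabilizing selection makes a 10% allele far less likely to fix
        assert wright_fixation_prob(4.0, 0.1) == pytest.approx(0.00953, rel=1e-3)


class TestRapidPhase:
    def setup_method(self):
        self.Lambda, self.VA0, self.VS = 116.0, 841.0, 2e4
        self.t1 = (self.VS / self.VA0) * math.log(self.Lambda)

    def test_pair_difference_vanishes_at_zero_frequency(self):
        d = rapid_phase_pair_difference(2.0, 1e-12, self.Lambda, self.VA0, self.t1, self.VS)
        assert d == pytest.approx(0.0, abs=1e-9)

    def test_pair_difference_formula(self):
        got = rapid_phase_pair_difference(2.0, 0.25, self.Lambda, self.VA0,
                                          self.t1, self.VS)
        DL1 = lande_distance(self.t1, self.Lambda, self.VA0, self.VS)
        assert got == pytest.approx((self.Lambda - DL1) * 2 * 2.0 * 0.1875 / self.VA0)

    def test_contribution_proportional_to_variance_density(self):
        kw = dict(Lambda=self.Lambda, VA0=self.VA0, t1=self.t1, VS=self.VS)
        r1 = rapid_phase_contribution(1.5, **kw)
        r2 = rapid_phase_contribution(4.0, **kw)
        assert r1 / r2 == pytest.approx(
            marginal_variance_density(1.5) / marginal_variance_density(4.0), rel=1e-12)
        # pointwise form uses the per-MAF density
        p = rapid_phase_contribution(4.0, 0.2, **kw)
        assert p / r2 == pytest.approx(
            variance_density(4.0, 0.2) / marginal_variance_density(4.0), rel=1e-12)

    def test_total_equals_distance_covered_in_rapid_phase(self, nonlande_preset):
        params, dist = nonlande_preset
        VA0 = equilibrium_variance(params, dist)
        t1 = rapid_phase_end(params, VA0)
        total = params.twoNU * dist.expect(
            lambda a: rapid_phase_contribution(a, Lambda=params.Lambda, VA0=VA0,
                                               t1=t1, VS=params.VS))
        expected = params.Lambda - lande_distance(t1, params.Lambda, VA0, params.VS)
        assert total == pytest.approx(expected, rel=1e-6)

    def test_expected_pair_gap_peaks_at_moderate_effects(self):
        # the x0-averaged gap is proportional to v(a)/a; its peak sits at
        # moderate magnitudes, not at the largest effects
        a = np.sqrt(np.linspace(0.25, 100.0, 2000))
        gap = marginal_variance_density(a) / a
        S_peak = a[np.argmax(gap)] ** 2
        assert 1.0 < S_peak < 10.0


class TestLongTermLande:
    def test_pair_contribution_independent_of_initial_frequency(self):
        v1 = longterm_contribution_lande(3.0, 0.05, Lambda=100.0, VA0=841.0)
        v2 = longterm_contribution_lande(3.0, 0.4, Lambda=100.0, VA0=841.0)
        assert v1 == v2

    def test_marginal_is_half_the_pair_value(self):
        pair = longterm_contribution_lande(3.0, 0.1, Lambda=100.0, VA0=841.0)
        marg = longterm_contribution_lande(3.0, Lambda=100.0, VA0=841.0)
        assert pair == pytest.approx(2.0 * marg)

    def test_total_underestimates_shift_by_amplification_factor(self, nonlande_preset):
        params, dist = nonlande_preset
        VA0 = equilibrium_variance(params, dist)
        C = amplification_factor(dist)
        total = params.twoNU * dist.expect(
            lambda a: longterm_contribution_lande(a, Lambda=params.Lambda, VA0=VA0))
        assert total == pytest.approx(params.Lambda / (1.0 + C), rel=1e-6)

    def test_large_effects_contribute_nothing_long_term(self):
        assert longterm_contribution_lande(20.0, Lambda=100.0, VA0=841.0) < 1e-10


class TestLongTermNonLande:
    def test_zero_amplification_reduces_to_lande(self):
        out = longterm_contribution_nonlande(3.0, Lambda=100.0, VA0=841.0, A=0.0, B=0.0)
        assert out["total"] == pytest.approx(
            longterm_contribution_lande(3.0, Lambda=100.0, VA0=841.0))
        assert out["new_mutations"] == 0.0

    def test_factors_resolve_and_check_consistency(self):
        out = longterm_contribution_nonlande(2.0, Lambda=10.0, VA0=841.0, A=0.4, C=1.0)
        assert out["B"] == pytest.approx(0.6)
        with pytest.raises(ValueError, match="inconsistent"):
            longterm_contribution_nonlande(2.0, Lambda=10.0, VA0=841.0,
                                           A=0.4, B=0.4, C=1.0)
        with pytest.raises(ValueError):
            longterm_contribution_nonlande(2.0, Lambda=10.0, VA0=841.0, C=1.0)

    def test_standing_and_new_proportions(self):
        A, B = 0.5, 0.7
        out = longterm_contribution_nonlande(2.0, Lambda=10.0, VA0=841.0, A=A, B=B)
        C = A + B
        assert out["standing"] / out["total"] == pytest.approx((1 + A) / (1 + C))
        assert out["new_mutations"] / out["total"] == pytest.approx(B / (1 + C))

    def test_grand_total_recovers_the_shift(self, nonlande_preset):
        params, dist = nonlande_preset
        VA0 = equilibrium_variance(params, dist)
        C = amplification_factor(dist)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # large-a tail trips the validity check
            total = params.twoNU * dist.expect(
                lambda a: longterm_contribution_nonlande(
                    a, Lambda=params.Lambda, VA0=VA0, A=0.3 * C, C=C)["total"])
        assert total == pytest.approx(params.Lambda, rel=1e-6)

    def test_validity_warning_outside_linear_regime(self):
        with pytest.warns(UserWarning, match="linear"):
            longterm_contribution_nonlande(10.0, Lambda=100.0, VA0=100.0, A=1.0, B=0.5)


class TestAmplificationEstimate:
    def test_lande_trajectory_gives_zero(self):
        t = np.linspace(0.0, 4000.0, 200_001)
        D = lande_distance(t, 116.0, 841.0, 2e4)
        assert estimate_amplification_A(t, D, 116.0, 841.0, 2e4) == pytest.approx(
            0.0, abs=1e-3)

    def test_doubled_trajectory_gives_one(self):
        t = np.linspace(0.0, 4000.0, 200_001)
        D = 2.0 * lande_distance(t, 116.0, 841.0, 2e4)
        assert estimate_amplification_A(t, D, 116.0, 841.0, 2e4) == pytest.approx(
            1.0, abs=2e-3)

    def test_undecayed_trajectory_warns(self):
        t = np.linspace(0.0, 10.0, 50)
        D = lande_distance(t, 116.0, 841.0, 2e4)
        with pytest.warns(UserWarning, match="not decayed"):
            estimate_amplification_A(t, D, 116.0, 841.0, 2e4)


class TestFixationExcessTable:
    def test_no_shift_means_no_excess(self):
        params = ModelParams(N=10_000, U=0.01, Lambda=0.0)
        dist = EffectSizeDistribution("exponential_in_S", 16.0)
        tbl = fixation_excess_table(params, dist)
        np.testing.assert_allclose(tbl["excess"], 0.0, atol=1e-14)
        np.testing.assert_allclose(tbl["total_fixation_increase"], 0.0, atol=1e-12)

    def test_excess_grows_with_effect_size_toward_one(self, nonlande_preset):
        params, dist = nonlande_preset
        tbl = fixation_excess_table(params, dist, S_bins=np.geomspace(0.1, 400.0, 14))
        e = tbl["excess"].to_numpy()
        assert np.all((e >= 0.0) & (e <= 1.0))
        assert np.all(np.diff(e) > -1e-9)      # nondecreasing in S
        assert e[-1] > 0.98                     # huge effects: aligned only
        assert e[0] < 0.1                       # weak effects: tiny excess
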