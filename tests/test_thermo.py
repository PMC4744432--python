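"""Melting thermodynamics: energies, degeneracies, Boltzmann statistics,
barrier shift and the initiation rate laws."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from topoburst import thermo
from topoburst.thermo import (
    InitiationKinetics,
    ThermoParams,
    barrier_shift,
    default_sigma_grid,
    fit_exponential_w,
    fit_production_rate,
    linear_stall_sigma,
    log_degeneracy,
    melt_number_distribution,
    production_rate_full,
    production_rate_linear,
    promoter_barrier,
    rate_factor,
    state_free_energy,
    supercoil_energy,
)


class TestParams:
    def test_defaults_and_derived(self, thermo_params):
        assert thermo_params.kBT == pytest.approx(1.987204259e-3 * 298.15)
        assert thermo_params.default_n_max == 10  # floor(0.06 * 180)

    @pytest.mark.parametrize("kwargs", [
        {"epsilon": -1.0}, {"alpha": 0.9}, {"Np": 200}, {"T": 0.0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ThermoParams(**kwargs)

    def test_kinetics_k_prime_derivation(self):
        kin = InitiationKinetics(k_on=1.0, w=5.0, k_off0=6.0, k_cat=3.0)
        assert kin.k_prime == pytest.approx(2.0)
        with pytest.raises(ValueError):
            InitiationKinetics(k_on=1.0, w=5.0)  # neither k_prime nor the pair
        with pytest.raises(ValueError):
            InitiationKinetics(k_on=1.0, w=5.0, k_off0=6.0, k_cat=3.0, k_prime=5.0)


class TestSupercoilEnergy:
    def test_fully_paired_relaxed_is_zero(self, thermo_params):
        assert supercoil_energy(0, 0.0, thermo_params) == 0.0

    def test_direct_arithmetic(self, thermo_params):
        # C*N*sigma^2/A^2 with the printed constants
        expected = 1638.0 * 180 * 0.05**2 / 10.4**2
        assert supercoil_energy(0, 0.05, thermo_params) == pytest.approx(expected)
        assert expected == pytest.approx(6.815, abs=5e-4)

    def test_fully_melted_boundary_is_finite(self, thermo_params):
        p = thermo_params
        val = supercoil_energy(p.N, 0.3, p)
        assert np.isfinite(val)
        assert val == pytest.approx(p.C * p.N * (1 + 0.3) ** 2 / (p.A**2 * p.alpha))

    @pytest.mark.parametrize("n", [-1, 181])
    def test_out_of_domain_melt_count(self, thermo_params, n):
        with pytest.raises(ValueError):
            supercoil_energy(n, 0.0, thermo_params)


def _exact_ln_g(n, nj, N):
    f = math.factorial
    h = nj // 2
    g = Fraction(N * f(N - n - 1) * f(n - 1), f(N - n - h) * f(n - h) * f(h - 1) * f(h))
    return math.log(g)


class TestDegeneracy:
    @pytest.mark.parametrize("n,nj,expected", [
        (1, 2, math.log(180)),            # one 1-bp bubble: N placements
        (2, 2, math.log(180)),            # one 2-bp bubble: N placements
        (2, 4, math.log(180 * 177 / 2)),  # two disjoint 1-bp bubbles
    ])
    def test_hand_cancellations(self, thermo_params, n, nj, expected):
        assert log_degeneracy(n, nj, thermo_params) == pytest.approx(expected, rel=1e-12)

    def test_two_bubble_count_matches_enumeration(self):
        # brute force: place two disjoint, non-adjacent 1-bp bubbles on a ring
        N = 24
        count = 0
        for i in range(N):
            for j in range(i + 1, N):
                gap = min(j - i, N - (j - i))
                if gap >= 2:  # bubbles may not merge into one junction pair
                    count += 1
        p = ThermoParams(N=N, Np=4)
        assert log_degeneracy(2, 4, p) == pytest.approx(math.log(count), rel=1e-12)

    def test_matches_exact_factorial_arithmetic(self):
        for N in (20, 41, 60):
            p = ThermoParams(N=N, Np=4)
            for n in range(1, 11):
                for nj in range(2, 2 * min(n, N - n) + 1, 2):
                    assert log_degeneracy(n, nj, p) == pytest.approx(
                        _exact_ln_g(n, nj, N), rel=1e-10
                    )

    @pytest.mark.parametrize("n,nj", [(0, 0), (1, 3), (1, 4), (5, 0), (179, 4), (180, 2)])
    def test_invalid_states_rejected(self, thermo_params, n, nj):
        with pytest.raises(ValueError):
            log_degeneracy(n, nj, thermo_params)


class TestStateFreeEnergy:
    def test_ground_state(self, thermo_params):
        assert state_free_energy(0, 0, 0.0, thermo_params) == 0.0
        assert state_free_energy(0, 0, 0.05, thermo_params) == pytest.approx(
            supercoil_energy(0, 0.05, thermo_params)
        )

    def test_term_by_term(self, thermo_params):
        p = thermo_params
        expected = (
            (p.epsilon - p.T * p.delta_S)
            + p.epsilon_o
            + supercoil_energy(1, 0.0, p)
            - p.kBT * math.log(180)
        )
        assert state_free_energy(1, 2, 0.0, p) == pytest.approx(expected, rel=1e-12)

    def test_printed_sign_flips_degeneracy_term(self, thermo_params):
        p = thermo_params
        diff = state_free_energy(3, 4, 0.01, p, "as_printed") - state_free_energy(
            3, 4, 0.01, p, "entropic"
        )
        assert diff == pytest.approx(2 * p.kBT * log_degeneracy(3, 4, p), rel=1e-12)

    def test_fully_paired_state_dominates_at_zero_sigma(self, thermo_params):
        """At room temperature with eps=7.9 melting is unfavourable: every melted
        microstate has higher free energy (lower Boltzmann weight) than n=0."""
        p = thermo_params
        g0 = state_free_energy(0, 0, 0.0, p)
        for n in range(1, p.default_n_max + 1):
            for nj in range(2, 2 * min(n, p.N - n) + 1, 2):
                assert state_free_energy(n, nj, 0.0, p) > g0


class TestMeltDistribution:
    @settings(deadline=None, max_examples=20)
    @given(st.floats(min_value=-0.06, max_value=0.06))
    def test_normalization(self, sigma):
        p = melt_number_distribution(sigma, ThermoParams())
        assert np.all(p >= 0)
        assert abs(p.sum() - 1.0) < 1e-12

    def test_single_state_partition(self, thermo_params):
        assert melt_number_distribution(0.0, thermo_params, n_max=0) == pytest.approx([1.0])

    def test_positive_supercoiling_suppresses_melting(self, thermo_params):
        """The (n/N + sigma)^2 stress term grows with n when sigma > 0, so
        positive supercoiling makes strand separation *less* likely."""
        p0 = melt_number_distribution(0.0, thermo_params)
        p5 = melt_number_distribution(0.05, thermo_params)
        assert p5[0] > p0[0]

    def test_truncation_bounds(self, thermo_params):
        with pytest.raises(ValueError):
            melt_number_distribution(0.0, thermo_params, n_max=180)


class TestBarrier:
    def test_barrier_positive_and_near_full_promoter_melting_cost(self, thermo_params):
        # with almost all DNA paired the barrier is dominated by melting all
        # Np promoter base pairs: Np * epsilon = 63.2 kcal/mol
        dg0 = promoter_barrier(0.0, thermo_params)
        assert dg0 > 0
        assert dg0 == pytest.approx(thermo_params.Np * thermo_params.epsilon, rel=0.15)

    def test_shift_zero_at_zero(self, thermo_params):
        assert barrier_shift(0.0, thermo_params) == 0.0

    def test_barrier_rises_with_positive_supercoiling(self, thermo_params):
        """Positive supercoils stabilise the duplex: the melting barrier is
        non-decreasing over the linear-response grid, hence ddG >= 0."""
        grid = default_sigma_grid()
        shifts = [barrier_shift(s, thermo_params) for s in grid]
        assert all(s >= 0 for s in shifts)
        assert all(b >= a for a, b in zip(shifts, shifts[1:]))

    def test_shift_linear_on_default_grid(self, thermo_params):
        grid = default_sigma_grid()
        shifts = [barrier_shift(s, thermo_params) for s in grid]
        res = stats.linregress(grid, shifts)
        assert res.rvalue**2 > 0.99

    def test_turnover_beyond_linear_regime(self, thermo_params):
        """The quadratic stress term caps the shift near
        sigma* = (Np/N)/((alpha-1) Np/N): past it the barrier falls again."""
        p = thermo_params
        frac = p.Np / p.N
        sigma_star = frac / ((p.alpha - 1.0) * frac)  # ~0.045 for the defaults
        assert barrier_shift(sigma_star, p) > barrier_shift(0.06, p)

    def test_both_degeneracy_signs_supported(self, thermo_params):
        a = barrier_shift(0.01, thermo_params, degeneracy_sign="entropic")
        b = barrier_shift(0.01, thermo_params, degeneracy_sign="as_printed")
        assert a > 0 and b > 0 and a != b


class TestRateFactor:
    def test_identity_at_zero_and_scaling(self, thermo_params):
        assert rate_factor(0.0, thermo_params) == pytest.approx(1.0)
        assert rate_factor(0.01, thermo_params, k0=3.0) == pytest.approx(
            3.0 * rate_factor(0.01, thermo_params), rel=1e-12
        )

    def test_log_roundtrip_recovers_shift(self, thermo_params):
        p = thermo_params
        for s in (0.005, 0.01, 0.02):
            assert -p.kBT * math.log(rate_factor(s, p)) == pytest.approx(
                barrier_shift(s, p), abs=1e-12
            )

    def test_single_exponential_fit_quality(self, thermo_params):
        """k(sigma) on the linear-response grid is well approximated by e^{-w sigma}."""
        grid = default_sigma_grid()[1:]
        factors = [rate_factor(s, thermo_params) for s in grid]
        fit = fit_exponential_w(grid, factors)
        assert fit.w > 0
        assert fit.r_squared > 0.99


class TestExponentialWFit:
    def test_exact_log_linear_data(self):
        s = np.linspace(0.001, 0.05, 10)
        fit = fit_exponential_w(s, np.exp(-3.0 * s))
        assert fit.w == pytest.approx(3.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_factors_give_zero(self):
        s = np.linspace(0.001, 0.05, 10)
        assert fit_exponential_w(s, np.ones(10)).w == 0.0

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            fit_exponential_w([0.0, 0.01], [1.0, 0.9])
        with pytest.raises(ValueError):
            fit_exponential_w([0.0, 0.01, 0.02], [1.0, -0.5, 0.9])


class TestProductionRates:
    kin = InitiationKinetics(k_on=2.0, w=40.0, k_prime=1.5)

    def test_shared_intercept_at_zero(self):
        v0 = self.kin.k_on / (self.kin.k_prime + 1.0)
        assert production_rate_full(0.0, self.kin) == pytest.approx(v0)
        assert production_rate_linear(0.0, self.kin) == pytest.approx(v0)

    def test_w_zero_is_flat(self):
        kin = InitiationKinetics(k_on=2.0, w=0.0, k_prime=1.5)
        s = np.linspace(0, 1, 11)
        assert np.allclose(production_rate_full(s, kin), 2.0 / 2.5)

    def test_large_sigma_limit(self):
        assert production_rate_full(100.0, self.kin) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_non_increasing(self):
        s = np.linspace(0.0, 0.2, 100)
        v = production_rate_full(s, self.kin)
        assert np.all(np.diff(v) <= 0)

    def test_first_order_agreement_near_zero(self):
        sig = 4e-3
        err = abs(production_rate_full(sig, self.kin) - production_rate_linear(sig, self.kin))
        err_half = abs(
            production_rate_full(sig / 2, self.kin) - production_rate_linear(sig / 2, self.kin)
        )
        assert err / err_half == pytest.approx(4.0, rel=0.2)  # O(sigma^2) residual

    def test_linear_clips_at_stall_point(self):
        s_star = linear_stall_sigma(self.kin)
        assert production_rate_linear(s_star, self.kin) == pytest.approx(0.0, abs=1e-12)
        assert production_rate_linear(2 * s_star, self.kin) == 0.0


class TestRateCurveFit:
    def test_recovers_full_model_parameters(self):
        j = np.arange(0, 14, dtype=float)
        true = {"k_on": 0.005, "k_prime": 0.8, "wc": 0.35}
        r = true["k_on"] / (true["k_prime"] * np.exp(true["wc"] * j) + 1.0)
        fit = fit_production_rate(j, r, model="full")
        for k, v in true.items():
            assert fit.params[k] == pytest.approx(v, rel=1e-2)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-6)

    def test_linear_model_on_collinear_data(self):
        j = np.arange(1, 10, dtype=float)
        fit = fit_production_rate(j, 1.0 - 0.05 * j, model="linear")
        assert fit.params["slope"] == pytest.approx(-0.05)
        assert fit.r_squared == pytest.approx(1.0)


def test_curve_tables_shapes(thermo_params, tmp_path):
    df = thermo.barrier_shift_curve(thermo_params, np.linspace(0, 0.01, 5))
    assert list(df.columns) == ["sigma", "ddG_kcal_mol"]
    assert df["ddG_kcal_mol"].iloc[0] == 0.0
    kin = InitiationKinetics(k_on=1.0, w=100.0, k_prime=1.0)
    rt = thermo.production_rate_curve(kin, np.linspace(0, 0.01, 5), model="linear")
    path = tmp_path / "rate.tsv"
    rt.to_csv(path, sep="\t", index=False)
    assert path.read_text().splitlines()[0] == "sigma\trate"
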