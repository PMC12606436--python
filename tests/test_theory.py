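import math

import numpy as np
import pytest

from dimorph import (ModelParams, ShiftSpec, adaptation_timescales,
                     breeder_step, drift_sd_prediction, equilibration_decay,
                     integrate_breeder, lande_trajectories, scaled_sd,
                     time_to_fraction_closed_form)

import pandas as pd


class TestDriftSD:
    def test_delta_unit_values(self, params):
        pred = drift_sd_prediction(params)
        assert pred["E_SD"] == pytest.approx(2 * math.sqrt(2 / math.pi))
        assert pred["E_SD"] == pytest.approx(1.596, abs=5e-4)
        assert pred["V_SD"] == 4.0
        assert pred["V_zfm"] == 2.0
        assert pred["V_zbar"] == 1.0

    def test_linear_scaling_in_delta(self):
        p = ModelParams(N=1000, U=0.01, VS=8 * 1000)  # delta = 2
        pred = drift_sd_prediction(p)
        assert pred["E_SD"] == pytest.approx(2 * 1.5958, abs=2e-3)
        assert pred["V_SD"] == pytest.approx(16.0)

    def test_scaled_sd_significance(self):
        e_sd = 2 * math.sqrt(2 / math.pi)
        assert scaled_sd(e_sd, 4.0) == pytest.approx(0.8, abs=5e-3)
        assert scaled_sd(e_sd, 9.0) == pytest.approx(0.53, abs=0.01)
        assert scaled_sd(e_sd, 1e12) == pytest.approx(0.0, abs=1e-5)
        with pytest.raises(ValueError):
            scaled_sd(e_sd, 0.0)


class TestBreederStep:
    def test_equilibrium_is_fixed_point(self, params):
        dd = breeder_step((0.0, 0.0), (40.0, 0.0, 20.0, 0.0, 0.0), params)
        assert dd == (0.0, 0.0)

    def test_skew_can_stall_adaptation(self, params):
        """When mu3_a = (V_A,a + B) * D_a (and V_A,d = 0) the directional
        and stabilizing terms cancel and the mean stops moving."""
        Da = 3.0
        VA_a, B = 40.0, 20.0
        mu3_a = (VA_a + B) * Da
        dDa, dDd = breeder_step((Da, 0.0), (VA_a, 0.0, B, mu3_a, 0.0), params)
        assert dDa == pytest.approx(0.0, abs=1e-12)
        assert dDd == pytest.approx(0.0, abs=1e-12)

    def test_reduces_to_decoupled_recursion(self, params):
        """With mu3 = 0 and V_A,d = 0 the step is the decoupled linear
        recursion with rates (V_A,a ± B)/(2 VS)."""
        Da, Dd = 5.0, -2.0
        VA_a, B = 40.0, 30.0
        dDa, dDd = breeder_step((Da, Dd), (VA_a, 0.0, B, 0.0, 0.0), params)
        assert dDa == pytest.approx(-(VA_a + B) / (2 * params.VS) * Da)
        assert dDd == pytest.approx(-(VA_a - B) / (2 * params.VS) * Dd)

    def test_general_gamma_master_equation(self):
        """With asymmetric selection shares the step must match a direct
        evaluation of the sex-coordinate master equation."""
        p = ModelParams(N=1000, U=0.01, gamma_f=0.6, gamma_m=0.8)
        VA_f, VA_m, B = 50.0, 30.0, 10.0
        mu3_f, mu3_m = 5.0, -3.0
        Df, Dm = 4.0, 1.0
        g2 = np.diag([2 * 0.36, 2 * 0.64])
        G = np.array([[VA_f, B], [B, VA_m]])
        dfm = (-g2 @ G @ np.array([Df, Dm])
               + g2 @ np.array([mu3_f, mu3_m])) / (2 * p.VS)
        expected = (0.5 * (dfm[0] + dfm[1]), 0.5 * (dfm[0] - dfm[1]))
        got = breeder_step(
            (0.5 * (Df + Dm), 0.5 * (Df - Dm)),
            (0.5 * (VA_f + VA_m), 0.5 * (VA_f - VA_m), B,
             0.5 * (mu3_f + mu3_m), 0.5 * (mu3_f - mu3_m)), p)
        assert got[0] == pytest.approx(expected[0])
        assert got[1] == pytest.approx(expected[1])


class TestLandeTrajectories:
    def test_initial_conditions(self, params):
        shift = ShiftSpec.from_avg_diff(10.0, 5.0)
        pred = lande_trajectories(params, (40.0, 40.0, 20.0), shift, 100)
        assert pred.D_a[0] == 10.0
        assert pred.D_d[0] == 5.0
        assert pred.SDpm[0] == 0.0

    def test_perfect_correlation_freezes_dimorphism(self, params):
        shift = ShiftSpec.from_avg_diff(0.0, 5.0)
        pred = lande_trajectories(params, (40.0, 40.0, 40.0), shift, 2000)
        assert np.allclose(pred.D_d, 5.0)

    def test_euler_recursion_matches_closed_form(self, params):
        """Stepping the discrete recursion generation by generation agrees
        with the continuous-time exponentials to near machine precision on
        long horizons (rates ~1e-2 per generation at most)."""
        shift = ShiftSpec.from_avg_diff(10.0, 5.0)
        G0 = (40.0, 40.0, 20.0)
        horizon = 10_000
        VA_a, B = 40.0, 20.0
        da, dd = 10.0, 5.0
        t_check = {100: None, 1000: None, 10_000: None}
        for t in range(1, horizon + 1):
            step = breeder_step((da, dd), (VA_a, 0.0, B, 0.0, 0.0), params)
            da, dd = da + step[0], dd + step[1]
            if t in t_check:
                t_check[t] = (da, dd)
        # discrete map: (1 - rate)^t ; closed form uses exactly this
        for t, (da_t, dd_t) in t_check.items():
            ra = (VA_a + B) / (2 * params.VS)
            rd = (VA_a - B) / (2 * params.VS)
            assert da_t == pytest.approx(10.0 * (1 - ra) ** t, rel=1e-10)
            assert dd_t == pytest.approx(5.0 * (1 - rd) ** t, rel=1e-10)
        # and the exponential solution agrees with the discrete map to the
        # accuracy of the continuous-time approximation, O(rate) per e-fold
        pred = lande_trajectories(params, G0, shift, horizon)
        assert pred.D_a[100] == pytest.approx(10.0 * (1 - ra) ** 100,
                                              rel=2e-2)

    def test_unequal_variances_integrated_numerically(self, params):
        """V_A,d != 0 couples the two coordinates; the numeric branch must
        agree with an independent matrix-exponential-free Euler oracle."""
        G0 = (50.0, 30.0, 10.0)
        shift = ShiftSpec.from_avg_diff(8.0, 3.0)
        pred = lande_trajectories(params, G0, shift, 500)
        VA_a, VA_d, B = 40.0, 10.0, 10.0
        da, dd = 8.0, 3.0
        for _ in range(500):
            nda = da - ((VA_a + B) * da + VA_d * dd) / (2 * params.VS)
            ndd = dd - (VA_d * da + (VA_a - B) * dd) / (2 * params.VS)
            da, dd = nda, ndd
        assert pred.D_a[-1] == pytest.approx(da, rel=1e-10)
        assert pred.D_d[-1] == pytest.approx(dd, rel=1e-10)

    def test_sdpm_approach(self, params):
        shift = ShiftSpec.from_avg_diff(0.0, 5.0)
        pred = lande_trajectories(params, (40.0, 40.0, 20.0), shift, 5000)
        rate = 40.0 * 0.5 / (2 * params.VS)
        assert pred.SDpm[-1] == pytest.approx(
            2 * 5.0 * (1 - math.exp(-5000 * rate)), rel=1e-9)


class TestTimescales:
    def test_uncorrelated_sexes_equal_phases(self, params):
        shift = ShiftSpec.from_avg_diff(10.0, 10.0)
        t_a, t_d, ratio = adaptation_timescales(params, (40.0, 40.0, 0.0),
                                                shift)
        assert t_a == pytest.approx(t_d)
        assert ratio == pytest.approx(1.0)

    def test_half_correlation_triples_discordant_phase(self, params):
        shift = ShiftSpec.from_avg_diff(10.0, 10.0)
        t_a, t_d, ratio = adaptation_timescales(params, (40.0, 40.0, 20.0),
                                                shift)
        assert ratio == pytest.approx(3.0)
        assert t_d / t_a == pytest.approx(3.0)

    def test_shift_at_delta_gives_zero_phase(self, params):
        shift = ShiftSpec.from_avg_diff(1.0, 1.0)   # delta = 1
        t_a, t_d, _ = adaptation_timescales(params, (40.0, 40.0, 20.0), shift)
        assert t_a == 0.0 and t_d == 0.0

    def test_perfect_correlation_infinite_discordant_phase(self, params):
        shift = ShiftSpec.from_avg_diff(10.0, 10.0)
        t_a, t_d, ratio = adaptation_timescales(params, (40.0, 40.0, 40.0),
                                                shift)
        assert math.isinf(t_d)
        assert math.isinf(ratio)

    def test_monotonicity_in_correlation(self, params):
        """t_a falls and t_d grows as the intersex correlation rises."""
        shift = ShiftSpec.from_avg_diff(10.0, 10.0)
        tas, tds = [], []
        for r in (0.0, 0.3, 0.6, 0.9):
            t_a, t_d, _ = adaptation_timescales(
                params, (40.0, 40.0, 40.0 * r), shift)
            tas.append(t_a)
            tds.append(t_d)
        assert all(a > b for a, b in zip(tas, tas[1:]))
        assert all(a < b for a, b in zip(tds, tds[1:]))


class TestEquilibration:
    def test_decay_rate_landmarks(self, params):
        shift = ShiftSpec.from_avg_diff(10.0, 6.0)
        Fa, Fd = equilibration_decay(shift, params, [0, 2 * params.N])
        assert Fa[0] == 10.0 and Fd[0] == 6.0
        assert Fa[1] == pytest.approx(10.0 / math.e)
        assert Fd[1] == pytest.approx(6.0 / math.e)

    def test_delta_crossing_time(self, params):
        """F_a falls to delta at t = 2N ln(Lambda_a / delta)."""
        La = 10.0
        t_cross = 2 * params.N * math.log(La / params.delta)
        Fa, _ = equilibration_decay(ShiftSpec.from_avg_diff(La, 0.0),
                                    params, [t_cross])
        assert Fa[0] == pytest.approx(params.delta)


class TestMomentDrivenIntegration:
    def test_constant_equilibrium_moments_reproduce_lande(self, params):
        """Driving the moment-resolved step with flat equilibrium moments
        (mu3 = 0, constant G) must reproduce the infinitesimal closed form
        exactly (same discrete map)."""
        VA_a, B = 40.0, 20.0
        gens = np.arange(0, 2001, 50)
        series = pd.DataFrame(dict(
            generation=gens, VA_a=VA_a, VA_d=0.0, B=B, mu3_a=0.0, mu3_d=0.0))
        out = integrate_breeder(series, (10.0, 5.0), params)
        ra = (VA_a + B) / (2 * params.VS)
        rd = (VA_a - B) / (2 * params.VS)
        t = out["generation"].to_numpy() - gens[0]
        assert np.allclose(out["D_a"], 10.0 * (1 - ra) ** t, rtol=1e-12)
        assert np.allclose(out["D_d"], 5.0 * (1 - rd) ** t, rtol=1e-12)

    def test_time_to_fraction_closed_form_inverts_sdpm(self, params):
        rfm, VA_a = 0.5, 40.0
        t80 = time_to_fraction_closed_form(0.8, params, VA_a, rfm)
        rate = VA_a * (1 - rfm) / (2 * params.VS)
        assert 1 - math.exp(-t80 * rate) == pytest.approx(0.8, rel=1e-12)
        assert time_to_fraction_closed_form(0.0, params, VA_a, rfm) == 0.0
        assert math.isinf(time_to_fraction_closed_form(0.5, params, VA_a, 1.0))
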