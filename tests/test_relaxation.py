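"""BPP model algebra, fitting, Arrhenius slopes and isomer inference."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import R

from spinbarrier.relaxation import (
    BPP_MIN_FACTOR,
    OMEGA_TAU_AT_MIN,
    BPPProcess,
    FieldSettings,
    RecoveryCurve,
    RelaxationDataset,
    arrhenius_ea,
    bpp_rate,
    expected_c_ratio,
    fit_bpp,
    fit_recovery,
    isomer_fraction,
    recovery_magnetization,
    round_fraction_to_percent,
    single_process_t1_minimum,
    t1_minimum,
    t1rho_rate,
    total_t1,
    total_t1rho,
)
from spinbarrier.synthdata import (
    METHYL_LOW_PROCESS,
    METHYL_MEDIUM_PROCESS,
    simulate_flank_dataset,
    simulate_t1_dataset,
)

FIELD = FieldSettings(larmor_frequency_mhz=25.0)


class TestRecovery:
    def test_noiseless_round_trip(self):
        t = np.linspace(0.01, 5.0, 30)
        m = recovery_magnetization(t, m0=3.0, t1=1.0)
        t1, m0 = fit_recovery(RecoveryCurve(t, m))
        assert t1 == pytest.approx(1.0, abs=1e-6)
        assert m0 == pytest.approx(3.0, abs=1e-6)

    def test_inversion_convention_at_zero_delay(self):
        assert recovery_magnetization(0.0, m0=2.0, t1=1.0) == pytest.approx(-2.0)

    def test_slow_carbonyl_like_t1_recovered(self):
        """T1 of 15.24 s sampled out to 40 s comes back exactly."""
        t = np.linspace(0.5, 40.0, 25)
        m = recovery_magnetization(t, m0=1.0, t1=15.24)
        t1, _ = fit_recovery(RecoveryCurve(t, m))
        assert t1 == pytest.approx(15.24, abs=1e-4)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            RecoveryCurve(np.array([0.0, 1.0, 2.0]), np.zeros(3))


class TestBPPRate:
    def test_rate_is_linear_in_c(self):
        p1 = BPPProcess(C=1e8, tau0=1e-11, EA=7.0)
        p2 = BPPProcess(C=2e8, tau0=1e-11, EA=7.0)
        T = np.array([100.0, 150.0, 250.0])
        assert np.allclose(bpp_rate(T, p2, FIELD), 2 * bpp_rate(T, p1, FIELD))

    def test_rate_at_omega_tau_unity(self):
        """Where w0*tau = 1 the bracket collapses to 1/2 + 4/5 = 1.3/w0."""
        p = BPPProcess(C=5e8, tau0=1e-11, EA=8.0)
        w0 = FIELD.omega0
        # temperature where tau = 1/w0
        T = p.EA * 1e3 / (R * np.log(1.0 / (w0 * p.tau0)))
        expected = p.C * 1.3 / w0
        assert bpp_rate(T, p, FIELD) == pytest.approx(expected, rel=1e-9)

    def test_maximum_at_stationary_omega_tau(self):
        """Grid search locates the rate maximum at w0*tau = 0.6158."""
        p = METHYL_MEDIUM_PROCESS
        T = np.linspace(80, 350, 27001)
        rates = bpp_rate(T, p, FIELD)
        t_star = T[np.argmax(rates)]
        tau_star = p.correlation_time(t_star)
        assert FIELD.omega0 * tau_star == pytest.approx(OMEGA_TAU_AT_MIN, rel=1e-3)

    def test_rates_add_and_duplication_halves_t1(self):
        p = METHYL_MEDIUM_PROCESS
        T = np.linspace(90, 300, 40)
        one = total_t1(T, [p], FIELD)
        two = total_t1(T, [p, p], FIELD)
        assert np.allclose(two, one / 2, rtol=1e-12)
        both = total_t1(T, [p, METHYL_LOW_PROCESS], FIELD)
        assert np.allclose(
            1 / both,
            1 / total_t1(T, [p], FIELD) + 1 / total_t1(T, [METHYL_LOW_PROCESS], FIELD),
            rtol=1e-12,
        )

    def test_single_process_reciprocal(self):
        p = METHYL_LOW_PROCESS
        assert total_t1(120.0, [p], FIELD) == pytest.approx(
            1.0 / bpp_rate(120.0, p, FIELD), rel=1e-12
        )

    def test_empty_process_list_rejected(self):
        with pytest.raises(ValueError):
            total_t1(100.0, [], FIELD)


class TestRotatingFrame:
    FIELD_B1 = FieldSettings(larmor_frequency_mhz=25.0, b1_gauss=10.0)

    def test_extreme_narrowing_equals_lab_frame(self):
        """w*tau << 1: both 1/T1 and 1/T1rho tend to 5*C*tau."""
        p = BPPProcess(C=1e8, tau0=1e-13, EA=2.0)
        T = 400.0
        tau = p.correlation_time(T)
        assert self.FIELD_B1.omega0 * tau < 1e-3
        r1 = bpp_rate(T, p, self.FIELD_B1)
        r1rho = t1rho_rate(T, p, self.FIELD_B1)
        assert r1 == pytest.approx(5 * p.C * tau, rel=1e-4)
        assert r1rho == pytest.approx(5 * p.C * tau, rel=1e-4)

    def test_t1rho_maximum_near_omega1_tau_half(self):
        """With w0 >> w1 the dominant term peaks where 2*w1*tau = 1."""
        p = BPPProcess(C=1e9, tau0=1e-13, EA=40.0)
        fld = FieldSettings(larmor_frequency_mhz=25.0, b1_gauss=10.0)
        T = np.linspace(150, 400, 100001)
        rate = t1rho_rate(T, p, fld)
        tau_star = p.correlation_time(T[np.argmax(rate)])
        assert fld.omega1 * tau_star == pytest.approx(0.5, rel=0.02)

    def test_doubling_c_doubles_rate(self):
        p1 = BPPProcess(C=1e8, tau0=1e-11, EA=10.0)
        p2 = BPPProcess(C=2e8, tau0=1e-11, EA=10.0)
        assert t1rho_rate(250.0, p2, self.FIELD_B1) == pytest.approx(
            2 * t1rho_rate(250.0, p1, self.FIELD_B1), rel=1e-12
        )

    def test_missing_b1_rejected(self):
        with pytest.raises(ValueError):
            t1rho_rate(250.0, METHYL_MEDIUM_PROCESS, FIELD)


class TestMinimumLocation:
    def test_single_process_matches_closed_form(self):
        p = METHYL_MEDIUM_PROCESS
        t_exp, t1_exp = single_process_t1_minimum(p, FIELD)
        t_num, t1_num = t1_minimum([p], FIELD, (80, 350))
        assert t_num == pytest.approx(t_exp, abs=0.01)
        assert t1_num == pytest.approx(t1_exp, rel=1e-6)
        assert t1_exp == pytest.approx(FIELD.omega0 / (BPP_MIN_FACTOR * p.C), rel=1e-9)

    def test_tau0_scaling_shifts_location_by_arrhenius_algebra(self):
        p = METHYL_MEDIUM_PROCESS
        scaled = BPPProcess(C=p.C, tau0=p.tau0 * np.e, EA=p.EA)
        t0, _ = t1_minimum([p], FIELD, (80, 350))
        t1, _ = t1_minimum([scaled], FIELD, (80, 350))
        # tau0 -> e*tau0 lowers ln(tau_min/tau0) by 1: 1/T drops by R/EA*1e-3
        predicted = 1.0 / (1.0 / t0 - R / (p.EA * 1e3))
        assert t1 == pytest.approx(predicted, abs=0.05)

    def test_monotone_range_rejected(self):
        with pytest.raises(ValueError, match="interior"):
            t1_minimum([METHYL_MEDIUM_PROCESS], FIELD, (250.0, 350.0))


class TestFitBPP:
    def test_noiseless_two_process_round_trip(self):
        ds = simulate_t1_dataset(noise_cv=0.0)
        fit = fit_bpp(ds, n_processes=2)
        assert fit.converged
        low, med = fit.processes
        for got, true in (
            (low.C, METHYL_LOW_PROCESS.C),
            (low.tau0, METHYL_LOW_PROCESS.tau0),
            (low.EA, METHYL_LOW_PROCESS.EA),
            (med.C, METHYL_MEDIUM_PROCESS.C),
            (med.tau0, METHYL_MEDIUM_PROCESS.tau0),
            (med.EA, METHYL_MEDIUM_PROCESS.EA),
        ):
            assert got == pytest.approx(true, rel=1e-3)

    @settings(deadline=None, max_examples=10)
    @given(
        c=st.floats(1e8, 5e9),
        tau0=st.floats(1e-13, 1e-11),
        ea=st.floats(5.0, 25.0),
    )
    def test_noiseless_single_process_round_trip_any_parameters(self, c, tau0, ea):
        p = BPPProcess(C=c, tau0=tau0, EA=ea)
        t_min, _ = single_process_t1_minimum(p, FIELD)
        # only attempt when the minimum is well inside a measurable window
        if not 60.0 < t_min < 280.0:
            return
        grid = np.arange(max(30.0, t_min - 90), t_min + 90, 2.0)
        ds = RelaxationDataset(grid, total_t1(grid, [p], FIELD), FIELD)
        fit = fit_bpp(ds, n_processes=1)
        assert fit.processes[0].EA == pytest.approx(ea, rel=1e-3)
        assert fit.processes[0].C == pytest.approx(c, rel=1e-3)

    def test_processes_reported_ea_ascending(self):
        ds = simulate_t1_dataset(noise_cv=0.05, seed=3)
        fit = fit_bpp(ds, n_processes=2)
        eas = [p.EA for p in fit.processes]
        assert eas == sorted(eas)

    def test_one_process_on_two_minimum_data_fits_much_worse(self):
        ds = simulate_t1_dataset(noise_cv=0.0)
        two = fit_bpp(ds, n_processes=2)
        one = fit_bpp(ds, n_processes=1)
        assert one.residual_norm > 10 * max(two.residual_norm, 1e-6)

    def test_fit_deterministic_given_data(self):
        ds = simulate_t1_dataset(noise_cv=0.05, seed=9)
        a = fit_bpp(ds, n_processes=2)
        b = fit_bpp(ds, n_processes=2)
        assert [(p.C, p.tau0, p.EA) for p in a.processes] == [
            (p.C, p.tau0, p.EA) for p in b.processes
        ]


class TestArrhenius:
    def test_noiseless_flank_recovers_ea_to_0p1_percent(self):
        ds = simulate_flank_dataset(ea=15.8, noise_cv=0.0)
        ea, _ = arrhenius_ea(ds, (260.0, 344.0), flank="high")
        assert ea == pytest.approx(15.8, rel=1e-3)

    def test_zero_slope_gives_zero_ea(self):
        T = np.linspace(260, 344, 12)
        ds = RelaxationDataset(T, np.full_like(T, 2.0), FIELD)
        ea, _ = arrhenius_ea(ds, (260.0, 344.0), flank="high")
        assert ea == pytest.approx(0.0, abs=1e-12)

    def test_global_scaling_of_t1_leaves_ea_unchanged(self):
        ds = simulate_flank_dataset(ea=13.3, noise_cv=0.0)
        scaled = RelaxationDataset(ds.temperatures, 7.5 * ds.times, FIELD)
        ea1, _ = arrhenius_ea(ds, (260.0, 344.0))
        ea2, _ = arrhenius_ea(scaled, (260.0, 344.0))
        assert ea1 == pytest.approx(ea2, rel=1e-12)

    def test_non_monotone_window_warns(self):
        ds = simulate_t1_dataset(noise_cv=0.0)  # spans both flanks of minima
        with pytest.warns(UserWarning, match="monotone|flank"):
            arrhenius_ea(ds, (100.0, 250.0), flank="high")


class TestIsomerInference:
    def test_pure_e_hypothetical_ratio_one_third(self):
        assert expected_c_ratio(1.0) == pytest.approx(1.0 / 3.0)
        assert isomer_fraction(1.0, 3.0) == pytest.approx(1.0)

    def test_zero_ratio_limit_is_pure_z(self):
        assert isomer_fraction(1e-15, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_reported_constants_give_about_three_quarters_e(self):
        f = isomer_fraction(2.29e8, 9.64e8)
        assert 2.29e8 / 9.64e8 == pytest.approx(0.24, abs=0.005)
        assert f == pytest.approx(0.768, abs=0.001)
        assert round_fraction_to_percent(f) == 75.0

    def test_out_of_model_ratio_clips_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            assert isomer_fraction(2.0, 1.0) == 1.0

    @settings(deadline=None, max_examples=50)
    @given(st.floats(1e-6, 0.33), st.floats(1e-6, 0.33))
    def test_monotone_in_ratio(self, r1, r2):
        lo, hi = sorted((r1, r2))
        assert isomer_fraction(lo, 1.0) <= isomer_fraction(hi, 1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            isomer_fraction(0.0, 1.0)
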