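"""PK and PK/PD solver correctness against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apopkpd import (
    InvalidParameterError,
    InvalidProfileError,
    PdParameters,
    PkParametersSC,
    TimeProfile,
    default_grid,
    effect_site_profile,
    sc_plasma_profile,
    sc_tmax_min,
    simulate_subject,
    sl_plasma_profile,
    updrs_change_profile,
)

from conftest import rk4_states, sc_ce_closed_form, sc_full_rhs, sl_full_rhs


class TestScPlasma:
    def test_peak_matches_closed_form_bateman_maximum(self, sc_typical, grid):
        # analytic tmax = ln(ka/kel)/(ka-kel); Cmax recomputed independently here
        ka, kel = sc_typical.ka, sc_typical.kel
        tmax_h = np.log(ka / kel) / (ka - kel)
        assert sc_tmax_min(sc_typical) == pytest.approx(10.8977, abs=1e-3)
        cmax = (
            1e6 / (sc_typical.volume_apparent * 1000.0) * ka / (ka - kel)
            * (np.exp(-kel * tmax_h) - np.exp(-ka * tmax_h))
        )
        assert cmax == pytest.approx(5.21, abs=0.005)
        prof = sc_plasma_profile(sc_typical, 1.0, np.array([0.0, tmax_h * 60.0]))
        assert prof.values[-1] == pytest.approx(cmax, rel=1e-12)
        # grid-based argmax agrees with the closed form within one grid step
        dense = sc_plasma_profile(sc_typical, 1.0, grid)
        assert abs(grid[np.argmax(dense.values)] - 10.8977) <= 0.25

    def test_zero_at_dose_time_and_nonnegative(self, sc_typical, grid):
        prof = sc_plasma_profile(sc_typical, 1.0, grid)
        assert prof.values[0] == 0.0
        assert np.all(prof.values >= 0)

    def test_dose_proportionality(self, sc_typical, grid):
        one = sc_plasma_profile(sc_typical, 1.0, grid).values
        two = sc_plasma_profile(sc_typical, 2.0, grid).values
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-12)

    @pytest.mark.parametrize("dose", [1.0, 4.0])
    def test_matches_rk4_oracle(self, sc_typical, pd_typical, dose, grid):
        states = rk4_states(sc_full_rhs(sc_typical, pd_typical), [dose * 1e6, 0, 0, 0], grid)
        cp_oracle = states[:, 1] / (sc_typical.volume_apparent * 1000.0)
        cp = sc_plasma_profile(sc_typical, dose, grid).values
        np.testing.assert_allclose(cp[1:], cp_oracle[1:], rtol=1e-6)

    def test_ka_equals_kel_limit_is_continuous(self):
        kel = 191.0 / 153.0
        degenerate = PkParametersSC(191.0, 153.0, ka=kel)
        assert degenerate.is_degenerate
        near = PkParametersSC(191.0, 153.0, ka=kel * (1 + 1e-7))
        t = default_grid()
        np.testing.assert_allclose(
            sc_plasma_profile(degenerate, 1.0, t).values[1:],
            sc_plasma_profile(near, 1.0, t).values[1:],
            rtol=1e-5,
        )

    def test_rejects_nonpositive_dose(self, sc_typical, grid):
        with pytest.raises(InvalidParameterError):
            sc_plasma_profile(sc_typical, 0.0, grid)


class TestSlPlasma:
    def test_zero_at_dose_time_peak_in_published_window(self, sl_typical, grid):
        prof = sl_plasma_profile(sl_typical, 30.0, grid)
        assert prof.values[0] == 0.0
        tmax = grid[np.argmax(prof.values)]
        assert 30.0 <= tmax <= 60.0

    @pytest.mark.parametrize("dose", [20.0, 50.0])
    def test_matches_rk4_oracle(self, sl_typical, pd_typical, dose, grid):
        x0 = [dose * 1e6 * sl_typical.bioavailability, 0, 0, 0, 0, 0, 0]
        states = rk4_states(sl_full_rhs(sl_typical, pd_typical), x0, grid)
        cp_oracle = states[:, 3] / (sl_typical.volume_apparent * 1000.0)
        cp = sl_plasma_profile(sl_typical, dose, grid).values
        np.testing.assert_allclose(cp[2:], cp_oracle[2:], rtol=1e-6)

    def test_mass_balance_with_elimination_accumulator(self, sl_typical, pd_typical, grid):
        dose_ng = 30.0 * 1e6 * sl_typical.bioavailability
        states = rk4_states(sl_full_rhs(sl_typical, pd_typical), [dose_ng, 0, 0, 0, 0, 0, 0], grid)
        total = states[:, :5].sum(axis=1) + states[:, 6]
        np.testing.assert_allclose(total, dose_ng, rtol=1e-6)

    def test_dose_proportionality(self, sl_typical, grid):
        low = sl_plasma_profile(sl_typical, 10.0, grid).values
        high = sl_plasma_profile(sl_typical, 35.0, grid).values
        np.testing.assert_allclose(high, 3.5 * low, rtol=1e-10)


class TestEffectSite:
    def test_step_response_is_exact(self):
        # constant Cp=c gives Ce(t) = c*(1 - exp(-ke0*t)) exactly
        t = default_grid(60.0, 0.5)
        cp = TimeProfile(t, np.full_like(t, 7.0))
        ke0 = 5.36
        ce = effect_site_profile(cp, ke0)
        np.testing.assert_allclose(ce.values, 7.0 * (1 - np.exp(-ke0 * t / 60.0)), rtol=1e-12)

    def test_zero_input_gives_zero_output(self, grid):
        ce = effect_site_profile(TimeProfile(grid, np.zeros_like(grid)), 5.36)
        assert np.all(ce.values == 0)

    def test_sc_effect_site_matches_triple_exponential_convolution(
        self, sc_typical, pd_typical, grid
    ):
        prof = simulate_subject(sc_typical, pd_typical, 1.0, grid)
        analytic = sc_ce_closed_form(sc_typical, pd_typical, 1.0, grid)
        np.testing.assert_allclose(prof.ce.values[1:], analytic[1:], rtol=1e-9)
        i = np.argmax(analytic)
        assert 25.0 <= grid[i] <= 27.0
        assert analytic[i] == pytest.approx(4.116, abs=0.005)

    @pytest.mark.parametrize("formulation,dose", [("sc", 1.0), ("sc", 4.0), ("sl", 30.0)])
    def test_ce_peak_crosses_cp(self, formulation, dose, sc_typical, sl_typical, pd_typical, grid):
        # dCe/dt = 0 at the Ce maximum, so Ce equals Cp there (within grid resolution)
        pk = sc_typical if formulation == "sc" else sl_typical
        prof = simulate_subject(pk, pd_typical, dose, grid)
        i = int(np.argmax(prof.ce.values))
        slope = np.abs(np.gradient(prof.cp.values, grid)).max()
        assert abs(prof.ce.values[i] - prof.cp.values[i]) <= slope * 0.25

    def test_rejects_nonpositive_ke0(self, grid):
        with pytest.raises(InvalidParameterError):
            effect_site_profile(TimeProfile(grid, np.zeros_like(grid)), 0.0)


class TestUpdrsChange:
    def test_half_maximal_at_ec50_and_limits(self, pd_typical):
        t = np.array([0.0, 1.0, 2.0])
        ce = TimeProfile(t, np.array([0.0, pd_typical.ec50, 1e6]))
        delta = updrs_change_profile(ce, pd_typical).values
        assert delta[0] == 0.0
        assert delta[1] == pytest.approx(-12.15, abs=1e-9)  # -B0*Emax/2 = -24.3/2
        assert delta[2] == pytest.approx(-24.3, abs=1e-3)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        ce_values=st.lists(st.floats(0, 100), min_size=2, max_size=30),
        b0=st.floats(5, 50),
        emax=st.floats(0.2, 1.0),
        g=st.floats(0.5, 5),
    )
    def test_bounded_and_monotone_in_ce(self, ce_values, b0, emax, g):
        pd_params = PdParameters(ke0=5.36, ec50=10.7, baseline_b0=b0, emax=emax, hill_g=g, mcic=b0 * emax / 10)
        t = np.arange(len(ce_values), dtype=float)
        delta = updrs_change_profile(TimeProfile(t, np.array(ce_values)), pd_params).values
        assert np.all(delta <= 0) and np.all(delta >= -b0 * emax)
        order = np.argsort(ce_values)
        assert np.all(np.diff(delta[order]) <= 1e-12)

    def test_rejects_negative_ce(self, pd_typical):
        with pytest.raises(InvalidProfileError):
            updrs_change_profile(TimeProfile(np.array([0.0, 1.0]), np.array([0.0, -1.0])), pd_typical)


class TestSimulateSubject:
    def test_full_system_matches_rk4_oracle(self, sc_typical, sl_typical, pd_typical, grid):
        for pk, dose, rhs, ncomp in (
            (sc_typical, 2.0, sc_full_rhs(sc_typical, pd_typical), 2),
            (sl_typical, 30.0, sl_full_rhs(sl_typical, pd_typical), 5),
        ):
            x0 = np.zeros(ncomp + 2)
            x0[0] = dose * 1e6 * pk.bioavailability
            states = rk4_states(rhs, x0, grid)
            prof = simulate_subject(pk, pd_typical, dose, grid)
            np.testing.assert_allclose(prof.ce.values[2:], states[2:, ncomp], rtol=1e-6)

    def test_consistent_with_individual_operations(self, sc_typical, pd_typical, grid):
        prof = simulate_subject(sc_typical, pd_typical, 1.0, grid)
        cp = sc_plasma_profile(sc_typical, 1.0, grid)
        np.testing.assert_allclose(prof.cp.values, cp.values, rtol=1e-12)
        ce = effect_site_profile(cp, pd_typical.ke0)
        # piecewise-linear link integration differs only by interpolation
        # error: ~1% relative on the first 0.25-min step where Ce is tiny,
        # ~1e-4 of the peak everywhere else
        np.testing.assert_allclose(ce.values, prof.ce.values, rtol=2e-2, atol=1e-6)
        np.testing.assert_allclose(ce.values, prof.ce.values, atol=1e-3 * prof.ce.values.max())

    def test_effect_bounds_hold_everywhere(self, sc_typical, sl_typical, pd_typical, grid):
        bound = pd_typical.baseline_b0 * pd_typical.emax
        for pk, dose in ((sc_typical, 4.0), (sl_typical, 50.0)):
            delta = simulate_subject(pk, pd_typical, dose, grid).updrs_change.values
            assert np.all(delta <= 0) and np.all(delta > -bound)


class TestParameterInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(clearance_apparent=-1.0, volume_apparent=153.0, ka=14.9),
            dict(clearance_apparent=191.0, volume_apparent=0.0, ka=14.9),
            dict(clearance_apparent=191.0, volume_apparent=153.0, ka=14.9, bioavailability=1.5),
        ],
    )
    def test_sc_rejects_invalid(self, kwargs):
        with pytest.raises(InvalidParameterError):
            PkParametersSC(**kwargs)

    def test_pd_flags_unreachable_mcic(self):
        pd_params = PdParameters(ke0=5.36, ec50=10.7, baseline_b0=24.3, emax=0.1, mcic=3.25)
        assert not pd_params.response_attainable  # max change 2.43 < 3.25

    def test_profile_grid_must_start_at_zero_and_increase(self):
        with pytest.raises(InvalidProfileError):
            TimeProfile(np.array([1.0, 2.0]), np.array([0.0, 0.0]))
        with pytest.raises(InvalidProfileError):
            TimeProfile(np.array([0.0, 2.0, 1.0]), np.zeros(3))
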