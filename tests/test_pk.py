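"""One-compartment closed forms against the numeric ODE oracle and limits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meropk import (
    DoseRegimen,
    PkParameters,
    conc_by_ode,
    conc_continuous_infusion,
    conc_intermittent_ss,
    conc_profile,
    conc_single_infusion,
)
from meropk.pk import InvalidParameterError


class TestParameters:
    def test_ke_is_cl_over_v(self):
        assert PkParameters(10.0, 25.0).k_e == pytest.approx(0.4)

    @pytest.mark.parametrize("cl,v", [(0.0, 25.0), (-1.0, 25.0), (5.0, 0.0), (5.0, -3.0), (math.nan, 25.0)])
    def test_nonpositive_parameters_rejected(self, cl, v):
        with pytest.raises(InvalidParameterError):
            PkParameters(cl, v)

    def test_regimen_infusion_longer_than_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            DoseRegimen(mode="intermittent", dose_mg=1000, infusion_duration_h=9.0, interval_h=8.0)

    def test_daily_dose_excludes_loading(self):
        loading = DoseRegimen(mode="loading", dose_mg=500, infusion_duration_h=0.25)
        assert loading.daily_dose_mg == 0.0
        q8 = DoseRegimen(mode="intermittent", dose_mg=1000, infusion_duration_h=0.5, interval_h=8.0)
        assert q8.daily_dose_mg == pytest.approx(3000.0)


class TestContinuousInfusion:
    def test_initial_condition_is_zero(self):
        assert conc_continuous_infusion(100.0, PkParameters(5.0, 25.0), 0.0) == 0.0

    def test_steady_state_is_rate_over_clearance(self):
        # t -> inf limit: R0/CL
        c = conc_continuous_infusion(100.0, PkParameters(10.0, 25.0), 1e6)
        assert c == pytest.approx(10.0, rel=1e-12)

    def test_agrees_with_ode_oracle(self):
        pk = PkParameters(5.0, 25.0)
        t = 5.0
        closed = conc_continuous_infusion(100.0, pk, t)
        numeric = conc_by_ode([(0.0, 1e4, 100.0)], pk, [t])[0]
        assert closed == pytest.approx(12.642, abs=5e-4)  # (100/5)(1-e^-1)
        assert closed == pytest.approx(numeric, rel=1e-6)

    def test_negative_rate_rejected(self):
        with pytest.raises(InvalidParameterError):
            conc_continuous_infusion(-1.0, PkParameters(5.0, 25.0), 1.0)

    @given(
        cl=st.floats(1.0, 30.0),
        v=st.floats(10.0, 60.0),
        rate=st.floats(0.0, 500.0),
        t=st.floats(0.0, 200.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_nonnegative_and_below_steady_state(self, cl, v, rate, t):
        c = conc_continuous_infusion(rate, PkParameters(cl, v), t)
        assert 0.0 <= c <= rate / cl + 1e-12


class TestIntermittentSteadyState:
    REG = DoseRegimen(mode="intermittent", dose_mg=1000, infusion_duration_h=0.5, interval_h=8.0)

    def test_trough_matches_superposed_ode_doses(self):
        """Closed-form trough equals numeric superposition of 30 infusions."""
        pk = PkParameters(7.1, 25.0)
        n_doses = 30
        segments = [(i * 8.0, 0.5, 2000.0) for i in range(n_doses)]
        t_trough = (n_doses - 1) * 8.0 + 8.0
        numeric = conc_by_ode(segments, pk, [t_trough])[0]
        closed = conc_intermittent_ss(self.REG, pk, 8.0)
        assert closed == pytest.approx(numeric, rel=1e-4)

    def test_infusion_spanning_interval_equals_continuous_steady_state(self):
        # Tinf -> tau limit: same daily dose as a constant infusion
        reg = DoseRegimen(mode="intermittent", dose_mg=1000, infusion_duration_h=8.0, interval_h=8.0)
        pk = PkParameters(7.1, 25.0)
        css = reg.daily_dose_mg / (24.0 * pk.clearance)
        # deep in the interval the profile has flattened onto Css
        assert conc_intermittent_ss(reg, pk, 8.0) == pytest.approx(css, rel=1e-9)

    def test_trough_decreases_with_clearance(self):
        lo = conc_intermittent_ss(self.REG, PkParameters(4.0, 25.0), 8.0)
        hi = conc_intermittent_ss(self.REG, PkParameters(8.0, 25.0), 8.0)
        assert hi < lo

    def test_time_outside_interval_rejected(self):
        with pytest.raises(InvalidParameterError):
            conc_intermittent_ss(self.REG, PkParameters(5.0, 25.0), 9.0)

    def test_peak_exceeds_trough(self):
        pk = PkParameters(7.1, 25.0)
        assert conc_intermittent_ss(self.REG, pk, 0.5) > conc_intermittent_ss(self.REG, pk, 8.0)


class TestProfile:
    LOADING = DoseRegimen(mode="loading", dose_mg=500, infusion_duration_h=0.25)
    CI = DoseRegimen(mode="continuous", dose_mg=2000, infusion_duration_h=24.0, interval_h=24.0)

    def test_loading_peak_hand_value(self):
        # (500/(7*0.25))*(1 - e^(-0.28*0.25)) = 19.316 mg/L at end of infusion
        pk = PkParameters(7.0, 25.0)
        c = conc_profile([(0.0, self.LOADING)], pk, [0.25])[0]
        assert c == pytest.approx(19.316, abs=5e-4)
        numeric = conc_by_ode([(0.0, 0.25, 2000.0)], pk, [0.25])[0]
        assert c == pytest.approx(numeric, rel=1e-6)

    def test_loading_bounded_by_dose_over_volume(self):
        pk = PkParameters(7.0, 25.0)
        t = np.linspace(0.01, 48.0, 200)
        c = conc_profile([(0.0, self.LOADING)], pk, t)
        assert (c <= 500.0 / 25.0).all()

    def test_superposition_linearity(self):
        pk = PkParameters(7.0, 25.0)
        t = np.linspace(0.1, 72.0, 50)
        both = conc_profile([(0.0, self.LOADING), (0.25, self.CI)], pk, t)
        ci_only = conc_profile([(0.25, self.CI)], pk, t)
        load_only = conc_profile([(0.0, self.LOADING)], pk, t)
        np.testing.assert_allclose(both - ci_only, load_only, rtol=1e-12, atol=1e-12)

    def test_loading_washes_out_to_ci_steady_state(self):
        pk = PkParameters(7.0, 25.0)
        c = conc_profile([(0.0, self.LOADING), (0.25, self.CI)], pk, [500.0])[0]
        assert c == pytest.approx(2000.0 / (24.0 * 7.0), rel=1e-9)

    def test_empty_regimen_list_rejected(self):
        with pytest.raises(InvalidParameterError):
            conc_profile([], PkParameters(7.0, 25.0), [1.0])

    def test_profile_matches_ode_for_loading_plus_ci(self):
        pk = PkParameters(7.0, 25.0)
        t = [0.25, 1.0, 6.0, 24.0, 48.0]
        closed = conc_profile([(0.0, self.LOADING), (0.25, self.CI)], pk, t)
        numeric = conc_by_ode([(0.0, 0.25, 2000.0), (0.25, 1e5, 2000.0 / 24.0)], pk, t)
        np.testing.assert_allclose(closed, numeric, rtol=1e-6)


def test_closed_forms_agree_with_ode_over_parameter_grid():
    """Spot grid of (CL, V) values; the full 100-point sweep runs in acceptance."""
    for cl in (2.0, 7.1, 20.0):
        for v in (15.0, 25.0, 40.0):
            pk = PkParameters(cl, v)
            closed = conc_continuous_infusion(100.0, pk, 7.5)
            numeric = conc_by_ode([(0.0, 100.0, 100.0)], pk, [7.5])[0]
            assert closed == pytest.approx(numeric, rel=1e-6)
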