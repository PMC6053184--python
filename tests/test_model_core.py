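"""Units of the core model: forcing, windows, mating kernel, derivatives."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from daphnia_hybrids.model_core import (
    CommunityState,
    HybridClass,
    ModelParameters,
    SeasonCalendar,
    class_sigma,
    day_of_year,
    derivatives,
    hatching_rate,
    mating_output,
    seasonal_sigma,
    switching_rate,
    temperature_factor,
)

nonneg = st.floats(min_value=0.0, max_value=1e3, allow_nan=False)


class TestDayOfYear:
    @pytest.mark.parametrize(
        "t,expected", [(0.0, 0.0), (365.0, 0.0), (36650.0, 150.0), (400.5, 35.5)]
    )
    def test_values(self, t, expected):
        assert day_of_year(t) == pytest.approx(expected)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            day_of_year(-1.0)


class TestSeasonalSigma:
    @pytest.mark.parametrize(
        "t,eps,expected",
        [
            (182.5, 0.7, 1.0),
            (365.0, 0.7, 0.3 / 1.7),
            (365.0, 0.25, 0.6),
            (0.0, 0.0, 1.0),
        ],
    )
    def test_values(self, t, eps, expected):
        assert seasonal_sigma(t, eps) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("eps", [-0.1, 1.0, 1.5])
    def test_amplitude_domain(self, eps):
        with pytest.raises(ValueError):
            seasonal_sigma(100.0, eps)

    @given(t=st.floats(0, 1e5, allow_nan=False), eps=st.floats(0, 0.99))
    @settings(max_examples=200, derandomize=True)
    def test_bounds_and_periodicity(self, t, eps):
        s = seasonal_sigma(t, eps)
        assert (1 - eps) / (1 + eps) - 1e-12 <= s <= 1 + 1e-12
        assert seasonal_sigma(t + 365.0, eps) == pytest.approx(s, abs=1e-9)


class TestClassSigma:
    def test_non_f1_never_overridden(self, params, calendar):
        p = params.with_(eps_winter_F1=0.1)
        for j in (1, 2, 4, 5, 6):
            assert class_sigma(330.0, j, p, calendar) == seasonal_sigma(330.0, 0.7)

    def test_f1_uses_winter_amplitude_in_winter(self, params, calendar):
        p = params.with_(eps_winter_F1=0.1)
        assert class_sigma(330.0, 3, p, calendar) == seasonal_sigma(330.0, 0.1)

    def test_f1_midsummer_is_seasonal_maximum(self, params, calendar):
        p = params.with_(eps_winter_F1=0.1)
        assert class_sigma(182.5, 3, p, calendar) == pytest.approx(1.0)


class TestWindows:
    @pytest.mark.parametrize("doy,expected", [(155.0, 0.5), (280.0, 0.5), (100.0, 0.0)])
    def test_switching(self, calendar, doy, expected):
        assert switching_rate(doy, calendar, 0.5) == expected

    def test_window_edges_half_open(self, calendar):
        # printed "days 151-165" becomes [150, 165)
        assert switching_rate(150.0, calendar, 0.5) == 0.5
        assert switching_rate(165.0, calendar, 0.5) == 0.0

    @pytest.mark.parametrize(
        "doy,j,expected", [(119.5, 1, 0.1), (119.5, 3, 0.05), (200.0, 1, 0.0)]
    )
    def test_hatching(self, calendar, params, doy, j, expected):
        assert hatching_rate(doy, j, calendar, params.h_max) == expected


class TestMatingOutput:
    def test_full_assortment_has_no_hybrid_output(self):
        phi = mating_output(3.0, 5.0, 2.0, c=1.0)
        np.testing.assert_allclose(phi, [1.5, 2.5, 0, 0, 0, 1.0])

    def test_random_mating_two_parents(self):
        phi = mating_output(1.0, 1.0, 0.0, c=0.0)
        np.testing.assert_allclose(phi, [0.25, 0.25, 0.5, 0, 0, 0])

    def test_no_sexuals_yields_zero(self):
        assert mating_output(0.0, 0.0, 0.0, 0.75).sum() == 0.0

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            mating_output(-1.0, 1.0, 1.0, 0.5)

    @given(S1=nonneg, S2=nonneg, S3=nonneg, c=st.floats(0, 1))
    @settings(max_examples=300, derandomize=True)
    def test_encounter_conservation(self, S1, S2, S3, c):
        # every encounter pairs one female and one male: sum(phi) = T/2
        phi = mating_output(S1, S2, S3, c)
        assert phi.sum() == pytest.approx((S1 + S2 + S3) / 2.0, rel=1e-12, abs=1e-12)
        assert np.all(phi >= 0)

    @given(S1=nonneg, S2=nonneg, S3=nonneg)
    @settings(max_examples=100, derandomize=True)
    def test_random_mating_limit(self, S1, S2, S3):
        T = S1 + S2 + S3
        if T == 0:
            return
        phi = mating_output(S1, S2, S3, c=0.0)
        assert phi[0] == pytest.approx(S1**2 / (2 * T), rel=1e-12, abs=1e-12)
        assert phi[5] == pytest.approx(S3**2 / (2 * T), rel=1e-12, abs=1e-12)


class TestTemperatureFactor:
    @pytest.mark.parametrize(
        "x,q", [(0.0, 1.0), (10.0, 2.0), (-5.0, 2**-0.5), (-3.0, 2**-0.3)]
    )
    def test_q10_scaling(self, x, q):
        assert temperature_factor(x) == pytest.approx(q, rel=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            temperature_factor(float("nan"))


def _r_const(value=0.35):
    vec = np.full(6, value)
    return lambda t: vec


class TestDerivatives:
    def test_zero_state_is_fixed_point(self, params, calendar):
        dy = derivatives(10.0, np.zeros(18), params, calendar, _r_const())
        np.testing.assert_array_equal(dy, np.zeros(18))

    def test_logistic_limit(self, calendar):
        # one class, no switching/hatching, eps=0: plain logistic growth
        p = ModelParameters(s_max=0.0, eps_base=0.0, eps_winter_F1=0.0)
        y = np.zeros(18)
        y[0] = 30.0
        dy = derivatives(200.0, y, p, calendar, _r_const(0.35))
        assert dy[0] == pytest.approx(0.35 * 30.0 * (1 - 30.0 / 150.0), rel=1e-12)
        assert np.all(dy[1:] == 0)

    def test_growth_vanishes_at_seasonal_capacity(self, params, calendar):
        t = 40.0  # outside all windows
        sigma = seasonal_sigma(t, params.eps_base)
        y = np.zeros(18)
        y[0:6] = sigma * params.K / 6.0  # total A+S exactly sigma*K
        dy = derivatives(t, y, params, calendar, _r_const())
        np.testing.assert_allclose(dy[0:6], np.zeros(6), atol=1e-12)

    def test_non_finite_state_rejected(self, params, calendar):
        y = np.zeros(18)
        y[3] = np.nan
        with pytest.raises(ValueError):
            derivatives(0.0, y, params, calendar, _r_const())

    @given(data=st.data())
    @settings(max_examples=100, derandomize=True)
    def test_boundary_nonnegativity(self, data, params, calendar):
        # a variable at zero can never be pushed negative
        y = np.array(
            data.draw(st.lists(nonneg, min_size=18, max_size=18))
        )
        i = data.draw(st.integers(0, 17))
        t = data.draw(st.floats(0, 365))
        y[i] = 0.0
        dy = derivatives(t, y, params, calendar, _r_const())
        assert dy[i] >= -1e-12


class TestContainers:
    def test_state_round_trip(self):
        y = np.arange(18.0)
        state = CommunityState.from_vector(y)
        np.testing.assert_array_equal(state.to_vector(), y)

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            CommunityState.from_vector(np.full(18, -1.0))

    def test_six_classes_in_canonical_order(self):
        roles = [c.name for c in HybridClass]
        assert roles == [
            "PARENTAL_1",
            "PARENTAL_2",
            "F1_HYBRID",
            "BACKCROSS_1",
            "BACKCROSS_2",
            "F2_HYBRID",
        ]

    def test_parameter_defaults_match_reference_table(self, params):
        assert (params.m, params.K, params.k, params.f) == (0.15, 150.0, 1.0, 0.14)
        assert params.c == 0.75
        np.testing.assert_array_equal(params.e, [0.7, 0.7, 0.8, 0.75, 0.75, 0.85])
        np.testing.assert_array_equal(params.h_max, [0.1, 0.1, 0.05, 0.05, 0.05, 0.05])
        assert params.s_max == 0.5
        assert params.eps_base == 0.7

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(c=1.5)
        with pytest.raises(ValueError):
            ModelParameters(eps_base=1.0)
        with pytest.raises(ValueError):
            SeasonCalendar(hatching_window=(370.0, 380.0))
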