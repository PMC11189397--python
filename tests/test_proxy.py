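"""Unit tests for the closed-form proxy chain."""
import math

import numpy as np
import pytest

from epco2.proxy import (
    ProxySaturationError,
    biomass_from_lipid,
    co2aq_hco3_fractionation,
    delta_co2aq_from_foram,
    delta_p_from_epsilon,
    epsilon_p,
    henry_k0,
    interpolate_series,
    pco2_point,
    weighted_sterane_delta,
)


class TestWeightedSteraneDelta:
    @pytest.mark.parametrize(
        "deltas, fractions, expected",
        [
            ([-27, -27, -27], [0.2, 0.3, 0.5], -27.0),
            ([-28.2, -24.3], [0.5, 0.5], -26.25),
            ([-26, -30], [1, 0], -26.0),
        ],
    )
    def test_values(self, deltas, fractions, expected):
        assert weighted_sterane_delta(deltas, fractions) == pytest.approx(expected)

    def test_unnormalised_weights_ok(self):
        assert weighted_sterane_delta([-26, -30], [2, 2]) == pytest.approx(-28.0)

    @pytest.mark.parametrize(
        "deltas, fractions",
        [([], []), ([-26], [0.0]), ([-26, -27], [0.0, 0.0]), ([-26], [-1.0]), ([-26, -27], [1.0])],
    )
    def test_invalid(self, deltas, fractions):
        with pytest.raises(ValueError):
            weighted_sterane_delta(deltas, fractions)


class TestBiomassFromLipid:
    @pytest.mark.parametrize(
        "lipid, offset, expected",
        [(-26.8, 3.5, -23.3), (-25.0, 0.0, -25.0), (-21.4, 3.9, -17.5)],
    )
    def test_values(self, lipid, offset, expected):
        assert biomass_from_lipid(lipid, offset) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            biomass_from_lipid(float("nan"), 3.5)


class TestDeltaCo2aq:
    def test_fractionation_at_25c(self):
        assert co2aq_hco3_fractionation(25.0) == pytest.approx(-8.9707, abs=1e-4)

    def test_combined_value(self):
        assert delta_co2aq_from_foram(1.5, 25.0) == pytest.approx(-7.484182, abs=1e-5)

    def test_zero_fractionation_limit(self):
        # at the (nonphysical) temperature where eps = 0 the correction vanishes
        t_zero = 9866.0 / 24.12 - 273.15
        assert co2aq_hco3_fractionation(t_zero) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_sst(self):
        ssts = np.linspace(-2, 45, 60)
        vals = delta_co2aq_from_foram(1.0, ssts)
        assert np.all(np.diff(vals) > 0)

    def test_sst_out_of_range(self):
        with pytest.raises(ValueError):
            delta_co2aq_from_foram(1.0, 50.0)


class TestEpsilonP:
    @pytest.mark.parametrize(
        "dd, dp, expected",
        [(-25.0, -25.0, 0.0), (-8.0, -26.0, 18.4805), (0.0, -10.0, 10.1010)],
    )
    def test_values(self, dd, dp, expected):
        assert epsilon_p(dd, dp) == pytest.approx(expected, abs=1e-4)

    def test_decreasing_in_delta_p(self):
        dps = np.linspace(-40, 0, 50)
        vals = epsilon_p(-8.0, dps)
        assert np.all(np.diff(vals) < 0)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            epsilon_p(-8.0, -1000.0)

    def test_first_order_approximation(self):
        # eps_p ~ dd - dp within 5% for realistic magnitudes
        rng = np.random.default_rng(0)
        dd = rng.uniform(-30, 30, 500)
        dp = rng.uniform(-30, 30, 500)
        keep = np.abs(dd - dp) > 1e-6
        ep = epsilon_p(dd[keep], dp[keep])
        diff = dd[keep] - dp[keep]
        assert np.all(np.abs(ep - diff) < 0.05 * np.abs(diff))

    def test_inverse_identity(self):
        dd, ep = -7.8, 14.2
        dp = delta_p_from_epsilon(dd, ep)
        assert epsilon_p(dd, dp) == pytest.approx(ep, abs=1e-12)


def _weiss_reference(t_c, s):
    """Independent transcription of the solubility ln-polynomial (scalar)."""
    tk = t_c + 273.15
    a = [-60.2409, 93.4517, 23.3585]
    b = [0.023517, -0.023656, 0.0047036]
    ln_k0 = (
        a[0]
        + a[1] * (100.0 / tk)
        + a[2] * math.log(tk / 100.0)
        + s * (b[0] + b[1] * (tk / 100.0) + b[2] * (tk / 100.0) ** 2)
    )
    return math.exp(ln_k0)


class TestHenryK0:
    def test_reference_point(self):
        assert henry_k0(25.0, 35.0) == pytest.approx(0.02839, abs=5e-5)

    def test_two_implementation_agreement(self):
        for t in np.linspace(-2, 45, 25):
            for s in (0.0, 20.0, 35.0, 45.0):
                assert henry_k0(float(t), s) == pytest.approx(
                    _weiss_reference(float(t), s), rel=1e-12
                )

    def test_monotone_in_temperature_and_salinity(self):
        assert henry_k0(0.0, 35.0) > henry_k0(25.0, 35.0)
        assert henry_k0(25.0, 0.0) > henry_k0(25.0, 35.0)
        t = np.linspace(-2, 45, 40)
        assert np.all(np.diff(henry_k0(t, 35.0)) < 0)

    @pytest.mark.parametrize("t, s", [(-5, 35), (50, 35), (25, -1), (25, 50)])
    def test_range_errors(self, t, s):
        with pytest.raises(ValueError):
            henry_k0(t, s)


class TestPco2Point:
    def test_phytane_endpoint_arithmetic(self):
        co2aq, pco2 = pco2_point(11.2, 168.0, 26.5, 0.02839)
        assert co2aq == pytest.approx(10.98, abs=0.01)
        assert pco2 == pytest.approx(386.8, abs=0.1)

    def test_exact_scaling(self):
        co2aq, pco2 = pco2_point(26.5 - 16.8, 168.0, 26.5, 0.025)
        assert co2aq == pytest.approx(10.0, rel=1e-12)
        assert pco2 == pytest.approx(400.0, rel=1e-12)

    def test_saturation_error(self):
        with pytest.raises(ProxySaturationError):
            pco2_point(26.5, 168.0, 26.5, 0.0284)

    def test_monotone_in_eps_p_and_k0(self):
        eps = np.linspace(5, 25, 30)
        pco2s = [pco2_point(e, 168.0, 26.5, 0.0284)[1] for e in eps]
        assert np.all(np.diff(pco2s) > 0)
        k0s = np.linspace(0.02, 0.06, 30)
        pco2s = [pco2_point(14.0, 168.0, 26.5, k)[1] for k in k0s]
        assert np.all(np.diff(pco2s) < 0)

    def test_forward_inverse_round_trip(self):
        # forward-model pCO2 -> eps_p -> delta_p, then invert the chain
        rng = np.random.default_rng(3)
        for _ in range(200):
            pco2_true = rng.uniform(150, 1200)
            sst = rng.uniform(0, 30)
            sal = rng.uniform(30, 40)
            b, ef = rng.uniform(120, 220), rng.uniform(25, 28)
            k0 = henry_k0(sst, sal)
            co2aq = pco2_true * k0
            ep = ef - b / co2aq
            if ep >= ef - 0.5:
                continue
            dd = delta_co2aq_from_foram(1.5, sst)
            dp = delta_p_from_epsilon(dd, ep)
            ep_back = epsilon_p(dd, dp)
            _, pco2_back = pco2_point(ep_back, b, ef, k0)
            assert pco2_back == pytest.approx(pco2_true, rel=1e-9)


class TestInterpolateSeries:
    def test_linear_identity(self):
        vals, in_rng = interpolate_series([5.0], [0.0, 10.0], [0.0, 10.0])
        assert vals[0] == pytest.approx(5.0)
        assert in_rng[0]

    def test_knot_exact(self):
        vals, _ = interpolate_series([3.2], [0.0, 3.2, 10.0], [0.0, 24.0, 67.0])
        assert vals[0] == 24.0

    def test_sea_level_tie_points(self):
        vals, _ = interpolate_series([6.6], [3.2, 10.0], [24.0, 67.0])
        assert vals[0] == pytest.approx(45.5)

    def test_out_of_range_flagged(self):
        vals, in_rng = interpolate_series([-1.0, 5.0, 11.0], [0.0, 10.0], [0.0, 10.0])
        assert list(in_rng) == [False, True, False]

    @pytest.mark.parametrize("ages", [[0.0], [5.0, 3.0], [1.0, 1.0, 2.0]])
    def test_bad_series(self, ages):
        with pytest.raises(ValueError):
            interpolate_series([1.0], ages, list(range(len(ages))))
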