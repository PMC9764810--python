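"""Equalizing-resistor optimization, regime curves and realizations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taueq.design import (
    DiameterRange,
    EnvelopeEmptyError,
    operating_envelope,
    optimal_equalizing_resistance,
    peak_diameter,
    required_pressure,
    resistor_realization,
    tau_eq_design,
    tau_eq_wss,
    wss_profile,
    wss_variation,
)
from taueq.hydraulics import (
    CircularChannel,
    FluidProperties,
    RectangularChannel,
    resistance_circular,
    resistance_rectangular,
)
from taueq.units import parse_quantity

from conftest import LUMEN_LENGTH


class TestOptimalResistance:
    def test_reference_value_for_target_range(self, target_range, medium):
        r_eq = optimal_equalizing_resistance(target_range, LUMEN_LENGTH, medium)
        assert r_eq == pytest.approx(3.72e10, rel=2e-3)

    def test_endpoint_wss_equality_by_construction(self, target_range, medium):
        r_eq = optimal_equalizing_resistance(target_range, LUMEN_LENGTH, medium)
        t_lo = tau_eq_wss(target_range.d_min, 330.0, LUMEN_LENGTH, medium, r_eq)
        t_hi = tau_eq_wss(target_range.d_max, 330.0, LUMEN_LENGTH, medium, r_eq)
        assert abs(t_lo - t_hi) <= 1e-9 * t_lo

    @given(
        d_min=st.floats(min_value=5e-5, max_value=4e-4),
        ratio=st.floats(min_value=1.05, max_value=3.0),
        length=st.floats(min_value=5e-3, max_value=5e-2),
        mu=st.floats(min_value=5e-4, max_value=5e-3),
    )
    @settings(derandomize=True, max_examples=100, deadline=None)
    def test_endpoint_equality_for_any_valid_design(self, d_min, ratio, length, mu):
        rng = DiameterRange(d_min, d_min * ratio)
        fluid = FluidProperties(mu)
        r_eq = optimal_equalizing_resistance(rng, length, fluid)
        lo = tau_eq_wss(rng.d_min, 100.0, length, fluid, r_eq)
        hi = tau_eq_wss(rng.d_max, 100.0, length, fluid, r_eq)
        assert abs(lo - hi) <= 1e-9 * lo

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            DiameterRange(200e-6, 200e-6)

    def test_variation_vanishes_as_range_shrinks(self, medium):
        spreads = []
        for width in (120e-6, 40e-6, 10e-6, 2e-6):
            rng = DiameterRange(240e-6 - width / 2, 240e-6 + width / 2)
            prof = wss_profile("tau_eq", rng, LUMEN_LENGTH, medium, 300.0,
                               grid_step=width / 100)
            spreads.append(wss_variation(prof).rel_difference)
        assert all(a > b for a, b in zip(spreads, spreads[1:]))
        assert spreads[-1] < 1e-4


class TestRegimeProfiles:
    def test_fixed_flow_spread_is_cubic_ratio(self, target_range, medium):
        prof = wss_profile("fixed_flow", target_range, LUMEN_LENGTH, medium, 1.71e-9)
        v = wss_variation(prof)
        assert v.ratio_max_min == pytest.approx((300 / 180) ** 3, rel=1e-6)
        assert v.ratio_max_min <= 5.0

    def test_fixed_dp_spread_is_linear_ratio(self, target_range, medium):
        prof = wss_profile("fixed_dp", target_range, LUMEN_LENGTH, medium, 183.0)
        v = wss_variation(prof)
        assert v.ratio_max_min == pytest.approx(300 / 180, rel=1e-6)
        assert v.ratio_max_min <= 2.0

    def test_equalized_profile_peaks_inside_the_range(self, target_range, medium):
        r_eq = optimal_equalizing_resistance(target_range, LUMEN_LENGTH, medium)
        d_star = peak_diameter(LUMEN_LENGTH, medium, r_eq)
        assert target_range.d_min < d_star < target_range.d_max
        assert d_star == pytest.approx(237e-6, rel=5e-3)
        prof = wss_profile("tau_eq", target_range, LUMEN_LENGTH, medium, 330.0)
        d_peak = prof.diameters[np.argmax(prof.wss)]
        assert d_peak == pytest.approx(d_star, abs=1e-6)

    def test_equalized_spread_below_ten_percent(self, target_range, medium):
        prof = wss_profile("tau_eq", target_range, LUMEN_LENGTH, medium, 330.0)
        v = wss_variation(prof)
        assert v.rel_difference < 0.10
        # the same spread expressed relative to the minimum is ~9.8%
        assert v.ratio_max_min - 1 == pytest.approx(0.098, abs=0.002)

    def test_equalized_always_narrower_than_either_baseline(self, medium):
        for d_min, d_max in ((150e-6, 250e-6), (180e-6, 300e-6), (100e-6, 280e-6)):
            rng = DiameterRange(d_min, d_max)
            spreads = {
                regime: wss_variation(
                    wss_profile(regime, rng, LUMEN_LENGTH, medium, drive)
                ).rel_difference
                for regime, drive in (
                    ("fixed_flow", 1e-9), ("fixed_dp", 200.0), ("tau_eq", 200.0),
                )
            }
            assert spreads["tau_eq"] < spreads["fixed_flow"]
            assert spreads["tau_eq"] < spreads["fixed_dp"]

    def test_unknown_regime_rejected(self, target_range, medium):
        with pytest.raises(ValueError):
            wss_profile("fixed_everything", target_range, LUMEN_LENGTH, medium, 1.0)

    def test_constant_profile_has_zero_variation(self, target_range, medium):
        prof = wss_profile("fixed_dp", target_range, LUMEN_LENGTH, medium, 100.0)
        prof.wss[:] = 0.75
        v = wss_variation(prof)
        assert v.ratio_max_min == 1.0 and v.rel_difference == 0.0 and v.cv == 0.0


class TestRequiredPressure:
    def test_bare_lumen_reduces_to_wall_force_balance(self, medium):
        lumen = CircularChannel(240e-6, LUMEN_LENGTH)
        dp = required_pressure(1.0, lumen, None, medium)
        assert dp == pytest.approx(4 * 1.0 * LUMEN_LENGTH / 240e-6, rel=1e-12)
        assert dp == pytest.approx(183.3, rel=1e-3)

    def test_with_equalizing_resistor_about_2p5_mbar(self, target_range, medium):
        r_eq = optimal_equalizing_resistance(target_range, LUMEN_LENGTH, medium)
        resistor = resistor_realization(r_eq, "tubing", medium, diameter=800e-6)
        lumen = CircularChannel(240e-6, LUMEN_LENGTH)
        dp = required_pressure(1.0, lumen, resistor, medium)
        assert dp == pytest.approx(247.0, rel=0.01)  # ≈ 2.5 mbar

    def test_linear_in_target_wss(self, medium):
        lumen = CircularChannel(200e-6, LUMEN_LENGTH)
        resistor = RectangularChannel(1e-3, 0.2e-3, 0.1)
        assert required_pressure(3.0, lumen, resistor, medium) == pytest.approx(
            3 * required_pressure(1.0, lumen, resistor, medium), rel=1e-12
        )


class TestRealization:
    def test_tubing_length_for_target_range(self, target_range, medium):
        r_eq = optimal_equalizing_resistance(target_range, LUMEN_LENGTH, medium)
        tubing = resistor_realization(r_eq, "tubing", medium, diameter=800e-6)
        # closed form: L = L_v (d2−d1) D⁴ / (d1 d2 (d2³−d1³)); viscosity cancels
        d1, d2, big_d = 180e-6, 300e-6, 800e-6
        expected = LUMEN_LENGTH * (d2 - d1) * big_d**4 / (d1 * d2 * (d2**3 - d1**3))
        assert tubing.length == pytest.approx(expected, rel=1e-9)
        assert tubing.length == pytest.approx(0.473, rel=1e-3)
        # the 52 cm used in practice on an assembled setup is within 15%
        assert abs(tubing.length - 0.52) / 0.52 < 0.15

    def test_viscosity_cancels_in_tubing_realization(self, target_range):
        lengths = []
        for mu in (0.5e-3, 0.79e-3, 3e-3):
            fluid = FluidProperties(mu)
            r_eq = optimal_equalizing_resistance(target_range, LUMEN_LENGTH, fluid)
            lengths.append(resistor_realization(r_eq, "tubing", fluid, diameter=800e-6).length)
        assert max(lengths) == pytest.approx(min(lengths), rel=1e-12)

    def test_length_linear_in_target(self, medium):
        a = resistor_realization(1e10, "tubing", medium, diameter=800e-6).length
        b = resistor_realization(2e10, "tubing", medium, diameter=800e-6).length
        assert b == pytest.approx(2 * a, rel=1e-12)

    @pytest.mark.parametrize("kind,kwargs", [
        ("tubing", {"diameter": 800e-6}),
        ("channel", {"width": 1e-3, "height": 0.2e-3}),
    ])
    def test_round_trip_identity(self, medium, kind, kwargs):
        r_target = 3.7e10
        realized = resistor_realization(r_target, kind, medium, **kwargs)
        back = (
            resistance_circular(realized, medium)
            if kind == "tubing"
            else resistance_rectangular(realized, medium)
        )
        assert back == pytest.approx(r_target, rel=1e-9)

    def test_nonpositive_target_rejected(self, medium):
        with pytest.raises(ValueError):
            resistor_realization(0.0, "tubing", medium, diameter=800e-6)


class TestDesignBundle:
    def test_complete_design_consistent(self, target_range, medium):
        d = tau_eq_design(target_range, LUMEN_LENGTH, medium, target_wss=1.0)
        assert d.variation.rel_difference < 0.10
        report = d.to_dict()
        assert report["rel_difference"] < 0.10
        assert report["equalizing_resistance"]["unit"] == "Pa.s/m3"

    def test_unit_round_trip_invariance(self, medium):
        # a design stated in µm/cm/mPa·s equals the same design stated in SI
        rng_a = DiameterRange(parse_quantity("180um"), parse_quantity("300um"))
        a = tau_eq_design(rng_a, parse_quantity("1.1cm"),
                          FluidProperties(parse_quantity("0.79mPas")))
        b = tau_eq_design(DiameterRange(180e-6, 300e-6), 1.1e-2, FluidProperties(0.79e-3))
        assert a.equalizing_resistance == pytest.approx(b.equalizing_resistance, rel=1e-12)
        assert a.dp_for_target_wss == pytest.approx(b.dp_for_target_wss, rel=1e-12)


class TestOperatingEnvelope:
    def test_zero_resistance_envelope_spans_almost_full_scale(self, target_range, medium):
        env = operating_envelope(1.0, target_range, LUMEN_LENGTH, medium,
                                 upstream_resistance=0.0, downstream_resistance=0.0)
        assert env.p_lumen_min == 0.0
        # upper bound is full scale minus only the drive ΔP (→ FS as τ → 0)
        assert env.p_lumen_max < 34_500.0
        tiny = operating_envelope(1e-6, target_range, LUMEN_LENGTH, medium)
        assert tiny.p_lumen_max == pytest.approx(34_500.0, abs=1.0)

    def test_head_correction_is_hydrostatic_and_monotone(self, target_range, medium):
        heads = [
            operating_envelope(1.0, target_range, LUMEN_LENGTH, medium,
                               liquid_height=h).head_correction
            for h in (0.0, 0.04, 0.085)
        ]
        assert heads[0] == 0.0
        assert heads[2] == pytest.approx(medium.density * 9.81 * 0.085, rel=1e-12)
        assert heads[0] < heads[1] < heads[2]
        capped = operating_envelope(1.0, target_range, LUMEN_LENGTH, medium,
                                    liquid_height=0.2, max_head=800.0)
        assert capped.head_correction == 800.0

    def test_envelope_shrinks_strictly_with_target_wss(self, target_range, medium):
        widths = []
        for tau in (1.0, 2.0, 3.0, 5.0):
            env = operating_envelope(
                tau, target_range, LUMEN_LENGTH, medium,
                upstream_resistance=5e10, downstream_resistance=5e10,
                cracking_pressure=1200.0,
            )
            widths.append(env.p_lumen_max - env.p_lumen_min)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_infeasible_target_raises(self, target_range, medium):
        with pytest.raises(EnvelopeEmptyError):
            operating_envelope(5.0, target_range, LUMEN_LENGTH, medium,
                               upstream_resistance=5e12, downstream_resistance=5e12)
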