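import numpy as np
import pytest
import xarray as xr
from hypothesis import given, settings, strategies as st

from isodenit.grid import GridSpec
from isodenit.isotope import (
    FdenitResult,
    IsotopeParams,
    NInputSet,
    ensemble_fdenit,
    epsilon_sensitivity,
    forward_delta,
    invert_fdenit,
    mix_input_delta,
    monte_carlo_fdenit,
    rock_delta_map,
)




def _v(x):
    """Scalar value of a single-cell field (or a plain number)."""
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    return float(arr.reshape(-1)[0])

def _cell(spec1cell, value):
    return spec1cell.full(_v(value))


def _inputs(spec1cell, dep, bnf, rock, delta_rock=4.02):
    return NInputSet(
        i_dep=_cell(spec1cell, dep),
        i_bnf=_cell(spec1cell, bnf),
        i_rock=_cell(spec1cell, rock),
        delta_rock=delta_rock,
    )


class TestMixInputDelta:
    def test_equal_signatures_pass_through(self, spec1cell):
        s = _inputs(spec1cell, 1.0, 2.0, 3.0, delta_rock=-2.0)
        s.delta_dep = s.delta_bnf = -2.0
        assert _v(mix_input_delta(s)) == pytest.approx(-2.0)

    def test_global_component_totals_give_minus_0p690(self, spec1cell):
        # (10*4.02 + 40*0 + 57*(-2)) / 107 = -0.68972
        s = _inputs(spec1cell, 40.0, 57.0, 10.0)
        assert _v(mix_input_delta(s)) == pytest.approx(-0.6897196, abs=1e-6)

    def test_zero_component_leaves_weighted_mean_of_rest(self, spec1cell):
        s = _inputs(spec1cell, 0.0, 1.0, 1.0, delta_rock=4.0)
        assert _v(mix_input_delta(s)) == pytest.approx((4.0 - 2.0) / 2.0)

    def test_zero_total_flux_masks_cell_with_warning(self, spec1cell):
        s = _inputs(spec1cell, 0.0, 0.0, 0.0)
        with pytest.warns(UserWarning, match="zero total"):
            out = mix_input_delta(s)
        assert bool(out.isnull().all())


class TestRockDeltaMap:
    def test_single_lithology_returns_its_signature(self, spec1cell):
        delta, gmean = rock_delta_map(
            {"igneous": _cell(spec1cell, 1.0)}, {"igneous": 3.3},
            _cell(spec1cell, 2.0),
        )
        assert _v(delta) == pytest.approx(3.3)
        assert gmean == pytest.approx(3.3)

    def test_equal_mix_of_bounds_gives_4p02(self, spec1cell):
        # midpoint of the lithology bounds 1.47 and 6.57 permil
        delta, gmean = rock_delta_map(
            {"low": _cell(spec1cell, 0.5), "high": _cell(spec1cell, 0.5)},
            {"low": 1.47, "high": 6.57},
            _cell(spec1cell, 1.0),
        )
        assert gmean == pytest.approx(4.02)

    def test_fractions_must_sum_to_one(self, spec1cell):
        with pytest.raises(ValueError, match="sum to 1"):
            rock_delta_map(
                {"a": _cell(spec1cell, 0.7)}, {"a": 2.0}, _cell(spec1cell, 1.0)
            )

    def test_zero_rock_flux_everywhere_is_undefined(self, spec1cell):
        with pytest.raises(ValueError, match="zero everywhere"):
            rock_delta_map(
                {"a": _cell(spec1cell, 1.0)}, {"a": 2.0}, _cell(spec1cell, 0.0)
            )


class TestInversion:
    def test_global_means_give_0p42(self, spec1cell, params):
        res = invert_fdenit(_cell(spec1cell, 4.8), _cell(spec1cell, -0.66), params)
        assert round(_v(res.mean), 2) == 0.42
        assert res.clipped_fraction == 0.0

    def test_soil_equals_input_gives_zero(self, spec1cell, params):
        res = invert_fdenit(_cell(spec1cell, 1.5), _cell(spec1cell, 1.5), params)
        assert _v(res.mean) == 0.0

    def test_volatilization_term_lowers_fdenit(self, spec1cell):
        # (4.8 + 0.66 - 0.05*29) / 13 = 0.30846
        p = IsotopeParams(f_vol=0.05, eps_vol=29.0)
        res = invert_fdenit(_cell(spec1cell, 4.8), _cell(spec1cell, -0.66), p)
        assert _v(res.mean) == pytest.approx(0.30846, abs=1e-4)

    def test_clipping_respects_physical_bounds(self, spec1cell, params):
        res = invert_fdenit(_cell(spec1cell, 30.0), _cell(spec1cell, 0.0), params)
        assert _v(res.mean) == 1.0
        assert res.clipped_fraction == 1.0

    def test_degenerate_fractionation_rejected(self):
        with pytest.raises(ValueError, match="eps_denit"):
            IsotopeParams(eps_denit=0.0, eps_leach=0.0)


class TestForward:
    def test_no_denitrification_returns_input_signature(self, spec1cell, params):
        out = forward_delta(_cell(spec1cell, 0.0), _cell(spec1cell, -0.66), params)
        assert _v(out) == pytest.approx(-0.66)

    def test_pure_denitrification_adds_full_epsilon(self, spec1cell, params):
        out = forward_delta(_cell(spec1cell, 1.0), _cell(spec1cell, 0.0), params)
        assert _v(out) == pytest.approx(13.0)

    def test_global_mean_forward_value(self, spec1cell, params):
        out = forward_delta(_cell(spec1cell, 0.42), _cell(spec1cell, -0.66), params)
        assert _v(out) == pytest.approx(4.80, abs=1e-12)

    def test_out_of_range_fraction_rejected(self, spec1cell, params):
        with pytest.raises(ValueError, match="fdenit"):
            forward_delta(_cell(spec1cell, 1.2), _cell(spec1cell, 0.0), params)


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    f=st.floats(0.0, 1.0),
    delta_input=st.floats(-5.0, 8.0),
    eps_denit=st.floats(8.0, 25.0),
    eps_leach=st.floats(-1.0, 2.0),
    f_vol=st.floats(0.0, 0.2),
    eps_vol=st.floats(29.0, 35.0),
)
def test_forward_inverse_round_trip(f, delta_input, eps_denit, eps_leach, f_vol, eps_vol):
    """invert(forward(f)) == f for any admissible parameters (round-off only)."""
    spec = GridSpec(lat_min=0, lat_max=2, lon_min=0, lon_max=2, resolution=2.0)
    p = IsotopeParams(
        eps_denit=eps_denit, eps_leach=eps_leach, eps_vol=eps_vol, f_vol=f_vol
    )
    f = min(f, 1.0 - f_vol)
    soil = forward_delta(spec.full(f), spec.full(delta_input), p)
    res = invert_fdenit(soil, spec.full(delta_input), p)
    assert _v(res.mean) == pytest.approx(f, abs=1e-10)


class TestMonteCarlo:
    def test_zero_sds_collapse_to_deterministic_inversion(self, spec1cell):
        p = IsotopeParams(sd_eps_denit=0.0, sd_eps_leach=0.0, sd_input_frac=0.0)
        res = monte_carlo_fdenit(
            _cell(spec1cell, 4.8), _cell(spec1cell, -0.66), p, n_draws=100, seed=0
        )
        assert _v(res.mean) == pytest.approx(0.42, abs=1e-12)
        assert _v(res.sd) == pytest.approx(0.0, abs=1e-12)

    def test_sd_matches_delta_method_for_eps_denit_only(self, spec1cell):
        # f = (ds - di)/eps  =>  sd_f ~= (ds - di) * sd_eps / eps^2 = 0.03295
        p = IsotopeParams(sd_eps_leach=0.0, sd_input_frac=0.0)
        res = monte_carlo_fdenit(
            _cell(spec1cell, 4.8), _cell(spec1cell, -0.66), p,
            n_draws=100_000, seed=3,
        )
        oracle = 5.46 * 1.02 / 13.0**2
        assert _v(res.sd) == pytest.approx(oracle, rel=0.15)

    def test_mean_converges_with_draw_count(self, spec1cell, params):
        small = monte_carlo_fdenit(
            _cell(spec1cell, 4.8), _cell(spec1cell, -0.66), params,
            n_draws=1_000, seed=5,
        )
        big = monte_carlo_fdenit(
            _cell(spec1cell, 4.8), _cell(spec1cell, -0.66), params,
            n_draws=100_000, seed=5,
        )
        mc_se = _v(small.sd) / np.sqrt(1_000)
        assert abs(_v(small.mean) - _v(big.mean)) < 3 * mc_se

    def test_ensemble_members_as_soil_uncertainty(self, spec1cell):
        p = IsotopeParams(sd_eps_denit=0.0, sd_eps_leach=0.0, sd_input_frac=0.0)
        members = [_cell(spec1cell, 4.0), _cell(spec1cell, 5.6)]
        res = monte_carlo_fdenit(
            members, _cell(spec1cell, -0.66), p, n_draws=4000, seed=9
        )
        lo, hi = (4.0 + 0.66) / 13, (5.6 + 0.66) / 13
        assert lo < _v(res.mean) < hi


class TestEnsembleFdenit:
    def test_identical_sets_have_zero_spread(self, spec1cell, params):
        sets = [_inputs(spec1cell, 40, 57, 10)] * 3
        mean, sd, _ = ensemble_fdenit(sets, _cell(spec1cell, 4.8), params)
        assert _v(sd) == pytest.approx(0.0, abs=1e-12)

    def test_two_sets_average_hand_inversions(self, spec1cell, params):
        s1 = _inputs(spec1cell, 40, 57, 10)   # delta_in = -0.68972
        s2 = _inputs(spec1cell, 42, 44, 10)   # delta_in = (40.2 - 88)/96
        d1 = (10 * 4.02 - 2 * 57) / 107
        d2 = (10 * 4.02 - 2 * 44) / 96
        hand = ((4.8 - d1) / 13 + (4.8 - d2) / 13) / 2
        mean, _, _ = ensemble_fdenit([s1, s2], _cell(spec1cell, 4.8), params)
        assert _v(mean) == pytest.approx(hand, abs=1e-12)

    def test_mean_of_maps_is_map_of_means(self, spec10, world10):
        truth, sets, params = world10
        mean, _, results = ensemble_fdenit(sets, truth.true_delta_soil, params)
        stacked = sum(r.mean for r in results) / len(results)
        assert np.allclose(mean.values, stacked.values, equal_nan=True)


class TestEpsilonSensitivity:
    def test_sweep_matches_hand_arithmetic(self, spec1cell, params):
        out = epsilon_sensitivity(
            _cell(spec1cell, 4.8), _cell(spec1cell, -0.66),
            eps_values=[10.0, 20.0], params=params,
        )
        assert _v(out["eps=10"].mean) == pytest.approx(0.546, abs=1e-3)
        assert _v(out["eps=20"].mean) == pytest.approx(0.273, abs=1e-3)

    def test_fdenit_decreases_with_epsilon(self, spec10, world10):
        truth, sets, params = world10
        din = mix_input_delta(sets[0])
        out = epsilon_sensitivity(
            truth.true_delta_soil, din, eps_values=[10, 13, 16, 20], params=params
        )
        means = [_v(out[k].mean.mean()) for k in ("eps=10", "eps=13", "eps=16", "eps=20")]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_constant_temperature_scenario_equals_fixed_eps(self, spec1cell, params):
        t = _cell(spec1cell, 8.0)
        out = epsilon_sensitivity(
            _cell(spec1cell, 4.8), _cell(spec1cell, -0.66),
            eps_values=[13.0], eps_of_t=(13.0, 0.0), t_field=t, params=params,
        )
        fixed = out["eps=13"].mean
        var = out["eps(T)=13+0T"].mean
        assert _v(fixed) == pytest.approx(_v(var), abs=1e-12)
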