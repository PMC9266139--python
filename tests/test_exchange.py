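"""Surface heat exchange: dry, evaporative, respiratory and solar terms."""
import numpy as np
import pytest

from heatstrain.constants import saturation_vapor_pressure_kpa
from heatstrain.environment import Environment
from heatstrain.exchange import (convective_coefficient, dry_heat_loss,
                                 evaporative_heat_loss, respiration_loss,
                                 solar_gain, default_exchange_coefficients)


def test_saturation_pressure_matches_steam_tables():
    # independent reference points from standard psychrometric tables
    assert float(saturation_vapor_pressure_kpa(37.0)) == pytest.approx(6.28, rel=0.01)
    assert float(saturation_vapor_pressure_kpa(34.0)) == pytest.approx(5.32, rel=0.01)
    assert float(saturation_vapor_pressure_kpa(20.0)) == pytest.approx(2.34, rel=0.01)


def test_dry_loss_zero_without_temperature_gradient():
    env = Environment(ta_c=34.0, rh_pct=50.0)
    c, r = dry_heat_loss(34.0, env, clo=0.5, f_cl=1.2, area_m2=0.1)
    assert c == pytest.approx(0.0, abs=1e-12)
    assert r == pytest.approx(0.0, abs=1e-12)


def test_nude_dry_loss_follows_surface_conductance():
    # nude segment, h = hc + hr = 9 W/m2K, dT = 10 K, area 0.1 m2 -> 9 W
    env = Environment(ta_c=25.0, rh_pct=50.0)
    c, r = dry_heat_loss(35.0, env, clo=0.0, f_cl=1.0, area_m2=0.1,
                         hc=4.0, hr=5.0)
    assert c + r == pytest.approx(9.0, rel=1e-12)
    assert c / r == pytest.approx(4.0 / 5.0, rel=1e-12)


def test_clothed_dry_loss_matches_series_resistance_arithmetic():
    env = Environment(ta_c=24.0, rh_pct=47.0)
    clo, fcl, hc, hr, area, tsk = 0.709, 1.36, 5.0, 4.5, 0.15, 34.0
    c, r = dry_heat_loss(tsk, env, clo=clo, f_cl=fcl, area_m2=area,
                         hc=hc, hr=hr)
    resistance = 0.155 * clo + 1.0 / (fcl * (hc + hr))
    assert c + r == pytest.approx(area * (tsk - 24.0) / resistance, rel=1e-12)


def test_evaporation_zero_at_saturated_equal_temperature():
    env = Environment(ta_c=36.0, rh_pct=100.0)
    e, emax = evaporative_heat_loss(36.0, 1.0, env, clo=0.5, f_cl=1.2,
                                    i_cl=0.34, area_m2=0.1)
    assert emax == pytest.approx(0.0, abs=1e-12)
    assert e == pytest.approx(0.0, abs=1e-12)


def test_no_sweat_leaves_minimum_diffusion_only():
    cf = default_exchange_coefficients()
    env = Environment(ta_c=30.0, rh_pct=40.0)
    e, emax = evaporative_heat_loss(34.0, 0.0, env, clo=0.0, f_cl=1.0,
                                    i_cl=1.0, area_m2=0.1)
    assert emax > 0
    assert e == pytest.approx(cf.w_min * emax, rel=1e-12)


def test_emax_matches_hand_evaluated_vapor_pressures():
    # nude skin at 37 degC in 37 degC / 55 % air, hc = 5: the whole
    # resistance is the air layer, Re = 1/(LR*hc)
    env = Environment(ta_c=37.0, rh_pct=55.0)
    _, emax = evaporative_heat_loss(37.0, 0.0, env, clo=0.0, f_cl=1.0,
                                    i_cl=1.0, area_m2=1.0, hc=5.0)
    psk = 6.28            # steam-table Psat(37)
    gradient = psk - 0.55 * psk
    assert emax == pytest.approx(16.5 * 5.0 * gradient, rel=0.01)


def test_respiration_sensible_part_vanishes_at_34C():
    cf = default_exchange_coefficients()
    env = Environment(ta_c=34.0, rh_pct=50.0)
    res = respiration_loss(200.0, env)
    latent_only = 200.0 * cf.res_latent_coef * (cf.res_ref_pressure_kpa
                                                - env.vapor_pressure_kpa)
    assert res == pytest.approx(latent_only, rel=1e-12)


def test_respiration_is_linear_in_metabolic_rate():
    env = Environment(ta_c=33.0, rh_pct=45.0)
    assert respiration_loss(400.0, env) == pytest.approx(
        2.0 * respiration_loss(200.0, env), rel=1e-12)
    with pytest.raises(ValueError):
        respiration_loss(0.0, env)


def test_solar_gain_zero_without_irradiance_and_product_otherwise():
    env0 = Environment(ta_c=33.0, rh_pct=45.0, solar_w_m2=0.0)
    assert float(solar_gain(env0, 0.1, clothed=False)) == 0.0
    env = Environment(ta_c=33.0, rh_pct=45.0, solar_w_m2=500.0)
    # absorptance 0.7, projected fraction 0.3, area 0.1 m2, 500 W/m2
    assert float(solar_gain(env, 0.1, clothed=False)) == pytest.approx(10.5)
    cf = default_exchange_coefficients()
    assert float(solar_gain(env, 0.1, clothed=True)) == pytest.approx(
        10.5 * cf.solar_clothing_attenuation)


@pytest.mark.parametrize("v_lo, v_hi", [(0.2, 0.5), (0.5, 1.0), (1.0, 2.0)])
def test_wind_never_reduces_convection_or_evaporative_ceiling(v_lo, v_hi):
    lo = Environment(ta_c=33.0, rh_pct=45.0, v_m_s=v_lo)
    hi = Environment(ta_c=33.0, rh_pct=45.0, v_m_s=v_hi)
    c_lo, _ = dry_heat_loss(36.0, lo, 0.5, 1.2, 0.1)
    c_hi, _ = dry_heat_loss(36.0, hi, 0.5, 1.2, 0.1)
    assert c_hi >= c_lo
    _, emax_lo = evaporative_heat_loss(36.0, 5.0, lo, 0.5, 1.2, 0.34, 0.1)
    _, emax_hi = evaporative_heat_loss(36.0, 5.0, hi, 0.5, 1.2, 0.34, 0.1)
    assert emax_hi >= emax_lo


@pytest.mark.parametrize("rh_lo, rh_hi", [(30.0, 50.0), (50.0, 80.0),
                                          (80.0, 100.0)])
def test_humidity_never_increases_evaporative_ceiling(rh_lo, rh_hi):
    lo = Environment(ta_c=38.0, rh_pct=rh_lo)
    hi = Environment(ta_c=38.0, rh_pct=rh_hi)
    _, emax_lo = evaporative_heat_loss(37.0, 5.0, lo, 0.5, 1.2, 0.34, 0.1)
    _, emax_hi = evaporative_heat_loss(37.0, 5.0, hi, 0.5, 1.2, 0.34, 0.1)
    assert emax_hi <= emax_lo


@pytest.mark.parametrize("clo_lo, clo_hi", [(0.0, 0.3), (0.3, 0.7), (0.7, 1.4)])
def test_insulation_strictly_reduces_dry_loss(clo_lo, clo_hi):
    env = Environment(ta_c=30.0, rh_pct=50.0)
    c1, r1 = dry_heat_loss(36.0, env, clo_lo, 1.0 + 0.31 * clo_lo, 0.1)
    c2, r2 = dry_heat_loss(36.0, env, clo_hi, 1.0 + 0.31 * clo_hi, 0.1)
    assert c2 + r2 < c1 + r1


def test_activity_raises_convective_coefficient_only_above_threshold():
    cf = default_exchange_coefficients()
    still = convective_coefficient(0.2, cf)
    rest = convective_coefficient(0.2, cf, met_w_m2=40.0)
    work = convective_coefficient(0.2, cf, met_w_m2=150.0)
    assert rest == pytest.approx(still)  # below threshold: no activity term
    assert work > rest
    # in truly still air the natural-convection floor applies
    assert convective_coefficient(0.0, cf) == pytest.approx(
        cf.hc_natural_w_per_m2k)


def test_environment_validation():
    with pytest.raises(ValueError):
        Environment(ta_c=30.0, rh_pct=120.0)
    with pytest.raises(ValueError):
        Environment(ta_c=30.0, rh_pct=50.0, v_m_s=-0.1)
    env = Environment(ta_c=30.0, rh_pct=50.0)
    assert env.mrt_c == 30.0
    assert Environment(ta_c=30.0, rh_pct=50.0, tr_c=45.0).mrt_c == 45.0
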