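"""Serial-model insulation estimation from manikin records."""
import logging

import numpy as np
import pandas as pd
import pytest

from heatstrain.constants import CLO
from heatstrain.insulation import (MissingSegmentsError, SerialInsulationModel,
                                   basic_insulation, steady_state_average,
                                   total_insulation)
from heatstrain.synth import default_manikin_spec, synth_manikin


def _records(segments, condition="clothed", run=1, minutes=30):
    rows = []
    for seg, (ts, h, a) in segments.items():
        for m in range(1, minutes + 1):
            h_m = h(m) if callable(h) else h
            rows.append(dict(segment=seg, condition=condition, run=run,
                             minute=m, tsurf_c=ts, heat_w=h_m, area_m2=a))
    return pd.DataFrame(rows)


def test_average_of_constant_record_is_the_constant():
    df = _records({"chest": (34.0, 12.0, 0.2)})
    avg = steady_state_average(df, window_min=30)
    assert avg.loc[0, "heat_w"] == pytest.approx(12.0)
    assert avg.loc[0, "tsurf_c"] == pytest.approx(34.0)


def test_two_runs_are_averaged():
    df = pd.concat([_records({"chest": (34.0, 10.0, 0.2)}, run=1),
                    _records({"chest": (34.0, 12.0, 0.2)}, run=2)])
    avg = steady_state_average(df, window_min=30)
    assert avg.loc[0, "heat_w"] == pytest.approx(11.0)


def test_linear_drift_averages_to_midpoint():
    df = _records({"chest": (34.0, lambda m: 10.0 + 0.1 * m, 0.2)})
    avg = steady_state_average(df, window_min=30)
    assert avg.loc[0, "heat_w"] == pytest.approx(10.0 + 0.1 * 15.5)


def test_short_series_rejected():
    df = _records({"chest": (34.0, 12.0, 0.2)}, minutes=10)
    with pytest.raises(ValueError, match="10 min"):
        steady_state_average(df, window_min=30)


def test_single_segment_total_insulation():
    # dT = 10 K, area 1.8 m2, H = 180 W -> 0.100 m2K/W = 0.645 clo
    avg = pd.DataFrame([dict(condition="clothed", segment="torso",
                             tsurf_c=34.0, heat_w=180.0, area_m2=1.8)])
    i_t = total_insulation(avg, ta_c=24.0, condition="clothed")
    assert i_t == pytest.approx(0.100, rel=1e-12)
    assert i_t / CLO == pytest.approx(0.645, abs=0.001)


def test_equal_local_resistances_give_that_resistance():
    avg = pd.DataFrame([
        dict(condition="clothed", segment="a", tsurf_c=34.0, heat_w=90.0,
             area_m2=0.9),
        dict(condition="clothed", segment="b", tsurf_c=34.0, heat_w=90.0,
             area_m2=0.9),
    ])
    assert total_insulation(avg, 24.0, "clothed") == pytest.approx(0.100)


def test_nonphysical_chamber_temperature_rejected():
    avg = pd.DataFrame([dict(condition="nude", segment="a", tsurf_c=34.0,
                             heat_w=90.0, area_m2=0.9)])
    with pytest.raises(ValueError, match="heated manikin"):
        total_insulation(avg, 35.0, "nude")


def test_basic_insulation_limiting_cases():
    assert basic_insulation(1.0, 0.4, 1.0) == pytest.approx(0.6)
    assert basic_insulation(1.0, 0.0, 1.4) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        basic_insulation(1.0, 0.4, 0.9)


def test_negative_basic_insulation_warns_but_returns(caplog):
    with caplog.at_level(logging.WARNING):
        out = basic_insulation(0.3, 0.9, 1.2)
    assert out < 0
    assert "negative" in caplog.text


def test_unit_consistency_clo_vs_si():
    si = basic_insulation(1.046 * CLO, 0.458 * CLO, 1.36)
    in_clo = basic_insulation(1.046, 0.458, 1.36)
    assert si / CLO == pytest.approx(in_clo, abs=1e-9)


def test_round_trip_recovers_truth_exactly_at_zero_noise():
    spec = default_manikin_spec(noise_frac=0.0)
    df = synth_manikin(spec)
    fit = SerialInsulationModel(df, ta_c=spec.chamber_ta_c, f_cl=1.36).fit()
    local = fit.local.set_index("segment")
    for seg, r_true in spec.true_total.items():
        assert local.loc[seg, "r_local_m2k_w"] == pytest.approx(r_true, rel=1e-12)
    f = local["f_i"].to_numpy()
    r = local["r_local_m2k_w"].to_numpy()
    assert fit.i_t_m2kw == pytest.approx(float(f @ r), rel=1e-12)
    assert fit.i_cl_m2kw == pytest.approx(
        fit.i_t_m2kw - fit.i_a_m2kw / 1.36, rel=1e-12)


def test_noisy_records_recover_total_insulation_within_2pct():
    spec = default_manikin_spec(noise_frac=0.05, seed=11)
    truth = default_manikin_spec(noise_frac=0.0)
    df_true = synth_manikin(truth)
    ref = SerialInsulationModel(df_true, ta_c=24.0).fit().i_t_m2kw
    df = synth_manikin(spec, n_minutes=30, n_runs=2)
    fit = SerialInsulationModel(df, ta_c=24.0).fit()
    assert fit.i_t_m2kw == pytest.approx(ref, rel=0.02)
    assert fit.i_t_se > 0


def test_estimate_spread_shrinks_with_averaging_window():
    est = {8: [], 32: []}
    for seed in range(24):
        df = synth_manikin(default_manikin_spec(noise_frac=0.08, seed=seed),
                           n_minutes=32, n_runs=1)
        for window in est:
            fit = SerialInsulationModel(df, ta_c=24.0, window_min=window).fit()
            est[window].append(fit.i_t_m2kw)
    ratio = np.std(est[8]) / np.std(est[32])
    assert 1.3 < ratio < 3.1  # expect ~2 for a 4x longer window


def test_segments_missing_one_condition_are_dropped_and_renormalised(caplog):
    spec = default_manikin_spec()
    df = synth_manikin(spec)
    df = df[~((df.segment == "left_hand") & (df.condition == "clothed"))]
    with caplog.at_level(logging.INFO):
        fit = SerialInsulationModel(df, ta_c=24.0).fit()
    assert fit.dropped_segments == ("left_hand",)
    assert fit.local["f_i"].sum() == pytest.approx(1.0)
    assert "left_hand" not in set(fit.local["segment"])


def test_missing_condition_entirely_raises():
    df = synth_manikin(default_manikin_spec())
    with pytest.raises(MissingSegmentsError):
        SerialInsulationModel(df[df.condition == "nude"], ta_c=24.0).fit()


def test_summary_and_dict_round_trip():
    fit = SerialInsulationModel(synth_manikin(default_manikin_spec()),
                                ta_c=24.0).fit()
    text = fit.summary()
    assert "basic I_cl" in text
    d = fit.to_dict()
    assert d["i_cl_clo"] == pytest.approx(fit.i_cl_clo)
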