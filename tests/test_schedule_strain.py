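"""Schedules, thresholds, AMWT logic and schedule comparison arithmetic."""
import numpy as np
import pytest

import heatstrain as hs
from heatstrain.model import SimulationResult, mean_skin_temperature
from heatstrain.schedule import Block, WorkRestSchedule
from heatstrain.strain import (AMWTResult, Thresholds, amwt,
                               effective_working_time, sweat_summary)


def _fake_result(core, sweat_ml, schedule, env=None):
    core = np.asarray(core, dtype=float)
    n = len(core)
    skin = np.tile(core - 3.0, (17, 1))
    return SimulationResult(
        time_min=np.arange(n, dtype=float), core_c=core,
        mean_skin_c=core - 3.0, skin_c=skin,
        sweat_ml=np.asarray(sweat_ml, dtype=float),
        secreted_ml=np.asarray(sweat_ml, dtype=float),
        t_nodes_c=np.tile(core, (85, 1)),
        schedule=schedule,
        env=env or hs.Environment(ta_c=38.0, rh_pct=55.0),
        clothing_label="test", core_node="head",
        segment_names=tuple(f"s{i}" for i in range(17)))


# -- schedules -------------------------------------------------------------

def test_cycle_schedule_structure():
    c2 = WorkRestSchedule.cycle(60, 30, 240, 3.3, 1.05, label="C2")
    kinds = [(b.duration_min, b.kind) for b in c2.blocks]
    assert kinds == [(60, "work"), (30, "rest"), (60, "work"), (30, "rest"),
                     (60, "work")]
    assert c2.total_minutes == 240
    assert c2.work_minutes == 180
    assert c2.rest_minutes == 60
    assert c2.met_at(0) == 3.3
    assert c2.met_at(65) == 1.05
    assert c2.met_at(95) == 3.3


def test_schedule_validation():
    with pytest.raises(ValueError):
        Block(0.0, 3.3)
    with pytest.raises(ValueError):
        Block(60.0, 0.8)
    with pytest.raises(ValueError):
        Block(60.0, 3.3, kind="nap")
    with pytest.raises(ValueError):
        WorkRestSchedule(blocks=())


def test_work_mask_matches_blocks():
    sched = WorkRestSchedule.cycle(2, 3, 10, 3.3, 1.05)
    mask = sched.work_mask(10)
    assert mask.tolist() == [True, True, False, False, False,
                             True, True, False, False, False]


# -- thresholds and AMWT ---------------------------------------------------

def test_threshold_validation_and_sweat_limit():
    th = Thresholds()
    assert th.sweat_limit_ml(hs.Anthropometry(weight_kg=60.0)) == 3000.0
    with pytest.raises(ValueError):
        Thresholds(core_limit_c=36.5)
    with pytest.raises(ValueError):
        Thresholds(sweat_frac_of_mass=0.2)


def test_amwt_core_crossing():
    sched = WorkRestSchedule.continuous(300.0)
    core = np.concatenate([np.linspace(37, 39.4, 121), np.full(180, 39.4)])
    res = _fake_result(core, np.zeros(301), sched)
    out = amwt(res, Thresholds())
    assert out.criterion == "core"
    assert out.minutes == np.flatnonzero(core >= 39.0)[0]


def test_amwt_sweat_crossing_beats_later_core_crossing():
    sched = WorkRestSchedule.continuous(300.0)
    core = np.linspace(37.0, 39.5, 301)          # crosses 39 at ~240
    sweat = np.linspace(0.0, 6000.0, 301)        # 3000 mL at minute 150
    res = _fake_result(core, sweat, sched)
    out = amwt(res, Thresholds(), hs.Anthropometry(weight_kg=60.0))
    assert out.criterion == "sweat"
    assert out.minutes == 150


def test_amwt_censored_when_no_threshold_reached():
    sched = WorkRestSchedule.continuous(300.0)
    res = _fake_result(np.full(301, 37.5), np.linspace(0, 500, 301), sched)
    out = amwt(res, Thresholds())
    assert out == AMWTResult(minutes=300.0, criterion="censored")


def test_amwt_result_validation():
    with pytest.raises(ValueError):
        AMWTResult(minutes=100.0, criterion="heat")


# -- effective working time and sweat summary ------------------------------

def test_effective_working_time_excludes_rest_minutes():
    sched = WorkRestSchedule.cycle(60, 30, 240, 3.3, 1.05)
    core = np.full(241, 37.0)
    core[150:] = 39.2          # crosses at minute 150 (inside 2nd rest... )
    res = _fake_result(core, np.zeros(241), sched)
    # crossing at t=150: work minutes are 0-59 and 90-149 -> 120
    assert effective_working_time(res, Thresholds()) == 120


def test_effective_working_time_without_crossing_is_total_work():
    sched = WorkRestSchedule.cycle(60, 45, 240, 3.3, 1.05)
    res = _fake_result(np.full(241, 38.0), np.zeros(241), sched)
    assert effective_working_time(res, Thresholds()) == sched.work_minutes


def test_sweat_summary_identical_schedules_report_zero_reduction():
    sched = WorkRestSchedule.continuous(240.0)
    r = _fake_result(np.full(241, 38.0), np.linspace(0, 1000, 241), sched)
    df = sweat_summary({"A": r, "B": r}, baseline="A")
    assert df.loc[df.schedule == "B", "reduction_pct"].iloc[0] == 0.0


def test_sweat_summary_slope_is_least_squares_over_rest_minutes():
    base = _fake_result(np.full(241, 38.0), np.linspace(0, 1200, 241),
                        WorkRestSchedule.continuous(240.0))
    results = {"C1": base}
    for label, rest, total in (("C2", 30, 1080.0), ("C3", 45, 1035.0),
                               ("C4", 60, 990.0)):
        sched = WorkRestSchedule.cycle(60, rest, 240, 3.3, 1.05, label=label)
        results[label] = _fake_result(np.full(241, 38.0),
                                      np.linspace(0, total, 241), sched)
    df = sweat_summary(results, baseline="C1")
    rests = df.set_index("schedule")["rest_min"]
    # totals fall 1.5 mL per additional rest minute by construction
    assert df.attrs["ml_per_rest_min"] == pytest.approx(
        (1080.0 - 990.0) / (rests["C4"] - rests["C2"]), rel=1e-9)


def test_sweat_summary_requires_known_baseline():
    r = _fake_result(np.full(11, 37.0), np.zeros(11),
                     WorkRestSchedule.continuous(10.0))
    with pytest.raises(ValueError, match="baseline"):
        sweat_summary({"A": r}, baseline="missing")


# -- mean skin -------------------------------------------------------------

def test_mean_skin_of_uniform_field_is_that_value():
    assert mean_skin_temperature(np.full(17, 34.0)) == pytest.approx(34.0)


def test_mean_skin_with_explicit_weights():
    assert mean_skin_temperature(np.array([33.0, 35.0]),
                                 weights=[1.0, 1.0]) == pytest.approx(34.0)


def test_mean_skin_weights_are_normalised():
    vals = np.array([33.0, 35.0])
    assert mean_skin_temperature(vals, weights=[2.0, 6.0]) == pytest.approx(
        (33.0 * 0.25 + 35.0 * 0.75))
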