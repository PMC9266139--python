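"""Heat-strain evaluation: acceptable maximum working time (AMWT), AMWT
charts over environment grids, and work/rest schedule comparison.

AMWT is the time from the start of work until either the core temperature
reaches its safety limit (default 39 degC) or the cumulative sweat loss
reaches a fraction of body mass (default 5 %), censored at a chart horizon
(default 300 min).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry
from .clothing import ClothingEnsemble
from .environment import Environment
from .model import HumanBioheatModel, SimulationResult
from .schedule import WorkRestSchedule

__all__ = ["Thresholds", "AMWTResult", "amwt", "amwt_for", "amwt_grid",
           "grid_to_matrix", "effective_working_time", "sweat_summary"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Safety limits defining the acceptable maximum working time."""

    core_limit_c: float = 39.0
    sweat_frac_of_mass: float = 0.05
    horizon_min: float = 300.0

    def __post_init__(self):
        if not self.core_limit_c > 37.0:
            raise ValueError("core limit must exceed 37 degC")
        if not 0.0 < self.sweat_frac_of_mass <= 0.15:
            raise ValueError("sweat fraction must be in (0, 0.15]")
        if self.horizon_min <= 0:
            raise ValueError("horizon must be positive")

    def sweat_limit_ml(self, anthro: Anthropometry) -> float:
        """Sweat-volume limit, mL (1 g/mL)."""
        return self.sweat_frac_of_mass * anthro.weight_kg * 1000.0


@dataclass(frozen=True)
class AMWTResult:
    minutes: float
    criterion: str  # 'core' | 'sweat' | 'censored'

    def __post_init__(self):
        if self.criterion not in ("core", "sweat", "censored"):
            raise ValueError(f"unknown criterion {self.criterion!r}")


def amwt(result: SimulationResult, thresholds: Thresholds | None = None,
         anthro: Anthropometry | None = None) -> AMWTResult:
    """First threshold crossing of a constant-work simulation.

    Censored at the horizon (or at the end of the simulated series if it
    is shorter).
    """
    th = thresholds or Thresholds()
    anthro = anthro or Anthropometry()
    horizon = min(th.horizon_min, float(result.time_min[-1]))
    t_core = result.first_crossing_min(result.core_c, th.core_limit_c)
    t_sweat = result.first_crossing_min(result.sweat_ml,
                                        th.sweat_limit_ml(anthro))
    candidates = [(t, c) for t, c in ((t_core, "core"), (t_sweat, "sweat"))
                  if t is not None and t <= horizon]
    if not candidates:
        return AMWTResult(minutes=horizon, criterion="censored")
    t, c = min(candidates)
    log.info("threshold crossing: %s limit reached at minute %g "
             "(Ta %g degC, RH %g %%, v %g m/s)", c, t,
             result.env.ta_c, result.env.rh_pct, result.env.v_m_s)
    return AMWTResult(minutes=float(t), criterion=c)


def amwt_for(env: Environment, clothing: ClothingEnsemble | None = None,
             anthro: Anthropometry | None = None, met: float = 3.3,
             thresholds: Thresholds | None = None, **model_kwargs) -> AMWTResult:
    """Simulate continuous work in one environment and evaluate AMWT."""
    th = thresholds or Thresholds()
    anthro = anthro or Anthropometry()
    schedule = WorkRestSchedule.continuous(th.horizon_min, met=met)
    model = HumanBioheatModel(env, clothing, anthro, schedule, **model_kwargs)
    return amwt(model.simulate(), th, anthro)


def amwt_grid(ta_values=None, rh_values=None, wind_values=(0.2, 1.0, 2.0),
              clothing: ClothingEnsemble | None = None,
              anthro: Anthropometry | None = None, met: float = 3.3,
              thresholds: Thresholds | None = None,
              **model_kwargs) -> pd.DataFrame:
    """AMWT over a (Ta, RH, wind) grid; one simulation per cell.

    Default ranges span hot outdoor work: Ta 30-42 degC step 1, RH 40-90 %
    step 5, winds {0.2, 1, 2} m/s.  Returns a long-format table with
    columns ta_c, rh_pct, v_m_s, amwt_min, criterion.
    """
    ta_values = np.arange(30.0, 43.0, 1.0) if ta_values is None else ta_values
    rh_values = np.arange(40.0, 95.0, 5.0) if rh_values is None else rh_values
    rows = []
    for v in wind_values:
        for ta in ta_values:
            for rh in rh_values:
                env = Environment(ta_c=float(ta), rh_pct=float(rh),
                                  v_m_s=float(v))
                res = amwt_for(env, clothing, anthro, met, thresholds,
                               **model_kwargs)
                rows.append(dict(ta_c=float(ta), rh_pct=float(rh),
                                 v_m_s=float(v), amwt_min=res.minutes,
                                 criterion=res.criterion))
    return pd.DataFrame(rows)


def grid_to_matrix(grid: pd.DataFrame, v_m_s: float) -> pd.DataFrame:
    """Chart-ready AMWT matrix (rows Ta, columns RH) for one wind level."""
    sub = grid[np.isclose(grid["v_m_s"], v_m_s)]
    if sub.empty:
        raise ValueError(f"no grid cells at wind {v_m_s} m/s")
    return sub.pivot(index="ta_c", columns="rh_pct", values="amwt_min")


def effective_working_time(result: SimulationResult,
                           thresholds: Thresholds | None = None) -> float:
    """Work minutes accumulated before the core limit is first reached.

    Rest minutes are excluded; if the limit is never reached the total
    scheduled work time is returned.
    """
    th = thresholds or Thresholds()
    n_min = int(result.time_min[-1])
    mask = result.schedule.work_mask(n_min)
    t_cross = result.first_crossing_min(result.core_c, th.core_limit_c)
    if t_cross is None:
        return float(mask.sum())
    return float(mask[:int(t_cross)].sum())


def sweat_summary(results: dict, baseline: str,
                  thresholds: Thresholds | None = None) -> pd.DataFrame:
    """Compare cumulative sweat loss across schedules.

    ``results`` maps schedule labels to :class:`SimulationResult` objects
    simulated over a common horizon and environment.  Reports, per
    schedule, the maximum (end-of-horizon) sweat loss in mL and the
    percent reduction relative to the baseline schedule's unconstrained
    loss.  The returned frame carries the fitted reduction slope in
    ``attrs['ml_per_rest_min']``: a least-squares fit of sweat reduction
    against total rest minutes across the non-baseline schedules.
    """
    if baseline not in results:
        raise ValueError(f"baseline label {baseline!r} not in results")
    base_ml = float(results[baseline].sweat_ml[-1])
    rows = []
    for label, res in results.items():
        ml = float(res.sweat_ml[-1])
        rows.append(dict(schedule=label,
                         rest_min=res.schedule.rest_minutes,
                         max_sweat_ml=ml,
                         reduction_ml=base_ml - ml,
                         reduction_pct=100.0 * (base_ml - ml) / base_ml))
    df = pd.DataFrame(rows)
    others = df[df["schedule"] != baseline]
    if len(others) >= 2 and others["rest_min"].nunique() > 1:
        slope = -np.polyfit(others["rest_min"], others["max_sweat_ml"], 1)[0]
    else:
        slope = np.nan
    df.attrs["ml_per_rest_min"] = float(slope)
    return df
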