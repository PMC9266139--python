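"""Simulation driver: the bioheat model assembled over a person, clothing,
an environment and a work/rest schedule.

:class:`HumanBioheatModel` wires the passive node network, the active
control laws and the surface exchange together and integrates the heat
balance forward in time.  Reporting is per minute; internally the solver
sub-divides each reporting step so the smallest nodes stay well inside the
explicit-Euler stability limit.

The initial condition of every simulation is the thermoneutral setpoint
state, i.e. the passive steady state at operative 30 degC (nude, basal
metabolism), which doubles as the setpoint table of the active system.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry
from .body import (BodyBuild, BodyState, SimulationInstabilityError,
                   build_body, euler_step, heat_balance_derivatives)
from .clothing import ClothingEnsemble, grid_summer_ensemble, nude_ensemble
from .constants import LAMBDA_SWEAT, SWEAT_DENSITY
from .environment import Environment
from .exchange import (ExchangeCoefficients, default_exchange_coefficients,
                       surface_fluxes)
from .regulation import (ControlGains, SetpointTable, default_gains,
                         error_signals, regulate)
from .schedule import WorkRestSchedule

__all__ = ["HumanBioheatModel", "SimulationResult", "simulate",
           "neutral_setpoints", "mean_skin_temperature"]

#: thermoneutral reference condition defining the setpoints
NEUTRAL_ENV = Environment(ta_c=30.0, rh_pct=50.0, v_m_s=0.2)

_setpoint_cache: dict = {}


def mean_skin_temperature(skin_c, weights=None):
    """Area-weighted mean over the 17 segment skin temperatures.

    ``skin_c`` may be a length-17 vector or a (17, n) series.  Weights
    default to the segment surface-area fractions and are normalised to
    sum to one.
    """
    skin = np.asarray(skin_c, dtype=float)
    if weights is None:
        from .body import _load_tables
        comp, _ = _load_tables()
        w = comp.groupby("segment", sort=False)["area_frac"].first().to_numpy()
    else:
        w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return w @ skin


def _passive_derivative(t_c, body: BodyBuild, env: Environment,
                        ensemble: ClothingEnsemble, cf: ExchangeCoefficients):
    """Derivatives with all active effectors silent (basal state)."""
    n = body.network.n_tissue
    tsk = t_c[body.skin_nodes]
    flux = surface_fluxes(tsk, np.zeros(17), env, ensemble,
                          body.segment_areas_m2,
                          body.anthropometry.basal_metabolic_rate_w, cf=cf)
    surf = np.zeros(n)
    surf[body.skin_nodes] = flux.net_skin_loss_w
    surf[body.chest_core_node] += flux.respiration_w
    return heat_balance_derivatives(t_c, body.network, surface_w=surf)


def neutral_setpoints(body: BodyBuild,
                      cf: ExchangeCoefficients | None = None) -> SetpointTable:
    """Setpoints = passive steady state in the thermoneutral reference.

    Solved by integrating the passive system to near-equilibrium and
    polishing with a Newton-type root find.  Cached per anthropometry.
    """
    from scipy.optimize import root

    cf = cf or default_exchange_coefficients()
    a = body.anthropometry
    key = (a.height_m, a.weight_kg, a.age_y, a.sex, cf)
    if key in _setpoint_cache:
        return _setpoint_cache[key]

    nude = nude_ensemble()
    t = np.full(body.n_nodes, 36.8)
    t[body.skin_nodes] = 33.5
    dt = 10.0
    for _ in range(int(8 * 3600 / dt)):
        t = t + dt * _passive_derivative(t, body, NEUTRAL_ENV, nude, cf)
    sol = root(lambda x: _passive_derivative(x, body, NEUTRAL_ENV, nude, cf),
               t, method="hybr", tol=1e-12)
    if sol.success and np.max(np.abs(sol.x - t)) < 0.5:
        t = sol.x
    table = SetpointTable(t_c=t)
    _setpoint_cache[key] = table
    return table


@dataclass
class SimulationResult:
    """Minute-resolution output of one simulation.

    Cumulative sweat loss is the evaporated water mass (1 g = 1 mL); the
    secreted series, which additionally counts sweat that dripped without
    evaporating, is kept alongside for diagnostics.
    """

    time_min: np.ndarray
    core_c: np.ndarray
    mean_skin_c: np.ndarray
    skin_c: np.ndarray            # (17, n)
    sweat_ml: np.ndarray          # cumulative evaporated
    secreted_ml: np.ndarray       # cumulative secreted
    t_nodes_c: np.ndarray         # (n_nodes, n) full trajectories
    schedule: WorkRestSchedule
    env: Environment
    clothing_label: str
    core_node: str
    segment_names: tuple

    def __post_init__(self):
        n = len(self.time_min)
        for name in ("core_c", "mean_skin_c", "sweat_ml", "secreted_ml"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series length mismatch for {name}")

    @property
    def minutes(self) -> int:
        return len(self.time_min) - 1

    def first_crossing_min(self, series: np.ndarray, limit: float):
        """First minute at which the series reaches the limit, or None."""
        hit = np.flatnonzero(np.asarray(series) >= limit)
        return int(self.time_min[hit[0]]) if hit.size else None

    def plateau_time_min(self, rate_c_per_min: float = 0.003,
                         sustain_min: int = 15):
        """First time after which |d(core)/dt| stays below the criterion.

        The rate is evaluated on the minute-sampled core series; the
        criterion must hold for ``sustain_min`` consecutive minutes.
        """
        rate = np.abs(np.diff(self.core_c))
        ok = rate < rate_c_per_min
        run = 0
        for i, flag in enumerate(ok):
            run = run + 1 if flag else 0
            if run >= sustain_min:
                return float(self.time_min[i + 1 - run + 1])
        return None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "time_min": self.time_min,
            "core_c": self.core_c,
            "mean_skin_c": self.mean_skin_c,
            "sweat_ml": self.sweat_ml,
            "secreted_ml": self.secreted_ml,
        })
        for i, s in enumerate(self.segment_names):
            df[f"skin_{s}_c"] = self.skin_c[i]
        return df

    def summary(self) -> str:
        end = -1
        lines = [
            f"Simulation: {self.schedule.label or 'schedule'} | "
            f"Ta {self.env.ta_c:g} C, RH {self.env.rh_pct:g} %, "
            f"v {self.env.v_m_s:g} m/s | clothing {self.clothing_label}",
            f"  duration            : {self.time_min[end]:7.0f} min",
            f"  core ({self.core_node}) start  : {self.core_c[0]:7.2f} C",
            f"  core end            : {self.core_c[end]:7.2f} C",
            f"  core max            : {self.core_c.max():7.2f} C",
            f"  mean skin start/end : {self.mean_skin_c[0]:7.2f} / "
            f"{self.mean_skin_c[end]:7.2f} C",
            f"  sweat loss          : {self.sweat_ml[end]:7.0f} mL",
        ]
        return "\n".join(lines)


class HumanBioheatModel:
    """Bioheat model of one worker in one environment under one schedule.

    Parameters
    ----------
    env : Environment
    clothing : ClothingEnsemble, default the packaged summer work uniform.
    anthro : Anthropometry, default (1.70 m, 60 kg, 20 y male).
    schedule : WorkRestSchedule, default 180 min continuous work at 3.3x
        basal (wire-hooking level).
    dt_s : reporting/integration step, s (default 60).
    dt_sub_max_s : ceiling on the internal sub-step, s.
    core_node : 'head' or 'pelvis'; which core node is reported.
    """

    def __init__(self, env: Environment,
                 clothing: ClothingEnsemble | None = None,
                 anthro: Anthropometry | None = None,
                 schedule: WorkRestSchedule | None = None,
                 gains: ControlGains | None = None,
                 exchange: ExchangeCoefficients | None = None,
                 dt_s: float = 60.0, dt_sub_max_s: float = 5.0,
                 core_node: str = "head"):
        if core_node not in ("head", "pelvis"):
            raise ValueError("core_node must be 'head' or 'pelvis'")
        self.env = env
        self.clothing = clothing or grid_summer_ensemble()
        self.anthro = anthro or Anthropometry()
        self.schedule = schedule or WorkRestSchedule.continuous(180.0)
        self.gains = gains or default_gains()
        self.exchange = exchange or default_exchange_coefficients()
        self.dt_s = float(dt_s)
        self.dt_sub_max_s = float(dt_sub_max_s)
        self.core_node = core_node
        self.body = build_body(self.anthro)
        self.setpoints = neutral_setpoints(self.body, self.exchange)
        self._core_idx = (self.body.head_core_node if core_node == "head"
                          else self.body.pelvis_core_node)
        self._node_names = self.body.node_names()

    # -- single evaluation --------------------------------------------------
    def derivatives(self, state: BodyState, met: float):
        """Full regulated derivative plus flux diagnostics at one instant."""
        body = self.body
        n = body.network.n_tissue
        errors = error_signals(state, self.setpoints, body)
        reg = regulate(errors, body, self.gains)

        bmr = self.anthro.basal_metabolic_rate_w
        work_w = max(met - 1.0, 0.0) * bmr
        production = (body.network.q_basal_w
                      + work_w * body.work_frac
                      + reg.shiver_w * body.shiver_frac)
        m_total = bmr + work_w + reg.shiver_w

        flow = body.network.basal_flow_l_h.copy()
        flow[body.skin_nodes] = reg.skin_flow_l_h
        flow += (self.gains.muscle_flow_l_per_h_w
                 * (work_w * body.work_frac + reg.shiver_w * body.shiver_frac))

        tsk = state.t_c[body.skin_nodes]
        flux = surface_fluxes(tsk, reg.sweat_g_min, self.env, self.clothing,
                              body.segment_areas_m2, m_total, cf=self.exchange)
        surf = np.zeros(n)
        surf[body.skin_nodes] = flux.net_skin_loss_w
        surf[body.chest_core_node] += flux.respiration_w

        d = heat_balance_derivatives(state.t_c, body.network,
                                     flow_l_h=flow, production_w=production,
                                     surface_w=surf)
        return d, reg, flux, m_total

    def step(self, state: BodyState, dt_s: float | None = None,
             met: float = 1.0) -> BodyState:
        """Advance one reporting step, sub-stepping for stability."""
        dt = self.dt_s if dt_s is None else float(dt_s)
        if dt <= 0:
            raise ValueError("dt must be positive")
        n_sub = max(1, math.ceil(dt / self.dt_sub_max_s))
        h = dt / n_sub
        for _ in range(n_sub):
            d, reg, flux, _ = self.derivatives(state, met)
            state = euler_step(state, h, d, node_names=self._node_names)
            state.sweat_g += flux.evaporative_w.sum() / LAMBDA_SWEAT * h
            state.secreted_g += reg.total_sweat_g_min / 60.0 * h
        return state

    def initial_state(self) -> BodyState:
        return BodyState(t_c=self.setpoints.t_c.copy())

    # -- full run -----------------------------------------------------------
    def simulate(self, minutes: float | None = None) -> SimulationResult:
        """Integrate over the schedule and return minute-resolution series."""
        horizon = float(minutes if minutes is not None
                        else self.schedule.total_minutes)
        n_out = int(round(horizon * 60.0 / self.dt_s))
        per_min = max(1, int(round(60.0 / self.dt_s)))

        state = self.initial_state()
        body = self.body
        n_rec = int(horizon) + 1
        t_hist = np.empty((body.n_nodes, n_rec))
        sweat = np.empty(n_rec)
        secreted = np.empty(n_rec)
        t_hist[:, 0] = state.t_c
        sweat[0] = state.sweat_g
        secreted[0] = state.secreted_g

        rec = 1
        for k in range(n_out):
            minute = k * self.dt_s / 60.0
            met = self.schedule.met_at(minute)
            state = self.step(state, self.dt_s, met)
            if (k + 1) % per_min == 0 and rec < n_rec:
                t_hist[:, rec] = state.t_c
                sweat[rec] = state.sweat_g
                secreted[rec] = state.secreted_g
                rec += 1

        skin = t_hist[body.skin_nodes, :rec]
        return SimulationResult(
            time_min=np.arange(rec, dtype=float),
            core_c=t_hist[self._core_idx, :rec],
            mean_skin_c=mean_skin_temperature(
                skin, body.skin_area_weights),
            skin_c=skin,
            sweat_ml=sweat[:rec] / SWEAT_DENSITY,
            secreted_ml=secreted[:rec] / SWEAT_DENSITY,
            t_nodes_c=t_hist[:, :rec],
            schedule=self.schedule, env=self.env,
            clothing_label=self.clothing.label, core_node=self.core_node,
            segment_names=tuple(s.name for s in body.segments),
        )


def simulate(env: Environment, clothing: ClothingEnsemble | None = None,
             anthro: Anthropometry | None = None,
             schedule: WorkRestSchedule | None = None,
             minutes: float | None = None, **kwargs) -> SimulationResult:
    """One-call wrapper around :class:`HumanBioheatModel`."""
    model = HumanBioheatModel(env, clothing, anthro, schedule, **kwargs)
    return model.simulate(minutes)
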