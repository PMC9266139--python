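"""Synthetic inputs: built-in study scenarios, manikin record generation
with known ground truth, and randomized environments/schedules.

The manikin generator inverts the serial-model arithmetic: given a true
local resistance R_i, a chamber temperature and the 34 degC surface
setpoint, the heat loss is H_ci = (T_si - Ta) * a_i / R_i, optionally with
multiplicative Gaussian noise.  A noiseless stream therefore reduces back
to the true resistances exactly, which is the primary oracle for the
insulation estimator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry
from .body import SEGMENT_NAMES
from .clothing import ClothingEnsemble, grid_summer_ensemble
from .environment import Environment
from .schedule import WorkRestSchedule

__all__ = ["ScenarioSet", "grid_worker_scenarios", "SynthManikinSpec",
           "default_manikin_spec", "synth_manikin", "random_environment",
           "random_schedule"]


@dataclass(frozen=True)
class ScenarioSet:
    """The canned study conditions for the outdoor-worker evaluation."""

    trajectory_envs: tuple       # three 180-min trajectory environments
    schedule_env: Environment    # environment of the work/rest comparison
    schedules: dict              # C1..C4 work/rest strategies (240-min horizon)
    worker: Anthropometry
    ensemble: ClothingEnsemble
    work_met: float              # activity ratio during work
    rest_met: float              # activity ratio during rest


def grid_worker_scenarios() -> ScenarioSet:
    """Scenario set for summer outdoor power-grid work.

    Three trajectory environments (33 degC/45 %, 35/50, 37/55; still air),
    one schedule environment (38 degC/55 %, still air) with four work/rest
    strategies over a 240-min horizon: C1 continuous work, C2 60 min work /
    30 min rest, C3 60/45, C4 60/60.  Work is wire-hooking at 3.3x basal;
    rest is light seated recovery (1.05x) in the same environment — the
    rest blocks stay in the heat, so recovery is limited.
    """
    work, rest = 3.3, 1.05
    horizon = 240.0
    schedules = {
        "C1": WorkRestSchedule.continuous(horizon, met=work, label="C1"),
        "C2": WorkRestSchedule.cycle(60, 30, horizon, work, rest, label="C2"),
        "C3": WorkRestSchedule.cycle(60, 45, horizon, work, rest, label="C3"),
        "C4": WorkRestSchedule.cycle(60, 60, horizon, work, rest, label="C4"),
    }
    return ScenarioSet(
        trajectory_envs=(
            Environment(ta_c=33.0, rh_pct=45.0, v_m_s=0.2),
            Environment(ta_c=35.0, rh_pct=50.0, v_m_s=0.2),
            Environment(ta_c=37.0, rh_pct=55.0, v_m_s=0.2),
        ),
        schedule_env=Environment(ta_c=38.0, rh_pct=55.0, v_m_s=0.2),
        schedules=schedules,
        worker=Anthropometry(height_m=1.70, weight_kg=60.0),
        ensemble=grid_summer_ensemble(),
        work_met=work, rest_met=rest,
    )


@dataclass(frozen=True)
class SynthManikinSpec:
    """Ground truth and protocol for synthetic manikin records.

    ``true_total`` / ``true_air`` map segment names to the clothed and
    nude local resistances (m2K/W).  The chamber defaults mirror a
    standard constant-skin-temperature test: surface held at 34 degC in a
    24 degC chamber.
    """

    true_total: dict
    true_air: dict
    chamber_ta_c: float = 24.0
    skin_setpoint_c: float = 34.0
    noise_frac: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be >= 0")
        for d in (self.true_total, self.true_air):
            if any(v < 0 for v in d.values()):
                raise ValueError("local resistances must be >= 0")
        if set(self.true_total) != set(self.true_air):
            raise ValueError("clothed and nude truth must cover the same segments")


def default_manikin_spec(noise_frac: float = 0.0, seed: int = 0
                         ) -> SynthManikinSpec:
    """A 16-segment manikin (head unmeasured) with a torso-heavy pattern.

    The clothed truth concentrates resistance on hips and thighs (coat and
    trousers overlap), leaves the hands at their air-layer value, and puts
    boots on the feet.
    """
    air = {
        "neck": 0.068, "chest": 0.070, "back": 0.072, "pelvis": 0.072,
        "shoulder": 0.070, "arm": 0.068, "hand": 0.060,
        "thigh": 0.072, "leg": 0.070, "foot": 0.062,
    }
    total = {
        "neck": 0.105, "chest": 0.125, "back": 0.160, "pelvis": 0.320,
        "shoulder": 0.175, "arm": 0.140, "hand": 0.060,
        "thigh": 0.220, "leg": 0.125, "foot": 0.195,
    }
    def expand(d):
        out = {}
        for seg in SEGMENT_NAMES:
            if seg == "head":
                continue
            out[seg] = d[seg.split("_")[-1]]
        return out
    return SynthManikinSpec(true_total=expand(total), true_air=expand(air),
                            noise_frac=noise_frac, seed=seed)


def synth_manikin(spec: SynthManikinSpec, n_minutes: int = 30,
                  n_runs: int = 2,
                  anthro: Anthropometry | None = None) -> pd.DataFrame:
    """Generate a minute-resolution manikin record stream.

    Returns a long-format table (segment, condition, run, minute, tsurf_c,
    heat_w, area_m2) whose noiseless reduction through the serial-model
    estimator recovers the true resistances exactly.  Reproducible for a
    fixed spec seed.
    """
    anthro = anthro or Anthropometry()
    from .body import _load_tables
    comp, _ = _load_tables()
    area_frac = comp.groupby("segment", sort=False)["area_frac"].first()
    bsa = anthro.body_surface_area_m2

    rng = np.random.default_rng(spec.seed)
    dt = spec.skin_setpoint_c - spec.chamber_ta_c
    rows = []
    for condition, truth in (("nude", spec.true_air),
                             ("clothed", spec.true_total)):
        for run in range(1, n_runs + 1):
            for seg, r in truth.items():
                area = float(area_frac[seg]) * bsa
                if r <= 0:
                    raise ValueError(
                        f"zero local resistance for {seg!r} with a nonzero "
                        "temperature difference implies infinite heat loss")
                h0 = dt * area / r
                noise = rng.normal(0.0, spec.noise_frac, size=n_minutes)
                for minute in range(1, n_minutes + 1):
                    rows.append(dict(segment=seg, condition=condition,
                                     run=run, minute=minute,
                                     tsurf_c=spec.skin_setpoint_c,
                                     heat_w=h0 * (1.0 + noise[minute - 1]),
                                     area_m2=area))
    return pd.DataFrame(rows)


def random_environment(seed, ta_bounds=(30.0, 42.0), rh_bounds=(40.0, 90.0),
                       wind_choices=(0.2, 1.0, 2.0)) -> Environment:
    """Uniform random environment within validated bounds (seeded)."""
    rng = np.random.default_rng(seed)
    return Environment(
        ta_c=float(rng.uniform(*ta_bounds)),
        rh_pct=float(rng.uniform(*rh_bounds)),
        v_m_s=float(rng.choice(wind_choices)),
    )


def random_schedule(seed, horizon_min: float = 240.0, met_work: float = 3.3,
                    met_rest: float = 1.2) -> WorkRestSchedule:
    """Random repeating work/rest cycle over the horizon (seeded)."""
    rng = np.random.default_rng(seed)
    work = float(rng.integers(30, 91))
    rest = float(rng.integers(15, 61))
    return WorkRestSchedule.cycle(work, rest, horizon_min, met_work, met_rest,
                                  label=f"rand{work:g}/{rest:g}")
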