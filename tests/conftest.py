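import numpy as np
import pytest

import heatstrain as hs
from heatstrain.model import HumanBioheatModel


class SimCache:
    """Lazily computed, session-shared scenario simulations."""

    def __init__(self):
        self.sc = hs.grid_worker_scenarios()
        self._store = {}

    def get(self, key):
        if key not in self._store:
            self._store[key] = self._run(key)
        return self._store[key]

    def _run(self, key):
        sc = self.sc
        if key.startswith("traj"):
            ta = float(key[4:6])
            env = next(e for e in sc.trajectory_envs if e.ta_c == ta)
            model = HumanBioheatModel(env, sc.ensemble, sc.worker,
                                      hs.WorkRestSchedule.continuous(180.0))
            return model.simulate()
        if key in sc.schedules:
            model = HumanBioheatModel(sc.schedule_env, sc.ensemble, sc.worker,
                                      sc.schedules[key])
            return model.simulate()
        if key == "neutral29":
            model = HumanBioheatModel(
                hs.Environment(ta_c=29.0, rh_pct=50.0, v_m_s=0.2),
                hs.nude_ensemble(), sc.worker,
                hs.WorkRestSchedule.continuous(180.0, met=1.0))
            return model.simulate()
        if key == "traj33_dt30":
            model = HumanBioheatModel(
                sc.trajectory_envs[0], sc.ensemble, sc.worker,
                hs.WorkRestSchedule.continuous(180.0), dt_s=30.0)
            return model.simulate()
        raise KeyError(key)


@pytest.fixture(scope="session")
def sims():
    return SimCache()


@pytest.fixture(scope="session")
def scenarios(sims):
    return sims.sc


@pytest.fixture(scope="session")
def body():
    return hs.build_body()


@pytest.fixture(scope="session")
def setpoints(body):
    from heatstrain.model import neutral_setpoints
    return neutral_setpoints(body)
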