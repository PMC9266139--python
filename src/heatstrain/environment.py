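"""Ambient environment description."""
from __future__ import annotations

from dataclasses import dataclass

from .constants import saturation_vapor_pressure_kpa

__all__ = ["Environment"]

#: conventional air speed representing still air ("no wind")
STILL_AIR_M_S = 0.2


@dataclass(frozen=True)
class Environment:
    """Thermal environment around the worker.

    Parameters
    ----------
    ta_c : air (dry-bulb) temperature, degC.
    rh_pct : relative humidity, 0-100 %.
    tr_c : mean radiant temperature, degC.  ``None`` means equal to the
        air temperature, the convention used for all built-in scenarios.
    v_m_s : air velocity, m/s.  Still air is represented as 0.2 m/s.
    solar_w_m2 : shortwave irradiance on the body, W/m2 (0 = indoors/shade).
    """

    ta_c: float
    rh_pct: float
    tr_c: float | None = None
    v_m_s: float = STILL_AIR_M_S
    solar_w_m2: float = 0.0

    def __post_init__(self):
        if not 0.0 <= self.rh_pct <= 100.0:
            raise ValueError(f"relative humidity must be in [0, 100], got {self.rh_pct}")
        if self.v_m_s < 0:
            raise ValueError(f"air velocity must be >= 0, got {self.v_m_s}")
        if self.solar_w_m2 < 0:
            raise ValueError(f"solar irradiance must be >= 0, got {self.solar_w_m2}")

    @property
    def mrt_c(self) -> float:
        """Mean radiant temperature actually used (defaults to ta)."""
        return self.ta_c if self.tr_c is None else self.tr_c

    @property
    def vapor_pressure_kpa(self) -> float:
        """Ambient water-vapour partial pressure, kPa."""
        return self.rh_pct / 100.0 * float(saturation_vapor_pressure_kpa(self.ta_c))
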