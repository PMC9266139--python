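"""Body-size description and the derived whole-body quantities.

Surface area follows the DuBois formula; the basal metabolic rate uses the
revised Harris-Benedict equations, which carry the age and sex dependence
of resting heat production.  Activity levels elsewhere in the package are
expressed as multiples of this basal rate (physical activity ratio).
"""
from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["Anthropometry"]

_KCAL_DAY_TO_W = 4184.0 / 86400.0


@dataclass(frozen=True)
class Anthropometry:
    """Height, weight, age and sex of the simulated worker.

    The default instance (1.70 m, 60 kg, 20 y male) is the reference
    outdoor worker used throughout the package.
    """

    height_m: float = 1.70
    weight_kg: float = 60.0
    age_y: float = 20.0
    sex: str = "male"

    def __post_init__(self):
        if not self.height_m > 0:
            raise ValueError(f"height must be positive, got {self.height_m}")
        if not self.weight_kg > 0:
            raise ValueError(f"weight must be positive, got {self.weight_kg}")
        if not 0 < self.age_y < 130:
            raise ValueError(f"age out of range: {self.age_y}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")

    @property
    def body_surface_area_m2(self) -> float:
        """DuBois surface area, m2."""
        return 0.007184 * self.weight_kg**0.425 * (self.height_m * 100.0) ** 0.725

    @property
    def basal_metabolic_rate_w(self) -> float:
        """Harris-Benedict basal metabolic rate, W."""
        if self.sex == "male":
            kcal = (66.473 + 13.7516 * self.weight_kg
                    + 5.0033 * self.height_m * 100.0 - 6.755 * self.age_y)
        else:
            kcal = (655.0955 + 9.5634 * self.weight_kg
                    + 1.8496 * self.height_m * 100.0 - 4.6756 * self.age_y)
        return kcal * _KCAL_DAY_TO_W
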