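"""Work/rest schedules as ordered blocks of (duration, activity level)."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Block", "WorkRestSchedule"]


@dataclass(frozen=True)
class Block:
    """One schedule block.

    ``met`` is the physical activity ratio: metabolic rate as a multiple
    of the person's basal rate (1.0 = basal).  ``kind`` labels the block
    as work or rest for the effective-working-time accounting.
    """

    duration_min: float
    met: float
    kind: str = "work"

    def __post_init__(self):
        if self.duration_min <= 0:
            raise ValueError("block duration must be positive")
        if self.met < 1.0:
            raise ValueError("activity level must be >= 1.0 (basal)")
        if self.kind not in ("work", "rest"):
            raise ValueError(f"block kind must be work or rest, got {self.kind!r}")


@dataclass(frozen=True)
class WorkRestSchedule:
    blocks: tuple
    label: str = ""

    def __post_init__(self):
        if not self.blocks:
            raise ValueError("schedule needs at least one block")

    @classmethod
    def continuous(cls, minutes: float, met: float = 3.3,
                   label: str = "continuous") -> "WorkRestSchedule":
        return cls(blocks=(Block(minutes, met, "work"),), label=label)

    @classmethod
    def cycle(cls, work_min: float, rest_min: float, horizon_min: float,
              met_work: float = 3.3, met_rest: float = 1.2,
              label: str = "") -> "WorkRestSchedule":
        """Repeating work/rest blocks truncated to the horizon."""
        blocks, t, working = [], 0.0, True
        while t < horizon_min - 1e-9:
            dur = min(work_min if working else rest_min, horizon_min - t)
            blocks.append(Block(dur, met_work if working else met_rest,
                                "work" if working else "rest"))
            t += dur
            working = not working
        return cls(blocks=tuple(blocks),
                   label=label or f"{work_min:g}w/{rest_min:g}r")

    @property
    def total_minutes(self) -> float:
        return sum(b.duration_min for b in self.blocks)

    @property
    def work_minutes(self) -> float:
        return sum(b.duration_min for b in self.blocks if b.kind == "work")

    @property
    def rest_minutes(self) -> float:
        return sum(b.duration_min for b in self.blocks if b.kind == "rest")

    def block_at(self, minute: float) -> Block:
        """Block active at the given minute (end-exclusive boundaries)."""
        t = 0.0
        for b in self.blocks:
            t += b.duration_min
            if minute < t - 1e-9:
                return b
        return self.blocks[-1]

    def met_at(self, minute: float) -> float:
        return self.block_at(minute).met

    def work_mask(self, n_minutes: int) -> np.ndarray:
        """Boolean work-block membership for minutes 0..n-1."""
        return np.array([self.block_at(m + 0.5).kind == "work"
                         for m in range(n_minutes)])
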