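"""Per-segment clothing ensembles.

An ensemble assigns each body segment a basic (intrinsic) insulation in
clo, a clothing area factor f_cl and a vapour-permeability index i_cl.
The packaged default emulates a summer work uniform (long-sleeve coat,
trousers, protective boots): torso and lower body carry most of the
insulation, the hips are double-covered by coat and trousers, head and
hands are bare.  The per-segment split behind the measured whole-body
value is not observable from a whole-body measurement, so the default
table is an editable fixture shipped with the package.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .body import SEGMENT_NAMES

__all__ = ["ClothingEnsemble", "grid_summer_ensemble", "nude_ensemble"]


@dataclass(frozen=True)
class ClothingEnsemble:
    """Per-segment basic insulation (clo), area factor and permeability."""

    clo: tuple          # basic insulation per segment, clo (0 = nude)
    f_cl: tuple         # clothing area factor per segment, >= 1
    i_cl: tuple         # permeability index per segment, (0, 1]
    label: str = "custom"

    def __post_init__(self):
        for name, vals in (("clo", self.clo), ("f_cl", self.f_cl), ("i_cl", self.i_cl)):
            if len(vals) != len(SEGMENT_NAMES):
                raise ValueError(f"{name} must have one entry per segment")
        if any(c < 0 for c in self.clo):
            raise ValueError("insulation must be >= 0")
        if any(f < 1 for f in self.f_cl):
            raise ValueError("clothing area factor must be >= 1")
        if any(not 0 < i <= 1 for i in self.i_cl):
            raise ValueError("permeability index must be in (0, 1]")

    @property
    def clo_array(self) -> np.ndarray:
        return np.asarray(self.clo, dtype=float)

    @property
    def f_cl_array(self) -> np.ndarray:
        return np.asarray(self.f_cl, dtype=float)

    @property
    def i_cl_array(self) -> np.ndarray:
        return np.asarray(self.i_cl, dtype=float)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "custom") -> "ClothingEnsemble":
        """Build an ensemble from a table with segment, clo, f_cl, i_cl columns."""
        df = df.set_index("segment").reindex(SEGMENT_NAMES)
        if df["clo"].isna().any():
            missing = df.index[df["clo"].isna()].tolist()
            raise ValueError(f"ensemble table is missing segments: {missing}")
        return cls(clo=tuple(df["clo"]), f_cl=tuple(df["f_cl"]),
                   i_cl=tuple(df["i_cl"]), label=label)

    @classmethod
    def uniform(cls, clo: float, f_cl: float | None = None, i_cl: float = 0.34,
                label: str = "uniform") -> "ClothingEnsemble":
        n = len(SEGMENT_NAMES)
        f = f_cl if f_cl is not None else max(1.0, 1.0 + 0.31 * clo)
        return cls(clo=(clo,) * n, f_cl=(f,) * n, i_cl=(i_cl,) * n, label=label)


def grid_summer_ensemble() -> ClothingEnsemble:
    """Default summer work uniform (0.709 clo whole-body basic insulation)."""
    with resources.files("heatstrain.data").joinpath("ensemble_grid_summer.csv").open() as fh:
        df = pd.read_csv(fh)
    return ClothingEnsemble.from_frame(df, label="grid_summer")


def nude_ensemble() -> ClothingEnsemble:
    """Unclothed body (zero insulation, area factor 1)."""
    n = len(SEGMENT_NAMES)
    return ClothingEnsemble(clo=(0.0,) * n, f_cl=(1.0,) * n, i_cl=(1.0,) * n,
                            label="nude")
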