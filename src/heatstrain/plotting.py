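"""Matplotlib helpers for trajectories and AMWT charts."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np

from .strain import grid_to_matrix

__all__ = ["plot_trajectories", "plot_amwt_chart"]


def plot_trajectories(results, what="core", ax=None):
    """Overlay core (or mean-skin) temperature trajectories.

    ``results`` maps labels to :class:`~heatstrain.model.SimulationResult`.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for label, res in results.items():
        y = res.core_c if what == "core" else res.mean_skin_c
        ax.plot(res.time_min, y, label=str(label))
    ax.set_xlabel("time (min)")
    ax.set_ylabel("core temperature (degC)" if what == "core"
                  else "mean skin temperature (degC)")
    ax.legend(frameon=False)
    return ax


def plot_amwt_chart(grid, v_m_s=0.2, ax=None, cmap="RdYlGn"):
    """Heat-map of AMWT over the (Ta, RH) plane for one wind level."""
    mat = grid_to_matrix(grid, v_m_s)
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(mat.to_numpy(), origin="lower", aspect="auto", cmap=cmap,
                   extent=(mat.columns.min(), mat.columns.max(),
                           mat.index.min(), mat.index.max()))
    ax.figure.colorbar(im, ax=ax, label="AMWT (min)")
    ax.set_xlabel("relative humidity (%)")
    ax.set_ylabel("air temperature (degC)")
    ax.set_title(f"acceptable maximum working time, wind {v_m_s:g} m/s")
    return ax
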