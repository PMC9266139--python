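"""Active system: setpoints, error signals and thermoregulatory control.

Effector outputs follow the classic multi-node control structure: every
effector is a linear (saturating) combination of the head-core error and
the area-integrated warm/cold skin signals, distributed over segments by
fixed fractions.  Sweating is additionally modulated locally by the skin
error (2^(err/10)); skin blood flow per segment is
(basal + dilation share) / (1 + constriction share).  Effectors are
memoryless functions of the current error signals.

Setpoints are defined as the passive steady state of the same body in a
thermoneutral reference condition (operative 30 degC, RH 50 %, still air,
nude, basal metabolism), so by construction every error signal is zero
exactly where the unregulated body is in balance.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .body import BodyBuild, BodyState
from .exchange import load_coefficients

__all__ = ["ControlGains", "SetpointTable", "ErrorSignals", "RegulationOutput",
           "default_gains", "error_signals", "regulate"]


@dataclass(frozen=True)
class ControlGains:
    """Scalar gains of the control laws (editable via coefficients.csv)."""

    csw_w_per_k: float          # sweating: head-core warm error gain
    ssw_w_per_k: float          # sweating: integrated skin warm signal gain
    cdl_l_per_h_k: float        # vasodilation: head-core gain
    sdl_l_per_h_k: float        # vasodilation: skin signal gain
    cst_per_k: float            # vasoconstriction: head-core cold gain
    sst_per_k: float            # vasoconstriction: skin cold gain
    csh_w_per_k2: float         # shivering: product gain
    sweat_local_half_range_k: float
    sweat_max_g_per_min: float
    skin_flow_max_l_per_h_m2: float
    skin_flow_min_l_per_h_m2: float
    shiver_max_w: float
    muscle_flow_l_per_h_w: float

    def __post_init__(self):
        for name in ("csw_w_per_k", "ssw_w_per_k", "cdl_l_per_h_k",
                     "sdl_l_per_h_k", "cst_per_k", "sst_per_k", "csh_w_per_k2"):
            if getattr(self, name) < 0:
                raise ValueError(f"control gain {name} must be >= 0")


def default_gains() -> ControlGains:
    t = load_coefficients()
    return ControlGains(**{k: t[k] for k in ControlGains.__dataclass_fields__})


@dataclass(frozen=True)
class SetpointTable:
    """Per-node setpoint temperatures (central blood last)."""

    t_c: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.t_c)):
            raise ValueError("setpoints must be finite")


@dataclass
class ErrorSignals:
    """Per-node errors and the integrated warm/cold skin signals."""

    err_k: np.ndarray        # per tissue node, T - Tset
    warm_k: float            # area-weighted positive skin errors
    cold_k: float            # area-weighted negative skin errors (magnitude)
    head_core_err_k: float
    skin_err_k: np.ndarray   # per segment


def error_signals(state: BodyState, setpoints: SetpointTable,
                  body: BodyBuild) -> ErrorSignals:
    """Err = T - Tset per node, plus area-weighted skin integrals."""
    n = body.network.n_tissue
    if state.t_c.shape[0] != setpoints.t_c.shape[0]:
        raise ValueError("state and setpoints cover different node sets")
    err = state.t_c[:n] - setpoints.t_c[:n]
    skin_err = err[body.skin_nodes]
    w = body.skin_area_weights
    warm = float(w @ np.clip(skin_err, 0.0, None))
    cold = float(w @ np.clip(-skin_err, 0.0, None))
    return ErrorSignals(err_k=err, warm_k=warm, cold_k=cold,
                        head_core_err_k=float(err[body.head_core_node]),
                        skin_err_k=skin_err)


@dataclass
class RegulationOutput:
    """Effector commands: per-segment sweat and skin flow, plus shivering."""

    sweat_g_min: np.ndarray      # per segment, secreted
    skin_flow_l_h: np.ndarray    # per segment
    shiver_w: float
    dilation_l_h: float
    constriction: float

    @property
    def total_sweat_g_min(self) -> float:
        return float(self.sweat_g_min.sum())


def regulate(errors: ErrorSignals, body: BodyBuild,
             gains: ControlGains | None = None) -> RegulationOutput:
    """Evaluate the control laws for the current error signals.

    Sweat and dilation respond to warm signals only, shivering and
    constriction to cold signals only, so a body at setpoint produces no
    effector output and skin blood flow equals its basal value.
    """
    g = gains or default_gains()
    warm_net = errors.warm_k - errors.cold_k
    e_cr = errors.head_core_err_k
    w = body.skin_area_weights

    # sweating, expressed as heat-equivalent W then converted to g/min
    sw_signal = max(g.csw_w_per_k * e_cr + g.ssw_w_per_k * warm_net, 0.0)
    local = np.power(2.0, errors.skin_err_k / g.sweat_local_half_range_k)
    sweat_w = sw_signal * w * local
    sweat_g_min = sweat_w * 60.0 / 2418.0
    total = sweat_g_min.sum()
    if total > g.sweat_max_g_per_min:
        sweat_g_min *= g.sweat_max_g_per_min / total

    # vasomotion
    dl = max(g.cdl_l_per_h_k * e_cr + g.sdl_l_per_h_k * warm_net, 0.0)
    st = max(g.cst_per_k * (-e_cr) + g.sst_per_k * (-warm_net), 0.0)
    basal_sk = body.network.basal_flow_l_h[body.skin_nodes]
    areas = body.segment_areas_m2
    flow = (basal_sk + w * dl) / (1.0 + w * st)
    flow = np.clip(flow, g.skin_flow_min_l_per_h_m2 * areas,
                   g.skin_flow_max_l_per_h_m2 * areas)

    # shivering
    shiver = min(g.csh_w_per_k2 * errors.cold_k * max(-e_cr, 0.0), g.shiver_max_w)

    return RegulationOutput(sweat_g_min=sweat_g_min, skin_flow_l_h=flow,
                            shiver_w=shiver, dilation_l_h=dl, constriction=st)
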