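"""Passive system: body segmentation, node network and heat-balance terms.

The body is divided into 17 segments.  Head and pelvis carry six tissue
layers (skin, fat, muscle, core, artery, vein); neck, chest and back carry
four (skin, core, artery, vein); the twelve limb segments carry five
(skin, core, artery, vein, superficial vein).  Together with a central
blood compartment this gives 85 nodes.  Every tissue node exchanges heat
with the central blood pool through its perfusion, with its neighbours
through conduction, and the skin nodes additionally with the environment.

Segment geometry, layer masses, heat capacities, basal perfusion and basal
heat production are read from an editable data table shipped with the
package and scaled to the simulated person's height and weight.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .anthropometry import Anthropometry
from .constants import BLOOD_W_PER_K_L_H

__all__ = [
    "SEGMENT_NAMES", "LAYERS_BY_SEGMENT", "SegmentSpec", "ThermalNetwork",
    "BodyBuild", "BodyState", "build_body", "heat_balance_derivatives",
    "euler_step", "SimulationInstabilityError", "CENTRAL_BLOOD",
]

CENTRAL_BLOOD = "central_blood"

SEGMENT_NAMES = (
    "head", "neck", "chest", "back", "pelvis",
    "left_shoulder", "right_shoulder", "left_arm", "right_arm",
    "left_hand", "right_hand", "left_thigh", "right_thigh",
    "left_leg", "right_leg", "left_foot", "right_foot",
)

_SIX = ("skin", "fat", "muscle", "core", "artery", "vein")
_FOUR = ("skin", "core", "artery", "vein")
_FIVE = ("skin", "core", "artery", "vein", "superficial_vein")

LAYERS_BY_SEGMENT = {
    "head": _SIX, "pelvis": _SIX,
    "neck": _FOUR, "chest": _FOUR, "back": _FOUR,
}
for _s in SEGMENT_NAMES[5:]:
    LAYERS_BY_SEGMENT[_s] = _FIVE

#: fraction of body mass assigned to the central blood pool
_CENTRAL_BLOOD_MASS_FRAC = 0.025
_CP_BLOOD = 3850.0  # J/kgK


class SimulationInstabilityError(RuntimeError):
    """Raised when integration produces a non-finite node temperature."""


@dataclass(frozen=True)
class SegmentSpec:
    """One body segment: its layers, surface area and mass fraction."""

    name: str
    layers: tuple
    surface_area_m2: float
    mass_frac: float


@dataclass
class BodyState:
    """Node temperatures plus the cumulative sweat account at one instant."""

    t_c: np.ndarray            # length n_nodes, central blood last
    sweat_g: float = 0.0       # cumulative evaporated sweat mass
    secreted_g: float = 0.0    # cumulative secreted sweat mass
    time_s: float = 0.0

    def copy(self) -> "BodyState":
        return BodyState(self.t_c.copy(), self.sweat_g, self.secreted_g, self.time_s)


@dataclass
class ThermalNetwork:
    """Capacities, conduction and basal blood-flow network over the nodes.

    Arrays are ordered with the central blood compartment last.  The class
    is generic over the node count so that small hand-built networks can be
    used to verify the heat-balance arithmetic in isolation.
    """

    c_j_per_k: np.ndarray          # (n+1,) heat capacity incl. central blood
    conduction_w_per_k: np.ndarray  # (n+1, n+1) symmetric, zero diagonal
    basal_flow_l_h: np.ndarray     # (n,) perfusion coupling each tissue node to blood
    q_basal_w: np.ndarray          # (n,) basal heat production

    def __post_init__(self):
        if np.any(self.c_j_per_k <= 0):
            raise ValueError("all heat capacities must be positive")
        if not np.allclose(self.conduction_w_per_k, self.conduction_w_per_k.T):
            raise ValueError("conduction matrix must be symmetric")

    @property
    def n_tissue(self) -> int:
        return len(self.basal_flow_l_h)


@dataclass
class BodyBuild:
    """A fully populated body: segments, node bookkeeping and network."""

    anthropometry: Anthropometry
    segments: list
    network: ThermalNetwork
    node_segment: np.ndarray       # (n,) segment index per tissue node
    node_layer: list               # (n,) layer name per tissue node
    skin_nodes: np.ndarray         # (17,) skin node index per segment
    work_frac: np.ndarray          # (n,) distribution of external work heat
    shiver_frac: np.ndarray        # (n,) distribution of shivering heat
    head_core_node: int = 0
    pelvis_core_node: int = 0
    chest_core_node: int = 0

    @property
    def n_nodes(self) -> int:
        """Total node count including the central blood compartment."""
        return self.network.n_tissue + 1

    @property
    def segment_areas_m2(self) -> np.ndarray:
        return np.array([s.surface_area_m2 for s in self.segments])

    @property
    def skin_area_weights(self) -> np.ndarray:
        a = self.segment_areas_m2
        return a / a.sum()

    def node_names(self) -> list:
        names = [f"{self.segments[s].name}:{l}"
                 for s, l in zip(self.node_segment, self.node_layer)]
        return names + [CENTRAL_BLOOD]

    def to_dict(self) -> dict:
        """JSON-ready dump of the build for inspection."""
        return {
            "anthropometry": vars(self.anthropometry).copy(),
            "body_surface_area_m2": self.anthropometry.body_surface_area_m2,
            "basal_metabolic_rate_w": self.anthropometry.basal_metabolic_rate_w,
            "n_nodes": self.n_nodes,
            "nodes": [
                {"name": n, "heat_capacity_j_per_k": float(c),
                 "basal_flow_l_h": float(b), "q_basal_w": float(q)}
                for n, c, b, q in zip(self.node_names()[:-1],
                                      self.network.c_j_per_k[:-1],
                                      self.network.basal_flow_l_h,
                                      self.network.q_basal_w)
            ],
            "central_blood_heat_capacity_j_per_k":
                float(self.network.c_j_per_k[-1]),
        }


def _load_tables():
    with resources.files("heatstrain.data").joinpath("body_composition.csv").open() as fh:
        comp = pd.read_csv(fh)
    with resources.files("heatstrain.data").joinpath("conduction.csv").open() as fh:
        cond = pd.read_csv(fh)
    return comp, cond


def build_body(anthro: Anthropometry | None = None) -> BodyBuild:
    """Assemble the 85-node body scaled to the given anthropometry.

    Layer masses scale linearly with body weight, segment areas with the
    DuBois surface area and basal production with the basal metabolic rate,
    so the same composition table serves any body size.
    """
    anthro = anthro or Anthropometry()
    comp, cond = _load_tables()

    bsa = anthro.body_surface_area_m2
    bmr = anthro.basal_metabolic_rate_w
    w = anthro.weight_kg

    seg_area = comp.groupby("segment", sort=False)["area_frac"].first()
    seg_mass = comp.groupby("segment", sort=False)["mass_frac"].sum()
    segments = [SegmentSpec(name=s, layers=tuple(LAYERS_BY_SEGMENT[s]),
                            surface_area_m2=float(seg_area[s]) * bsa,
                            mass_frac=float(seg_mass[s]))
                for s in SEGMENT_NAMES]

    # enumerate tissue nodes in canonical order
    node_rows = []
    for si, s in enumerate(SEGMENT_NAMES):
        sub = comp[comp.segment == s].set_index("layer")
        for layer in LAYERS_BY_SEGMENT[s]:
            node_rows.append((si, layer, sub.loc[layer]))
    n = len(node_rows)
    if n != 84:
        raise RuntimeError(f"expected 84 tissue nodes, table gives {n}")

    node_segment = np.array([r[0] for r in node_rows])
    node_layer = [r[1] for r in node_rows]
    mass = np.array([r[2].mass_frac for r in node_rows]) * w
    cp = np.array([r[2].cp_j_per_kg_k for r in node_rows])
    c = np.empty(n + 1)
    c[:n] = mass * cp
    c[n] = _CENTRAL_BLOOD_MASS_FRAC * w * _CP_BLOOD

    basal_flow = mass * np.array([r[2].basal_flow_l_per_h_kg for r in node_rows])
    q_basal = bmr * np.array([r[2].q_basal_frac for r in node_rows])
    work_frac = np.array([r[2].work_frac for r in node_rows])
    shiver_frac = np.array([r[2].shiver_frac for r in node_rows])

    index = {(si, l): i for i, (si, l) in enumerate(zip(node_segment, node_layer))}
    L = np.zeros((n + 1, n + 1))
    for row in cond.itertuples():
        si = SEGMENT_NAMES.index(row.segment)
        i, j = index[(si, row.layer_a)], index[(si, row.layer_b)]
        g = row.k_w_per_m2k * float(seg_area[row.segment]) * bsa
        L[i, j] += g
        L[j, i] += g

    network = ThermalNetwork(c_j_per_k=c, conduction_w_per_k=L,
                             basal_flow_l_h=basal_flow, q_basal_w=q_basal)
    skin_nodes = np.array([index[(si, "skin")] for si in range(17)])
    return BodyBuild(
        anthropometry=anthro, segments=segments, network=network,
        node_segment=node_segment, node_layer=node_layer,
        skin_nodes=skin_nodes, work_frac=work_frac, shiver_frac=shiver_frac,
        head_core_node=index[(0, "core")],
        pelvis_core_node=index[(4, "core")],
        chest_core_node=index[(2, "core")],
    )


def heat_balance_derivatives(
    t_c: np.ndarray,
    network: ThermalNetwork,
    flow_l_h: np.ndarray | None = None,
    production_w: np.ndarray | None = None,
    surface_w: np.ndarray | None = None,
) -> np.ndarray:
    """Node temperature derivatives, K/s.

    Each tissue node obeys  c dT/dt = Q + B + D - (surface losses),
    where B couples the node to the central blood pool through its
    perfusion and D is conduction with adjacent layers.  The central blood
    derivative is minus the sum of all B terms divided by its capacity, so
    blood exchange conserves energy exactly.

    Parameters are absolute: ``flow_l_h`` defaults to the basal perfusion,
    ``production_w`` to the basal production and ``surface_w`` (positive =
    loss to the environment, per node) to zero.
    """
    n = network.n_tissue
    t_c = np.asarray(t_c, dtype=float)
    if t_c.shape != (n + 1,):
        raise ValueError(f"state has {t_c.shape[0]} nodes, network has {n + 1}")
    flow = network.basal_flow_l_h if flow_l_h is None else flow_l_h
    q = network.q_basal_w if production_w is None else production_w
    if flow.shape != (n,) or q.shape != (n,):
        raise ValueError("flow and production must have one entry per tissue node")

    t_cb = t_c[n]
    beta = BLOOD_W_PER_K_L_H * flow
    blood = beta * (t_cb - t_c[:n])

    g = network.conduction_w_per_k
    cond = g @ t_c - g.sum(axis=1) * t_c

    d = np.empty(n + 1)
    d[:n] = q + blood + cond[:n]
    if surface_w is not None:
        d[:n] -= surface_w
    d[:n] /= network.c_j_per_k[:n]
    d[n] = (-blood.sum() + cond[n]) / network.c_j_per_k[n]
    return d


def euler_step(state: BodyState, dt_s: float, derivatives: np.ndarray,
               node_names: list | None = None) -> BodyState:
    """One explicit first-order step: T <- T + dT/dt * dt.

    Raises :class:`SimulationInstabilityError` naming the first offending
    node if any temperature leaves the finite range.
    """
    if dt_s <= 0:
        raise ValueError(f"dt must be positive, got {dt_s}")
    t_new = state.t_c + np.asarray(derivatives) * dt_s
    if not np.all(np.isfinite(t_new)):
        bad = int(np.flatnonzero(~np.isfinite(t_new))[0])
        name = node_names[bad] if node_names else f"node {bad}"
        raise SimulationInstabilityError(
            f"non-finite temperature at {name} after step of {dt_s} s")
    return BodyState(t_new, state.sweat_g, state.secreted_g, state.time_s + dt_s)
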