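"""Heat exchange between the clothed body surface and the environment.

Dry exchange treats each segment as a series resistance: intrinsic clothing
insulation (0.155 * clo) plus the boundary air layer 1/(f_cl*(hc+hr)).
Evaporation uses the Lewis relation to convert those dry resistances into
vapour resistances, scaled by the clothing permeability index i_cl.
Respiratory loss is the standard sensible+latent function of metabolic
rate, air temperature and humidity, applied at the chest core node.
All coefficients live in the packaged ``coefficients.csv`` table.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .constants import (CLO, KELVIN, MET_W_PER_M2, SIGMA,
                        saturation_vapor_pressure_kpa)
from .environment import Environment

__all__ = [
    "ExchangeCoefficients", "load_coefficients", "SurfaceFluxes",
    "convective_coefficient", "radiative_coefficient",
    "dry_heat_loss", "evaporative_heat_loss", "respiration_loss", "solar_gain",
]


@dataclass(frozen=True)
class ExchangeCoefficients:
    hc_natural_w_per_m2k: float
    hc_forced_coef: float
    hc_forced_exp: float
    hc_activity_coef: float
    hc_activity_exp: float
    hc_activity_threshold_met: float
    emissivity: float
    f_eff_radiation: float
    lewis_k_per_kpa: float
    w_min: float
    solar_absorptance: float
    solar_projected_fraction: float
    solar_clothing_attenuation: float
    res_sensible_coef: float
    res_latent_coef: float
    res_ref_temp_c: float
    res_ref_pressure_kpa: float


def _load_table() -> dict:
    with resources.files("heatstrain.data").joinpath("coefficients.csv").open() as fh:
        df = pd.read_csv(fh)
    return dict(zip(df["name"], df["value"]))


_TABLE = None


def load_coefficients() -> dict:
    """All scalar model coefficients from the packaged table (cached)."""
    global _TABLE
    if _TABLE is None:
        _TABLE = _load_table()
    return dict(_TABLE)


def default_exchange_coefficients() -> ExchangeCoefficients:
    t = load_coefficients()
    return ExchangeCoefficients(
        **{k: t[k] for k in ExchangeCoefficients.__dataclass_fields__})


@dataclass
class SurfaceFluxes:
    """Per-segment surface fluxes (W) plus the respiratory loss."""

    convective_w: np.ndarray
    radiative_w: np.ndarray
    evaporative_w: np.ndarray
    evaporative_max_w: np.ndarray
    solar_w: np.ndarray
    respiration_w: float = 0.0

    @property
    def net_skin_loss_w(self) -> np.ndarray:
        """(C + R) + E - SW per segment, the term entering the skin balance."""
        return (self.convective_w + self.radiative_w
                + self.evaporative_w - self.solar_w)


def convective_coefficient(v_m_s, cf: ExchangeCoefficients | None = None,
                           met_w_m2: float | None = None):
    """Convective coefficient hc, W/m2K.

    The largest of a natural-convection floor, a power law in air
    velocity, and (when a metabolic rate is given) an activity term that
    accounts for the air movement generated by the working body's own
    motion.  The activity term vanishes at rest, so still-air conditions
    at low activity sit on the natural floor.
    """
    cf = cf or default_exchange_coefficients()
    hc = np.maximum(cf.hc_natural_w_per_m2k,
                    cf.hc_forced_coef
                    * np.power(np.maximum(v_m_s, 0.0), cf.hc_forced_exp))
    if met_w_m2 is not None:
        excess = max(met_w_m2 / MET_W_PER_M2 - cf.hc_activity_threshold_met, 0.0)
        hc = np.maximum(hc, cf.hc_activity_coef * excess ** cf.hc_activity_exp)
    return hc


def radiative_coefficient(tr_c, cf: ExchangeCoefficients | None = None):
    """Linearised radiative coefficient hr about the mean radiant temperature."""
    cf = cf or default_exchange_coefficients()
    return (4.0 * cf.emissivity * cf.f_eff_radiation * SIGMA
            * (np.asarray(tr_c, dtype=float) + KELVIN) ** 3)


def dry_heat_loss(tsk_c, env: Environment, clo, f_cl, area_m2,
                  hc=None, hr=None, cf: ExchangeCoefficients | None = None):
    """Convective and radiative loss (C, R) of a segment, W.

    loss = area * (Tsk - Top) / (0.155*clo + 1/(f_cl*(hc+hr))), split into
    C and R in proportion hc:hr.  Positive values are losses to the
    environment.  ``hc``/``hr`` may be supplied explicitly (e.g. measured
    values); otherwise they come from the coefficient table.
    """
    cf = cf or default_exchange_coefficients()
    hc = convective_coefficient(env.v_m_s, cf) if hc is None else hc
    hr = radiative_coefficient(env.mrt_c, cf) if hr is None else hr
    h = hc + hr
    top = (hc * env.ta_c + hr * env.mrt_c) / h
    u = np.asarray(area_m2) / (CLO * np.asarray(clo) + 1.0 / (np.asarray(f_cl) * h))
    total = u * (np.asarray(tsk_c) - top)
    return total * hc / h, total * hr / h


def evaporative_heat_loss(tsk_c, sweat_g_min, env: Environment, clo, f_cl, i_cl,
                          area_m2, hc=None, cf: ExchangeCoefficients | None = None,
                          lambda_j_g: float = 2418.0):
    """Evaporative loss E of a segment, W, and the ceiling Emax.

    Emax = area * (Psat(Tsk) - Pa) / Re with the total vapour resistance
    Re = 0.155*clo/(i_cl*LR) + 1/(LR*hc*f_cl) from the Lewis relation.
    Secreted sweat evaporates up to that ceiling; a skin without sweat
    still loses the minimum diffusion fraction w_min of Emax.

    Returns ``(E, Emax)``.
    """
    cf = cf or default_exchange_coefficients()
    hc = convective_coefficient(env.v_m_s, cf) if hc is None else hc
    lr = cf.lewis_k_per_kpa
    re = CLO * np.asarray(clo) / (np.asarray(i_cl) * lr) + 1.0 / (lr * hc * np.asarray(f_cl))
    gradient = saturation_vapor_pressure_kpa(tsk_c) - env.vapor_pressure_kpa
    emax = np.maximum(np.asarray(area_m2) * gradient / re, 0.0)
    e_sw = lambda_j_g * np.asarray(sweat_g_min) / 60.0
    e = np.minimum((1.0 - cf.w_min) * e_sw + cf.w_min * emax, emax)
    return e, emax


def respiration_loss(metabolic_w: float, env: Environment,
                     cf: ExchangeCoefficients | None = None) -> float:
    """Sensible plus latent respiratory heat loss, W (chest core node).

    RES = 0.0014*M*(34 - Ta) + 0.0173*M*(5.867 - Pa); linear in M, zero
    sensible part at 34 degC and zero latent part at Pa = 5.867 kPa.
    """
    if metabolic_w <= 0:
        raise ValueError("metabolic rate must be positive")
    cf = cf or default_exchange_coefficients()
    return metabolic_w * (
        cf.res_sensible_coef * (cf.res_ref_temp_c - env.ta_c)
        + cf.res_latent_coef * (cf.res_ref_pressure_kpa - env.vapor_pressure_kpa))


def solar_gain(env: Environment, area_m2, clothed,
               cf: ExchangeCoefficients | None = None):
    """Shortwave gain SW per segment, W.

    SW = absorptance * projected-area fraction * area * irradiance,
    attenuated by a transmission factor where the segment is clothed.
    Exactly zero when the irradiance is zero.
    """
    cf = cf or default_exchange_coefficients()
    atten = np.where(np.asarray(clothed, dtype=bool),
                     cf.solar_clothing_attenuation, 1.0)
    return (cf.solar_absorptance * cf.solar_projected_fraction
            * np.asarray(area_m2) * env.solar_w_m2 * atten)


def surface_fluxes(tsk_c, sweat_g_min, env: Environment, ensemble, areas_m2,
                   metabolic_w: float, cf: ExchangeCoefficients | None = None
                   ) -> SurfaceFluxes:
    """Vectorised per-segment fluxes for the full 17-segment body."""
    cf = cf or default_exchange_coefficients()
    clo = ensemble.clo_array
    met_w_m2 = metabolic_w / np.asarray(areas_m2).sum()
    hc = convective_coefficient(env.v_m_s, cf, met_w_m2=met_w_m2)
    c_w, r_w = dry_heat_loss(tsk_c, env, clo, ensemble.f_cl_array, areas_m2,
                             hc=hc, cf=cf)
    e_w, emax = evaporative_heat_loss(tsk_c, sweat_g_min, env, clo,
                                      ensemble.f_cl_array, ensemble.i_cl_array,
                                      areas_m2, hc=hc, cf=cf)
    sw = solar_gain(env, areas_m2, clo > 0, cf=cf)
    res = respiration_loss(metabolic_w, env, cf=cf)
    return SurfaceFluxes(convective_w=c_w, radiative_w=r_w, evaporative_w=e_w,
                         evaporative_max_w=emax, solar_w=sw, respiration_w=res)
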